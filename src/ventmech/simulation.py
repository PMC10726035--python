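"""Forward simulation: predict volume from a pressure program.

The fitted regression maps (V, V') to P; prediction goes the other way.
Each model is discretized fully implicitly on the sampling grid: at step
i the unknown volume V solves

    g(V) = sum_terms(V; history) + P0 - P[i] = 0

with flow approximated by the backward difference (V - V[i-1])/h,
acceleration by (V - 2 V[i-1] + V[i-2])/h^2, and each fractional term by
the GL sum h^(-alpha) (w_0 V + memory(history)), where the memory uses
*previously simulated* volumes — the simulator is self-consistent and
never peeks at measured volume, which is what makes cross-validation a
genuine prediction.  The backward scheme is unconditionally stable for
the positive-coefficient family and first-order accurate; its slope in
V (E + R/h + a h^(-alpha) + ...) is strictly positive for admissible
coefficients, so the per-step root is unique.

Models that are linear in the current volume sample (all integer- and
fractional-order linear models) get a closed-form per-step update;
nonlinear terms (powers, nested exponentials) are handled by a Newton
iteration safeguarded by bracket expansion and bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Mapping

import numpy as np

from .evaluation import EvalMetrics, evaluate
from .fractional import gl_coefficients
from .io import WaveformRecord
from .models import ModelSpec

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import FitResult

__all__ = ["SimulationConfig", "SimulationError", "simulate_volume", "cross_validate"]

_MAX_EXP_ARG = 700.0  # exp argument beyond which doubles overflow


class SimulationError(RuntimeError):
    """Raised when the per-step root solve fails, naming the step."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs of the implicit stepper.

    tol : residual tolerance on |g| in mbar (default 1e-10)
    max_iter : Newton iteration cap before the bisection fallback
    v0 : initial volume in L (default 0; set to the record's first
        measured volume for cross-validation realism)
    memory_window : optional GL short-memory truncation in lags
        (default: full memory)
    """

    tol: float = 1e-10
    max_iter: int = 100
    v0: float = 0.0
    memory_window: int | None = None

    def __post_init__(self) -> None:
        if not (self.tol > 0):
            raise ValueError("tol must be positive")
        if not math.isfinite(self.v0):
            raise ValueError("v0 must be finite")


def _exp_term_factory(
    c: float, x: float, depth: int, with_volume: bool
) -> Callable[[float], tuple[float, float]]:
    """Scalar (value, d/dV) evaluator for c * nested_exp(x V) [* V]."""

    def evaluate_scalar(V: float) -> tuple[float, float]:
        z = x * V
        if z > _MAX_EXP_ARG:
            return math.inf, math.inf
        e1 = math.exp(z)
        val, dval = e1, x * e1  # depth 1 chain
        if depth >= 2:
            if e1 > _MAX_EXP_ARG:
                return math.inf, math.inf
            e2 = math.exp(e1)
            val, dval = e2, e2 * dval
            if depth == 3:
                if e2 > _MAX_EXP_ARG:
                    return math.inf, math.inf
                e3 = math.exp(e2)
                val, dval = e3, e3 * dval
        if with_volume:
            return c * val * V, c * (dval * V + val)
        return c * val, c * dval

    return evaluate_scalar


def simulate_volume(
    pressure: np.ndarray,
    spec: ModelSpec,
    coefficients: np.ndarray,
    ncp_values: Mapping[str, float] | None = None,
    h: float = 0.01,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Simulated volume series driven by ``pressure``.

    ``coefficients`` is the fitted vector in the spec's term order
    (intercept P0 last); ``ncp_values`` supplies fractional orders and
    exponential rates by name.  Returns V-hat with V-hat[0] = v0.
    """
    P = np.asarray(pressure, dtype=float)
    if P.ndim != 1 or P.size < 1:
        raise ValueError("pressure must be a non-empty 1-D series")
    if not np.all(np.isfinite(P)):
        raise ValueError("pressure contains non-finite values")
    A = np.asarray(coefficients, dtype=float)
    if A.shape[0] != len(spec.terms):
        raise ValueError("coefficient vector length does not match spec")
    cfg = config or SimulationConfig()
    ncp = dict(ncp_values or {})
    n = P.size

    # --- compile the step equation --------------------------------------
    lin_slope = 0.0  # d g / dV from terms linear in the current sample
    P0 = 0.0
    flow_coeff = 0.0  # sum of c/h from flow terms
    accel_coeff = 0.0
    frac_terms: list[tuple[float, float, np.ndarray]] = []  # (c*h^-a, h^-a..), see below
    nonlinear: list[Callable[[float, float], tuple[float, float]]] = []

    window = cfg.memory_window
    for term, c in zip(spec.terms, A):
        kind = term.kind
        if kind == "intercept":
            P0 = float(c)
        elif kind == "volume":
            lin_slope += c
        elif kind == "flow":
            flow_coeff += c / h
            lin_slope += c / h
        elif kind == "accel":
            accel_coeff += c / (h * h)
            lin_slope += c / (h * h)
        elif kind == "frac_deriv":
            alpha = float(term.resolve_param(ncp))
            scale = c * h ** (-alpha)
            omega = gl_coefficients(alpha, n if window is None else min(window, n))
            # omega reversed once so per-step memory dots are views
            frac_terms.append((scale, omega[::-1].copy(), float(len(omega) - 1)))
            lin_slope += scale  # w_0 = 1 carries the unknown sample
        elif kind == "poly_volume":
            p = float(term.resolve_param(ncp))
            if p == 1.0:
                lin_slope += c
            else:

                def poly_v(V, Vp, c=c, p=p):
                    return c * V**p, c * p * V ** (p - 1.0)

                nonlinear.append(poly_v)
        elif kind == "poly_flow":
            p = float(term.resolve_param(ncp))
            if p == 1.0:
                flow_coeff += c / h
                lin_slope += c / h
            else:

                def poly_f(V, Vp, c=c, p=p, h=h):
                    q = (V - Vp) / h
                    return c * q**p, c * p * q ** (p - 1.0) / h

                nonlinear.append(poly_f)
        elif kind == "exp_volume":
            x = float(term.resolve_param(ncp))
            f = _exp_term_factory(float(c), x, term.exp_depth, term.includes_volume_factor)
            nonlinear.append(lambda V, Vp, f=f: f(V))
        else:  # pragma: no cover
            raise AssertionError(kind)

    V = np.empty(n)
    V[0] = cfg.v0
    v_prev2 = cfg.v0  # flat pre-history for the acceleration stencil

    for i in range(1, n):
        vp = V[i - 1]
        const = P0 - P[i]
        const -= flow_coeff * vp
        const += accel_coeff * (-2.0 * vp + v_prev2)
        for scale, omega_rev, Jmax in frac_terms:
            L = i if window is None else min(i, int(Jmax))
            # sum_{j=1..L} w_j V[i-j] with both operands as views
            m = len(omega_rev)
            const += scale * float(
                np.dot(omega_rev[m - 1 - L : m - 1], V[i - L : i])
            )

        if not nonlinear:
            V[i] = -const / lin_slope
        else:
            V[i] = _solve_step(lin_slope, const, nonlinear, vp, cfg, i)
        v_prev2 = vp

    return V


def _g(lin_slope, const, nonlinear, vp, V):
    g = lin_slope * V + const
    dg = lin_slope
    for f in nonlinear:
        val, dval = f(V, vp)
        g += val
        dg += dval
    return g, dg


def _solve_step(lin_slope, const, nonlinear, vp, cfg: SimulationConfig, step: int) -> float:
    """Newton from the previous volume, safeguarded by bracket+bisection."""
    x = vp
    for _ in range(cfg.max_iter):
        g, dg = _g(lin_slope, const, nonlinear, vp, x)
        if math.isfinite(g) and abs(g) < cfg.tol:
            return x
        if not (math.isfinite(g) and math.isfinite(dg)) or dg <= 0:
            break
        x_new = x - g / dg
        if not math.isfinite(x_new):
            break
        x = x_new
    else:
        # Newton ran out of iterations; fall through to bisection
        pass

    # bracket around the previous volume; g is increasing for admissible fits
    delta = 1e-6 + 0.1 * abs(vp)
    lo, hi = vp - delta, vp + delta
    glo, _ = _g(lin_slope, const, nonlinear, vp, lo)
    ghi, _ = _g(lin_slope, const, nonlinear, vp, hi)
    for _ in range(60):
        if math.isfinite(glo) and glo <= 0 and math.isfinite(ghi) and ghi >= 0:
            break
        delta *= 2.0
        if glo > 0 or not math.isfinite(glo):
            lo -= delta
            glo, _ = _g(lin_slope, const, nonlinear, vp, lo)
        if ghi < 0 or not math.isfinite(ghi):
            hi += delta
            ghi, _ = _g(lin_slope, const, nonlinear, vp, hi)
    else:
        raise SimulationError(f"step {step}: could not bracket the implicit root")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm, _ = _g(lin_slope, const, nonlinear, vp, mid)
        if math.isfinite(gm) and abs(gm) < cfg.tol:
            return mid
        if not math.isfinite(gm) or gm > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-16 * (1.0 + abs(mid)):
            return mid
    raise SimulationError(f"step {step}: bisection failed to reach tolerance")


def cross_validate(
    fit: "FitResult",
    other: WaveformRecord,
    config: SimulationConfig | None = None,
) -> EvalMetrics:
    """Score a fitted model against a different time period.

    Drives the simulator with ``other``'s pressure using the parameters
    estimated elsewhere, then evaluates against ``other``'s measured
    volume.  With ``other`` equal to the fitting record and the same
    simulation config this reproduces the fit's stored metrics exactly.
    """
    if not fit.admissible:
        raise ValueError("cross-validation requires an admissible fit")
    cfg = config or fit.sim_config or SimulationConfig()
    vhat = simulate_volume(
        other.pressure,
        fit.spec,
        fit.coefficients,
        fit.ncp_values,
        h=other.h,
        config=cfg,
    )
    return evaluate(other.volume, vhat, k=fit.spec.k)
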