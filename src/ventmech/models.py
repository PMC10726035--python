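"""Declarative lumped-parameter lung model family and its design matrices.

Every candidate model relates airway pressure to volume and flow as a
linear combination of (possibly nonlinear) basis terms plus an offset:

    P(t) = a_1 f_1(t) + ... + a_m f_m(t) + P0

where the f_i are built from the measured volume V, flow V' and their
derived quantities (acceleration, fractional derivatives, powers,
nested exponentials).  The coefficients a_i (and the offset P0, which is
the end-expiratory pressure) are linear and solved by least squares;
parameters that enter nonlinearly — a fractional order or an
exponential rate — are "non-coefficient parameters" (NCPs) searched by
particle swarm or an integer grid.

The catalogue covers the classical single-compartment model
(P = E V + R V' + P0), its second-order extension with inertance,
single- and two-term fractional-derivative models, polynomial
elastance/resistance models, nested-exponential elastance models, and
the hybrid model

    P = E V + R V' + a D^alpha V + b e^{e^{beta V}} + P0

which combines the fractional viscoelastic term with a stand-alone
double-exponential volume term.  Note the asymmetry, kept deliberately:
the exponential models' term multiplies V (a e^{e^{xV}} V) while the
hybrid's double exponential stands alone (b e^{e^{beta V}}).

Closed-form step and sinusoid responses of the first-order model and the
tan-form solution of the quadratic model are provided as analytic
oracles for the numerical simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fractional import gl_derivative
from .io import WaveformRecord

__all__ = [
    "ModelTerm",
    "NCP",
    "ModelSpec",
    "DesignMatrixError",
    "predefined_specs",
    "get_spec",
    "build_design_matrix",
    "admissible",
    "resolve_ncp_bounds",
    "nested_exp",
    "step_response_first_order",
    "sine_response_first_order",
    "step_response_quadratic",
]

TERM_KINDS = (
    "volume",
    "flow",
    "accel",
    "frac_deriv",
    "poly_volume",
    "poly_flow",
    "exp_volume",
    "intercept",
)

#: largest admissible innermost exponent so the nested exponential stays
#: finite in double precision: e^{e^{6.5}} ~ 1e288 < realmax
_EXP_SAFE = 6.5


@dataclass(frozen=True)
class ModelTerm:
    """One basis column f_i of the regression.

    ``param`` is either a fixed number (e.g. a polynomial exponent) or
    the *name* of an NCP whose value is filled in at fit time.
    ``label`` is the conventional symbol of the term's coefficient
    (E, R, I, a, b, P0) used in reports.
    """

    kind: str
    label: str
    param: float | str | None = None
    exp_depth: int = 2
    includes_volume_factor: bool = True

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "exp_volume" and self.exp_depth not in (1, 2, 3):
            raise ValueError("exp_depth must be 1, 2 or 3")

    def resolve_param(self, ncp_values: Mapping[str, float]) -> float | None:
        if isinstance(self.param, str):
            try:
                return float(ncp_values[self.param])
            except KeyError:
                raise ValueError(
                    f"term {self.label!r} needs NCP {self.param!r}, not provided"
                ) from None
        return self.param


@dataclass(frozen=True)
class NCP:
    """A nonlinearly-entering parameter with its search box.

    ``ub=None`` means the bound is data-dependent and resolved against a
    record (exponential rates: the bound keeping e^{e^{xV}} finite).
    ``integer_grid`` switches the search from PSO to exhaustive
    enumeration (polynomial exponents).
    """

    name: str
    lb: float = 0.0
    ub: float | None = None
    integer_grid: tuple[int, ...] | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list plus NCP declarations.

    The parameter count k counts every estimated quantity: one per
    term's coefficient (the intercept's P0 included) plus one per NCP —
    the convention under which the published BIC values back-calculate
    consistently.
    """

    name: str
    terms: tuple[ModelTerm, ...]
    ncps: tuple[NCP, ...] = ()

    def __post_init__(self) -> None:
        n_icpt = sum(1 for t in self.terms if t.kind == "intercept")
        if n_icpt != 1:
            raise ValueError("a model spec needs exactly one intercept term")
        if self.terms[-1].kind != "intercept":
            raise ValueError("the intercept must be the last term")
        names = [p.name for p in self.ncps]
        if len(set(names)) != len(names):
            raise ValueError("duplicate NCP names")

    @property
    def k(self) -> int:
        return len(self.terms) + len(self.ncps)

    @property
    def ncp_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.ncps)

    @property
    def coefficient_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def is_linear_in_state(self) -> bool:
        """True if every term is linear in the current volume sample —
        the implicit time-stepper then has a closed-form update."""
        for t in self.terms:
            if t.kind in ("poly_volume", "poly_flow"):
                if isinstance(t.param, str) or t.param != 1:
                    return False
            elif t.kind == "exp_volume":
                return False
        return True


class DesignMatrixError(ValueError):
    """Raised when a basis column evaluates to non-finite values."""


def nested_exp(z: np.ndarray | float, depth: int) -> np.ndarray | float:
    """e^z, e^{e^z} or e^{e^{e^z}} depending on depth."""
    out = z
    for _ in range(depth):
        out = np.exp(out)
    return out


# ---------------------------------------------------------------------------
# catalogue


def predefined_specs() -> dict[str, ModelSpec]:
    """The candidate-model catalogue, addressable by name."""
    V = lambda: ModelTerm("volume", "E")
    F = lambda: ModelTerm("flow", "R")
    I_ = lambda: ModelTerm("intercept", "P0")
    alpha = NCP("alpha", 0.01, 2.0)
    beta_frac = NCP("beta", 0.01, 2.0)
    grid = tuple(range(1, 12))

    specs = [
        ModelSpec("single", (V(), F(), I_())),
        ModelSpec("second_order", (V(), F(), ModelTerm("accel", "I"), I_())),
        ModelSpec(
            "fractional",
            (V(), F(), ModelTerm("frac_deriv", "a", param="alpha"), I_()),
            (alpha,),
        ),
        ModelSpec(
            "fractional2",
            (
                V(),
                F(),
                ModelTerm("frac_deriv", "a", param="alpha"),
                ModelTerm("frac_deriv", "b", param="beta"),
                I_(),
            ),
            (alpha, beta_frac),
        ),
        ModelSpec(
            "poly_vv",
            (
                V(),
                F(),
                ModelTerm("poly_volume", "a", param="x"),
                ModelTerm("poly_flow", "b", param="y"),
                I_(),
            ),
            (NCP("x", integer_grid=grid), NCP("y", integer_grid=grid)),
        ),
        ModelSpec(
            "poly_v",
            (V(), F(), ModelTerm("poly_volume", "a", param="x"), I_()),
            (NCP("x", integer_grid=grid),),
        ),
        ModelSpec(
            "poly_f",
            (V(), F(), ModelTerm("poly_flow", "b", param="y"), I_()),
            (NCP("y", integer_grid=grid),),
        ),
    ]
    for depth, name in ((1, "exp1"), (2, "exp2"), (3, "exp3")):
        specs.append(
            ModelSpec(
                name,
                (
                    V(),
                    ModelTerm("exp_volume", "a", param="x", exp_depth=depth),
                    F(),
                    I_(),
                ),
                (NCP("x", lb=0.0, ub=None),),
            )
        )
    specs.append(
        ModelSpec(
            "hybrid",
            (
                V(),
                F(),
                ModelTerm("frac_deriv", "a", param="alpha"),
                ModelTerm(
                    "exp_volume",
                    "b",
                    param="beta",
                    exp_depth=2,
                    includes_volume_factor=False,
                ),
                I_(),
            ),
            (alpha, NCP("beta", lb=0.0, ub=None)),
        )
    )
    return {s.name: s for s in specs}


def get_spec(name: str) -> ModelSpec:
    catalogue = predefined_specs()
    try:
        return catalogue[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(sorted(catalogue))}"
        ) from None


def resolve_ncp_bounds(
    spec: ModelSpec, record: WaveformRecord
) -> tuple[np.ndarray, np.ndarray]:
    """Concrete (lb, ub) arrays for the spec's NCPs on a given record.

    Exponential rates get the data-dependent cap keeping the nested
    exponential finite: x <= 6.5/max(V) for single/double depth and
    x <= ln(6.5)/max(V) for triple depth.
    """
    vmax = float(np.max(np.abs(record.volume)))
    lbs, ubs = [], []
    for p in spec.ncps:
        ub = p.ub
        if ub is None:
            depth = 2
            for t in spec.terms:
                if t.kind == "exp_volume" and t.param == p.name:
                    depth = t.exp_depth
            cap = _EXP_SAFE if depth <= 2 else math.log(_EXP_SAFE)
            ub = cap / vmax if vmax > 0 else cap
        if not (p.lb < ub):
            raise ValueError(f"NCP {p.name}: lb must be < ub, got [{p.lb}, {ub}]")
        lbs.append(p.lb)
        ubs.append(ub)
    return np.array(lbs), np.array(ubs)


# ---------------------------------------------------------------------------
# design matrix


def _term_column(
    term: ModelTerm, record: WaveformRecord, ncp_values: Mapping[str, float]
) -> np.ndarray:
    V, F, h, n = record.volume, record.flow, record.h, record.n
    if term.kind == "volume":
        return V
    if term.kind == "flow":
        # measured flow, never a numerical derivative of the volume
        return F
    if term.kind == "accel":
        # central differences of measured flow, one-sided at the ends
        return np.gradient(F, h)
    if term.kind == "frac_deriv":
        alpha = term.resolve_param(ncp_values)
        return gl_derivative(V, alpha, h)
    if term.kind == "poly_volume":
        return V ** float(term.resolve_param(ncp_values))
    if term.kind == "poly_flow":
        return F ** float(term.resolve_param(ncp_values))
    if term.kind == "exp_volume":
        x = term.resolve_param(ncp_values)
        with np.errstate(over="ignore"):  # overflow surfaces as DesignMatrixError
            col = nested_exp(x * V, term.exp_depth)
            return col * V if term.includes_volume_factor else np.asarray(col)
    if term.kind == "intercept":
        return np.ones(n)
    raise AssertionError(term.kind)


def build_design_matrix(
    record: WaveformRecord,
    spec: ModelSpec,
    ncp_values: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Regression matrix X (n rows, one column per term, intercept last).

    Columns for linear terms are the record's series verbatim; derived
    columns use central differences (acceleration) or the GL operator
    (fractional terms) on the *measured* channels.

    Raises
    ------
    DesignMatrixError
        If any column contains non-finite entries (typically exponential
        overflow), naming the offending term.
    """
    ncp_values = dict(ncp_values or {})
    cols = []
    for term in spec.terms:
        col = np.asarray(_term_column(term, record, ncp_values), dtype=float)
        if not np.all(np.isfinite(col)):
            raise DesignMatrixError(
                f"non-finite design column for term {term.label!r} "
                f"(kind={term.kind}, param={term.resolve_param(ncp_values)!r})"
            )
        cols.append(col)
    return np.column_stack(cols)


def admissible(coefficients: Sequence[float], spec: ModelSpec | None = None) -> bool:
    """Strict positivity of every coefficient including the offset P0.

    For the integer-order family this is the Routh–Hurwitz stability
    condition; physically, elastance, resistance and PEEP are positive.
    Zero fails: the criterion is strict, with no tolerance.
    """
    A = np.asarray(coefficients, dtype=float)
    if spec is not None and A.shape[0] != len(spec.terms):
        raise ValueError(
            f"coefficient vector length {A.shape[0]} does not match "
            f"spec {spec.name!r} with {len(spec.terms)} terms"
        )
    return bool(np.all(np.isfinite(A)) and np.all(A > 0.0))


# ---------------------------------------------------------------------------
# analytic oracles


def _check_first_order(E: float, R: float) -> None:
    if not (E > 0 and R > 0):
        raise ValueError(f"E and R must be positive, got E={E}, R={R}")


def step_response_first_order(
    E: float,
    R: float,
    P0: float,
    Pc: float,
    times: np.ndarray,
    V0: float = 0.0,
) -> np.ndarray:
    """Volume response of P = E V + R V' + P0 to constant pressure Pc.

    V(t) = (Pc - P0)/E * (1 - e^{-E t / R}) + V0 e^{-E t / R};
    satisfies the ODE exactly, with V(0) = V0 and steady state
    (Pc - P0)/E.
    """
    _check_first_order(E, R)
    t = np.asarray(times, dtype=float)
    decay = np.exp(-E * t / R)
    return (Pc - P0) / E * (1.0 - decay) + V0 * decay


def sine_response_first_order(
    E: float,
    R: float,
    P0: float,
    P_const: float,
    a: float,
    times: np.ndarray,
    K: float | None = None,
    V0: float | None = None,
) -> np.ndarray:
    """General solution of R V' + E V = P_const sin(a t) - P0.

    V(t) = K e^{-t/(C R)} + P_const C / (a^2 C^2 R^2 + 1)
           * (sin at - a C R cos at) - C P0,   with C = 1/E.

    Exactly one of K (the integration constant) or V0 (the initial
    volume, from which K is derived) may be given; default is K = 0.
    """
    _check_first_order(E, R)
    if K is not None and V0 is not None:
        raise ValueError("give either K or V0, not both")
    C = 1.0 / E
    t = np.asarray(times, dtype=float)
    denom = a * a * C * C * R * R + 1.0
    particular = P_const * C / denom * (np.sin(a * t) - a * C * R * np.cos(a * t)) - C * P0
    if V0 is not None:
        part0 = P_const * C / denom * (-a * C * R) - C * P0
        K = V0 - part0
    elif K is None:
        K = 0.0
    return K * np.exp(-t / (C * R)) + particular


def step_response_quadratic(
    E: float,
    R: float,
    a: float,
    P0: float,
    Pc: float,
    times: np.ndarray,
    K: float | None = None,
    V0: float | None = None,
) -> np.ndarray:
    """Tan-form solution of P = E V + R V' + a V^2 + P0 at constant Pc.

    V(t) = [-E + s tan(s (-t + K R) / (2 R))] / (2 a),
    s = sqrt(4 a (P0 - Pc) - E^2).

    Evaluated over the complex field so that the usual physical branch
    (4 a (Pc - P0) > -E^2, where s is imaginary and tan turns into tanh)
    needs no special casing; the imaginary part of the result must
    vanish to rounding.  The steady state solves
    a V^2 + E V + P0 - Pc = 0.

    ``K`` is the integration constant of the printed general solution;
    alternatively give ``V0`` and K is derived from V(0) = V0
    (default V0 = 0).

    Raises on evaluation at (or numerically near) a tan singularity.
    """
    _check_first_order(E, R)
    if a == 0:
        raise ValueError("a must be nonzero; use step_response_first_order for a=0")
    if K is not None and V0 is not None:
        raise ValueError("give either K or V0, not both")
    t = np.asarray(times, dtype=float)
    s = np.sqrt(complex(4.0 * a * (P0 - Pc) - E * E))
    if K is None:
        v0 = 0.0 if V0 is None else float(V0)
        # tan(s K / 2) = (2 a V0 + E) / s
        K = complex(2.0 / s * np.arctan((2.0 * a * v0 + E) / s))
    arg = s * (-t + np.asarray(K) * R) / (2.0 * R)
    V = (-E + s * np.tan(arg)) / (2.0 * a)
    if not np.all(np.isfinite(V.real)) or np.max(np.abs(V.imag)) > 1e-8 * (
        1.0 + np.max(np.abs(V.real))
    ):
        raise FloatingPointError(
            "quadratic step response evaluated at or beyond a tan singularity"
        )
    return V.real
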