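"""Parameter estimation: least squares for coefficients, PSO for NCPs.

Coefficients enter linearly and are solved from the normal equations
A = (X^T X)^{-1} X^T P, with an automatic switch to the pseudo-inverse
(minimal-norm SVD solution) when the design is near-singular — the
nested-exponential columns are prone to producing singular designs.

Non-coefficient parameters (fractional orders, exponential rates) are
searched by a particle swarm: positions initialised uniformly in the
box [LB, UB]^D, velocities in +/-(UB-LB)/2, per-particle and global
best tracking, positions clamped to the boundary when they leave the
box, a fixed number of iterations, fully deterministic given a seed.
The velocity update uses the standard constriction-style constants
(inertia 0.729, cognitive = social = 1.49445), which are configurable.

Each swarm candidate is scored the way the model is ultimately judged:
set the NCPs, solve the coefficients, reject the candidate outright if
any coefficient is non-positive (score +inf; inadmissible fits are
never repaired), otherwise forward-simulate volume from pressure and
take the SSR between measured and simulated volume.  A fast alternative
objective scoring the pressure-regression residual is available but is
not the default, since the models are compared on predicted volume.

Recommended swarm sizes (N particles = M iterations): 5 for the single
fractional model, 10 for the exponential models, 20 for the hybrid —
the points at which repeated runs saturate to a stable optimum.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .evaluation import EvalMetrics, evaluate
from .io import WaveformRecord
from .models import (
    DesignMatrixError,
    ModelSpec,
    admissible,
    build_design_matrix,
    resolve_ncp_bounds,
)
from .simulation import SimulationConfig, SimulationError, simulate_volume

__all__ = [
    "PSOConfig",
    "PSOResult",
    "FitResult",
    "solve_coefficients",
    "pso_optimize",
    "fit_model",
    "default_swarm_size",
]

#: saturation swarm sizes per model family, (particles, iterations)
DEFAULT_SWARM = {
    "fractional": (5, 5),
    "exp1": (10, 10),
    "exp2": (10, 10),
    "exp3": (10, 10),
    "hybrid": (20, 20),
    "fractional2": (20, 20),
}


def default_swarm_size(spec_name: str) -> tuple[int, int]:
    return DEFAULT_SWARM.get(spec_name, (10, 10))


def solve_coefficients(
    X: np.ndarray, P: np.ndarray, rcond_threshold: float = 1e-12
) -> np.ndarray:
    """Least-squares coefficient vector minimising ||X A - P||^2.

    Solves the normal equations when the design is well conditioned;
    below a reciprocal condition of ``rcond_threshold`` (or on a
    numerically singular Gram matrix) it falls back to the SVD
    pseudo-inverse, returning the minimal-norm solution.
    """
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, m = X.shape
    if P.shape[0] != n:
        raise ValueError("row count of X and length of P differ")
    if n < m:
        raise ValueError(f"underdetermined system: {n} rows < {m} columns")

    with np.errstate(all="ignore"):
        cond = np.linalg.cond(X)
    if np.isfinite(cond) and cond > 0 and 1.0 / cond >= rcond_threshold:
        try:
            return np.linalg.solve(X.T @ X, X.T @ P)
        except np.linalg.LinAlgError:
            pass
    return np.linalg.pinv(X) @ P


# ---------------------------------------------------------------------------
# particle swarm


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyper-parameters; ``seed`` governs every random draw."""

    n_particles: int = 10
    n_iterations: int = 10
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")


@dataclass(frozen=True)
class PSOResult:
    position: np.ndarray
    score: float
    trace: np.ndarray  # global best after init and after each iteration
    n_evaluations: int


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    lb: np.ndarray,
    ub: np.ndarray,
    config: PSOConfig | None = None,
) -> PSOResult:
    """Minimise ``objective`` over the box [lb, ub].

    Non-finite objective values are treated as +inf (inadmissible
    candidate).  The returned trace is non-increasing by construction.
    """
    cfg = config or PSOConfig()
    lb = np.atleast_1d(np.asarray(lb, dtype=float))
    ub = np.atleast_1d(np.asarray(ub, dtype=float))
    if lb.shape != ub.shape or np.any(lb >= ub):
        raise ValueError("bounds must satisfy lb < ub elementwise")
    D = lb.size
    rng = np.random.default_rng(cfg.seed)
    span = ub - lb

    def score(x: np.ndarray) -> float:
        val = objective(x)
        return float(val) if math.isfinite(val) else math.inf

    pos = rng.uniform(lb, ub, size=(cfg.n_particles, D))
    vel = rng.uniform(-span / 2.0, span / 2.0, size=(cfg.n_particles, D))
    pbest = pos.copy()
    pbest_score = np.array([score(p) for p in pos])
    g_idx = int(np.argmin(pbest_score))
    gbest = pbest[g_idx].copy()
    gbest_score = float(pbest_score[g_idx])
    trace = [gbest_score]
    evals = cfg.n_particles

    for _ in range(cfg.n_iterations):
        r1 = rng.random((cfg.n_particles, D))
        r2 = rng.random((cfg.n_particles, D))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lb, ub)  # boundary clamping
        for i in range(cfg.n_particles):
            s = score(pos[i])
            evals += 1
            if s < pbest_score[i]:
                pbest_score[i] = s
                pbest[i] = pos[i]
                if s < gbest_score:
                    gbest_score = s
                    gbest = pos[i].copy()
        trace.append(gbest_score)

    return PSOResult(
        position=gbest, score=gbest_score, trace=np.array(trace), n_evaluations=evals
    )


# ---------------------------------------------------------------------------
# full model fit


@dataclass(frozen=True)
class FitResult:
    """An estimated, admissibility-checked, evaluated model fit."""

    spec: ModelSpec
    coefficients: np.ndarray
    ncp_values: dict[str, float]
    admissible: bool
    metrics: EvalMetrics | None
    simulated_volume: np.ndarray | None
    elapsed_seconds: float
    sim_config: SimulationConfig | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.admissible and self.metrics is not None

    @property
    def k(self) -> int:
        return self.spec.k

    def coefficients_by_label(self) -> dict[str, float]:
        return {
            label: float(c)
            for label, c in zip(self.spec.coefficient_labels, self.coefficients)
        }

    def as_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "coefficients": self.coefficients_by_label(),
            "ncp_values": {k: float(v) for k, v in self.ncp_values.items()},
            "admissible": self.admissible,
            "k": self.k,
            "metrics": self.metrics.as_dict() if self.metrics else None,
            "elapsed_seconds": self.elapsed_seconds,
            "provenance": self.provenance,
        }


def fit_model(
    record: WaveformRecord,
    spec: ModelSpec,
    pso: PSOConfig | None = None,
    sim_config: SimulationConfig | None = None,
    objective: str = "simulation",
    seed: int | None = None,
) -> FitResult:
    """Estimate a model on one record.

    Without NCPs this is a single least-squares solve; integer-grid NCPs
    (polynomial exponents) are enumerated exhaustively; continuous NCPs
    are searched by PSO with the model family's saturation swarm size
    unless a ``pso`` config is given.  Candidates whose coefficients are
    not strictly positive score +inf.  The winning candidate is re-
    evaluated to produce the stored simulated series and metrics.

    ``objective`` selects the candidate score: "simulation" (default)
    simulates volume from pressure and scores SSR on volume;
    "pressure" scores the regression residual ||X A - P||^2 instead
    (fast screening only).
    """
    if objective not in ("simulation", "pressure"):
        raise ValueError("objective must be 'simulation' or 'pressure'")
    t_start = time.perf_counter()
    cfg = sim_config or SimulationConfig()

    def candidate_score(ncp_values: Mapping[str, float]) -> tuple[float, np.ndarray | None]:
        try:
            X = build_design_matrix(record, spec, ncp_values)
        except DesignMatrixError:
            return math.inf, None
        A = solve_coefficients(X, record.pressure)
        if not admissible(A):
            return math.inf, A
        if objective == "pressure":
            resid = X @ A - record.pressure
            return float(resid @ resid), A
        try:
            vhat = simulate_volume(
                record.pressure, spec, A, ncp_values, h=record.h, config=cfg
            )
        except (SimulationError, FloatingPointError, OverflowError):
            return math.inf, A
        diff = record.volume - vhat
        return float(diff @ diff), A

    names = spec.ncp_names
    provenance: dict = {"objective": objective, "n_samples": record.n, "h": record.h}
    best_ncps: dict[str, float] = {}
    pso_result = None

    if not names:
        score, _ = candidate_score({})
    elif all(p.integer_grid is not None for p in spec.ncps):
        best = (math.inf, None)
        for combo in itertools.product(*(p.integer_grid for p in spec.ncps)):
            vals = dict(zip(names, (float(c) for c in combo)))
            s, _ = candidate_score(vals)
            if s < best[0]:
                best = (s, vals)
        score, best_ncps = best[0], best[1] or {
            n: float(p.integer_grid[0]) for n, p in zip(names, spec.ncps)
        }
        provenance["search"] = "integer_grid"
    else:
        lb, ub = resolve_ncp_bounds(spec, record)
        if pso is None:
            npart, niter = default_swarm_size(spec.name)
            pso = PSOConfig(n_particles=npart, n_iterations=niter, seed=seed)
        elif pso.seed is None and seed is not None:
            pso = PSOConfig(
                n_particles=pso.n_particles,
                n_iterations=pso.n_iterations,
                inertia=pso.inertia,
                cognitive=pso.cognitive,
                social=pso.social,
                seed=seed,
            )
        pso_result = pso_optimize(
            lambda x: candidate_score(dict(zip(names, x)))[0], lb, ub, pso
        )
        score = pso_result.score
        best_ncps = dict(zip(names, (float(v) for v in pso_result.position)))
        provenance.update(
            search="pso",
            pso={
                "n_particles": pso.n_particles,
                "n_iterations": pso.n_iterations,
                "seed": pso.seed,
                "bounds": [list(map(float, lb)), list(map(float, ub))],
            },
            pso_trace=[float(v) for v in pso_result.trace],
        )

    # re-evaluate the winner for the stored series and metrics
    elapsed = lambda: time.perf_counter() - t_start
    if not math.isfinite(score):
        try:
            X = build_design_matrix(record, spec, best_ncps)
            A = solve_coefficients(X, record.pressure)
        except DesignMatrixError:
            A = np.full(len(spec.terms), math.nan)
        return FitResult(
            spec=spec,
            coefficients=A,
            ncp_values=best_ncps,
            admissible=False,
            metrics=None,
            simulated_volume=None,
            elapsed_seconds=elapsed(),
            sim_config=cfg,
            provenance=provenance | {"failure": "no admissible candidate"},
        )

    X = build_design_matrix(record, spec, best_ncps)
    A = solve_coefficients(X, record.pressure)
    vhat = simulate_volume(record.pressure, spec, A, best_ncps, h=record.h, config=cfg)
    metrics = evaluate(record.volume, vhat, k=spec.k)
    return FitResult(
        spec=spec,
        coefficients=A,
        ncp_values=best_ncps,
        admissible=True,
        metrics=metrics,
        simulated_volume=vhat,
        elapsed_seconds=elapsed(),
        sim_config=cfg,
        provenance=provenance,
    )
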