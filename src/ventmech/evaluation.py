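"""Goodness-of-fit metrics and model comparison.

All scores are computed between the measured volume V and the volume
V-hat produced by forward simulation from pressure:

    SSR      = sum (V_i - Vhat_i)^2                      [L^2]
    RMSE     = sqrt(SSR / n)                             [L]
    CV(RMSE) = RMSE / mean(V)                            [-]
    BIC      = n ln(SSR) + k ln(n)                       [-]

The BIC is the "equivalent" simplified form obtained by dropping the
constants of the Gaussian-residual likelihood — note ln(SSR), not the
classical ln(SSR/n); natural logarithm throughout.  k counts every
estimated quantity: linear coefficients, the offset P0, and each
swarm-searched non-coefficient parameter.  Models are ranked ascending
by BIC with SSR as the tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import FitResult

__all__ = [
    "EvalMetrics",
    "ssr",
    "rmse",
    "cv_rmse",
    "bic",
    "pearson",
    "evaluate",
    "compare_models",
    "render_comparison",
]


def _pair(measured, simulated) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(measured, dtype=float)
    vh = np.asarray(simulated, dtype=float)
    if v.shape != vh.shape or v.ndim != 1:
        raise ValueError(f"series length mismatch: {v.shape} vs {vh.shape}")
    return v, vh


def ssr(measured, simulated) -> float:
    """Sum of squared residuals, L^2."""
    v, vh = _pair(measured, simulated)
    return float(np.sum((v - vh) ** 2))


def rmse(measured, simulated) -> float:
    """Root mean square error sqrt(SSR/n), L."""
    v, vh = _pair(measured, simulated)
    if v.size == 0:
        raise ValueError("empty series")
    return math.sqrt(ssr(v, vh) / v.size)


def cv_rmse(measured, simulated) -> float:
    """Coefficient of variation of the RMSE: RMSE / mean measured volume."""
    v, vh = _pair(measured, simulated)
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("mean measured volume is zero; CV(RMSE) undefined")
    return rmse(v, vh) / mean


def bic(n: int, ssr_value: float, k: int) -> float:
    """Equivalent Bayesian information criterion n ln(SSR) + k ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if not (ssr_value > 0):
        raise ValueError(f"SSR must be positive, got {ssr_value}")
    return n * math.log(ssr_value) + k * math.log(n)


def pearson(measured, simulated) -> float:
    """Sample Pearson correlation between measured and simulated volume."""
    v, vh = _pair(measured, simulated)
    if np.ptp(v) == 0 or np.ptp(vh) == 0:
        raise ValueError("Pearson correlation undefined for a constant series")
    return float(np.corrcoef(v, vh)[0, 1])


@dataclass(frozen=True)
class EvalMetrics:
    """Bundle of all scores for one fit on one record."""

    ssr: float
    rmse: float
    cv_rmse: float
    bic: float
    pearson_r: float
    n: int
    k: int

    def as_dict(self) -> dict:
        return {
            "SSR": self.ssr,
            "RMSE": self.rmse,
            "CV_RMSE": self.cv_rmse,
            "BIC": self.bic,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "k": self.k,
        }


def evaluate(measured, simulated, k: int) -> EvalMetrics:
    """All metrics at once.

    Degenerate edge cases are reported rather than raised: a perfect fit
    (SSR = 0) yields BIC = -inf, and a constant simulated series yields
    a NaN correlation.
    """
    v, vh = _pair(measured, simulated)
    s = ssr(v, vh)
    r = rmse(v, vh)
    cv = cv_rmse(v, vh) if np.mean(v) != 0 else math.nan
    b = bic(v.size, s, k) if s > 0 else -math.inf
    try:
        pr = pearson(v, vh)
    except ValueError:
        pr = math.nan
    return EvalMetrics(ssr=s, rmse=r, cv_rmse=cv, bic=b, pearson_r=pr, n=v.size, k=k)


def compare_models(fits: Sequence["FitResult"]) -> pd.DataFrame:
    """Ranked comparison table, ascending BIC, ties broken by SSR.

    All fits must have been evaluated on the same record (same n).
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.metrics.n for f in fits if f.metrics is not None}
    if len(ns) > 1:
        raise ValueError(f"fits evaluated on records of different length: {sorted(ns)}")
    rows = []
    for f in fits:
        m = f.metrics
        rows.append(
            {
                "model": f.spec.name,
                "BIC": m.bic if m else math.inf,
                "SSR": m.ssr if m else math.inf,
                "RMSE": m.rmse if m else math.nan,
                "CV_RMSE": m.cv_rmse if m else math.nan,
                "r": m.pearson_r if m else math.nan,
                "k": f.spec.k,
                "time_s": f.elapsed_seconds,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["BIC", "SSR"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def render_comparison(df: pd.DataFrame) -> str:
    """Aligned text table of a comparison DataFrame."""
    return df.to_string(
        index=False,
        float_format=lambda x: f"{x:.4f}",
        justify="right",
    )
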