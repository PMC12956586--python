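"""Statistical process control and rater concordance for a multi-site network.

EWMA chart
----------
Per-site lesion-volume series are monitored with an exponentially weighted
moving average, M_i = lambda * x_i + (1 - lambda) * M_{i-1}, started at the
process target M_o (the network-wide certification mean). Recent observations
carry more weight. Control limits are time-varying,

    M_o +/- L * V_i,   V_i^2 = sigma0^2 * (1 - (1-lambda)^(2i)) * lambda / (2 - lambda),

with sigma0^2 the certification variance; V_i grows from lambda*sigma0 at the
first observation toward the asymptote sigma0*sqrt(lambda/(2-lambda)).
Defaults lambda = 0.15 and L = 3.

Rater concordance
-----------------
Agreement among blinded video raters is quantified with the two-way
random-effects, absolute-agreement, single-rater intraclass correlation
ICC(A,1), estimated from the two-way ANOVA mean squares with the standard
F-distribution confidence bounds (McGraw & Wong). An optional adjustment
residualizes scores on covariate factors (e.g. time point, intervention)
before computing the ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "EwmaChart",
    "IccResult",
    "ewma_series",
    "ewma_limits",
    "ewma_chart",
    "flag_out_of_control",
    "icc_concordance",
]

DEFAULT_LAMBDA = 0.15
DEFAULT_L = 3.0


def _check_lambda(lam: float) -> None:
    if not 0 < lam <= 1:
        raise InvalidParameterError(f"lambda must be in (0, 1], got {lam}")


def ewma_series(observations: Sequence[float], center: float, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Exponentially weighted moving averages M_1..M_n started at the center."""
    _check_lambda(lam)
    x = np.asarray(observations, dtype=float)
    out = np.empty_like(x)
    prev = center
    for i, xi in enumerate(x):
        prev = lam * xi + (1.0 - lam) * prev
        out[i] = prev
    return out


def ewma_limits(
    sigma0: float,
    center: float,
    lam: float = DEFAULT_LAMBDA,
    L: float = DEFAULT_L,
    i=1,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-varying control limits center +/- L*V_i at step(s) i (1-based)."""
    _check_lambda(lam)
    if sigma0 < 0:
        raise InvalidParameterError("sigma0 must be nonnegative")
    steps = np.asarray(i, dtype=float)
    if np.any(steps < 1):
        raise InvalidParameterError("steps must be >= 1")
    v = sigma0 * np.sqrt((1.0 - (1.0 - lam) ** (2.0 * steps)) * lam / (2.0 - lam))
    return center - L * v, center + L * v


@dataclass(frozen=True)
class EwmaChart:
    """One site's chart: observations, moving averages, limits and flags."""

    center: float
    sigma0: float
    lam: float
    L: float
    observations: np.ndarray
    means: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def flags(self) -> np.ndarray:
        return (self.means < self.lower) | (self.means > self.upper)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, len(self.observations) + 1),
                "observation": self.observations,
                "ewma": self.means,
                "lower": self.lower,
                "upper": self.upper,
                "flag": self.flags,
            }
        )


def ewma_chart(
    observations: Sequence[float],
    center: float,
    sigma0: float,
    lam: float = DEFAULT_LAMBDA,
    L: float = DEFAULT_L,
) -> EwmaChart:
    """Assemble a full EWMA chart for one observation series."""
    x = np.asarray(observations, dtype=float)
    means = ewma_series(x, center, lam)
    steps = np.arange(1, len(x) + 1)
    if len(x):
        lower, upper = ewma_limits(sigma0, center, lam, L, steps)
    else:
        lower = upper = np.empty(0)
    return EwmaChart(center, sigma0, lam, L, x, means, lower, upper)


def flag_out_of_control(chart: EwmaChart) -> tuple[np.ndarray, int | None]:
    """Out-of-control flags and the first excursion index (0-based), if any."""
    flags = chart.flags
    first = int(np.argmax(flags)) if flags.any() else None
    return flags, first


# ---------------------------------------------------------------------------
# Inter-rater concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    confidence: float = 0.95


def _to_grid(ratings: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Coerce ratings to a complete subjects x raters grid.

    Accepts a wide frame/array (rows = subjects, columns = raters) or a long
    frame with columns ``subject, rater, score``.
    """
    if isinstance(ratings, pd.DataFrame) and {"subject", "rater", "score"} <= set(
        ratings.columns
    ):
        dup = ratings.duplicated(["subject", "rater"])
        if dup.any():
            raise InvalidParameterError("duplicate subject x rater scores")
        grid = ratings.pivot(index="subject", columns="rater", values="score")
        values = grid.to_numpy(dtype=float)
    else:
        values = np.asarray(ratings, dtype=float)
    if values.ndim != 2:
        raise InvalidParameterError("ratings must form a 2-d subjects x raters grid")
    if np.isnan(values).any():
        raise InvalidParameterError("ratings grid has missing cells")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InvalidParameterError("need at least 2 subjects and 2 raters")
    return values


def _residualize(ratings: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Remove additive covariate factor effects, keeping the grand mean."""
    out = ratings.copy()
    grand = out["score"].mean()
    resid = out["score"].astype(float)
    for cov in covariates:
        if cov not in out.columns:
            raise InvalidParameterError(f"covariate column '{cov}' not in ratings")
        resid = resid - resid.groupby(out[cov]).transform("mean") + resid.mean()
    out["score"] = resid - resid.mean() + grand
    return out


def icc_concordance(
    ratings: pd.DataFrame | np.ndarray,
    confidence: float = 0.95,
    adjust_for: Sequence[str] | None = None,
) -> IccResult:
    """Two-way random-effects absolute-agreement single-rater ICC with CI.

    Computed from the two-way ANOVA mean squares; the confidence interval
    uses the F bounds with a Satterthwaite denominator degrees-of-freedom
    approximation. ``adjust_for`` optionally residualizes long-format scores
    on covariate factors first (an interpretation choice: the resulting
    coefficient measures agreement net of those factors).
    """
    if adjust_for:
        if not isinstance(ratings, pd.DataFrame) or "score" not in ratings.columns:
            raise InvalidParameterError("covariate adjustment needs a long-format frame")
        ratings = _residualize(ratings, adjust_for)
    y = _to_grid(ratings)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return IccResult(float("nan"), float("nan"), float("nan"), n, k, confidence)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if msc == 0 and mse == 0:
        # perfect agreement: no rater or residual variance
        return IccResult(icc, icc, icc, n, k, confidence)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else float("inf")
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else float("inf")
    if not math.isfinite(a):
        return IccResult(icc, icc, icc, n, k, confidence)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return IccResult(float(icc), float(lower), float(upper), n, k, confidence)
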