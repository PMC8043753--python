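"""Allometric and chronological inference on risk summaries.

Ordinary least-squares fits of risk measures against log10 body mass or
log10 generation length, compared against an intercept-only model with
small-sample-corrected information-criterion (AICc) evidence ratios, plus
rank-correlation tests of risk against the extinction chronology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "ExtinctionWindow",
    "ConcordanceReport",
    "aicc",
    "fit_allometry",
    "chronology_concordance",
    "outlier_sensitivity",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    evidence_ratio: float
    n: int
    slope_se: float
    aicc_slope: float
    aicc_null: float


@dataclass(frozen=True)
class ExtinctionWindow:
    """Bounds of a species' estimated extinction window, in thousands of
    years before present (so earliest >= latest)."""

    species: str
    earliest_ka: float
    latest_ka: float

    def __post_init__(self) -> None:
        if self.earliest_ka < self.latest_ka:
            raise ValueError(
                f"{self.species}: earliest_ka must be >= latest_ka (ka counts backwards)"
            )

    @property
    def midpoint_ka(self) -> float:
        return 0.5 * (self.earliest_ka + self.latest_ka)


@dataclass(frozen=True)
class ConcordanceReport:
    """Rank correlation and OLS of a risk measure against extinction date."""

    n: int
    spearman_rho: float
    spearman_p: float
    ols: RegressionResult
    permutation_p: float | None = None


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    Falls back to the uncorrected criterion when the correction
    denominator n - k - 1 is non-positive (n <= k + 1).
    """
    base = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return base
    return base + 2.0 * k * (k + 1) / (n - k - 1)


def fit_allometry(x, y) -> RegressionResult:
    """OLS of y on x with an AICc evidence ratio against intercept-only.

    The evidence ratio is the AICc weight of the slope model divided by
    the weight of the intercept-only model; values > 1 favour a
    relationship. Gaussian likelihoods, sigma counted as a parameter
    (k = 3 vs k = 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    dof = n - 2
    if dof > 0 and ss_res > 0:
        sigma2_hat = ss_res / dof
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = math.sqrt(sigma2_hat / sxx)
    else:
        slope_se = 0.0
    a_slope = aicc(_gaussian_loglik(resid), 3, n)
    a_null = aicc(_gaussian_loglik(y - y.mean()), 2, n)
    # ER = w_slope / w_null = exp((AICc_null - AICc_slope) / 2)
    er = math.exp(min((a_null - a_slope) / 2.0, 700.0))
    return RegressionResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r_squared=r2,
        evidence_ratio=er,
        n=n,
        slope_se=slope_se,
        aicc_slope=a_slope,
        aicc_null=a_null,
    )


def chronology_concordance(
    windows: list[ExtinctionWindow],
    risk: dict[str, float] | np.ndarray,
    n_permutations: int = 0,
    seed: int = 0,
    date_bound: str = "midpoint",
) -> ConcordanceReport:
    """Does risk predict when species went extinct?

    Computes the Spearman rank correlation and the OLS/evidence-ratio fit
    of extinction date (ka before present, per ``date_bound``:
    midpoint, earliest, or latest) against the risk measure for the
    windowed (extinct) species. Optionally adds a permutation p-value for
    the rank correlation.
    """
    if len(windows) < 3:
        raise ValueError("need at least 3 extinct species with windows")
    if isinstance(risk, dict):
        missing = [w.species for w in windows if w.species not in risk]
        if missing:
            raise ValueError(f"risk measure missing for: {missing}")
        r = np.array([float(risk[w.species]) for w in windows])
    else:
        r = np.asarray(risk, dtype=float)
        if len(r) != len(windows):
            raise ValueError("risk vector length does not match windows")
    if date_bound == "midpoint":
        dates = np.array([w.midpoint_ka for w in windows])
    elif date_bound == "earliest":
        dates = np.array([w.earliest_ka for w in windows])
    elif date_bound == "latest":
        dates = np.array([w.latest_ka for w in windows])
    else:
        raise ValueError(f"unknown date_bound {date_bound!r}")

    rho, p = stats.spearmanr(r, dates)
    ols = fit_allometry(r, dates)
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = abs(rho)
        count = 0
        for _ in range(n_permutations):
            perm_rho, _ = stats.spearmanr(rng.permutation(r), dates)
            if abs(perm_rho) >= obs:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
    return ConcordanceReport(
        n=len(windows),
        spearman_rho=float(rho),
        spearman_p=float(p),
        ols=ols,
        permutation_p=perm_p,
    )


def outlier_sensitivity(
    x, y, labels: list[str], drop_labels: list[str]
) -> tuple[RegressionResult, RegressionResult]:
    """Full-data fit alongside the fit with ``drop_labels`` removed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not set(drop_labels) <= set(labels):
        unknown = sorted(set(drop_labels) - set(labels))
        raise ValueError(f"drop_labels not in labels: {unknown}")
    keep = np.array([lab not in set(drop_labels) for lab in labels])
    if keep.sum() < 3:
        raise ValueError("dropping labels leaves fewer than 3 points")
    return fit_allometry(x, y), fit_allometry(x[keep], y[keep])
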