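"""Causal estimators and pleiotropy diagnostics for two-sample MR.

Given J harmonized instruments with SNP-exposure effects gamma_j (SE
sigma_Xj) and SNP-outcome effects Gamma_j (SE sigma_Yj), the per-SNP Wald
ratio Gamma_j / gamma_j estimates the causal effect under the instrumental
variable assumptions.  This module pools those ratios:

* **IVW-MRE** — inverse-variance-weighted meta-analysis, equivalent to
  weighted regression of Gamma on gamma through the origin with weights
  1/sigma_Y^2; the multiplicative random-effects variant inflates the SE by
  the residual overdispersion sqrt(Q/(J-1)) when Cochran's Q exceeds its
  expectation (floored at the fixed-effect SE).
* **Weighted median** — the 50% weighted quantile of ordered Wald ratios;
  consistent when instruments carrying at least half the weight are valid.
  SE by seeded parametric bootstrap.
* **MR-Egger** — weighted regression of Gamma on gamma *with* an intercept;
  the slope is the causal estimate, the intercept the average directional
  pleiotropy, valid when pleiotropy is independent of instrument strength
  (InSIDE).  I-squared(GX) quantifies the relative measurement-error-free
  variation in gamma-hat (the "NO Measurement Error" diagnostic).

All estimators operate on the log-odds (binary outcome) or raw-unit
(continuous outcome) scale; exponentiation to odds ratios happens at
reporting time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInstrumentError, EstimationError
from .instruments import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal estimate with its diagnostics.

    ``beta`` is on the log-OR scale for binary outcomes (``or_scale=True``)
    and in raw units (mean difference) for continuous ones.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_scale: bool = False
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    i2_gx: float | None = None
    i2_gx_raw: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.method}: se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(f"{self.method}: CI does not bracket the estimate")

    @property
    def odds_ratio(self) -> float | None:
        return math.exp(self.beta) if self.or_scale else None

    @property
    def or_ci(self) -> tuple[float, float] | None:
        if not self.or_scale:
            return None
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _normal_summary(beta: float, se: float) -> tuple[float, float, float]:
    """95% normal CI bounds and two-sided p for a point estimate."""
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return beta - Z95 * se, beta + Z95 * se, float(p)


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def wald_ratio(
    gamma_hat: float, sigma_x: float, Gamma_hat: float, sigma_y: float
) -> tuple[float, float]:
    """Per-SNP causal estimate Gamma/gamma with first-order SE sigma_Y/|gamma|."""
    if gamma_hat == 0:
        raise DegenerateInstrumentError("SNP-exposure effect is zero; Wald ratio undefined")
    return Gamma_hat / gamma_hat, sigma_y / abs(gamma_hat)


def _first_order_weights(s: HarmonizedInstrumentSet) -> np.ndarray:
    """Inverse-variance weights of the Wald ratios, gamma^2 / sigma_Y^2."""
    return (s.gamma_hat / s.sigma_y) ** 2


def cochran_q(s: HarmonizedInstrumentSet, beta: float) -> tuple[float, float]:
    """Cochran's Q of the per-SNP Wald ratios around a pooled estimate.

    Uses first-order weights gamma^2/sigma_Y^2; p from chi-squared with J-1
    degrees of freedom.
    """
    if s.J < 2:
        raise EstimationError("Cochran's Q requires at least 2 instruments")
    ratios = s.Gamma_hat / s.gamma_hat
    w = _first_order_weights(s)
    q = float(np.sum(w * (ratios - beta) ** 2))
    p = float(stats.chi2.sf(q, df=s.J - 1))
    return q, p


def ivw_mre(s: HarmonizedInstrumentSet, or_scale: bool = False) -> MREstimate:
    """IVW with multiplicative random effects.

    beta = sum(w_j r_j) / sum(w_j) over Wald ratios r_j with weights
    w_j = gamma_j^2 / sigma_Yj^2 — algebraically the origin-constrained WLS
    slope of Gamma on gamma with weights 1/sigma_Y^2.  The SE is the
    fixed-effect SE inflated by sqrt(phi) where the overdispersion
    phi = Q/(J-1) is floored at 1, so heterogeneity beyond its expectation
    widens the CI but can never shrink it.

    With a single instrument the estimate degrades to the Wald ratio (with a
    warning); Q is then undefined.
    """
    if s.J == 0:
        raise EstimationError("IVW requires at least 1 instrument")
    w = 1.0 / s.sigma_y**2
    sxx = float(np.sum(w * s.gamma_hat**2))
    sxy = float(np.sum(w * s.gamma_hat * s.Gamma_hat))
    beta = sxy / sxx
    if s.J == 1:
        logger.warning("single instrument: IVW degrades to the Wald ratio")
        b, se = wald_ratio(s.gamma_hat[0], s.sigma_x[0], s.Gamma_hat[0], s.sigma_y[0])
        lo, hi, p = _normal_summary(b, se)
        return MREstimate("ivw", b, se, lo, hi, p, 1, or_scale=or_scale)
    q, q_p = cochran_q(s, beta)
    phi = max(1.0, q / (s.J - 1))
    se = math.sqrt(phi / sxx)
    lo, hi, p = _normal_summary(beta, se)
    return MREstimate(
        "ivw", beta, se, lo, hi, p, s.J, or_scale=or_scale, q_stat=q, q_pvalue=q_p
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the weighted 50% quantile of ratios.

    With normalized weights w_(j) in ratio order, the cumulative midpoint of
    SNP j is s_j = sum_{k<=j} w_(k) - w_(j)/2; the estimate linearly
    interpolates the ordered ratios at s = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(
    s: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    or_scale: bool = False,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Weights are the first-order inverse variances gamma^2/sigma_Y^2.  The
    bootstrap redraws gamma* ~ N(gamma_hat, sigma_X) and
    Gamma* ~ N(Gamma_hat, sigma_Y) independently (two-sample structure),
    recomputes the weighted median, and takes the SD across ``n_boot``
    replicates; the seed is mandatory-by-default via NumPy's Generator for
    reproducibility.
    """
    if s.J < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    ratios = s.Gamma_hat / s.gamma_hat
    weights = _first_order_weights(s)
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(s.gamma_hat, s.sigma_x, size=(n_boot, s.J))
    G_star = rng.normal(s.Gamma_hat, s.sigma_y, size=(n_boot, s.J))
    r_star = G_star / g_star
    w_star = (g_star / s.sigma_y) ** 2
    # Vectorized row-wise interpolated weighted median.
    order = np.argsort(r_star, axis=1, kind="stable")
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    w_sorted /= w_sorted.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp is 1-D; rows are small
        boots[i] = np.interp(0.5, cum[i], r_sorted[i])
    se = float(boots.std(ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    lo, hi, p = _normal_summary(beta, se)
    return MREstimate("weighted_median", beta, se, lo, hi, p, s.J, or_scale=or_scale)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def i_squared_gx(s: HarmonizedInstrumentSet, oriented_gamma: np.ndarray | None = None) -> tuple[float, float]:
    """I-squared(GX): relative measurement-error-free variation in gamma-hat.

    Q_GX = sum_j (gamma_j - gamma_bar_w)^2 / sigma_Xj^2 with the
    1/sigma_X^2-weighted mean gamma_bar_w; I2 = (Q_GX - (J-1)) / Q_GX.
    Returns (clipped-at-0, raw).  Values near 1 support MR-Egger's
    no-measurement-error assumption; low values signal regression-dilution
    attenuation of the Egger slope.
    """
    g = s.gamma_hat if oriented_gamma is None else oriented_gamma
    wx = 1.0 / s.sigma_x**2
    gbar = float(np.sum(wx * g) / np.sum(wx))
    q_gx = float(np.sum((g - gbar) ** 2 / s.sigma_x**2))
    if q_gx == 0:
        return 0.0, -math.inf
    raw = (q_gx - (s.J - 1)) / q_gx
    return max(0.0, raw), raw


def mr_egger(s: HarmonizedInstrumentSet, or_scale: bool = False) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma = b0 + b1 * gamma.

    Each SNP is first oriented so its exposure effect is non-negative
    (negating both gamma and Gamma where needed — a sign convention, not a
    data change).  Weights are 1/sigma_Y^2; coefficient SEs carry a
    multiplicative overdispersion max(1, chi2_resid/(J-2)) and normal
    reference.  The slope estimates the causal effect under InSIDE; an
    intercept distinguishable from zero indicates directional pleiotropy.
    """
    if s.J < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    sign = np.where(s.gamma_hat < 0, -1.0, 1.0)
    x = s.gamma_hat * sign
    y = s.Gamma_hat * sign
    w = 1.0 / s.sigma_y**2

    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swy = float(np.sum(w * y))
    swxx = float(np.sum(w * x * x))
    swxy = float(np.sum(w * x * y))
    denom = sw * swxx - swx**2
    if denom <= 0 or np.ptp(x) == 0:
        raise EstimationError("zero variance in oriented gamma-hat; Egger slope undefined")
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw

    resid = y - intercept - slope * x
    chi2_resid = float(np.sum(w * resid**2))
    phi = max(1.0, chi2_resid / (s.J - 2))
    se_slope = math.sqrt(phi * sw / denom)
    se_intercept = math.sqrt(phi * swxx / denom)

    lo, hi, p = _normal_summary(slope, se_slope)
    _, _, p_int = _normal_summary(intercept, se_intercept)
    i2, i2_raw = i_squared_gx(s, oriented_gamma=x)
    return MREstimate(
        "egger", slope, se_slope, lo, hi, p, s.J, or_scale=or_scale,
        q_stat=chi2_resid, q_pvalue=float(stats.chi2.sf(chi2_resid, df=s.J - 2)),
        egger_intercept=intercept, egger_intercept_se=se_intercept,
        egger_intercept_pvalue=p_int, i2_gx=i2, i2_gx_raw=i2_raw,
    )


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def estimate_all(
    s: HarmonizedInstrumentSet,
    trait_type: str = "binary",
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, MREstimate | None]:
    """Run every estimator whose instrument-count precondition holds.

    Returns a mapping method -> estimate; methods whose J requirement fails
    map to None (reported "not applicable" rather than raising).  Estimates
    carry ``or_scale=True`` for binary outcomes so reporting exponentiates
    them to odds ratios; continuous outcomes stay on the mean-difference
    scale.
    """
    or_scale = trait_type == "binary"
    out: dict[str, MREstimate | None] = {}
    out["ivw"] = ivw_mre(s, or_scale=or_scale)
    if s.J >= 3:
        out["weighted_median"] = weighted_median(s, n_boot=n_boot, seed=seed, or_scale=or_scale)
        out["egger"] = mr_egger(s, or_scale=or_scale)
    else:
        out["weighted_median"] = None
        out["egger"] = None
    return out
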