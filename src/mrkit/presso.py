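"""MR-PRESSO: pleiotropy residual sum and outlier test.

The global test asks whether the observed residual sum of squares (RSS) of
the instruments around the IVW fit is larger than expected under a
pleiotropy-free model.  Each SNP's residual is measured against the
leave-one-out IVW estimate (so a pleiotropic SNP cannot mask itself), and
the null distribution of the RSS is built by parametric simulation:
redraw gamma* ~ N(gamma_hat, sigma_X) and Gamma* ~ N(beta_loo * gamma_hat,
sigma_Y), recompute the RSS, and compare.  Per-SNP versions of the same
comparison flag individual outliers (Bonferroni-adjusted across the J
tests); the outlier-corrected estimate is plain IVW-MRE on the remaining
instruments, and the distortion test asks whether removing the flagged SNPs
moved the estimate more than removing an equally sized random subset would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .estimators import MREstimate, ivw_mre
from .instruments import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)


@dataclass
class PressoSimulations:
    """Observed and simulated per-SNP residual terms from the global test."""

    obs_terms: np.ndarray        # (J,) observed weighted squared residuals
    sim_terms: np.ndarray        # (n_sim, J) simulated counterparts
    n_sim: int


@dataclass
class PressoResult:
    """Full MR-PRESSO output for one instrument set."""

    global_rss: float
    global_pvalue: float
    outliers: list[str]
    outlier_pvalues: dict[str, float] = field(default_factory=dict)
    corrected: MREstimate | None = None
    distortion_pvalue: float | None = None
    n_sim: int = 0
    seed: int | None = None


def _loo_ivw_betas(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized by subtracting each SNP's term."""
    sxx = np.sum(w * g * g, axis=-1, keepdims=True)
    sxy = np.sum(w * g * G, axis=-1, keepdims=True)
    return (sxy - w * g * G) / (sxx - w * g * g)


def _rss_terms(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP weighted squared residuals around the leave-one-out fits."""
    beta_loo = _loo_ivw_betas(g, G, w)
    return w * (G - beta_loo * g) ** 2


def presso_global(
    s: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float, PressoSimulations]:
    """Global pleiotropy test: observed RSS against its parametric null.

    p = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1) — the add-one Monte-Carlo
    estimator, bounded below by 1/(n_sim+1).  Also returns the per-SNP
    simulation terms consumed by :func:`presso_outliers`.
    """
    if s.J < 4:
        raise EstimationError("MR-PRESSO requires at least 4 instruments")
    w = 1.0 / s.sigma_y**2
    obs_terms = _rss_terms(s.gamma_hat, s.Gamma_hat, w)
    rss_obs = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    beta_loo = _loo_ivw_betas(s.gamma_hat, s.Gamma_hat, w)
    # Null data: each SNP's expected outcome effect is its LOO prediction.
    g_star = rng.normal(s.gamma_hat, s.sigma_x, size=(n_sim, s.J))
    G_star = rng.normal(beta_loo * s.gamma_hat, s.sigma_y, size=(n_sim, s.J))
    sim_terms = _rss_terms(g_star, G_star, w)
    rss_sim = sim_terms.sum(axis=1)

    p = (1.0 + np.count_nonzero(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return rss_obs, float(p), PressoSimulations(obs_terms, sim_terms, n_sim)


def presso_outliers(
    s: HarmonizedInstrumentSet,
    sims: PressoSimulations,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, float]]:
    """Flag per-SNP outliers by comparing each observed residual term with
    its simulated null, Bonferroni-adjusted across the J tests."""
    n_sim = sims.n_sim
    raw_p = (1.0 + np.count_nonzero(sims.sim_terms >= sims.obs_terms, axis=0)) / (n_sim + 1.0)
    adj_p = np.minimum(1.0, raw_p * s.J)
    outliers = [s.rsids[j] for j in range(s.J) if adj_p[j] < alpha]
    pvals = {s.rsids[j]: float(adj_p[j]) for j in range(s.J)}
    return outliers, pvals


def presso_corrected(
    s: HarmonizedInstrumentSet, outliers: list[str], or_scale: bool = False
) -> MREstimate:
    """Outlier-corrected estimate: IVW-MRE excluding the flagged SNPs.

    With no outliers this is exactly the uncorrected IVW-MRE.
    """
    if len(outliers) >= s.J - 1:
        raise EstimationError(
            f"removing {len(outliers)} outliers leaves fewer than 2 of {s.J} instruments"
        )
    sub = s.exclude(outliers, action="presso_outlier") if outliers else s
    est = ivw_mre(sub, or_scale=or_scale)
    est.method = "presso"
    return est


def presso_distortion(
    s: HarmonizedInstrumentSet,
    outliers: list[str],
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> float | None:
    """Distortion test: is the corrected-vs-uncorrected shift larger than
    removing a random equally-sized subset would produce?

    Returns None ("not applicable") when there are no outliers.  Two-sided
    add-one Monte-Carlo p, bounded below by 1/(n_boot+1).
    """
    k = len(outliers)
    if k == 0:
        return None
    beta_full = ivw_mre(s).beta
    beta_corr = presso_corrected(s, outliers).beta
    d_obs = abs(beta_corr - beta_full)

    rng = np.random.default_rng(seed)
    w = 1.0 / s.sigma_y**2
    sxx = float(np.sum(w * s.gamma_hat**2))
    sxy = float(np.sum(w * s.gamma_hat * s.Gamma_hat))
    count = 0
    for _ in range(n_boot):
        idx = rng.choice(s.J, size=k, replace=False)
        dxx = float(np.sum((w * s.gamma_hat**2)[idx]))
        dxy = float(np.sum((w * s.gamma_hat * s.Gamma_hat)[idx]))
        beta_b = (sxy - dxy) / (sxx - dxx)
        if abs(beta_b - sxy / sxx) >= d_obs:
            count += 1
    return (1.0 + count) / (n_boot + 1.0)


def run_presso(
    s: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    alpha: float = 0.05,
    n_boot_distortion: int = 1000,
    or_scale: bool = False,
) -> PressoResult:
    """Full MR-PRESSO battery: global test, outlier scan, corrected estimate,
    distortion test.  Deterministic given (inputs, n_sim, seed)."""
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, type(None))) else seed
    seeds = ss.spawn(2)
    rss, global_p, sims = presso_global(s, n_sim=n_sim, seed=seeds[0])
    outliers, pvals = presso_outliers(s, sims, alpha=alpha)
    corrected = None
    if len(outliers) < s.J - 1:
        corrected = presso_corrected(s, outliers, or_scale=or_scale)
    else:
        logger.warning("too many PRESSO outliers (%d of %d); no corrected estimate", len(outliers), s.J)
    distortion = presso_distortion(s, outliers, n_boot=n_boot_distortion, seed=seeds[1])
    return PressoResult(
        global_rss=rss,
        global_pvalue=global_p,
        outliers=outliers,
        outlier_pvalues=pvals,
        corrected=corrected,
        distortion_pvalue=distortion,
        n_sim=n_sim,
        seed=seed if isinstance(seed, int) else None,
    )
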