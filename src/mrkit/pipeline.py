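"""Study-design orchestration: direction runs, bi-directional batteries,
confounder screens, multiple-testing control, and power.

A "direction" is one exposure -> outcome analysis: select genome-wide
significant LD-independent instruments from the exposure GWAS, substitute
proxies for instruments absent from the outcome GWAS, harmonize, compute
instrument strength, and run the full estimator battery (IVW-MRE, weighted
median, MR-Egger, MR-PRESSO).  A bi-directional run executes both
directions, checks for instruments shared (identical or r2 >= 0.8) between
them, and — when any exist — reruns that direction without them as a
sensitivity analysis.  Family-wise error over a battery of traits is
controlled by Bonferroni correction (0.05/16 for the canonical
eight-traits-by-two-directions design), and the minimally detectable odds
ratio at a target power is computed from the standard two-sample MR
noncentrality approximation for binary outcomes.
"""

from __future__ import annotations

import logging
import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .errors import ConfigurationError, MRKitError, PipelineStageError, SelectionError
from .estimators import MREstimate, estimate_all
from .instruments import (
    InstrumentSelectionConfig,
    flag_overlap,
    greedy_clump,
    harmonize,
    mean_f_statistic,
    select_instruments,
    substitute_proxies,
)
from .presso import PressoResult, run_presso
from .summary_io import GWASSummaryTable, LDTable, filter_variants

logger = logging.getLogger(__name__)

#: Canonical family size: eight traits tested in both directions.
DEFAULT_FAMILY_SIZE = 16

METHOD_ORDER = ("ivw", "weighted_median", "egger", "presso")


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs beyond the data tables."""

    selection: InstrumentSelectionConfig = field(default_factory=InstrumentSelectionConfig)
    alpha: float = 0.05
    family_size: int = DEFAULT_FAMILY_SIZE
    overlap_r2: float = 0.8
    n_boot: int = 1000          # weighted-median bootstrap replicates
    n_sim: int = 1000           # MR-PRESSO global-test simulations
    presso_alpha: float = 0.05  # per-SNP outlier threshold (Bonferroni-adjusted)
    n_boot_distortion: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sel = data.pop("selection", None)
        cfg = cls(**data)
        if sel:
            cfg.selection = InstrumentSelectionConfig(**sel)
        return cfg


@dataclass
class PowerSpec:
    """Inputs to the binary-outcome power approximation.

    ``r2_gx`` is the fraction of exposure variance explained by the
    instruments; ``case_fraction`` is the outcome case proportion K in the
    outcome GWAS of ``n_total`` participants.
    """

    n_total: float
    case_fraction: float
    r2_gx: float
    alpha: float = 0.05
    power_target: float = 0.80

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError(f"n_total must be positive, got {self.n_total}")
        for name in ("case_fraction", "r2_gx", "alpha", "power_target"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.power_target <= self.alpha:
            raise ConfigurationError("power_target must exceed alpha")

    @property
    def information(self) -> float:
        """n * r2 * K * (1-K): the effective information for ln(OR)."""
        K = self.case_fraction
        return self.n_total * self.r2_gx * K * (1.0 - K)


@dataclass
class DirectionResult:
    """The full estimator battery for one exposure -> outcome direction."""

    exposure: str
    outcome: str
    outcome_type: str
    estimates: dict[str, MREstimate | None]
    presso: PressoResult | None
    f_statistic: float
    n_snps: int
    instruments: list[str]
    significance_tier: str
    audit: dict
    sensitivity: "DirectionResult | None" = None
    analysis: str = "primary"

    def to_rows(self) -> list[dict]:
        """Flatten to the delimited reporting layout, one row per method."""
        rows = []
        for method in METHOD_ORDER:
            if method == "presso":
                est = self.presso.corrected if self.presso else None
            else:
                est = self.estimates.get(method)
            if est is None:
                continue
            row: dict = {
                "exposure": self.exposure,
                "outcome": self.outcome,
                "method": method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "f_statistic": self.f_statistic,
                "significance_tier": self.significance_tier,
                "analysis": self.analysis,
            }
            if est.or_scale:
                row["or"] = math.exp(est.beta)
                row["or_ci_low"] = math.exp(est.ci_low)
                row["or_ci_high"] = math.exp(est.ci_high)
            if est.q_stat is not None and method == "ivw":
                row["q_stat"] = est.q_stat
                row["q_pvalue"] = est.q_pvalue
            if method == "egger":
                row["egger_intercept"] = est.egger_intercept
                row["egger_intercept_pvalue"] = est.egger_intercept_pvalue
                row["i2_gx"] = est.i2_gx
            if method == "presso" and self.presso is not None:
                row["presso_global_pvalue"] = self.presso.global_pvalue
                row["presso_n_outliers"] = len(self.presso.outliers)
                row["presso_distortion_pvalue"] = self.presso.distortion_pvalue
            rows.append(row)
        if self.sensitivity is not None:
            rows.extend(self.sensitivity.to_rows())
        return rows


@dataclass
class BidirectionalResult:
    """Both directions of one trait pair, with overlap sensitivity reruns."""

    forward: DirectionResult
    reverse: DirectionResult
    overlap_forward: list[str]
    overlap_reverse: list[str]


# ---------------------------------------------------------------------------
# Multiple testing and significance tiers
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n (0.05/16 = 0.003125 for the
    canonical eight-trait bi-directional battery)."""
    if n_tests < 1:
        raise ConfigurationError(f"n_tests must be >= 1, got {n_tests}")
    return alpha_family / n_tests


def significance_tier(pvalue: float, alpha: float, bonferroni_alpha: float) -> str:
    """Classify an IVW p-value: 'bonferroni' beats the corrected threshold,
    'nominal' beats alpha only, 'null' otherwise."""
    if pvalue < bonferroni_alpha:
        return "bonferroni"
    if pvalue < alpha:
        return "nominal"
    return "null"


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def power_binary_outcome(or_value: float, spec: PowerSpec) -> float:
    """Two-sided power to detect a given OR in a two-sample MR with a binary
    outcome.

    Uses the noncentrality z = |ln OR| * sqrt(n * r2_gx * K(1-K)); power is
    the two-sided normal rejection probability Phi(z - c) + Phi(-z - c) with
    c the upper alpha/2 quantile, so power at OR = 1 equals alpha exactly.
    """
    if or_value <= 0:
        raise ConfigurationError(f"OR must be positive, got {or_value}")
    z = abs(math.log(or_value)) * math.sqrt(spec.information)
    c = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(z - c) + stats.norm.cdf(-z - c))


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest OR > 1 detectable at the target power.

    Power depends on the data only through z = ln(OR) * sqrt(information), so
    the root is found once in z (monotone for z > 0) and mapped back; ln(OR)
    therefore shrinks by exactly sqrt(2) when the information doubles.
    Returned at full precision; round for display.
    """
    c = stats.norm.ppf(1.0 - spec.alpha / 2.0)

    def gap(z: float) -> float:
        return float(stats.norm.cdf(z - c) + stats.norm.cdf(-z - c)) - spec.power_target

    z_star = optimize.brentq(gap, 0.0, 60.0, xtol=1e-13, rtol=8.9e-16)
    return math.exp(z_star / math.sqrt(spec.information))


# ---------------------------------------------------------------------------
# Direction runs
# ---------------------------------------------------------------------------

@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except MRKitError as exc:
        raise PipelineStageError(name, exc) from exc


def run_direction(
    exposure: GWASSummaryTable,
    outcome: GWASSummaryTable,
    ld: LDTable,
    config: AnalysisConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    exclude_rsids: Sequence[str] | None = None,
    analysis: str = "primary",
) -> DirectionResult:
    """Run one full exposure -> outcome analysis.

    Stages: variant filter -> instrument selection -> LD clumping -> proxy
    substitution -> harmonization -> F-statistic -> estimator battery ->
    MR-PRESSO.  ``exclude_rsids`` removes instruments up front (overlap
    sensitivity reruns).  Deterministic given (inputs, config, seed).
    """
    config = config or AnalysisConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_wm, seed_presso = ss.spawn(2)
    audit: dict = {"config": config.selection.to_dict(), "stages": {}}

    with _stage("filter_exposure"):
        exposure_f, drops_exp = filter_variants(exposure)
        audit["stages"]["filter_exposure"] = drops_exp
    with _stage("filter_outcome"):
        outcome_f, drops_out = filter_variants(outcome)
        audit["stages"]["filter_outcome"] = drops_out

    with _stage("select"):
        candidates = select_instruments(exposure_f, config.selection)
        if exclude_rsids:
            drop = set(exclude_rsids)
            candidates = [r for r in candidates if r not in drop]
            audit["stages"]["excluded_upfront"] = sorted(drop)
            if not candidates:
                raise SelectionError("all candidate instruments were excluded")
        audit["stages"]["select"] = {"n_candidates": len(candidates)}

    with _stage("clump"):
        clumped = greedy_clump(candidates, ld, config.selection.clump_r2)
        audit["stages"]["clump"] = {"n_independent": len(clumped)}

    with _stage("proxy"):
        missing = [r for r in clumped if r not in outcome_f]
        proxy_map = substitute_proxies(missing, outcome_f, ld, config.selection.proxy_r2)
        audit["stages"]["proxy"] = {
            "n_missing": len(missing),
            "map": {k: v for k, v in proxy_map.items()},
        }

    with _stage("harmonize"):
        instruments = [exposure_f.records[r] for r in clumped]
        hset = harmonize(instruments, outcome_f, config.selection, proxy_map=proxy_map)
        actions: dict[str, int] = {}
        for act in hset.audit.values():
            actions[act] = actions.get(act, 0) + 1
        audit["stages"]["harmonize"] = {"actions": actions, "per_snp": dict(hset.audit)}

    with _stage("f_statistic"):
        f_mean, f_per_snp = mean_f_statistic(hset)
        audit["stages"]["f_statistic"] = {"mean_f": f_mean}

    with _stage("estimate"):
        estimates = estimate_all(
            hset, trait_type=outcome.trait_type, n_boot=config.n_boot, seed=seed_wm
        )

    presso_result: PressoResult | None = None
    if hset.J >= 4:
        with _stage("presso"):
            presso_result = run_presso(
                hset,
                n_sim=config.n_sim,
                seed=seed_presso,
                alpha=config.presso_alpha,
                n_boot_distortion=config.n_boot_distortion,
                or_scale=outcome.trait_type == "binary",
            )

    ivw = estimates["ivw"]
    assert ivw is not None
    tier = significance_tier(
        ivw.pvalue, config.alpha, bonferroni_threshold(config.alpha, config.family_size)
    )
    return DirectionResult(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        outcome_type=outcome.trait_type,
        estimates=estimates,
        presso=presso_result,
        f_statistic=f_mean,
        n_snps=hset.J,
        instruments=list(hset.rsids),
        significance_tier=tier,
        audit=audit,
        analysis=analysis,
    )


def run_bidirectional(
    trait_a: GWASSummaryTable,
    trait_b: GWASSummaryTable,
    ld: LDTable,
    config: AnalysisConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> BidirectionalResult:
    """Run A -> B and B -> A, with overlap-SNP sensitivity reruns.

    Instruments of one direction that are identical to — or in LD r2 >= 0.8
    with — an instrument of the reverse direction are flagged; when any are,
    that direction is rerun without them and the rerun attached as its
    ``sensitivity`` result.
    """
    config = config or AnalysisConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_fwd, s_rev, s_fwd2, s_rev2 = ss.spawn(4)

    forward = run_direction(trait_a, trait_b, ld, config, seed=s_fwd)
    reverse = run_direction(trait_b, trait_a, ld, config, seed=s_rev)

    ov_fwd = flag_overlap(forward.instruments, reverse.instruments, ld, config.overlap_r2)
    ov_rev = flag_overlap(reverse.instruments, forward.instruments, ld, config.overlap_r2)

    if ov_fwd:
        logger.info("%s -> %s: %d overlapping instrument(s); sensitivity rerun",
                    trait_a.trait_name, trait_b.trait_name, len(ov_fwd))
        forward.sensitivity = run_direction(
            trait_a, trait_b, ld, config, seed=s_fwd2,
            exclude_rsids=ov_fwd, analysis="sensitivity_excl_overlap",
        )
    if ov_rev:
        logger.info("%s -> %s: %d overlapping instrument(s); sensitivity rerun",
                    trait_b.trait_name, trait_a.trait_name, len(ov_rev))
        reverse.sensitivity = run_direction(
            trait_b, trait_a, ld, config, seed=s_rev2,
            exclude_rsids=ov_rev, analysis="sensitivity_excl_overlap",
        )
    return BidirectionalResult(
        forward=forward, reverse=reverse,
        overlap_forward=ov_fwd, overlap_reverse=ov_rev,
    )


def confounder_screen(
    exposure: GWASSummaryTable,
    confounders: Mapping[str, GWASSummaryTable],
    ld: LDTable,
    config: AnalysisConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> list[DirectionResult]:
    """Associate the exposure's instruments with each candidate confounder.

    A valid instrument set should show null associations with socio-economic
    and lifestyle traits (the instrumental-variable independence condition).
    Continuous confounders are reported as mean differences, binary ones as
    odds ratios, following each table's ``trait_type``.
    """
    config = config or AnalysisConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(max(1, len(confounders)))
    results = []
    for child, (name, table) in zip(seeds, confounders.items()):
        if table.trait_name != name:
            table.trait_name = name
        results.append(run_direction(exposure, table, ld, config, seed=child))
    return results
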