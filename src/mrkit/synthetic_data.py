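"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the statistical structure of consortium GWAS summary
data as consumed by two-sample MR: J independent instruments with true
exposure effects gamma_j (log-OR scale), outcome effects
Gamma_j = beta_true * gamma_j + alpha_j where alpha_j is horizontal
pleiotropy, and *independently* noised observed estimates in the two
samples (gamma_hat ~ N(gamma, se_x), Gamma_hat ~ N(Gamma, se_y)).
Pleiotropy regimes: none, balanced (zero-mean), directional (nonzero mean,
InSIDE holds), and InSIDE-violating (pleiotropy correlated with instrument
strength).  Planted outliers receive a fixed extra pleiotropic effect.

On top of the effect arrays the generator lays the bookkeeping real data
bring: allele pairs (a configurable fraction palindromic), effect-allele
frequencies, strand flips and allele swaps in the outcome table, and
instruments omitted from the outcome GWAS with a high-LD proxy available —
so selection, clumping, proxy substitution and harmonization are all
exercised end-to-end without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .instruments import COMPLEMENT, HarmonizedInstrumentSet
from .summary_io import GWASSummaryTable, LDTable, SummaryAssociation, MIN_PVALUE

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class ScenarioConfig:
    """Data-generating conditions for one synthetic two-sample scenario.

    Effects are on the log-odds scale throughout (binary traits); the same
    machinery serves continuous outcomes with ``outcome_trait_type`` set to
    ``"continuous"``, where betas read as raw-unit mean effects.

    ``target_mean_F``, when set, calibrates ``se_x`` so the *expected* mean
    per-SNP F-statistic, mean(gamma^2)/se_x^2 + 1, hits the target.
    """

    J: int = 100
    beta_true: float = 0.2
    gamma_range: tuple[float, float] = (0.06, 0.10)
    se_x: float = 0.002
    se_y: float = 0.02
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_coupling: float = 1.0     # alpha ~ coupling * (gamma - mean) in inside_violating mode
    outlier_indices: tuple[int, ...] = ()
    outlier_alpha: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.95)
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0
    frac_missing_in_outcome: float = 0.0
    target_mean_F: float | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_trait_type: str = "binary"
    rsid_start: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ConfigurationError(f"J must be >= 1, got {self.J}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, got {self.pleiotropy_mode!r}"
            )
        for name in ("frac_palindromic", "frac_strand_flipped", "frac_missing_in_outcome"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ConfigurationError("se_x and se_y must be positive")
        if self.target_mean_F is not None and self.target_mean_F <= 1.0:
            raise ConfigurationError("target_mean_F must exceed 1 (the pure-noise floor)")
        if any(i < 0 or i >= self.J for i in self.outlier_indices):
            raise ConfigurationError("outlier_indices out of range")
        if self.frac_missing_in_outcome >= 1.0 and self.J > 0:
            raise ConfigurationError("cannot omit every instrument from the outcome table")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated scenario, for recovery tests."""

    beta_true: float
    rsids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    se_x: float
    se_y: float
    outlier_indices: tuple[int, ...]
    palindromic: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    strand_flipped: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    allele_swapped: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    missing_in_outcome: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    proxy_map: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2)


def _pvalue(beta: np.ndarray, se: float) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, MIN_PVALUE)


def _draw_effects(config: ScenarioConfig, rng: np.random.Generator):
    """True and observed effect arrays, plus the calibrated se_x."""
    gamma = rng.uniform(*config.gamma_range, size=config.J)
    se_x = config.se_x
    if config.target_mean_F is not None:
        # E[mean F] = mean(gamma^2)/se_x^2 + 1 because gamma_hat carries
        # one unit of chi-squared noise per SNP.
        se_x = float(np.sqrt(np.mean(gamma**2) / (config.target_mean_F - 1.0)))

    mode = config.pleiotropy_mode
    if mode == "none":
        alpha = np.zeros(config.J)
    elif mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=config.J)
    elif mode == "directional":
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=config.J)
    else:  # inside_violating: pleiotropy tracks instrument strength
        alpha = (
            config.pleiotropy_mean
            + config.inside_coupling * (gamma - gamma.mean())
            + rng.normal(0.0, config.pleiotropy_sd, size=config.J)
        )
    if config.outlier_indices:
        alpha = alpha.copy()
        alpha[list(config.outlier_indices)] += config.outlier_alpha

    Gamma = config.beta_true * gamma + alpha
    gamma_hat = rng.normal(gamma, se_x)
    Gamma_hat = rng.normal(Gamma, config.se_y)
    return gamma, alpha, Gamma, gamma_hat, Gamma_hat, se_x


def generate_instrument_set(
    config: ScenarioConfig,
) -> tuple[HarmonizedInstrumentSet, SyntheticTruth]:
    """Fast path for estimator studies: already-harmonized arrays.

    Skips the allele/frequency bookkeeping (equivalent to a scenario with no
    palindromes, flips or missingness) and returns the instrument set the
    estimators consume directly.
    """
    rng = np.random.default_rng(config.seed)
    gamma, alpha, _, gamma_hat, Gamma_hat, se_x = _draw_effects(config, rng)
    rsids = [f"rs{config.rsid_start + i}" for i in range(config.J)]
    hset = HarmonizedInstrumentSet(
        rsids=rsids,
        gamma_hat=gamma_hat,
        sigma_x=np.full(config.J, se_x),
        Gamma_hat=Gamma_hat,
        sigma_y=np.full(config.J, config.se_y),
        audit={r: "kept" for r in rsids},
    )
    truth = SyntheticTruth(
        beta_true=config.beta_true, rsids=rsids, gamma=gamma, alpha=alpha,
        se_x=se_x, se_y=config.se_y, outlier_indices=config.outlier_indices,
    )
    return hset, truth


def generate_two_sample(
    config: ScenarioConfig,
) -> tuple[GWASSummaryTable, GWASSummaryTable, LDTable, SyntheticTruth]:
    """Generate a full (exposure table, outcome table, LD table, truth) tuple.

    The exposure table holds the J instrument records; the outcome table
    holds the same variants' outcome associations, after applying the
    configured fractions of strand flips, allele swaps (half of the flipped
    variants), palindromic coding, and omissions covered by an in-LD proxy
    variant (r2 drawn uniformly from [0.8, 1.0]).  Instruments are mutually
    unlinked (absent LD pairs read as r2 = 0), so clumping keeps them all.
    Fully deterministic given the config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    gamma, alpha, Gamma, gamma_hat, Gamma_hat, se_x = _draw_effects(config, rng)
    J = config.J
    rsids = [f"rs{config.rsid_start + i}" for i in range(J)]

    # Allele assignment: a fixed-count random subset is palindromic.
    n_pal = int(round(config.frac_palindromic * J))
    pal_mask = np.zeros(J, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(J, size=n_pal, replace=False)] = True
    pairs = []
    for j in range(J):
        pool = PALINDROMIC_PAIRS if pal_mask[j] else NON_PALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])

    eaf_exp = rng.uniform(*config.maf_range, size=J)
    eaf_out = np.clip(eaf_exp + rng.normal(0.0, 0.01, size=J), 0.01, 0.99)

    # Outcome-table presentation quirks.
    flip_mask = np.zeros(J, dtype=bool)
    n_flip = int(round(config.frac_strand_flipped * J))
    if n_flip:
        candidates = np.flatnonzero(~pal_mask)
        n_flip = min(n_flip, candidates.size)
        if n_flip:
            flip_mask[rng.choice(candidates, size=n_flip, replace=False)] = True
    # Half of the presentation-quirked variants also list alleles in swapped
    # order (negated beta, complemented EAF); palindromes may be swapped too.
    swap_mask = rng.random(J) < 0.5 * (flip_mask | pal_mask)

    miss_mask = np.zeros(J, dtype=bool)
    n_miss = int(round(config.frac_missing_in_outcome * J))
    if n_miss:
        miss_mask[rng.choice(J, size=n_miss, replace=False)] = True

    p_exp = _pvalue(gamma_hat, se_x)
    p_out = _pvalue(Gamma_hat, config.se_y)

    exposure = GWASSummaryTable(
        trait_name=config.exposure_name, trait_type="binary",
        provenance=f"synthetic seed={config.seed}",
    )
    outcome = GWASSummaryTable(
        trait_name=config.outcome_name, trait_type=config.outcome_trait_type,
        provenance=f"synthetic seed={config.seed}",
    )
    ld = LDTable()
    proxy_map: dict[str, str] = {}

    for j in range(J):
        ea, oa = pairs[j]
        exposure.add(SummaryAssociation(
            rsid=rsids[j], effect_allele=ea, other_allele=oa,
            beta=float(gamma_hat[j]), se=se_x, pvalue=float(p_exp[j]),
            eaf=float(eaf_exp[j]),
        ))

        out_ea, out_oa = ea, oa
        out_beta = float(Gamma_hat[j])
        out_eaf = float(eaf_out[j])
        if flip_mask[j]:
            out_ea, out_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
        if swap_mask[j]:
            out_ea, out_oa = out_oa, out_ea
            out_beta = -out_beta
            out_eaf = 1.0 - out_eaf

        if miss_mask[j]:
            # The instrument itself is absent; an in-LD proxy carries an
            # independent measurement of (approximately) the same signal.
            proxy_rsid = f"rs{9_000_000 + config.rsid_start + j}"
            proxy_beta = float(rng.normal(Gamma[j], config.se_y))
            if swap_mask[j]:
                proxy_beta = -proxy_beta
            outcome.add(SummaryAssociation(
                rsid=proxy_rsid, effect_allele=out_ea, other_allele=out_oa,
                beta=proxy_beta, se=config.se_y,
                pvalue=float(_pvalue(np.array([proxy_beta]), config.se_y)[0]),
                eaf=out_eaf,
            ))
            ld.set(rsids[j], proxy_rsid, float(rng.uniform(0.8, 1.0)))
            proxy_map[rsids[j]] = proxy_rsid
        else:
            outcome.add(SummaryAssociation(
                rsid=rsids[j], effect_allele=out_ea, other_allele=out_oa,
                beta=out_beta, se=config.se_y,
                pvalue=float(p_out[j]), eaf=out_eaf,
            ))

    truth = SyntheticTruth(
        beta_true=config.beta_true, rsids=rsids, gamma=gamma, alpha=alpha,
        se_x=se_x, se_y=config.se_y, outlier_indices=config.outlier_indices,
        palindromic=pal_mask, strand_flipped=flip_mask, allele_swapped=swap_mask,
        missing_in_outcome=miss_mask, proxy_map=proxy_map,
    )
    return exposure, outcome, ld, truth


def generate_bidirectional(
    config_ab: ScenarioConfig,
    config_ba: ScenarioConfig,
    n_ld_bridges: int = 0,
    bridge_r2: float = 0.9,
) -> tuple[GWASSummaryTable, GWASSummaryTable, LDTable, SyntheticTruth, SyntheticTruth]:
    """Merge two one-direction scenarios into full bi-directional trait tables.

    Trait A's table gets A's instrument records plus A-outcome associations
    at B's instruments, and vice versa.  ``n_ld_bridges`` adds LD pairs
    (r2 = ``bridge_r2``) between the first instruments of A and of B, so the
    overlap check and its sensitivity rerun have something to find.  The two
    configs must use disjoint ``rsid_start`` ranges.
    """
    if abs(config_ab.rsid_start - config_ba.rsid_start) < max(config_ab.J, config_ba.J):
        raise ConfigurationError("rsid_start ranges of the two scenarios overlap")
    exp_a, out_b, ld_ab, truth_a = generate_two_sample(config_ab)
    exp_b, out_a, ld_ba, truth_b = generate_two_sample(config_ba)

    table_a = GWASSummaryTable(
        trait_name=config_ab.exposure_name, trait_type="binary",
        provenance="synthetic bidirectional",
    )
    for rec in list(exp_a.records.values()) + list(out_a.records.values()):
        table_a.add(rec)
    table_b = GWASSummaryTable(
        trait_name=config_ba.exposure_name, trait_type="binary",
        provenance="synthetic bidirectional",
    )
    for rec in list(exp_b.records.values()) + list(out_b.records.values()):
        table_b.add(rec)

    ld = LDTable()
    for src in (ld_ab, ld_ba):
        for (a, b), r2 in src._pairs.items():  # noqa: SLF001 - same package
            ld.set(a, b, r2)
    for k in range(min(n_ld_bridges, config_ab.J, config_ba.J)):
        ld.set(truth_a.rsids[k], truth_b.rsids[k], bridge_r2)
    return table_a, table_b, ld, truth_a, truth_b


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named scenario catalogue covering the qualitative regimes the
    estimator battery must distinguish.

    * ``valid_strong`` — J=100 valid, strong instruments; parameter recovery.
    * ``valid_110`` — the realistic instrument battery: J=110 instruments
      calibrated to a mean F-statistic of 89.3, with palindromes, strand
      flips and proxy-covered missingness; end-to-end pipeline exercise.
    * ``null_balanced`` — no causal effect, balanced pleiotropy; type-I error.
    * ``directional_inside`` — directional pleiotropy, InSIDE holds; MR-Egger
      should recover the intercept and de-bias the slope.
    * ``inside_violating`` — pleiotropy correlated with instrument strength;
      even MR-Egger is biased (negative control).
    * ``presso_outliers`` — 5 of 50 SNPs carry pleiotropy 10x the outcome SE;
      MR-PRESSO detection and correction.
    * ``proxy_rich`` — 15% of instruments missing from the outcome GWAS with
      in-LD proxies available.
    * ``palindrome_mix`` — half the variants palindromic with EAF spanning
      both sides of the MAF 0.42 rule.
    """
    return {
        "valid_strong": ScenarioConfig(J=100, beta_true=0.2),
        "valid_110": ScenarioConfig(
            J=110, beta_true=0.2, target_mean_F=89.3,
            frac_palindromic=0.2, frac_strand_flipped=0.1,
            frac_missing_in_outcome=0.05,
        ),
        "null_balanced": ScenarioConfig(
            J=100, beta_true=0.0, pleiotropy_mode="balanced", pleiotropy_sd=0.02,
        ),
        "directional_inside": ScenarioConfig(
            J=100, beta_true=0.2, pleiotropy_mode="directional",
            pleiotropy_mean=0.05, pleiotropy_sd=0.02,
        ),
        "inside_violating": ScenarioConfig(
            J=100, beta_true=0.2, pleiotropy_mode="inside_violating",
            pleiotropy_mean=0.05, pleiotropy_sd=0.02, inside_coupling=1.0,
        ),
        "presso_outliers": ScenarioConfig(
            J=50, beta_true=0.2, outlier_indices=tuple(range(5)), outlier_alpha=0.2,
        ),
        "proxy_rich": ScenarioConfig(J=60, beta_true=0.2, frac_missing_in_outcome=0.15),
        "palindrome_mix": ScenarioConfig(J=80, beta_true=0.2, frac_palindromic=0.5),
    }


def write_scenario(
    config: ScenarioConfig, outdir, delimiter: str = "\t"
) -> dict[str, str]:
    """Materialize a scenario as delimited text plus a truth JSON.

    Returns the written file paths.  The tables use the canonical column
    names, so they read back with the default column map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, ld, truth = generate_two_sample(config)
    paths = {}
    for name, table in (("exposure", exposure), ("outcome", outcome)):
        path = outdir / f"{name}.tsv"
        df = table.to_frame()
        df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")
        paths[name] = str(path)
    ld_path = outdir / "ld.tsv"
    with open(ld_path, "w") as fh:
        fh.write(delimiter.join(["rsid_a", "rsid_b", "r2"]) + "\n")
        for (a, b), r2 in sorted(ld._pairs.items()):
            fh.write(delimiter.join([a, b, f"{r2:.10g}"]) + "\n")
    paths["ld"] = str(ld_path)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json() + "\n")
    paths["truth"] = str(truth_path)
    return paths
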