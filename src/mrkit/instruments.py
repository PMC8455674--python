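"""Instrument selection, LD clumping, proxy substitution and harmonization.

Two-sample Mendelian randomization needs, per instrument SNP j, an aligned
quadruple: the SNP-exposure effect gamma_j with SE sigma_Xj and the
SNP-outcome effect Gamma_j with SE sigma_Yj, both expressed for the same
effect allele.  This module selects genome-wide significant, LD-independent
instruments from an exposure GWAS, substitutes high-LD proxies for
instruments absent from the outcome GWAS, aligns outcome effects onto the
exposure's effect allele (handling allele swaps, strand flips and
palindromic A/T / C/G variants via allele frequency), flags instruments
shared between the two directions of a bi-directional analysis, and
computes the mean F-statistic as an instrument-strength diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, HarmonizationError, SelectionError
from .summary_io import GWASSummaryTable, LDTable, SummaryAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Audit actions; every input instrument receives exactly one.
KEPT = "kept"
ALLELE_FLIPPED = "allele_flipped"
PROXY_SUBSTITUTED = "proxy_substituted"
DROPPED_PALINDROME = "dropped_palindrome"
DROPPED_MISSING = "dropped_missing"
DROPPED_OVERLAP = "dropped_overlap"


@dataclass
class InstrumentSelectionConfig:
    """Thresholds governing instrument selection and harmonization.

    Parameters
    ----------
    p_threshold
        Genome-wide significance cutoff for SNP-exposure associations.
        5e-8 by convention; a relaxed 5e-6 is conventional for rare outcomes
        that lack genome-wide significant hits.
    clump_r2
        Maximum pairwise r-squared between retained instruments (LD
        independence).
    proxy_r2
        Minimum r-squared for a proxy to stand in for an instrument missing
        from the outcome GWAS.
    palindrome_maf_max
        Palindromic (A/T, C/G) variants are retained only when the minor
        allele frequency is at most this value, so that allele frequency can
        resolve the strand.
    palindrome_maf_both_samples
        If True (default, conservative) the MAF condition must hold in both
        the exposure and the outcome sample; if False, the exposure sample
        alone decides.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    palindrome_maf_max: float = 0.42
    palindrome_maf_both_samples: bool = True

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_r2", "proxy_r2", "palindrome_maf_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.proxy_r2 <= self.clump_r2:
            raise ConfigurationError(
                f"proxy_r2 ({self.proxy_r2}) must exceed clump_r2 ({self.clump_r2})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InstrumentSelectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP effect quadruples ready for estimation.

    Arrays are parallel over the J retained instruments.  ``audit`` records
    one action per *input* instrument (kept / allele_flipped /
    proxy_substituted / dropped_*), so its keys cover a superset of
    ``rsids``.
    """

    rsids: list[str]
    gamma_hat: np.ndarray   # SNP-exposure effects
    sigma_x: np.ndarray     # their SEs
    Gamma_hat: np.ndarray   # SNP-outcome effects, aligned
    sigma_y: np.ndarray     # their SEs
    audit: dict[str, str] = field(default_factory=dict)
    proxy_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        self.Gamma_hat = np.asarray(self.Gamma_hat, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        J = len(self.rsids)
        if J < 1:
            raise HarmonizationError("harmonized instrument set is empty")
        for name in ("gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"):
            if getattr(self, name).shape != (J,):
                raise ValueError(f"{name} must have shape ({J},)")
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def J(self) -> int:
        return len(self.rsids)

    def exclude(self, rsids: Sequence[str], action: str = DROPPED_OVERLAP) -> "HarmonizedInstrumentSet":
        """A new set without the given rsids; their audit action is updated."""
        drop = set(rsids)
        keep = [i for i, r in enumerate(self.rsids) if r not in drop]
        if not keep:
            raise HarmonizationError("excluding these rsids empties the instrument set")
        audit = dict(self.audit)
        for r in self.rsids:
            if r in drop:
                audit[r] = action
        idx = np.asarray(keep)
        return HarmonizedInstrumentSet(
            rsids=[self.rsids[i] for i in keep],
            gamma_hat=self.gamma_hat[idx],
            sigma_x=self.sigma_x[idx],
            Gamma_hat=self.Gamma_hat[idx],
            sigma_y=self.sigma_y[idx],
            audit=audit,
            proxy_map=dict(self.proxy_map),
        )

    def subset(self, indices: Sequence[int]) -> "HarmonizedInstrumentSet":
        idx = np.asarray(indices, dtype=int)
        return HarmonizedInstrumentSet(
            rsids=[self.rsids[i] for i in idx],
            gamma_hat=self.gamma_hat[idx],
            sigma_x=self.sigma_x[idx],
            Gamma_hat=self.Gamma_hat[idx],
            sigma_y=self.sigma_y[idx],
            audit=dict(self.audit),
            proxy_map=dict(self.proxy_map),
        )


# ---------------------------------------------------------------------------
# Selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(
    table: GWASSummaryTable, config: InstrumentSelectionConfig
) -> list[str]:
    """Candidate instruments: variants with p below threshold, best-first.

    The returned list is sorted ascending by p-value (ties broken by rsid for
    determinism), which is the order greedy clumping consumes.
    """
    cands = [
        (rec.pvalue, rsid)
        for rsid, rec in table.records.items()
        if rec.pvalue < config.p_threshold
    ]
    if not cands:
        raise SelectionError(
            f"no variants in {table.trait_name!r} pass p < {config.p_threshold:g}"
        )
    cands.sort()
    return [rsid for _, rsid in cands]


def greedy_clump(
    candidates: Sequence[str], ld: LDTable, clump_r2: float
) -> list[str]:
    """Greedy LD clumping: keep a candidate iff r2 < threshold with all kept.

    Candidates must arrive sorted ascending by p-value; the most significant
    variant of each LD block then dominates its neighbours, matching the
    standard clumping convention.  Deterministic given input order.
    """
    kept: list[str] = []
    for rsid in candidates:
        if all(ld.r2(rsid, k) < clump_r2 for k in kept):
            kept.append(rsid)
    return kept


def substitute_proxies(
    missing: Sequence[str],
    outcome: GWASSummaryTable,
    ld: LDTable,
    proxy_r2: float,
) -> dict[str, str | None]:
    """Find an outcome-present proxy (r2 >= threshold) for each missing SNP.

    The best proxy is the one with the highest r-squared; ties are broken by
    smaller outcome p-value, then lexicographic rsid.  SNPs with no
    qualifying proxy map to None and are dropped downstream.
    """
    mapping: dict[str, str | None] = {}
    for rsid in missing:
        best: tuple[float, float, str] | None = None  # (-r2, pvalue, rsid)
        for other, r2 in ld.neighbors(rsid).items():
            if r2 < proxy_r2 or other not in outcome:
                continue
            key = (-r2, outcome.records[other].pvalue, other)
            if best is None or key < best:
                best = key
        mapping[rsid] = best[2] if best is not None else None
        if mapping[rsid] is None:
            logger.info("no proxy with r2 >= %.2f for %s; dropping", proxy_r2, rsid)
    return mapping


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _align_outcome(
    exp: SummaryAssociation,
    out: SummaryAssociation,
    config: InstrumentSelectionConfig,
) -> tuple[float, bool] | str:
    """Align one outcome record onto the exposure's effect allele.

    Returns (aligned_beta, flipped) on success or a drop-action string.
    Palindromic variants are aligned purely by effect-allele frequency: both
    EAFs on the same side of 0.5 means the listed effect alleles refer to the
    same allele, opposite sides means they refer to opposite alleles.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return DROPPED_MISSING  # allele mismatch
        if exp.eaf is None or out.eaf is None:
            return DROPPED_PALINDROME  # frequency alignment undefined
        mafs = [exp.maf] if not config.palindrome_maf_both_samples else [exp.maf, out.maf]
        if any(m > config.palindrome_maf_max for m in mafs):  # type: ignore[operator]
            return DROPPED_PALINDROME
        concordant = (exp.eaf - 0.5) * (out.eaf - 0.5) >= 0.0
        return (out.beta, False) if concordant else (-out.beta, True)

    # Non-palindromic: try direct, swapped, complement, complement+swapped.
    if (o_ea, o_oa) == (e_ea, e_oa):
        return (out.beta, False)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return (-out.beta, True)
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return (out.beta, False)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return (-out.beta, True)
    return DROPPED_MISSING


def harmonize(
    exposure_instruments: Sequence[SummaryAssociation],
    outcome: GWASSummaryTable,
    config: InstrumentSelectionConfig,
    proxy_map: dict[str, str | None] | None = None,
) -> HarmonizedInstrumentSet:
    """Align outcome effects onto the exposure effect alleles.

    ``proxy_map`` (from :func:`substitute_proxies`) redirects instruments
    missing from the outcome table to their proxy's outcome record; the
    proxy's alleles are harmonized against the original instrument's alleles
    and its effect is used as-is, without r-squared rescaling.

    Every input instrument receives exactly one audit action.
    """
    proxy_map = proxy_map or {}
    rsids: list[str] = []
    g, sx, G, sy = [], [], [], []
    audit: dict[str, str] = {}
    used_proxies: dict[str, str] = {}

    for exp in exposure_instruments:
        out_rec = outcome.get(exp.rsid)
        via_proxy = False
        if out_rec is None:
            proxy = proxy_map.get(exp.rsid)
            if proxy is None:
                audit[exp.rsid] = DROPPED_MISSING
                continue
            out_rec = outcome.get(proxy)
            if out_rec is None:
                audit[exp.rsid] = DROPPED_MISSING
                continue
            via_proxy = True

        aligned = _align_outcome(exp, out_rec, config)
        if isinstance(aligned, str):
            audit[exp.rsid] = aligned
            continue
        beta_out, flipped = aligned
        rsids.append(exp.rsid)
        g.append(exp.beta)
        sx.append(exp.se)
        G.append(beta_out)
        sy.append(out_rec.se)
        if via_proxy:
            audit[exp.rsid] = PROXY_SUBSTITUTED
            used_proxies[exp.rsid] = out_rec.rsid
        else:
            audit[exp.rsid] = ALLELE_FLIPPED if flipped else KEPT

    if not rsids:
        raise HarmonizationError(
            f"no instruments could be harmonized against {outcome.trait_name!r}"
        )
    return HarmonizedInstrumentSet(
        rsids=rsids,
        gamma_hat=np.array(g),
        sigma_x=np.array(sx),
        Gamma_hat=np.array(G),
        sigma_y=np.array(sy),
        audit=audit,
        proxy_map=used_proxies,
    )


# ---------------------------------------------------------------------------
# Overlap check and instrument strength
# ---------------------------------------------------------------------------

def flag_overlap(
    exposure_instruments: Sequence[str],
    reverse_instruments: Sequence[str],
    ld: LDTable,
    r2_threshold: float = 0.8,
) -> list[str]:
    """Exposure instruments identical to, or in high LD with, any
    reverse-direction instrument.

    Such shared signals can induce spurious bi-directional associations;
    callers rerun the analysis without them as a sensitivity check.
    """
    rev = list(reverse_instruments)
    rev_set = set(rev)
    flagged = []
    for rsid in exposure_instruments:
        if rsid in rev_set or any(ld.r2(rsid, r) >= r2_threshold for r in rev):
            flagged.append(rsid)
    return flagged


def mean_f_statistic(instruments: HarmonizedInstrumentSet) -> tuple[float, np.ndarray]:
    """Mean per-SNP approximate F-statistic, (gamma/sigma_X)^2.

    F > 10 is the conventional bar for low weak-instrument bias.  Returns
    the mean and the per-SNP values.
    """
    per_snp = (instruments.gamma_hat / instruments.sigma_x) ** 2
    return float(per_snp.mean()), per_snp
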