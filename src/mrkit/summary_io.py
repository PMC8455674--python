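"""Reading, validating and writing GWAS summary-statistic tables.

A GWAS summary-statistic table carries, per variant, the estimated
per-allele association with one trait: effect/other allele, effect-allele
frequency (EAF), beta (log odds ratio for binary traits, raw units for
continuous ones), its standard error, and a p-value.  This module parses
headered delimited text into :class:`GWASSummaryTable`, applies the
variant-level exclusion rules used throughout two-sample Mendelian
randomization (biallelic single-base variants with an rs identifier only),
reads pairwise LD (r-squared) reference tables, and serializes estimator
results back to delimited text.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
RSID_PATTERN = re.compile(r"^rs\d+$", re.IGNORECASE)

#: Smallest positive double; p-values of exactly 0 are floored here.
MIN_PVALUE = np.nextafter(0.0, 1.0)

#: Canonical field names and the default source-column spellings.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
    "n_total": "n_total",
}

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_FIELDS = ("eaf", "n_cases", "n_controls", "n_total")


@dataclass
class SummaryAssociation:
    """One variant's estimated association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    n_total: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if self.pvalue == 0.0:
            logger.warning("%s: p-value of exactly 0 floored to %.3g", self.rsid, MIN_PVALUE)
            self.pvalue = float(MIN_PVALUE)
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf must be in [0, 1], got {self.eaf}")
        # Consistency between the reported p and the Wald p implied by beta/se
        # is advisory only: many GWAS report p from a different test.
        z = abs(self.beta / self.se)
        if z < 37:  # beyond this the normal tail underflows
            wald_p = 2.0 * stats.norm.sf(z)
            if wald_p > 0 and abs(math.log10(wald_p) - math.log10(self.pvalue)) > 1.0:
                logger.warning(
                    "%s: reported p=%.3g differs from Wald-implied p=%.3g",
                    self.rsid, self.pvalue, wald_p,
                )

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, if EAF is known."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class GWASSummaryTable:
    """A collection of per-variant associations for one trait.

    ``trait_type`` decides the reporting scale downstream: estimates against a
    binary trait are exponentiated to odds ratios, continuous ones stay as
    mean differences.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    records: dict[str, SummaryAssociation] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def get(self, rsid: str) -> SummaryAssociation | None:
        return self.records.get(rsid)

    def add(self, rec: SummaryAssociation) -> None:
        self.records[rec.rsid] = rec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records.values()])


class LDTable:
    """Sparse symmetric pairwise r-squared lookup.

    Absent pairs are treated as r-squared 0 (unlinked); self-pairs are 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return  # self-pairs are implicitly 1
        self._pairs[self._key(a, b)] = float(r2)
        self._adj.setdefault(a, {})[b] = float(r2)
        self._adj.setdefault(b, {})[a] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def neighbors(self, rsid: str) -> dict[str, float]:
        """All variants with a recorded nonzero r-squared against ``rsid``."""
        return dict(self._adj.get(rsid, {}))

    def __len__(self) -> int:
        return len(self._pairs)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary_table(
    path: str | Path,
    trait_type: str,
    trait_name: str | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    provenance: str = "",
) -> GWASSummaryTable:
    """Parse a headered delimited file into a :class:`GWASSummaryTable`.

    ``column_map`` maps canonical field names (``rsid``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n_*``) to the
    source file's column names; unmapped optional fields are simply absent.
    Rows with unparseable numerics in mandatory fields are dropped and
    counted.  Duplicate rsids keep the record with the smallest p-value.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP) if column_map is None else dict(column_map)
    missing = [f for f in MANDATORY_FIELDS if f not in cmap]
    if missing:
        raise ConfigurationError(f"column_map is missing mandatory field(s): {missing}")

    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mapped column {cmap[fld]!r} for field {fld!r} not present in {path.name}"
            )

    table = GWASSummaryTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        provenance=provenance or str(path),
    )
    n_dropped = 0
    n_duplicates = 0
    for _, row in df.iterrows():
        try:
            kwargs: dict[str, object] = {
                "rsid": str(row[cmap["rsid"]]).strip(),
                "effect_allele": str(row[cmap["effect_allele"]]).strip(),
                "other_allele": str(row[cmap["other_allele"]]).strip(),
                "beta": float(row[cmap["beta"]]),
                "se": float(row[cmap["se"]]),
                "pvalue": float(row[cmap["pvalue"]]),
            }
            for fld in OPTIONAL_FIELDS:
                col = cmap.get(fld)
                if col is not None and col in df.columns and pd.notna(row[col]):
                    kwargs[fld] = float(row[col])
            rec = SummaryAssociation(**kwargs)  # type: ignore[arg-type]
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.info("dropped unparseable row in %s: %s", path.name, exc)
            continue
        prev = table.records.get(rec.rsid)
        if prev is not None:
            n_duplicates += 1
            logger.warning("duplicate rsid %s in %s; keeping smaller p-value", rec.rsid, path.name)
            if rec.pvalue >= prev.pvalue:
                continue
        table.add(rec)

    if len(table) == 0:
        raise InputError(f"no parseable records in {path}")
    if n_dropped:
        logger.info("%s: dropped %d unparseable row(s)", path.name, n_dropped)
    table.provenance += f" (parsed={len(table)}, dropped={n_dropped}, duplicates={n_duplicates})"
    return table


def read_ld_table(path: str | Path, delimiter: str | None = None) -> LDTable:
    """Read a three-column (rsid_a, rsid_b, r2) delimited text file.

    A header row is tolerated: any row whose third field is not a float is
    skipped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"LD table not found: {path}")
    sep = delimiter or _detect_delimiter(path)
    ld = LDTable()
    with open(path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split(sep)]
            if len(parts) < 3:
                continue
            try:
                r2 = float(parts[2])
            except ValueError:
                continue  # header or malformed row
            ld.set(parts[0], parts[1], r2)
    return ld


# ---------------------------------------------------------------------------
# Variant-level exclusion rules
# ---------------------------------------------------------------------------

def filter_variants(table: GWASSummaryTable) -> tuple[GWASSummaryTable, dict[str, int]]:
    """Apply the variant-level exclusion rules, returning per-rule drop counts.

    Excluded are multi-base (indel) or identical allele pairs, alleles outside
    A/C/G/T, and variants without an rs-number identifier.  The operation is
    idempotent.
    """
    if len(table) == 0:
        raise InputError(f"cannot filter empty table for {table.trait_name}")
    kept: dict[str, SummaryAssociation] = {}
    drops = {"non_biallelic_or_indel": 0, "no_rs_number": 0}
    for rsid, rec in table.records.items():
        ea, oa = rec.effect_allele, rec.other_allele
        if ea not in VALID_BASES or oa not in VALID_BASES or ea == oa:
            drops["non_biallelic_or_indel"] += 1
            continue
        if not RSID_PATTERN.match(rsid):
            drops["no_rs_number"] += 1
            continue
        kept[rsid] = rec
    out = GWASSummaryTable(
        trait_name=table.trait_name,
        trait_type=table.trait_type,
        records=kept,
        provenance=table.provenance,
    )
    if sum(drops.values()):
        logger.info("%s: variant filter dropped %s", table.trait_name, drops)
    return out, drops


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "beta", "se", "ci_low", "ci_high",
    "pvalue", "or", "or_ci_low", "or_ci_high", "q_stat", "q_pvalue",
    "egger_intercept", "egger_intercept_pvalue", "i2_gx",
    "presso_global_pvalue", "presso_n_outliers", "presso_distortion_pvalue",
    "f_statistic", "significance_tier", "analysis",
]


def _fmt(x: object) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_results(results: Iterable, path: str | Path, delimiter: str = "\t") -> None:
    """Serialize direction results to delimited text, one row per (direction, method).

    Layout mirrors the conventional MR reporting table: estimate, 95% CI, P,
    heterogeneity Q and its P, Egger intercept P and I-squared(GX); binary
    outcomes additionally carry the exponentiated odds-ratio columns.
    Numbers are written to 6 significant digits and round-trip through
    :func:`read_results` losslessly at that precision.
    """
    results = list(results)
    if not results:
        raise InputError("write_results requires at least one DirectionResult")
    rows = []
    for dr in results:
        rows.extend(dr.to_rows())
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(delimiter.join(RESULT_COLUMNS) + "\n")
            for row in rows:
                fh.write(delimiter.join(_fmt(row.get(c)) for c in RESULT_COLUMNS) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"])
    return df


def write_audit_log(audit: Mapping, path: str | Path) -> None:
    """Write the per-stage audit trail (drops, flips, thresholds) as JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
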