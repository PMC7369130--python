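"""Readers and writers for the pipeline's external text formats.

Every coordinate inside the package is 0-based, half-open, which matches BED
on disk.  The bismark coverage dialect is 1-based with start == end per CpG;
positions are shifted on ingest and restored on write, so
``read_cpg_counts(write_cpg_counts(t))`` is the identity on
``(chrom, pos, n_meth, n_unmeth)``.

CpG count tables travel through the pipeline as pandas DataFrames with the
columns ``chrom, pos, n_meth, n_unmeth`` sorted by ``(chrom, pos)`` and
unique per position.  Input files are expected to be dyad-merged (one record
per CpG site, the standard bismark CpG-context coverage output); a duplicate
``(chrom, pos)`` row is rejected because the coverage dialect carries no
strand column that would allow collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

COUNT_COLUMNS = ("chrom", "pos", "n_meth", "n_unmeth")
FEATURE_CLASSES = ("CDS", "promoter", "CGI")
ARMS = ("control", "heat")
DESIGN_COLUMNS = ("sample_id", "father_group", "arm", "organ", "pooled")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotation interval (BED semantics: 0-based, half-open)."""

    chrom: str
    start: int
    end: int
    feature_class: str
    gene_id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# CpG count tables (bismark coverage dialect)
# ---------------------------------------------------------------------------

def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column layout, non-negative counts, sortedness and uniqueness."""
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"count table lacks columns {missing}")
    if len(table):
        if (table["n_meth"] < 0).any() or (table["n_unmeth"] < 0).any():
            raise ValidationError("negative read count in count table")
        key = table[["chrom", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate CpG record at {dup['chrom']}:{dup['pos']}"
            )
    return table


def _sorted_counts(table: pd.DataFrame) -> pd.DataFrame:
    out = table.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return out[list(COUNT_COLUMNS)]


def read_cpg_counts(path: str | Path, dialect: str = "bismark_cov") -> pd.DataFrame:
    """Read one sample's per-CpG counts.

    The bismark coverage dialect is tab-separated with columns
    ``chrom, start(1-based), end, percent_methylation, count_meth,
    count_unmeth``.  The percent column is ignored (it is recomputed from the
    counts downstream) and positions are shifted to 0-based.
    """
    if dialect != "bismark_cov":
        raise ValidationError(f"unsupported count dialect {dialect!r}")
    rows: list[tuple[str, int, int, int]] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start_s, _end, _pct, meth_s, unmeth_s = fields[:6]
            try:
                start = int(start_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative read count")
            if start < 1:
                raise ValidationError(f"{path}:{lineno}: 1-based position must be >= 1")
            rows.append((chrom, start - 1, n_meth, n_unmeth))
    table = pd.DataFrame(rows, columns=list(COUNT_COLUMNS))
    if not len(table):
        table = table.astype({"pos": "int64", "n_meth": "int64", "n_unmeth": "int64"})
    validate_count_table(table)
    return _sorted_counts(table)


def write_cpg_counts(table: pd.DataFrame, path: str | Path,
                     dialect: str = "bismark_cov") -> None:
    """Write a count table in the bismark coverage dialect (1-based positions)."""
    if dialect != "bismark_cov":
        raise ValidationError(f"unsupported count dialect {dialect!r}")
    validate_count_table(table)
    table = _sorted_counts(table)
    with open(path, "wt", encoding="utf-8") as handle:
        for chrom, pos, n_meth, n_unmeth in table.itertuples(index=False):
            total = n_meth + n_unmeth
            pct = 100.0 * n_meth / total if total else 0.0
            handle.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{n_meth}\t{n_unmeth}\n")


# ---------------------------------------------------------------------------
# Feature tracks (BED)
# ---------------------------------------------------------------------------

def read_bed_features(path: str | Path, feature_class: str) -> list[FeatureRecord]:
    """Read a BED3+ track as features of one class.

    Column 4 (name), when present and not ``"."``, carries the gene
    identifier; column 6 the strand.  Intervals are kept unchanged (BED is
    already 0-based half-open).
    """
    features: list[FeatureRecord] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            features.append(FeatureRecord(fields[0], start, end, feature_class, name, strand))
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    return features


def write_bed_features(features: Iterable[FeatureRecord], path: str | Path) -> None:
    feats = sorted(features, key=lambda f: (f.chrom, f.start, f.end))
    with open(path, "wt", encoding="utf-8") as handle:
        for f in feats:
            name = f.gene_id if f.gene_id else "."
            handle.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# Study design table
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design table lacks columns {missing}")
    if design["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in design table")
    bad = set(design["arm"]) - set(ARMS)
    if bad:
        raise ValidationError(f"unknown arm labels {sorted(bad)}; expected {ARMS}")
    return design


def read_design_table(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "father_group": str,
                                                "arm": str, "organ": str})
    if "pooled" in design.columns:
        design["pooled"] = design["pooled"].astype(bool)
    return validate_design(design)


def write_design_table(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design)
    design[list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMR / region BED output
# ---------------------------------------------------------------------------

def _dmr_bed_score(combined_score: float) -> int:
    """Display score for BED column 5: -log10 of the Stouffer two-sided p."""
    from scipy.stats import norm

    p = max(2.0 * norm.sf(abs(combined_score)), 1e-300)
    import math

    return min(1000, round(-math.log10(p)))


def write_dmr_bed(dmrs: Sequence, path: str | Path) -> None:
    """Write DMRs as BED6+ (extra columns: n_sites, mean_delta, direction,
    combined_score, father_group).  Sorted by (chrom, start)."""
    from .clustering import DMR  # local import to avoid a cycle

    dmrs = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("#chrom\tstart\tend\tname\tscore\tstrand\t"
                     "n_sites\tmean_delta\tdirection\tcombined_score\tfather_group\n")
        for i, d in enumerate(dmrs):
            if not isinstance(d, DMR):
                raise ValidationError("write_dmr_bed expects DMR objects")
            handle.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tdmr_{i + 1}\t"
                f"{_dmr_bed_score(d.combined_score)}\t.\t{d.n_sites}\t"
                f"{d.mean_delta!r}\t{d.direction}\t{d.combined_score!r}\t"
                f"{d.father_group or '.'}\n"
            )


def read_dmr_bed(path: str | Path) -> list:
    """Re-read a BED written by :func:`write_dmr_bed` into DMR objects."""
    from .clustering import DMR

    out: list[DMR] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ParseError(f"{path}:{lineno}: expected 11 DMR BED columns")
            group = f[10] if f[10] != "." else None
            out.append(DMR(chrom=f[0], start=int(f[1]), end=int(f[2]),
                           n_sites=int(f[6]), mean_delta=float(f[7]),
                           direction=f[8], combined_score=float(f[9]),
                           father_group=group))
    return out


def write_region_bed(regions: Sequence, path: str | Path) -> None:
    """Write congruent regions as BED4+ with the supporting-group count."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("#chrom\tstart\tend\tname\tsupport\n")
        for i, r in enumerate(regions):
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i + 1}\t{r.support}\n")


# ---------------------------------------------------------------------------
# Truth set (planted-DMR intervals, simulation only)
# ---------------------------------------------------------------------------

def write_truth_bed(truth: Sequence, path: str | Path) -> None:
    rows = sorted(truth, key=lambda t: (t.chrom, t.start, t.end))
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("#chrom\tstart\tend\tname\teffect\tn_cpgs\tdirection\n")
        for i, t in enumerate(rows):
            handle.write(f"{t.chrom}\t{t.start}\t{t.end}\ttruth_{i + 1}\t"
                         f"{t.effect!r}\t{t.n_cpgs}\t{t.direction}\n")


def read_truth_bed(path: str | Path) -> list:
    from .simulate import TruthRecord

    out = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 truth BED columns")
            out.append(TruthRecord(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                   effect=float(f[4]), n_cpgs=int(f[5]),
                                   direction=f[6]))
    return out
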