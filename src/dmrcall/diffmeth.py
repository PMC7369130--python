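"""Per-CpG differential methylation between the control and heat arms.

One comparison covers the sons of a single sire: the control arm (sired
before the father's heat exposure) versus the heat arm (sired after).  The
chain is

1. joint coverage filter -- keep only CpGs covered at >= ``min_coverage``
   reads in *every* sample of the comparison;
2. pool read counts by arm (summation; sire-pooled testis libraries are
   single samples and pass through unchanged);
3. a two-sided Fisher exact test on the pooled 2x2 table per CpG;
4. threshold at the site-level alpha and annotate each significant CpG with
   its methylation-ratio difference (heat - control) and direction.

The Fisher test uses the point-probability convention for two-sidedness: the
p-value sums every table of the hypergeometric support whose probability is
at most that of the observed table, with a 1+1e-7 relative guard so that
equal-probability tables are never misclassified by floating-point noise.
It is vectorised over sites because the permutation null re-tests every
position hundreds of times.

No site-level multiple-testing correction is applied anywhere in the
pipeline: the empirical error control is the per-position shuffle test
(:mod:`dmrcall.permutation`), which bounds the number of regions the whole
chain produces under the null.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, UndefinedRatioError, ValidationError
from .io_formats import validate_count_table

_REL_TOL = 1.0 + 1e-7

POOLED_COLUMNS = ("chrom", "pos", "ctrl_meth", "ctrl_unmeth", "heat_meth", "heat_unmeth")


def methylation_ratio(n_meth: int, n_unmeth: int) -> float:
    """C/(C+T): fraction of reads carrying the methylated state at one site."""
    total = n_meth + n_unmeth
    if total <= 0:
        raise UndefinedRatioError("methylation ratio undefined at zero coverage")
    return n_meth / total


def joint_coverage_filter(tables: Mapping[str, pd.DataFrame],
                          min_coverage: int = 5) -> pd.DataFrame:
    """Positions covered at >= ``min_coverage`` reads in every sample.

    A CpG absent from any one sample is dropped, as is a CpG below the
    threshold in any one sample.  Returns a ``(chrom, pos)`` frame sorted by
    position.
    """
    if not tables:
        raise ConfigurationError("joint_coverage_filter needs at least one sample")
    kept: pd.Index | None = None
    for sample_id in sorted(tables):
        table = validate_count_table(tables[sample_id])
        cov = table["n_meth"] + table["n_unmeth"]
        idx = pd.MultiIndex.from_frame(table.loc[cov >= min_coverage, ["chrom", "pos"]])
        kept = idx if kept is None else kept.intersection(idx)
    frame = kept.to_frame(index=False)
    return frame.sort_values(["chrom", "pos"], ignore_index=True)


def restrict_tables(tables: Mapping[str, pd.DataFrame],
                    positions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Subset every sample table to the given (chrom, pos) set, in order."""
    key = pd.MultiIndex.from_frame(positions[["chrom", "pos"]])
    out = {}
    for sample_id, table in tables.items():
        indexed = table.set_index(["chrom", "pos"])
        sub = indexed.loc[key]
        out[sample_id] = sub.reset_index()[["chrom", "pos", "n_meth", "n_unmeth"]]
    return out


def _arm_samples(design: pd.DataFrame, father_group: str, organ: str) -> dict[str, list[str]]:
    cell = design[(design["father_group"] == father_group) & (design["organ"] == organ)]
    arms = {arm: sorted(cell.loc[cell["arm"] == arm, "sample_id"]) for arm in ("control", "heat")}
    for arm, ids in arms.items():
        if not ids:
            raise ConfigurationError(
                f"father group {father_group!r} ({organ}) has no {arm} samples")
    return arms


def pool_counts_by_arm(tables: Mapping[str, pd.DataFrame], design: pd.DataFrame,
                       father_group: str, organ: str) -> pd.DataFrame:
    """Sum counts across the samples of each arm at every retained position.

    ``tables`` must already be restricted to the jointly covered positions of
    this comparison (all tables share one position set).  For sire-pooled
    inputs each arm holds a single sample and pooling is the identity.
    """
    arms = _arm_samples(design, father_group, organ)
    ref = None
    pooled: dict[str, np.ndarray] = {}
    for arm, ids in arms.items():
        meth = unmeth = None
        for sample_id in ids:
            if sample_id not in tables:
                raise ConfigurationError(f"no count table for sample {sample_id!r}")
            table = tables[sample_id]
            if ref is None:
                ref = table[["chrom", "pos"]].reset_index(drop=True)
            elif len(table) != len(ref) or not (
                    table["pos"].to_numpy() == ref["pos"].to_numpy()).all() or not (
                    table["chrom"].to_numpy() == ref["chrom"].to_numpy()).all():
                raise ValidationError(
                    "pool_counts_by_arm requires tables aligned on one position set; "
                    "apply joint_coverage_filter/restrict_tables first")
            m = table["n_meth"].to_numpy(dtype=np.int64)
            u = table["n_unmeth"].to_numpy(dtype=np.int64)
            meth = m if meth is None else meth + m
            unmeth = u if unmeth is None else unmeth + u
        prefix = "ctrl" if arm == "control" else "heat"
        pooled[f"{prefix}_meth"] = meth
        pooled[f"{prefix}_unmeth"] = unmeth
    out = ref.copy()
    for col in ("ctrl_meth", "ctrl_unmeth", "heat_meth", "heat_unmeth"):
        out[col] = pooled[col]
    return out


# ---------------------------------------------------------------------------
# Fisher exact test (vectorised, point-probability two-sided)
# ---------------------------------------------------------------------------

def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_two_sided(ctrl_meth, ctrl_unmeth, heat_meth, heat_unmeth) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables, vectorised over sites.

    For each table ``[[a, b], [c, d]]`` the full hypergeometric support of
    the first cell is enumerated and every table with point probability
    <= pmf(observed) * (1 + 1e-7) contributes.  Zero-margin tables (a whole
    row or column empty) have a single-table support and return p = 1.
    """
    a = np.atleast_1d(np.asarray(ctrl_meth, dtype=np.int64))
    b = np.atleast_1d(np.asarray(ctrl_unmeth, dtype=np.int64))
    c = np.atleast_1d(np.asarray(heat_meth, dtype=np.int64))
    d = np.atleast_1d(np.asarray(heat_unmeth, dtype=np.int64))
    a, b, c, d = np.broadcast_arrays(a, b, c, d)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValidationError("negative cell in 2x2 table")
    n1 = a + b          # control-arm total
    big_k = a + c       # methylated-read margin
    big_n = n1 + c + d  # grand total
    if not len(a):
        return np.empty(0, dtype=float)

    lo = np.maximum(0, n1 + big_k - big_n)
    hi = np.minimum(big_k, n1)
    lens = (hi - lo + 1).astype(np.int64)
    offsets = np.concatenate(([0], np.cumsum(lens)))
    ks = (np.arange(offsets[-1], dtype=np.int64)
          - np.repeat(offsets[:-1], lens) + np.repeat(lo, lens))
    r_n = np.repeat(big_n, lens).astype(float)
    r_k = np.repeat(big_k, lens).astype(float)
    r_n1 = np.repeat(n1, lens).astype(float)
    log_denom = _log_binom(r_n, r_n1)
    pmf = np.exp(_log_binom(r_k, ks.astype(float))
                 + _log_binom(r_n - r_k, r_n1 - ks.astype(float)) - log_denom)
    p_obs = np.exp(_log_binom(big_k.astype(float), a.astype(float))
                   + _log_binom((big_n - big_k).astype(float), (n1 - a).astype(float))
                   - _log_binom(big_n.astype(float), n1.astype(float)))
    include = pmf <= np.repeat(p_obs, lens) * _REL_TOL
    p = np.add.reduceat(np.where(include, pmf, 0.0), offsets[:-1])
    return np.minimum(p, 1.0)


def site_fisher_test(ctrl_meth: int, ctrl_unmeth: int,
                     heat_meth: int, heat_unmeth: int) -> float:
    """Scalar two-sided Fisher exact p for one pooled site (see vector form)."""
    if ctrl_meth + ctrl_unmeth <= 0 or heat_meth + heat_unmeth <= 0:
        raise ValidationError("both arm totals must be positive")
    return float(fisher_exact_two_sided(ctrl_meth, ctrl_unmeth, heat_meth, heat_unmeth)[0])


def is_degenerate(pooled: pd.DataFrame) -> np.ndarray:
    """True where the methylated (or unmethylated) margin is empty."""
    meth = pooled["ctrl_meth"].to_numpy() + pooled["heat_meth"].to_numpy()
    unmeth = pooled["ctrl_unmeth"].to_numpy() + pooled["heat_unmeth"].to_numpy()
    return (meth == 0) | (unmeth == 0)


def site_tests(pooled: pd.DataFrame) -> pd.DataFrame:
    """Fisher p, ratio difference and direction for every pooled site."""
    for col in POOLED_COLUMNS:
        if col not in pooled.columns:
            raise ValidationError(f"pooled table lacks column {col!r}")
    ctrl_tot = pooled["ctrl_meth"] + pooled["ctrl_unmeth"]
    heat_tot = pooled["heat_meth"] + pooled["heat_unmeth"]
    if (ctrl_tot <= 0).any() or (heat_tot <= 0).any():
        raise ValidationError("pooled site with an empty arm; filter first")
    out = pooled[["chrom", "pos"]].copy()
    out["p_value"] = fisher_exact_two_sided(
        pooled["ctrl_meth"], pooled["ctrl_unmeth"],
        pooled["heat_meth"], pooled["heat_unmeth"])
    delta = (pooled["heat_meth"] / heat_tot - pooled["ctrl_meth"] / ctrl_tot).to_numpy()
    out["delta"] = delta
    out["direction"] = np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "none"))
    out["degenerate"] = is_degenerate(pooled)
    for col in POOLED_COLUMNS[2:]:
        out[col] = pooled[col].to_numpy()
    return out


def call_differential_sites(pooled: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant CpGs: p < alpha (strict) and a non-zero ratio difference.

    Hyper- and hypomethylated sites are both retained; downstream gene-set
    work deliberately combines the two directions.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError("alpha must lie in (0, 1]")
    sites = site_tests(pooled) if "p_value" not in pooled.columns else pooled
    keep = (sites["p_value"].to_numpy() < alpha) & (sites["delta"].to_numpy() != 0.0)
    return sites.loc[keep].reset_index(drop=True)


def write_sites_table(sites: pd.DataFrame, path) -> None:
    """Debug/report TSV of per-site test results."""
    cols = ["chrom", "pos", "ctrl_meth", "ctrl_unmeth", "heat_meth", "heat_unmeth",
            "p_value", "delta", "direction"]
    sites.to_csv(path, sep="\t", index=False, columns=cols,
                 float_format="%.10g")
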