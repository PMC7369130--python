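"""Per-position permutation null for empirical false-positive control.

At every retained CpG independently, the (methylated, unmethylated) count
pairs are randomly reassigned among the samples of one comparison while the
arm labels stay fixed; the full filter -> test -> cluster chain then runs on
the shuffled data and the number of regions it calls is recorded.  Repeated
(100 times per sire group by default) this measures how many DMRs the
pipeline produces when there is no real group difference.

The underlying count pairs are shuffled rather than the ratios alone: the
Fisher test consumes counts, and the ratio is a deterministic function of
the pair, so permuting pairs realises the same randomisation while keeping
the test defined.  Shuffling across all samples of the comparison (both
arms) is the standard two-group permutation null.

One master seed; permutation ``i`` draws from the substream ``(seed, i)``,
so any single permutation is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import cluster_sites
from .config import DmrCallParams
from .diffmeth import (_arm_samples, fisher_exact_two_sided,
                       joint_coverage_filter, restrict_tables)
from .errors import ValidationError


@dataclass(frozen=True)
class NullSummary:
    n_permutations: int
    dmr_counts: tuple
    max_count: int
    mean_count: float
    seed: int


def _stack_tables(tables: Mapping[str, pd.DataFrame]):
    """Align sample tables (identical position sets required) into arrays."""
    sample_ids = sorted(tables)
    if len(sample_ids) < 2:
        raise ValidationError("permutation needs at least two samples")
    ref = tables[sample_ids[0]][["chrom", "pos"]].reset_index(drop=True)
    meth = np.empty((len(sample_ids), len(ref)), dtype=np.int64)
    unmeth = np.empty_like(meth)
    for i, sid in enumerate(sample_ids):
        t = tables[sid]
        if len(t) != len(ref) or not (t["pos"].to_numpy() == ref["pos"].to_numpy()).all() \
                or not (t["chrom"].to_numpy() == ref["chrom"].to_numpy()).all():
            raise ValidationError(
                "samples must share one position set; restrict to jointly covered CpGs")
        meth[i] = t["n_meth"].to_numpy()
        unmeth[i] = t["n_unmeth"].to_numpy()
    return sample_ids, ref, meth, unmeth


def _permute(meth: np.ndarray, unmeth: np.ndarray, rng: np.random.Generator):
    """Independently permute the sample axis at every position."""
    n_samples, n_pos = meth.shape
    order = np.argsort(rng.random((n_samples, n_pos)), axis=0)
    cols = np.arange(n_pos)
    return meth[order, cols], unmeth[order, cols]


def shuffle_per_position(tables: Mapping[str, pd.DataFrame],
                         rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Return new tables with count pairs reassigned among samples per site."""
    sample_ids, ref, meth, unmeth = _stack_tables(tables)
    pm, pu = _permute(meth, unmeth, rng)
    out = {}
    for i, sid in enumerate(sample_ids):
        t = ref.copy()
        t["n_meth"] = pm[i]
        t["n_unmeth"] = pu[i]
        out[sid] = t
    return out


def run_shuffle_test(tables: Mapping[str, pd.DataFrame], design: pd.DataFrame,
                     father_group: str, organ: str,
                     params: DmrCallParams = DmrCallParams(),
                     n_permutations: int = 100, seed: int = 0) -> NullSummary:
    """Permute, re-run the calling chain, and count DMRs per permutation.

    ``params`` must equal the real analysis' parameters for the counts to be
    interpretable as that analysis' empirical false-positive rate.
    """
    params.validate()
    arms = _arm_samples(design, father_group, organ)
    comparison = {sid: tables[sid] for ids in arms.values() for sid in ids}
    positions = joint_coverage_filter(comparison, params.min_coverage)
    restricted = restrict_tables(comparison, positions)
    sample_ids, ref, meth, unmeth = _stack_tables(restricted)
    ctrl_rows = np.array([sample_ids.index(s) for s in arms["control"]])
    heat_rows = np.array([sample_ids.index(s) for s in arms["heat"]])
    chroms = ref["chrom"].to_numpy()
    pos = ref["pos"].to_numpy()

    counts = []
    for i in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        try:
            pm, pu = _permute(meth, unmeth, rng)
            cm = pm[ctrl_rows].sum(axis=0)
            cu = pu[ctrl_rows].sum(axis=0)
            hm = pm[heat_rows].sum(axis=0)
            hu = pu[heat_rows].sum(axis=0)
            p = fisher_exact_two_sided(cm, cu, hm, hu)
            with np.errstate(invalid="ignore"):
                delta = hm / (hm + hu) - cm / (cm + cu)
            keep = (p < params.alpha) & (delta != 0.0)
            sig = pd.DataFrame({"chrom": chroms[keep], "pos": pos[keep],
                                "p_value": p[keep], "delta": delta[keep]})
            dmrs = cluster_sites(sig, max_gap=params.max_gap,
                                 min_sites=params.min_sites,
                                 break_on_nonsig=params.break_on_nonsig,
                                 tested_positions=ref if params.break_on_nonsig else None)
        except Exception as exc:
            raise type(exc)(f"permutation {i}: {exc}") from exc
        counts.append(len(dmrs))
    counts_t = tuple(counts)
    return NullSummary(n_permutations=n_permutations, dmr_counts=counts_t,
                       max_count=max(counts_t, default=0),
                       mean_count=float(np.mean(counts_t)) if counts_t else 0.0,
                       seed=seed)


def write_null_report(summary: NullSummary, path) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("permutation\tdmr_count\n")
        for i, c in enumerate(summary.dmr_counts):
            handle.write(f"{i}\t{c}\n")
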