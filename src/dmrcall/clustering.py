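"""Aggregate significant CpGs into differentially methylated regions.

A DMR is a maximal run of significant CpGs on one chromosome in which the
distance between consecutive member positions is at most ``max_gap``
(default 100 bp, read inclusively: a gap of exactly 100 still joins).  Runs
with fewer than ``min_sites`` members (default 2) are discarded -- a region
needs at least two CpGs.

By default the run structure is computed over significant sites only:
covered-but-non-significant CpGs inside a run neither join nor break it.
``break_on_nonsig=True`` switches to the stricter reading in which any
tested, non-significant CpG between two significant ones breaks the run
(``tested_positions`` must then be supplied).

Each region carries a Stouffer-combined z across its member sites,
z = sum_i( Phi^{-1}(1 - p_i/2) * sign(delta_i) ) / sqrt(n).  The score is
reported for ranking and export only; the default pipeline never filters
on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError


@dataclass(frozen=True)
class DMR:
    """One differentially methylated region (0-based, half-open)."""

    chrom: str
    start: int
    end: int            # last member CpG position + 1
    n_sites: int
    mean_delta: float
    direction: str      # hyper | hypo | mixed
    combined_score: float
    father_group: str | None = None


def score_dmr(p_values: Sequence[float], deltas: Sequence[float]) -> tuple[float, float, str]:
    """Stouffer-combined z, mean ratio difference and direction of a run."""
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if len(p) == 0 or len(p) != len(d):
        raise ValidationError("score_dmr needs matching, non-empty p and delta vectors")
    z = norm.isf(p / 2.0) * np.sign(d)
    combined = float(z.sum() / np.sqrt(len(z)))
    mean_delta = float(d.mean())
    if (d > 0).all():
        direction = "hyper"
    elif (d < 0).all():
        direction = "hypo"
    else:
        direction = "mixed"
    return combined, mean_delta, direction


def cluster_sites(sites: pd.DataFrame, max_gap: int = 100, min_sites: int = 2,
                  father_group: str | None = None,
                  break_on_nonsig: bool = False,
                  tested_positions: pd.DataFrame | None = None) -> list[DMR]:
    """Cluster significant CpGs into DMRs with the inclusive gap rule.

    ``sites`` needs columns ``chrom, pos, p_value, delta`` sorted by
    ``(chrom, pos)``; rows from one comparison only.
    """
    for col in ("chrom", "pos", "p_value", "delta"):
        if col not in sites.columns:
            raise ValidationError(f"sites table lacks column {col!r}")
    if break_on_nonsig and tested_positions is None:
        raise ValidationError("break_on_nonsig requires tested_positions")

    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    order = np.lexsort((pos, chroms))
    if not (order == np.arange(len(sites))).all():
        raise ValidationError("sites must be sorted by (chrom, pos)")

    tested: dict[str, np.ndarray] = {}
    if break_on_nonsig:
        for chrom, grp in tested_positions.groupby("chrom", sort=False):
            tested[chrom] = np.sort(grp["pos"].to_numpy())

    dmrs: list[DMR] = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos[mask]
        cp = sites["p_value"].to_numpy()[mask]
        cd = sites["delta"].to_numpy()[mask]
        if len(cpos) == 0:
            continue
        breaks = np.diff(cpos) > max_gap
        if break_on_nonsig and chrom in tested:
            tpos = tested[chrom]
            # a tested position strictly between two consecutive members that
            # is not itself a member breaks the run
            member = np.isin(tpos, cpos)
            nonsig = tpos[~member]
            between = (np.searchsorted(nonsig, cpos[1:], side="left")
                       - np.searchsorted(nonsig, cpos[:-1], side="right")) > 0
            breaks = breaks | between
        run_starts = np.concatenate(([0], np.flatnonzero(breaks) + 1))
        run_ends = np.concatenate((np.flatnonzero(breaks) + 1, [len(cpos)]))
        for lo, hi in zip(run_starts, run_ends):
            if hi - lo < min_sites:
                continue
            combined, mean_delta, direction = score_dmr(cp[lo:hi], cd[lo:hi])
            dmrs.append(DMR(chrom=str(chrom), start=int(cpos[lo]),
                            end=int(cpos[hi - 1]) + 1, n_sites=int(hi - lo),
                            mean_delta=mean_delta, direction=direction,
                            combined_score=combined, father_group=father_group))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs
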