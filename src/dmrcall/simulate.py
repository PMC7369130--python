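"""RRBS-like synthetic data with planted differentially methylated regions.

The generator emulates the study design the pipeline targets: five sire
("father") groups F-J, each with a control arm (sons sired before the
father's heat exposure) and a heat arm (sons sired after); liver-style data
carry one count table per individual son, testis-style data one
sire-pooled table per (father, arm).

Structure of the simulated methylome:

* a small genome with annotated genes (one CDS interval per gene body, a
  promoter defined as the 2,000 bp immediately upstream of the gene start,
  strand-aware) and CpG islands, some of which sit on promoters;
* CpG positions with geometric inter-CpG gaps, dense inside islands and
  sparse outside.  The background spacing default (1 kb) is deliberately
  sparse: it models the CpG set that *survives* a joint >=5x coverage
  filter across all samples of a comparison, which strongly restricts the
  retained sites;
* bimodal per-site baseline methylation, Beta-distributed around a low
  island mean and a high background mean;
* read counts: per sample and CpG, coverage ~ Poisson(coverage_mean)
  truncated to >= 1 and methylated reads ~ beta-binomial with a small
  between-individual overdispersion.  Sire-specific random intercepts (on
  the logit scale, shared by both arms of a family) induce the congruence
  structure between groups without disturbing control-vs-heat null
  calibration;
* planted DMRs: runs of ``planted_width_cpgs`` consecutive CpGs whose heat-
  arm methylation is shifted by ``planted_effect`` (hyper where the local
  baseline is low, hypo where it is high; always clipped to [0.01, 0.99]).

Randomness is fully determined by ``params.seed``: annotation, landscape,
baselines, sire intercepts and truth placement each use a tagged substream,
and every sample uses a stream keyed by (seed, crc32(sample_id)), so adding
samples never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, ValidationError
from .io_formats import (FeatureRecord, write_bed_features, write_cpg_counts,
                         write_design_table, write_truth_bed)

_STREAM_ANNOTATION = 1
_STREAM_LANDSCAPE = 2
_STREAM_BASELINE = 3
_STREAM_FATHERS = 4
_STREAM_TRUTH = 5
_STREAM_SAMPLE_BASE = 1000

_EFFECT_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes_per_chrom: int = 12
    gene_length: int = 4_000
    promoter_length: int = 2_000
    n_islands_per_chrom: int = 10
    island_length: int = 500
    island_cpg_spacing: float = 60.0
    background_cpg_spacing: float = 1000.0
    baseline_meth_island: float = 0.15
    baseline_meth_background: float = 0.90
    baseline_concentration: float = 6.0
    overdispersion: float = 0.005
    coverage_mean: float = 10.0
    n_father_groups: int = 5
    father_labels: tuple = ("F", "G", "H", "I", "J")
    samples_per_cell: int = 3
    pooled: bool = False
    father_sd: float = 0.3
    n_planted_dmrs: int = 10
    planted_effect: float = 0.4
    planted_width_cpgs: int = 5
    organ: str = "liver"
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if not 0.0 < self.baseline_meth_island < 1.0:
            raise ConfigurationError("baseline_meth_island must lie in (0,1)")
        if not 0.0 < self.baseline_meth_background < 1.0:
            raise ConfigurationError("baseline_meth_background must lie in (0,1)")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ConfigurationError("overdispersion must lie in [0,1)")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.island_cpg_spacing < 1 or self.background_cpg_spacing < 1:
            raise ConfigurationError("CpG spacings must be >= 1 bp")
        if self.n_father_groups < 1:
            raise ConfigurationError("need at least one father group")
        if len(self.father_labels) < self.n_father_groups:
            raise ConfigurationError("not enough father labels for n_father_groups")
        if self.n_planted_dmrs < 0 or self.planted_width_cpgs < 1:
            raise ConfigurationError("invalid planted-DMR parameters")
        if self.samples_per_cell < 1 and not self.pooled:
            raise ConfigurationError("samples_per_cell must be >= 1")
        return self

    @property
    def fathers(self) -> tuple:
        return tuple(self.father_labels[: self.n_father_groups])


@dataclass(frozen=True)
class TruthRecord:
    """A planted DMR interval (evaluation scaffolding, not pipeline input)."""

    chrom: str
    start: int
    end: int
    effect: float          # signed methylation-ratio shift in the heat arm
    n_cpgs: int
    direction: str         # hyper | hypo


@dataclass(frozen=True)
class CpGLandscape:
    """CpG positions plus their per-site baseline methylation."""

    positions: Mapping[str, np.ndarray]
    baseline: Mapping[str, np.ndarray]
    island_mask: Mapping[str, np.ndarray]


@dataclass(frozen=True)
class SimulatedDataset:
    params: SimulationParams
    design: pd.DataFrame
    annotation: Mapping[str, Sequence[FeatureRecord]]
    landscape: CpGLandscape
    truth: tuple
    tables: Mapping[str, pd.DataFrame]


def _rng(params: SimulationParams, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, *tags]))


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(params: SimulationParams) -> dict[str, list[FeatureRecord]]:
    """Genes (CDS + strand-aware upstream promoter) and CpG islands.

    Genes are laid out in per-chromosome slots so that gene+promoter blocks
    never overlap; CGIs are placed independently, with roughly half of them
    centred on a transcription start so that promoter/CGI overlaps occur.
    """
    params.validate()
    rng = _rng(params, _STREAM_ANNOTATION)
    tracks: dict[str, list[FeatureRecord]] = {"CDS": [], "promoter": [], "CGI": []}
    margin = params.promoter_length + 500
    for ci in range(params.n_chroms):
        chrom = _chrom_name(ci)
        tss: list[tuple[int, str]] = []  # (tss position, strand)
        if params.n_genes_per_chrom > 0:
            slot = params.chrom_length // params.n_genes_per_chrom
            if slot < params.gene_length + 2 * margin:
                raise ConfigurationError(
                    f"chromosome too short for {params.n_genes_per_chrom} genes "
                    f"of {params.gene_length} bp plus promoters")
            for gi in range(params.n_genes_per_chrom):
                lo = gi * slot + margin
                hi = (gi + 1) * slot - params.gene_length - margin
                start = int(rng.integers(lo, hi + 1))
                end = start + params.gene_length
                strand = "+" if rng.random() < 0.5 else "-"
                gene_id = f"gene_{chrom}_{gi + 1:03d}"
                tracks["CDS"].append(FeatureRecord(chrom, start, end, "CDS",
                                                   gene_id, strand))
                if strand == "+":
                    prom = FeatureRecord(chrom, start - params.promoter_length,
                                         start, "promoter", gene_id, strand)
                    tss.append((start, strand))
                else:
                    prom = FeatureRecord(chrom, end, end + params.promoter_length,
                                         "promoter", gene_id, strand)
                    tss.append((end, strand))
                tracks["promoter"].append(prom)
        placed: list[tuple[int, int]] = []
        for _ in range(params.n_islands_per_chrom):
            for _try in range(200):
                if tss and rng.random() < 0.5:
                    centre, _strand = tss[int(rng.integers(len(tss)))]
                else:
                    centre = int(rng.integers(params.island_length,
                                              params.chrom_length - params.island_length))
                start = max(0, centre - params.island_length // 2)
                end = min(params.chrom_length, start + params.island_length)
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise ConfigurationError("could not place CpG islands without overlap")
        for ii, (start, end) in enumerate(sorted(placed)):
            tracks["CGI"].append(FeatureRecord(chrom, start, end, "CGI", "", "."))
    for track in tracks.values():
        track.sort(key=lambda f: (f.chrom, f.start, f.end))
    return tracks


# ---------------------------------------------------------------------------
# CpG landscape
# ---------------------------------------------------------------------------

def _positions_with_spacing(rng, start: int, end: int, mean_gap: float) -> list[int]:
    out = []
    pos = start + int(rng.geometric(1.0 / mean_gap))
    while pos < end:
        out.append(pos)
        pos += int(rng.geometric(1.0 / mean_gap))
    return out


def generate_cpg_landscape(annotation: Mapping[str, Sequence[FeatureRecord]],
                           params: SimulationParams) -> CpGLandscape:
    """Geometric inter-CpG gaps, dense inside islands; baselines per site."""
    params.validate()
    rng = _rng(params, _STREAM_LANDSCAPE)
    rng_base = _rng(params, _STREAM_BASELINE)
    positions: dict[str, np.ndarray] = {}
    baseline: dict[str, np.ndarray] = {}
    island_mask: dict[str, np.ndarray] = {}
    cgis = [f for f in annotation.get("CGI", [])]
    conc = params.baseline_concentration
    for ci in range(params.n_chroms):
        chrom = _chrom_name(ci)
        islands = sorted((f.start, f.end) for f in cgis if f.chrom == chrom)
        pos_list: list[int] = []
        mask_list: list[bool] = []
        cursor = 0
        for s, e in islands + [(params.chrom_length, params.chrom_length)]:
            bg = _positions_with_spacing(rng, cursor, s, params.background_cpg_spacing)
            pos_list.extend(bg)
            mask_list.extend([False] * len(bg))
            isl = _positions_with_spacing(rng, s, e, params.island_cpg_spacing)
            pos_list.extend(isl)
            mask_list.extend([True] * len(isl))
            cursor = e
        pos_arr = np.asarray(pos_list, dtype=np.int64)
        mask_arr = np.asarray(mask_list, dtype=bool)
        means = np.where(mask_arr, params.baseline_meth_island,
                         params.baseline_meth_background)
        base = rng_base.beta(means * conc, (1.0 - means) * conc)
        positions[chrom] = pos_arr
        baseline[chrom] = np.clip(base, *_EFFECT_CLIP)
        island_mask[chrom] = mask_arr
    return CpGLandscape(positions=positions, baseline=baseline, island_mask=island_mask)


# ---------------------------------------------------------------------------
# Truth placement
# ---------------------------------------------------------------------------

def plant_truth(landscape: CpGLandscape, params: SimulationParams,
                max_internal_gap: int = 100, min_separation: int = 500,
                ) -> tuple[TruthRecord, ...]:
    """Choose disjoint runs of consecutive CpGs to carry the planted effect.

    Preferred ('tight') windows have every internal gap <=
    ``max_internal_gap``, so a planted region is recoverable as a single
    DMR under the default clustering gap.  When the landscape offers too
    few tight windows, windows with at most one wider internal gap (up to
    3 x ``max_internal_gap``) fill the remainder; such a region clusters as
    two sub-runs that both overlap the truth interval, so recovery by
    interval overlap is preserved.  Windows keep >= ``min_separation`` bp
    apart.
    """
    params.validate()
    if params.n_planted_dmrs == 0 or params.planted_effect == 0.0:
        return ()
    rng = _rng(params, _STREAM_TRUTH)
    w = params.planted_width_cpgs
    tiers: tuple[list[tuple[str, int, int]], ...] = ([], [])  # tight, relaxed
    for chrom in sorted(landscape.positions):
        pos = landscape.positions[chrom]
        if len(pos) < w:
            continue
        gaps = np.diff(pos)
        if w > 1:
            gw = np.lib.stride_tricks.sliding_window_view(gaps, w - 1)
            tight = (gw <= max_internal_gap).all(axis=1)
            relaxed = (~tight & ((gw > max_internal_gap).sum(axis=1) <= 1)
                       & (gw <= 3 * max_internal_gap).all(axis=1))
        else:
            tight = np.ones(len(pos), dtype=bool)
            relaxed = np.zeros(len(pos), dtype=bool)
        for i in np.flatnonzero(tight):
            tiers[0].append((chrom, int(i), int(i + w - 1)))
        for i in np.flatnonzero(relaxed):
            tiers[1].append((chrom, int(i), int(i + w - 1)))
    chosen: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tier in tiers:
        for oi in rng.permutation(len(tier)):
            chrom, i0, i1 = tier[oi]
            pos = landscape.positions[chrom]
            s, e = int(pos[i0]), int(pos[i1]) + 1
            spans = occupied.setdefault(chrom, [])
            if all(e + min_separation <= a or s >= b + min_separation for a, b in spans):
                spans.append((s, e))
                chosen.append((chrom, i0, i1))
            if len(chosen) == params.n_planted_dmrs:
                break
        if len(chosen) == params.n_planted_dmrs:
            break
    if len(chosen) < params.n_planted_dmrs:
        raise ConfigurationError(
            f"landscape offers only {len(chosen)} disjoint tight windows; "
            f"requested {params.n_planted_dmrs}")
    truths = []
    for chrom, i0, i1 in sorted(chosen):
        pos = landscape.positions[chrom]
        base = landscape.baseline[chrom][i0:i1 + 1]
        direction = "hyper" if float(base.mean()) < 0.5 else "hypo"
        effect = params.planted_effect if direction == "hyper" else -params.planted_effect
        truths.append(TruthRecord(chrom=chrom, start=int(pos[i0]),
                                  end=int(pos[i1]) + 1, effect=float(effect),
                                  n_cpgs=i1 - i0 + 1, direction=direction))
    return tuple(truths)


# ---------------------------------------------------------------------------
# Study design and counts
# ---------------------------------------------------------------------------

def make_design(params: SimulationParams) -> pd.DataFrame:
    """Sample sheet for one organ: per-son tables, or sire-pooled ones."""
    rows = []
    for father in params.fathers:
        for arm in ("control", "heat"):
            if params.pooled:
                rows.append((f"{params.organ}_{father}_{arm}_pool", father, arm,
                             params.organ, True))
            else:
                for i in range(params.samples_per_cell):
                    rows.append((f"{params.organ}_{father}_{arm}_s{i + 1}", father,
                                 arm, params.organ, False))
    return pd.DataFrame(rows, columns=["sample_id", "father_group", "arm",
                                       "organ", "pooled"])


def _sample_rng(params: SimulationParams, sample_id: str) -> np.random.Generator:
    tag = zlib.crc32(sample_id.encode("utf-8")) % (2 ** 30)
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, _STREAM_SAMPLE_BASE, tag]))


def simulate_counts(landscape: CpGLandscape, design: pd.DataFrame,
                    truth: Sequence[TruthRecord], params: SimulationParams,
                    ) -> dict[str, pd.DataFrame]:
    """Beta-binomial counts per sample over the landscape CpGs."""
    params.validate()
    chroms = sorted(landscape.positions)
    for t in truth:
        if t.chrom not in landscape.positions:
            raise ValidationError(f"truth interval on unknown chromosome {t.chrom}")
        pos = landscape.positions[t.chrom]
        inside = (pos >= t.start) & (pos < t.end)
        if not inside.any():
            raise ValidationError(
                f"truth interval {t.chrom}:{t.start}-{t.end} covers no landscape CpG")

    rng_f = _rng(params, _STREAM_FATHERS)
    father_offset = {father: float(rng_f.normal(0.0, params.father_sd))
                     for father in params.fathers}

    # per-chromosome heat-arm effect vector
    effect = {chrom: np.zeros(len(landscape.positions[chrom])) for chrom in chroms}
    for t in truth:
        pos = landscape.positions[t.chrom]
        inside = (pos >= t.start) & (pos < t.end)
        effect[t.chrom][inside] = t.effect

    rho = params.overdispersion
    tables: dict[str, pd.DataFrame] = {}
    for row in design.itertuples(index=False):
        rng = _sample_rng(params, row.sample_id)
        if row.father_group not in father_offset:
            raise ConfigurationError(
                f"design sample {row.sample_id!r} references unknown father "
                f"group {row.father_group!r}")
        frames = []
        for chrom in chroms:
            base = landscape.baseline[chrom]
            p = base if row.arm == "control" else np.clip(base + effect[chrom],
                                                          *_EFFECT_CLIP)
            p = expit(logit(p) + father_offset[row.father_group])
            cov = np.maximum(1, rng.poisson(params.coverage_mean, len(p)))
            if rho > 0.0:
                shape = (1.0 - rho) / rho
                p_draw = rng.beta(p * shape, (1.0 - p) * shape)
            else:
                p_draw = p
            meth = rng.binomial(cov, p_draw)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": landscape.positions[chrom],
                "n_meth": meth.astype(np.int64),
                "n_unmeth": (cov - meth).astype(np.int64),
            }))
        tables[row.sample_id] = pd.concat(frames, ignore_index=True)
    return tables


def generate_dataset(params: SimulationParams,
                     outdir: str | Path | None = None) -> SimulatedDataset:
    """End-to-end generation; optionally write all pipeline input files.

    Written layout: ``counts/<sample>.cov`` (bismark coverage dialect),
    ``design.tsv``, ``annotation/{cds,promoter,cgi}.bed`` and ``truth.bed``.
    """
    params.validate()
    annotation = generate_annotation(params)
    landscape = generate_cpg_landscape(annotation, params)
    truth = plant_truth(landscape, params)
    design = make_design(params)
    tables = simulate_counts(landscape, design, truth, params)
    dataset = SimulatedDataset(params=params, design=design, annotation=annotation,
                               landscape=landscape, truth=truth, tables=tables)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "counts").mkdir(parents=True, exist_ok=True)
        (outdir / "annotation").mkdir(exist_ok=True)
        for sample_id, table in tables.items():
            write_cpg_counts(table, outdir / "counts" / f"{sample_id}.cov")
        write_design_table(design, outdir / "design.tsv")
        for cls, fname in (("CDS", "cds.bed"), ("promoter", "promoter.bed"),
                           ("CGI", "cgi.bed")):
            write_bed_features(annotation[cls], outdir / "annotation" / fname)
        write_truth_bed(truth, outdir / "truth.bed")
    return dataset


def null_params(params: SimulationParams) -> SimulationParams:
    """The same design with no planted effect (for null/permutation studies)."""
    return replace(params, planted_effect=0.0, n_planted_dmrs=0)
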