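"""End-to-end orchestration: counts -> DMRs -> congruence -> genes -> null.

For every organ in the design and every father group, the chain
filter -> pool -> Fisher -> cluster runs independently (results do not
depend on execution order; all outputs are sorted).  Per organ, the group
DMR sets are intersected (k_min groups: 4 of 5 for liver, all 5 for
testis), congruent regions are annotated against the CDS/promoter/CGI
tracks, and gene lists are derived.  When both organs are present the
DMR-linked genes are partitioned into liver-only / testis-only / shared.
The per-position shuffle test then reruns the identical chain on permuted
data, 100 times per group by default.

Stage-level logging reports counts in and out of every filter so the
attrition chain (sites -> significant sites -> DMRs -> congruent ->
annotated -> genes) is always visible.  A manifest records parameters,
seed, input checksums and output checksums; two runs with one config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .clustering import DMR, cluster_sites
from .config import PipelineConfig
from .congruence import (AnnotatedDMR, CongruentRegion, annotate_dmrs,
                         export_gene_list, genes_from_dmrs, partition_gene_sets,
                         write_annotated_report)
from .diffmeth import (call_differential_sites, joint_coverage_filter,
                       pool_counts_by_arm, restrict_tables, site_tests,
                       write_sites_table)
from .errors import ConfigurationError, DmrcallError
from .io_formats import (read_bed_features, read_cpg_counts, read_design_table,
                         read_truth_bed, write_dmr_bed, write_region_bed)
from .permutation import run_shuffle_test, write_null_report

logger = logging.getLogger("dmrcall")


@dataclass
class OrganResult:
    organ: str
    dmrs_by_group: dict = field(default_factory=dict)
    congruent: list = field(default_factory=list)
    annotated: list = field(default_factory=list)
    genes: set = field(default_factory=set)
    null_summaries: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: PipelineConfig
    organs: dict
    partition: object = None
    evaluation: dict | None = None
    manifest: dict | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(organ: str, group: str | None, stage: str):
    label = f"[{organ}{'/' + group if group else ''}] {stage}"

    def fail(exc: Exception) -> DmrcallError:
        return DmrcallError(f"stage {label} failed: {exc}")

    return label, fail


def call_group_dmrs(tables: Mapping[str, pd.DataFrame], design: pd.DataFrame,
                    father_group: str, organ: str, config: PipelineConfig,
                    ) -> tuple[pd.DataFrame, list[DMR]]:
    """filter -> pool -> test -> cluster for one (organ, father group)."""
    call = config.call
    comparison_ids = design.loc[
        (design["father_group"] == father_group) & (design["organ"] == organ),
        "sample_id"]
    missing = [sid for sid in comparison_ids if sid not in tables]
    if missing:
        raise ConfigurationError(f"no count tables for samples {missing}")
    comparison = {sid: tables[sid] for sid in comparison_ids}
    positions = joint_coverage_filter(comparison, call.min_coverage)
    restricted = restrict_tables(comparison, positions)
    pooled = pool_counts_by_arm(restricted, design, father_group, organ)
    sites = site_tests(pooled)
    significant = call_differential_sites(sites, call.alpha)
    dmrs = cluster_sites(significant, max_gap=call.max_gap, min_sites=call.min_sites,
                         father_group=father_group,
                         break_on_nonsig=call.break_on_nonsig,
                         tested_positions=positions if call.break_on_nonsig else None)
    logger.info("[%s/%s] %d joint CpGs -> %d significant -> %d DMRs",
                organ, father_group, len(positions), len(significant), len(dmrs))
    return sites, dmrs


def evaluate_against_truth(regions: Sequence, truth: Sequence) -> dict:
    """Recall/precision of called regions against planted intervals.

    A call matches a truth record iff they share >= 1 bp.  With no calls,
    precision is reported as 1.0 together with an explicit ``no_calls``
    flag (no false positives were produced), keeping summaries numeric.
    The boundary error averages |start - start| and |end - end| over
    matched call/truth pairs.
    """
    def overlaps(a, b) -> bool:
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    matched_truth = [t for t in truth if any(overlaps(r, t) for r in regions)]
    matching_calls = [r for r in regions if any(overlaps(r, t) for t in truth)]
    recall = len(matched_truth) / len(truth) if truth else 1.0
    no_calls = len(regions) == 0
    precision = 1.0 if no_calls else len(matching_calls) / len(regions)
    errors = []
    for r in matching_calls:
        best = min((0.5 * (abs(r.start - t.start) + abs(r.end - t.end)))
                   for t in truth if overlaps(r, t))
        errors.append(best)
    boundary = float(pd.Series(errors).mean()) if errors else 0.0
    return {"recall": recall, "precision": precision,
            "boundary_error_bp": boundary, "n_truth": len(truth),
            "n_calls": len(regions), "no_calls": no_calls}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    design = read_design_table(config.design_path)
    counts_dir = Path(config.counts_dir)
    input_files = {"design": Path(config.design_path)}
    tables: dict[str, pd.DataFrame] = {}
    for sid in design["sample_id"]:
        path = counts_dir / f"{sid}.cov"
        if not path.exists():
            raise ConfigurationError(f"missing count file {path}")
        tables[sid] = read_cpg_counts(path)
        input_files[f"counts/{sid}"] = path

    tracks = {}
    for cls, path in sorted(config.annotation_paths.items()):
        tracks[cls] = read_bed_features(path, cls)
        input_files[f"annotation/{cls}"] = Path(path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    organs = sorted(design["organ"].unique())
    results: dict[str, OrganResult] = {}
    for oi, organ in enumerate(organs):
        odir = outdir / organ
        odir.mkdir(exist_ok=True)
        k_min = config.k_min.get(organ)
        if k_min is None:
            raise ConfigurationError(f"no k_min configured for organ {organ!r}")
        res = OrganResult(organ=organ)
        groups = sorted(design.loc[design["organ"] == organ, "father_group"].unique())
        if k_min > len(groups):
            raise ConfigurationError(
                f"k_min={k_min} for {organ} exceeds its {len(groups)} father groups")
        for group in groups:
            label, fail = _stage(organ, group, "call-dmrs")
            try:
                sites, dmrs = call_group_dmrs(tables, design, group, organ, config)
            except DmrcallError as exc:
                raise fail(exc) from exc
            res.dmrs_by_group[group] = dmrs
            write_sites_table(sites, odir / f"sites_{group}.tsv")
            write_dmr_bed(dmrs, odir / f"dmrs_{group}.bed")
        label, fail = _stage(organ, None, "congruence")
        try:
            res.congruent = intersect_for_organ(res.dmrs_by_group, k_min)
        except DmrcallError as exc:
            raise fail(exc) from exc
        write_region_bed(res.congruent, odir / "congruent.bed")
        res.annotated = annotate_dmrs(res.congruent, tracks) if tracks else []
        if tracks:
            write_annotated_report(res.annotated, odir / "annotated_dmrs.tsv")
            res.genes = genes_from_dmrs(res.annotated)
            export_gene_list(res.genes, odir / "genes.txt")
        logger.info("[%s] %d congruent regions (k_min=%d), %d annotated, %d genes",
                    organ, len(res.congruent), k_min,
                    sum(a.annotated for a in res.annotated), len(res.genes))
        if config.n_permutations > 0:
            for gi, group in enumerate(groups):
                label, fail = _stage(organ, group, "shuffle-test")
                try:
                    summary = run_shuffle_test(
                        tables, design, group, organ, config.call,
                        n_permutations=config.n_permutations,
                        seed=config.seed + 7919 * oi + 101 * gi)
                except DmrcallError as exc:
                    raise fail(exc) from exc
                res.null_summaries[group] = summary
                write_null_report(summary, odir / f"null_{group}.tsv")
                logger.info("[%s/%s] shuffle test: max %d, mean %.3f DMRs over %d runs",
                            organ, group, summary.max_count, summary.mean_count,
                            summary.n_permutations)
        results[organ] = res

    partition = None
    if tracks:
        liver = results.get("liver").genes if "liver" in results else set()
        testis = results.get("testis").genes if "testis" in results else set()
        if "liver" in results or "testis" in results:
            partition = partition_gene_sets(liver, testis)
            vdir = outdir / "venn"
            vdir.mkdir(exist_ok=True)
            export_gene_list(partition.liver_only, vdir / "liver_only.txt")
            export_gene_list(partition.testis_only, vdir / "testis_only.txt")
            export_gene_list(partition.shared, vdir / "shared.txt")

    evaluation = None
    if config.truth_path:
        truth = read_truth_bed(config.truth_path)
        input_files["truth"] = Path(config.truth_path)
        evaluation = {organ: evaluate_against_truth(res.congruent, truth)
                      for organ, res in results.items()}
        with open(outdir / "evaluation.json", "wt", encoding="utf-8") as handle:
            json.dump(evaluation, handle, indent=2, sort_keys=True)
            handle.write("\n")

    manifest = {
        "dmrcall_version": __version__,
        "config": config.to_dict(),
        "inputs_sha256": {k: _sha256(p) for k, p in sorted(input_files.items())},
        "outputs_sha256": {},
        "counts": {
            organ: {
                "dmrs_per_group": {g: len(d) for g, d in res.dmrs_by_group.items()},
                "congruent_regions": len(res.congruent),
                "annotated_regions": sum(a.annotated for a in res.annotated),
                "genes": len(res.genes),
                "null_max_dmrs": {g: s.max_count
                                  for g, s in res.null_summaries.items()},
            } for organ, res in results.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path != manifest_path:
            manifest["outputs_sha256"][str(path.relative_to(outdir))] = _sha256(path)
    with open(manifest_path, "wt", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    return PipelineResult(config=config, organs=results, partition=partition,
                          evaluation=evaluation, manifest=manifest)


def intersect_for_organ(dmrs_by_group: Mapping[str, Sequence[DMR]],
                        k_min: int) -> list[CongruentRegion]:
    """Group-keyed convenience wrapper around :func:`congruence.intersect_groups`."""
    from .congruence import intersect_groups

    ordered = [dmrs_by_group[g] for g in sorted(dmrs_by_group)]
    return intersect_groups(ordered, k_min)
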