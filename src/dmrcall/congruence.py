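"""Cross-sire congruence, annotation overlap and organ gene-set partition.

Reproducibility across sire families is the pipeline's region-level filter:
an interval only counts when the DMR sets of at least ``k_min`` of the n
father groups cover it (at least 4 of 5 for liver, all 5 for testis).  The
reported interval is the maximal sub-interval covered by >= k_min groups
with constant support (multi-intersection semantics), not the union of the
contributing DMRs; the contributing DMRs are kept for traceability.

A region is 'annotated' when it shares at least one base (half-open
semantics, so abutting intervals do not overlap) with a coding sequence
(CDS), a promoter, or a CpG island.  Gene identifiers are taken from CDS and
promoter hits only -- a CGI-only region contributes no gene.  Direction
(hyper/hypo) is carried through but deliberately ignored when partitioning
genes between organs: the analysis combines hypo- and hypermethylated
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .clustering import DMR
from .errors import ConfigurationError, ValidationError
from .io_formats import FEATURE_CLASSES, FeatureRecord

GENE_FEATURE_CLASSES = ("CDS", "promoter")


@dataclass(frozen=True)
class CongruentRegion:
    chrom: str
    start: int
    end: int
    support: int                      # number of father groups covering every base
    member_dmrs: tuple = ()           # contributing DMRs (any overlap, any group)


@dataclass(frozen=True)
class AnnotatedDMR:
    region: object                    # CongruentRegion or DMR
    annotated: bool
    hits: tuple                       # (feature_class, gene_id) pairs, sorted
    categories: frozenset = frozenset()


@dataclass(frozen=True)
class VennPartition:
    liver_only: frozenset
    testis_only: frozenset
    shared: frozenset


def _check_disjoint_sorted(dmrs: Sequence[DMR]) -> None:
    by_chrom: dict[str, list[DMR]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        for prev, cur in zip(ds, ds[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"group DMRs overlap or are unsorted on {chrom}: "
                    f"[{prev.start},{prev.end}) then [{cur.start},{cur.end})")


def intersect_groups(dmr_sets: Sequence[Sequence[DMR]], k_min: int) -> list[CongruentRegion]:
    """Maximal constant-support sub-intervals covered by >= k_min groups.

    Each group's DMRs must be disjoint and sorted (they are, by
    construction, within one comparison).  Adjacent qualifying segments with
    equal support merge; a change in support starts a new region.
    """
    n_groups = len(dmr_sets)
    if k_min > n_groups:
        raise ConfigurationError(f"k_min={k_min} exceeds number of groups ({n_groups})")
    if k_min < 1:
        raise ConfigurationError("k_min must be >= 1")
    events: dict[str, list[tuple[int, int]]] = {}
    for dmrs in dmr_sets:
        _check_disjoint_sorted(dmrs)
        for d in dmrs:
            events.setdefault(d.chrom, []).append((d.start, +1))
            events[d.chrom].append((d.end, -1))

    regions: list[CongruentRegion] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        segments: list[tuple[int, int, int]] = []  # start, end, support
        cov = 0
        i = 0
        while i < len(evs):
            x = evs[i][0]
            while i < len(evs) and evs[i][0] == x:
                cov += evs[i][1]
                i += 1
            if i < len(evs) and cov >= k_min:
                segments.append((x, evs[i][0], cov))
        # merge adjacent equal-support segments
        merged: list[list[int]] = []
        for s, e, c in segments:
            if merged and merged[-1][1] == s and merged[-1][2] == c:
                merged[-1][1] = e
            else:
                merged.append([s, e, c])
        all_dmrs = [d for dmrs in dmr_sets for d in dmrs if d.chrom == chrom]
        for s, e, c in merged:
            members = tuple(sorted((d for d in all_dmrs if d.start < e and d.end > s),
                                   key=lambda d: (d.start, d.end, d.father_group or "")))
            regions.append(CongruentRegion(chrom=chrom, start=s, end=e,
                                           support=c, member_dmrs=members))
    return regions


def build_feature_trees(tracks: Mapping[str, Sequence[FeatureRecord]],
                        ) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for feature_class, records in tracks.items():
        if feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"unknown feature class {feature_class!r}")
        for rec in records:
            trees.setdefault((feature_class, rec.chrom), IntervalTree()).addi(
                rec.start, rec.end, rec.gene_id)
    return trees


def annotate_dmrs(regions: Sequence, tracks: Mapping[str, Sequence[FeatureRecord]],
                  ) -> list[AnnotatedDMR]:
    """Overlap every region with the CDS/promoter/CGI tracks (>=1 shared base)."""
    trees = build_feature_trees(tracks)
    out: list[AnnotatedDMR] = []
    for region in regions:
        hits: set[tuple[str, str]] = set()
        for feature_class in FEATURE_CLASSES:
            tree = trees.get((feature_class, region.chrom))
            if tree is None:
                continue
            for iv in tree.overlap(region.start, region.end):
                hits.add((feature_class, iv.data))
        hits_sorted = tuple(sorted(hits))
        out.append(AnnotatedDMR(region=region, annotated=bool(hits),
                                hits=hits_sorted,
                                categories=frozenset(h[0] for h in hits_sorted)))
    return out


def genes_from_dmrs(annotated: Iterable[AnnotatedDMR]) -> set[str]:
    """Union of gene ids hit through CDS or promoter; CGI-only hits count not."""
    genes: set[str] = set()
    for ann in annotated:
        for feature_class, gene_id in ann.hits:
            if feature_class in GENE_FEATURE_CLASSES and gene_id:
                genes.add(gene_id)
    return genes


def partition_gene_sets(liver_genes: Iterable[str], testis_genes: Iterable[str],
                        ) -> VennPartition:
    liver = frozenset(liver_genes)
    testis = frozenset(testis_genes)
    return VennPartition(liver_only=liver - testis,
                         testis_only=testis - liver,
                         shared=liver & testis)


def export_gene_list(genes: Iterable[str], path) -> None:
    """One gene symbol per line, sorted and unique, ready for manual
    submission to an external protein-network service."""
    with open(path, "wt", encoding="utf-8") as handle:
        for gene in sorted(set(genes)):
            handle.write(f"{gene}\n")


def write_annotated_report(annotated: Sequence[AnnotatedDMR], path) -> None:
    """TSV report: region, support, categories, genes, member directions."""
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("chrom\tstart\tend\tsupport\tannotated\tcategories\tgenes\tdirections\n")
        for ann in annotated:
            r = ann.region
            support = getattr(r, "support", 1)
            genes = sorted({g for c, g in ann.hits if c in GENE_FEATURE_CLASSES and g})
            cats = ",".join(sorted(ann.categories)) or "."
            members = getattr(r, "member_dmrs", ())
            dirs = ",".join(sorted({m.direction for m in members})) or "."
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{support}\t"
                         f"{int(ann.annotated)}\t{cats}\t{','.join(genes) or '.'}\t{dirs}\n")
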