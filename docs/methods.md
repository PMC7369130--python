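# Methods

## The analysis problem

Reduced-representation bisulfite sequencing (RRBS) yields, per sample and
CpG site, a count of methylated reads (cytosine retained, `C`) and
unmethylated reads (converted to `T`).  The methylation ratio at a site is

    m = C / (C + T)

The pipeline asks where methylation differs between two groups of related
animals — sons sired before ("control") and after ("heat") their father's
exposure to elevated ambient temperature — separately within each of five
sire families (labelled F–J), in two organs.  Liver libraries are sequenced
per individual son; testis libraries are physically pooled per sire and
arm, so a testis "sample" already represents a family.

## The calling chain

For one family's control-vs-heat comparison:

1. **Joint coverage filter.**  Keep only CpGs present with at least
   `min_coverage` (default 5) reads in *every* sample of the comparison.
   This is deliberately conservative and strongly restricts the retained
   site set.
2. **Arm pooling.**  Read counts are summed across the samples of each arm.
   Summation (rather than averaging ratios) is used because the exact test
   consumes counts, and because the sire-pooled testis libraries are the
   physical analogue of summation; pooling is then the identity for them.
3. **Per-CpG Fisher exact test.**  For the pooled 2×2 table
   `[[C_ctrl, T_ctrl], [C_heat, T_heat]]`, the two-sided p-value is computed
   by the point-probability rule: every table of the hypergeometric support
   with point probability ≤ pmf(observed)·(1+1e−7) contributes.  The 1e−7
   relative guard prevents floating-point noise from misclassifying
   equal-probability tables.  Zero-margin tables (no methylated or no
   unmethylated read in either arm) return p = 1 and are flagged
   degenerate, so fully (un)methylated regions are silently
   non-significant.  The implementation is vectorised over sites via
   `scipy.special.gammaln`; with ≤ 61 support terms per table its absolute
   error against exact integer enumeration is below 1e−13 (checked
   exhaustively for margins ≤ 30 by the acceptance suite).
4. **Site calling.**  Sites with p < `alpha` (default 0.05, strict
   inequality) and a non-zero ratio difference Δ = m_heat − m_ctrl are
   retained, labelled hyper (Δ > 0) or hypo (Δ < 0).  Both directions are
   kept throughout.  No site-level multiple-testing correction is applied;
   error control is empirical, via the shuffle test below.
5. **Gap clustering.**  Maximal runs of significant CpGs with consecutive
   positions at most `max_gap` = 100 bp apart (inclusive: exactly 100
   joins) and at least `min_sites` = 2 members become DMRs.  Distance is
   measured between successive CpG positions.  By default non-significant
   covered CpGs inside a run neither join nor break it; the stricter
   `break_on_nonsig` variant is available as a flag.  Each DMR carries a
   Stouffer-combined score z = Σᵢ Φ⁻¹(1 − pᵢ/2)·sign(Δᵢ) / √n, reported for
   ranking and export only — the default pipeline never filters on it.

## Region-level reproducibility: congruence across families

DMR sets from the five families are intersected with multi-intersection
semantics: the reported regions are maximal sub-intervals covered by DMRs
of at least `k_min` families (default 4 of 5 for liver, all 5 for the
sire-pooled testis data), with constant support; contributing DMRs are kept
for traceability.  Overlap anywhere counts — one shared base suffices, and
intervals are half-open, so abutting intervals do not overlap.  Annotation
is applied *after* intersection.

A region is **annotated** when it overlaps a coding sequence (CDS), a
promoter, or a CpG island (CGI).  Gene identifiers come from CDS and
promoter hits only.  DMR-linked gene sets from the two organs are
partitioned into liver-only / testis-only / shared (directions are combined
deliberately: a gene counts whether its regions are hyper- or
hypomethylated).  Gene lists are exported one symbol per line for manual
submission to external network services; network retrieval and enrichment
statistics are out of scope.

## Empirical false-positive control: the per-position shuffle test

At every retained CpG independently, the (methylated, unmethylated) count
pairs are randomly reassigned among the samples of the comparison, arm
labels fixed; the full chain reruns on the shuffled data and the number of
DMRs is recorded, 100 times per family.  Count pairs are shuffled rather
than ratios alone because the exact test consumes counts and the ratio is a
deterministic function of the pair, so the same randomisation is realised
while the test stays defined.  Permuting data across all samples of both
arms is the standard two-group permutation null and is equivalent to
permuting arm labels per position.  On effect-free data the per-run DMR
count stays below 2 in ≥ 99 % of runs under the default design (computed by
the acceptance script); note that on data carrying strong real effects the
permuted runs retain residual signal, so the shuffle counts are a
false-positive estimate only where the null holds.

One master seed is used; permutation *i* draws from substream (seed, i), so
any single permutation is reproducible in isolation and extending the run
never changes earlier counts.

## The synthetic-data generator

The generator emulates the study design so that every stage is testable
with no external data: 5 sire families × {control, heat} × (3 sons per cell
for liver-style data, or one pooled table per cell for testis-style data).
Defaults, with rationale:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_chroms` × `chrom_length` | 2 × 1 Mb | small genome; ~2,100 CpGs total |
| `background_cpg_spacing` | 1000 bp | mean geometric gap outside islands.  Deliberately sparse: it models the site set that *survives* the joint ≥5× filter across all samples, which is what the pipeline actually sees |
| `n_islands_per_chrom`, `island_length`, `island_cpg_spacing` | 10, 500 bp, 60 bp | CpG islands dense enough to host multi-CpG regions |
| `baseline_meth_island` / `baseline_meth_background` | 0.15 / 0.90 | bimodal methylome: islands hypo-, background hypermethylated |
| `baseline_concentration` | 6 | Beta concentration of per-site baselines around those means |
| `coverage_mean` | 10 | reads per CpG per sample, Poisson truncated ≥ 1; an assumption, not an estimate of any particular dataset.  At 10× the ≥5× joint filter genuinely removes sites |
| `overdispersion` | 0.005 | beta-binomial correlation ρ between reads of one sample.  Kept small on purpose: the pooled Fisher test assumes binomial sampling within arms, and larger between-individual dispersion makes it anti-conservative.  Set ρ = 0 to recover pure binomial; raising ρ is the intended robustness experiment |
| `father_sd` | 0.3 | SD of per-family logit intercepts, shared by both arms of a family — induces family-level congruence structure without disturbing control-vs-heat null calibration |
| `planted_effect`, `planted_width_cpgs`, `n_planted_dmrs` | +0.4, 5, 10 | treatment-responsive regions: heat-arm methylation shifted by ±effect (hyper where local baseline is low, hypo where high), clipped to [0.01, 0.99] |

Planted regions are placed on disjoint runs of consecutive CpGs, preferring
"tight" windows (all internal gaps ≤ 100 bp) so a planted region is
recoverable as a single DMR; when a landscape offers too few tight windows,
windows with at most one internal gap ≤ 300 bp fill the remainder (such
regions cluster as two sub-runs, both overlapping the truth interval, so
interval-overlap recovery is preserved).

Randomness: annotation, landscape, baselines, family intercepts and truth
placement each use a tagged substream of the master seed; each sample's
counts use a stream keyed by (seed, crc32(sample_id)), so adding samples
never perturbs existing ones and identical parameters give byte-identical
outputs.

**What the generator does not model:** read-level artefacts (FASTQ,
alignment, bisulfite-conversion error), restriction-fragment structure of
RRBS libraries (coverage is independent across sites, whereas real RRBS
coverage is fragment-correlated across samples), strand-resolved CpG
dyads, copy-number or SNP effects on apparent methylation, and realistic
chromosome-scale annotation.  Passing tests therefore demonstrate the
statistical behaviour of the chain under its own assumptions, not
performance on any real dataset.

## Evaluation conventions

A called region matches a planted interval iff they share ≥ 1 bp.
Recall = matched truth / all truth; precision = matching calls / all calls;
with an empty call set precision is reported as 1.0 together with an
explicit `no_calls` flag (an empty set contains no false positives), which
keeps summary tables numeric.  The boundary error averages the start- and
end-offsets of matched pairs in bp.

## Numerical and design notes

* Coordinates are 0-based half-open everywhere; bismark coverage input
  (1-based) is shifted on ingest and restored on write.
* The site-level α is strict (< 0.05): p exactly 0.05 is not called.
* The gap rule is inclusive (a 100 bp gap joins); both are config keys.
* Count-table input is assumed dyad-merged (one row per CpG site); a
  duplicate (chrom, pos) row is an error, not a silent collapse, because
  the coverage dialect carries no strand column.
* Under the effect-free generator the Fisher test is *conservative*: the
  observed site-level rejection rate at α = 0.05 is ≈ 0.016 (discreteness
  of small-count 2×2 tables, strongest at extreme baselines).  Its p-value
  distribution is therefore sub-uniform by design; calibration is checked
  as the one-sided bound rate ≤ α + 3·SE rather than as uniformity.
* Pipeline outputs contain no timestamps and are sorted at every stage, so
  a rerun with the same config is byte-identical; the manifest records
  parameter values, seed and SHA-256 checksums of all inputs and outputs.
* Problem sizes used by the test and acceptance suites (2 × 1 Mb genome,
  ~2,000 retained CpGs, 100 permutations × 5 families, 20 recovery
  replicates) are the package's chosen study scale; all scale linearly.

## Known limitations

* Fisher on arm-pooled counts ignores between-individual variability; with
  realistic overdispersion (ρ ≳ 0.02) it is anti-conservative at the site
  level.  The shuffle test measures, but does not remove, this.  A
  beta-binomial or logistic-mixed site test is explicitly out of scope.
* No region-level q-values or analytic FDR; the empirical shuffle bound is
  the only error control, as in the modelled workflow.
* The promoter definition (2 kb upstream of the gene start, strand-aware)
  is a convention, exposed as a parameter.
* Congruence requires base-level overlap of DMR intervals; no reciprocal-
  overlap fraction or distance slack is implemented.
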