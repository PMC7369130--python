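import numpy as np
import pandas as pd
import pytest

from dmrcall import (ConfigurationError, SimulationParams, TruthRecord,
                     ValidationError, generate_annotation,
                     generate_cpg_landscape, generate_dataset, make_design,
                     null_params, plant_truth, simulate_counts)
from dmrcall.diffmeth import fisher_exact_two_sided
from dmrcall.pipeline import call_group_dmrs, evaluate_against_truth, intersect_for_organ
from dmrcall.config import PipelineConfig

from conftest import small_sim_params


class TestAnnotation:
    def test_promoter_is_2kb_upstream_strand_aware(self):
        tracks = generate_annotation(small_sim_params())
        proms = {f.gene_id: f for f in tracks["promoter"]}
        for cds in tracks["CDS"]:
            prom = proms[cds.gene_id]
            if cds.strand == "+":
                assert (prom.start, prom.end) == (cds.start - 2000, cds.start)
            else:
                assert (prom.start, prom.end) == (cds.end, cds.end + 2000)

    def test_same_seed_reproduces_track(self):
        p = small_sim_params()
        assert generate_annotation(p) == generate_annotation(p)

    def test_zero_genes_leaves_cgis(self):
        tracks = generate_annotation(small_sim_params(n_genes_per_chrom=0))
        assert tracks["CDS"] == [] and tracks["promoter"] == []
        assert len(tracks["CGI"]) > 0

    def test_too_short_chromosome_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            generate_annotation(small_sim_params(chrom_length=20_000,
                                                 n_genes_per_chrom=10))


class TestLandscape:
    def test_island_gaps_denser_than_background(self):
        p = SimulationParams(n_chroms=1, chrom_length=2_000_000,
                             n_islands_per_chrom=40, island_length=2000,
                             island_cpg_spacing=10.0,
                             background_cpg_spacing=150.0, seed=5)
        ls = generate_cpg_landscape(generate_annotation(p), p)
        pos = ls.positions["chr1"]
        mask = ls.island_mask["chr1"]
        gaps = np.diff(pos)
        both_island = mask[:-1] & mask[1:]
        both_bg = ~mask[:-1] & ~mask[1:]
        assert both_island.sum() > 1000 and both_bg.sum() > 1000
        mean_isl = gaps[both_island].mean()
        mean_bg = gaps[both_bg].mean()
        assert mean_isl < mean_bg
        # empirical means match configured geometric means within 3 SE
        for observed, configured, n in ((mean_isl, 10.0, both_island.sum()),
                                        (mean_bg, 150.0, both_bg.sum())):
            se = configured / np.sqrt(n)  # geometric sd ~ mean for mean >> 1
            assert abs(observed - configured) < 3 * se + 1.0

    def test_positions_strictly_increasing_and_deterministic(self):
        p = small_sim_params()
        ann = generate_annotation(p)
        ls1 = generate_cpg_landscape(ann, p)
        ls2 = generate_cpg_landscape(ann, p)
        for chrom in ls1.positions:
            assert (np.diff(ls1.positions[chrom]) > 0).all()
            np.testing.assert_array_equal(ls1.positions[chrom], ls2.positions[chrom])
            np.testing.assert_array_equal(ls1.baseline[chrom], ls2.baseline[chrom])

    def test_empty_annotation_gives_background_spacing(self):
        p = small_sim_params(n_islands_per_chrom=0, n_genes_per_chrom=0,
                             n_planted_dmrs=0)
        ls = generate_cpg_landscape({"CGI": []}, p)
        assert not ls.island_mask["chr1"].any()


class TestCounts:
    def test_same_seed_identical_tables(self):
        p = small_sim_params()
        d1 = generate_dataset(p)
        d2 = generate_dataset(p)
        for sid in d1.tables:
            pd.testing.assert_frame_equal(d1.tables[sid], d2.tables[sid])

    def test_truth_interval_off_landscape_rejected(self):
        p = small_sim_params(n_planted_dmrs=0)
        ann = generate_annotation(p)
        ls = generate_cpg_landscape(ann, p)
        bogus = TruthRecord("chr1", 1, 3, 0.4, 1, "hyper")
        with pytest.raises(ValidationError):
            simulate_counts(ls, make_design(p), [bogus], p)

    def test_high_coverage_ratio_converges_to_baseline(self):
        # law of large numbers: binomial noise at 500x is < 0.05 for ~all sites
        p = small_sim_params(overdispersion=0.0, coverage_mean=500.0,
                             father_sd=0.0, n_planted_dmrs=0,
                             samples_per_cell=1)
        ds = generate_dataset(p)
        table = ds.tables["liver_F_control_s1"]
        ratio = table["n_meth"] / (table["n_meth"] + table["n_unmeth"])
        dev = np.abs(ratio.to_numpy() - ds.landscape.baseline["chr1"])
        assert np.quantile(dev, 0.95) < 0.05

    def test_pooled_design_one_sample_per_father_and_arm(self):
        p = small_sim_params(pooled=True, organ="testis")
        design = make_design(p)
        assert len(design) == 2 * p.n_father_groups
        assert design["pooled"].all()

    def test_null_data_site_rejections_bounded_by_alpha(self):
        # With no planted effect the Fisher test must not exceed its nominal
        # level (discrete tables make it conservative, so <= is the bound).
        p = null_params(SimulationParams(seed=29))
        ds = generate_dataset(p)
        from dmrcall.diffmeth import joint_coverage_filter, pool_counts_by_arm, restrict_tables
        rejections = {0.01: 0, 0.05: 0, 0.2: 0}
        n = 0
        for father in p.fathers[:2]:
            ids = ds.design.loc[ds.design["father_group"] == father, "sample_id"]
            tables = {s: ds.tables[s] for s in ids}
            pos = joint_coverage_filter(tables, 5)
            pooled = pool_counts_by_arm(restrict_tables(tables, pos),
                                        ds.design, father, "liver")
            pvals = fisher_exact_two_sided(pooled["ctrl_meth"], pooled["ctrl_unmeth"],
                                           pooled["heat_meth"], pooled["heat_unmeth"])
            n += len(pvals)
            for alpha in rejections:
                rejections[alpha] += (pvals < alpha).sum()
        assert n >= 2000
        for alpha, k in rejections.items():
            se = np.sqrt(alpha * (1 - alpha) / n)
            assert k / n <= alpha + 3 * se


class TestPlantedEffects:
    @staticmethod
    def _recovery(effect, coverage, seeds=(3, 4)):
        recalls = []
        for seed in seeds:
            p = small_sim_params(planted_effect=effect, coverage_mean=coverage,
                                 seed=seed)
            ds = generate_dataset(p)
            cfg = PipelineConfig()
            dmrs = {g: call_group_dmrs(ds.tables, ds.design, g, "liver", cfg)[1]
                    for g in p.fathers}
            regions = intersect_for_organ(dmrs, 4)
            recalls.append(evaluate_against_truth(regions, ds.truth)["recall"])
        return float(np.mean(recalls))

    def test_recovery_monotone_in_effect_size(self):
        recalls = [self._recovery(e, 20.0) for e in (0.05, 0.25, 0.5)]
        assert recalls[0] <= recalls[1] + 0.05
        assert recalls[1] <= recalls[2] + 0.05
        assert recalls[2] > recalls[0]

    def test_recovery_monotone_in_coverage(self):
        recalls = [self._recovery(0.3, c) for c in (5.0, 12.0, 40.0)]
        assert recalls[0] <= recalls[1] + 0.05
        assert recalls[1] <= recalls[2] + 0.05
        assert recalls[2] > recalls[0]

    def test_truth_records_disjoint_and_on_landscape(self, small_dataset):
        truth = sorted(small_dataset.truth, key=lambda t: (t.chrom, t.start))
        for a, b in zip(truth, truth[1:]):
            assert a.chrom != b.chrom or a.end <= b.start
        for t in truth:
            pos = small_dataset.landscape.positions[t.chrom]
            inside = (pos >= t.start) & (pos < t.end)
            assert inside.sum() == t.n_cpgs
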