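"""Contracts of the synthetic-screen generator: determinism, filter fodder,
monitoring-grid discretization, structural annotation cases, and noiseless
qPCR recovery."""

import numpy as np
import pandas as pd
import pytest

from precond.annotation import assign_variants, load_annotation
from precond.simulate import (
    SimulationConfig,
    default_true_folds,
    discretize_to_grid,
    monitoring_grid_points,
    simulate_annotation,
    simulate_counts_and_ct,
    simulate_orthologs,
    simulate_panel,
    simulate_survival,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=5, n_causal=6)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.1, 0.6))
        with pytest.raises(ValueError):
            SimulationConfig(flies_per_arm=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_causal=2, effect_sizes=(1.0,))


class TestPanel:
    def test_seeded_runs_identical(self):
        cfg = SimulationConfig(n_strains=40, n_variants=200, seed=3)
        p1, t1 = simulate_panel(cfg)
        p2, t2 = simulate_panel(cfg)
        np.testing.assert_array_equal(p1.dosage, p2.dosage)
        pd.testing.assert_frame_equal(p1.variants, p2.variants)
        pd.testing.assert_series_equal(
            t1.per_strain_true_log_hr, t2.per_strain_true_log_hr
        )

    def test_dosages_binary_and_subthreshold_sites_present(self):
        cfg = SimulationConfig(
            n_strains=80, n_variants=1000, frac_subthreshold=0.1, seed=1
        )
        panel, _ = simulate_panel(cfg)
        vals = panel.dosage[~np.isnan(panel.dosage)]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert (panel.maf() < 0.05).sum() >= 1
        assert (panel.variants["n_alleles"] == 3).sum() > 0

    def test_true_log_hr_is_dosage_weighted_effect_sum(self):
        cfg = SimulationConfig(n_strains=50, n_variants=300, seed=7)
        panel, truth = simulate_panel(cfg)
        idx = [
            panel.variants.index[panel.variants.variant_id == v][0]
            for v in truth.causal_variant_ids
        ]
        expect = panel.imputed_dosage()[:, idx] @ truth.effect_sizes
        np.testing.assert_allclose(
            truth.per_strain_true_log_hr.to_numpy(), expect, atol=1e-12
        )

    def test_realized_maf_within_binomial_error_of_target(self):
        """With per-strain-independent draws (one block per strain) the
        realized MAF sits within binomial sampling error of its target."""
        n = 500
        cfg = SimulationConfig(
            n_strains=n, n_variants=400, n_blocks=n, frac_subthreshold=0.0,
            seed=9,
        )
        panel, _ = simulate_panel(cfg)
        target = panel.variants["target_maf"].to_numpy()
        realized = np.nanmean(panel.dosage, axis=0)
        realized = np.minimum(realized, 1 - realized)
        se = np.sqrt(target * (1 - target) / n)
        frac_ok = np.mean(np.abs(realized - np.minimum(target, 1 - target)) <= 3 * se)
        assert frac_ok >= 0.95

    def test_block_structure_raises_within_block_similarity(self):
        cfg = SimulationConfig(
            n_strains=60, n_variants=500, n_blocks=4, block_share=0.8, seed=2
        )
        panel, truth = simulate_panel(cfg)
        blocks = np.array([truth.block_membership[s] for s in panel.strains])
        X = panel.imputed_dosage()
        Xc = X - X.mean(0)
        C = np.corrcoef(Xc)
        same = C[blocks[:, None] == blocks[None, :]]
        diff = C[(blocks[:, None] != blocks[None, :])]
        assert same[same < 0.999].mean() > diff.mean() + 0.1


class TestSurvival:
    def test_death_times_on_grid_inside_window(self, small_config, small_panel):
        panel, truth = small_panel
        surv = simulate_survival(panel, truth, small_config)
        events = surv[surv.event == 1]
        grid = monitoring_grid_points(
            small_config, small_config.censor_horizon_h + 48
        )
        assert np.isin(events["time_h"].to_numpy(), grid).all()
        clock = events["time_h"].to_numpy() % 24.0
        assert (clock >= small_config.monitor_interval_h).all()
        assert (clock <= 12.0).all()  # last evening check of an 8-20 window

    def test_discretization_censors_upward(self, rng):
        cfg = SimulationConfig()
        t = rng.uniform(0.01, 200, 5000)
        d = discretize_to_grid(t, cfg)
        assert (d >= t).all()
        # overnight deaths land on the next morning's first check
        overnight = (t % 24) > 12
        assert np.allclose(d[overnight] % 24, cfg.monitor_interval_h)

    def test_seeded_survival_identical_and_arms_complete(
        self, small_config, small_panel
    ):
        panel, truth = small_panel
        s1 = simulate_survival(panel, truth, small_config)
        s2 = simulate_survival(panel, truth, small_config)
        pd.testing.assert_frame_equal(s1, s2)
        per = s1.groupby(["strain", "arm"]).size()
        assert (per == small_config.flies_per_arm).all()

    def test_nonpositive_hazard_rejected(self, small_panel):
        panel, truth = small_panel
        cfg = SimulationConfig(n_strains=60, n_variants=300, seed=11)
        cfg.baseline_hazard = 0.0
        with pytest.raises(ValueError):
            simulate_survival(panel, truth, cfg)

    def test_null_strain_recovers_unit_hazard(self):
        """A strain with true log-HR = 0: the mean fitted Cox HR over
        replicates is within Monte-Carlo error of 1."""
        from precond.survival import fit_cox_hr

        log_hrs = []
        for seed in range(60):
            cfg = SimulationConfig(
                n_strains=2, n_variants=50, n_causal=1, effect_sizes=(0.0,),
                flies_per_arm=100, seed=seed,
            )
            panel, truth = simulate_panel(cfg)
            surv = simulate_survival(panel, truth, cfg)
            est = fit_cox_hr(surv, panel.strains[0])
            log_hrs.append(est.log_hr)
        mean = np.mean(log_hrs)
        mc_se = np.std(log_hrs, ddof=1) / np.sqrt(len(log_hrs))
        assert abs(mean) < 3 * mc_se + 1e-3


@pytest.fixture(scope="module")
def annotated(small_config, small_panel):
    panel, truth = small_panel
    annot, sets = simulate_annotation(panel, small_config, truth)
    return panel, truth, annot, sets


class TestAnnotationFixture:
    def test_structural_cases_present(self, annotated):
        panel, truth, annot, _ = annotated
        index = load_annotation(annot)
        assigned = assign_variants(panel.variants, index)
        classes = set(assigned["site_class"])
        assert {"exon", "UTR", "intron", "upstream", "downstream",
                "unassigned"} <= classes

    def test_exonic_variant_with_second_gene_within_1kb(self, annotated):
        panel, truth, annot, _ = annotated
        genes = annot[annot.feature == "gene"]
        index = load_annotation(annot)
        assigned = assign_variants(panel.variants, index)
        exonic = assigned[assigned.site_class == "exon"].merge(
            panel.variants, on="variant_id"
        )
        found = False
        for v in exonic.itertuples():
            near = genes[
                (genes.chrom == v.chrom)
                & (genes.gene_id != v.gene_id)
                & (genes.start - 1000 <= v.pos)
                & (v.pos <= genes.end + 1000)
            ]
            if len(near):
                found = True
                break
        assert found

    def test_some_variant_beyond_1kb_of_every_gene(self, annotated):
        panel, truth, annot, _ = annotated
        index = load_annotation(annot)
        assigned = assign_variants(panel.variants, index)
        assert (assigned.site_class == "unassigned").any()

    def test_overlapping_genes_case_present(self, annotated):
        panel, truth, annot, _ = annotated
        genes = annot[annot.feature == "gene"]
        pos = panel.variants
        found = False
        for v in pos.itertuples():
            inside = genes[
                (genes.chrom == v.chrom)
                & (genes.start <= v.pos) & (v.pos <= genes.end)
            ]
            if len(inside) >= 2:
                found = True
                break
        assert found

    def test_every_causal_variant_maps_to_a_gene(self, annotated):
        panel, truth, annot, sets = annotated
        index = load_annotation(annot)
        causal = panel.variants[
            panel.variants.variant_id.isin(truth.causal_variant_ids)
        ]
        assigned = assign_variants(causal, index)
        assert assigned["gene_id"].notna().all()
        assert set(assigned["gene_id"]) <= set(sets["enriched_set"])

    def test_gene_sets_well_formed(self, annotated):
        _, _, annot, sets = annotated
        all_genes = set(annot["gene_id"])
        assert {"enriched_set", "random_set"} <= set(sets)
        for name, members in sets.items():
            assert len(members) >= 5
            assert set(members) <= all_genes


class TestCountsAndCt:
    def test_seeded_tables_identical(self, small_config):
        a = simulate_counts_and_ct(small_config)
        b = simulate_counts_and_ct(small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.ct, b.ct)

    def test_no_planted_shift_means_no_recorded_outlier(self, small_config):
        assert simulate_counts_and_ct(small_config).outlier_sample is None

    def test_noiseless_ct_recovers_planted_folds_exactly(self):
        from precond.qpcr import delta_delta_ct

        cfg = SimulationConfig(qpcr_noise_sd=0.0, seed=8)
        expr = simulate_counts_and_ct(cfg)
        summary, _ = delta_delta_ct(expr.ct)
        for row in summary.itertuples():
            truth = expr.true_folds[(row.genotype, row.timepoint, row.gene)]
            base = expr.true_folds[(row.genotype, "no_treatment", row.gene)]
            assert row.fold_mean == pytest.approx(truth / base, abs=1e-10)

    def test_planted_outlier_detected_downstream(self):
        from precond.expression_qc import (
            median_of_ratios_normalize,
            pca_outlier_detection,
        )

        cfg = SimulationConfig(rnaseq_outlier_shift=8.0, seed=4)
        expr = simulate_counts_and_ct(cfg)
        _, norm = median_of_ratios_normalize(expr.counts)
        report = pca_outlier_detection(norm)
        assert report.flagged == [expr.outlier_sample]


def test_ortholog_table_contract(small_config):
    genes = [f"SG{i:04d}" for i in range(1, 40)]
    orth = simulate_orthologs(genes, small_config)
    assert set(orth.columns) == {"source_gene", "target_gene", "score"}
    assert orth["score"].between(1, 15).all()
    assert (orth["score"] >= 5).any() and (orth["score"] < 5).any()
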