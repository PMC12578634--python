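"""Generator contracts: determinism, construction invariants, null settings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from legacyscope import synthgen
from legacyscope._streams import child_rng, child_seed


def test_child_streams_are_distinct_and_stable():
    a = child_rng(1, "community").normal(size=4)
    b = child_rng(1, "community").normal(size=4)
    c = child_rng(1, "traits").normal(size=4)
    assert np.allclose(a, b)
    assert not np.allclose(a, c)
    assert 0 <= child_seed(123, "x") < 2**31


class TestGenDesign:
    def test_legacy_split_by_construction(self, design48):
        by_site = design48.samples.drop_duplicates("site_id")
        assert (by_site["legacy"] == ["dry"] * 3 + ["wet"] * 3).all()

    def test_two_sites(self):
        d = synthgen.gen_design(2, 4, (500, 800), seed=0)
        assert sorted(d.samples.drop_duplicates("site_id")["legacy"]) == ["dry", "wet"]

    def test_odd_sites_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_design(5, 4, (400, 1000), seed=0)

    def test_deterministic(self):
        a = synthgen.gen_design(6, 4, (400, 1000), seed=1)
        b = synthgen.gen_design(6, 4, (400, 1000), seed=1)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_factorial_balanced_within_site(self):
        d = synthgen.gen_design(6, 8, (400, 1000), seed=2)
        cells = d.samples.groupby(
            ["site_id", "cond_water", "cond_host", "test_water"]
        ).size()
        assert (cells == 1).all()  # 8 reps cover the 8 combos exactly once


class TestGenCommunity:
    def test_deterministic(self, design48):
        a, _ = synthgen.gen_community(design48, 30, 5, seed=3)
        b, _ = synthgen.gen_community(design48, 30, 5, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_depth_and_truth_ids(self, design48):
        table, truth = synthgen.gen_community(design48, 50, 10, depth=20000,
                                              seed=4)
        assert table.counts.sum(axis=0).mean() == pytest.approx(20000, rel=0.05)
        assert set(truth.marker_taxa) <= set(table.counts.index)

    def test_null_slope_markers_exchangeable(self, design48):
        """With slope 0, per-taxon precipitation correlations of markers and
        non-markers come from the same distribution."""
        table, truth = synthgen.gen_community(design48, 80, 20, slope=0.0,
                                              zero_prob=0.0, seed=5)
        z = design48.precip_z.to_numpy()
        rel = table.relative_abundance()
        cors = rel.apply(lambda row: np.corrcoef(row, z)[0, 1], axis=1)
        mk = cors[list(truth.marker_taxa)]
        null = cors.drop(index=list(truth.marker_taxa))
        assert stats.mannwhitneyu(mk, null).pvalue > 0.01

    def test_no_structural_zeros_matches_nb(self, design48):
        """zero_prob=0: the observed zero fraction is consistent with a
        parametric NB bootstrap at the same means and dispersion."""
        disp = 0.5
        table, _ = synthgen.gen_community(design48, 100, 0, slope=0.0,
                                          dispersion=disp, zero_prob=0.0,
                                          depth=5000, seed=6)
        counts = table.counts.to_numpy()
        mu = np.maximum(counts.mean(axis=1, keepdims=True), 1e-9)
        obs_zero = (counts == 0).mean()
        expect_zero = np.mean((1 + disp * mu) ** (-1 / disp))
        boot_sd = np.sqrt(expect_zero * (1 - expect_zero) / counts.size) + 1e-4
        assert abs(obs_zero - expect_zero) < 6 * boot_sd + 0.01

    def test_marker_slope_sign_recovery(self, design48):
        """Strong slope, low dispersion: fitted per-marker slope signs match
        the planted signs for >= 90% of markers (Monte Carlo over seeds)."""
        hits = total = 0
        for seed in range(10):
            table, truth = synthgen.gen_community(
                design48, 40, 10, slope=1.0, dispersion=0.05, zero_prob=0.0,
                seed=seed,
            )
            z = design48.precip_z.to_numpy()
            logc = np.log1p(table.counts.loc[list(truth.marker_taxa)])
            fitted = logc.apply(lambda row: np.polyfit(z, row, 1)[0], axis=1)
            signs = np.sign(pd.Series(truth.marker_taxa))
            hits += (np.sign(fitted) == signs).sum()
            total += len(signs)
        assert hits / total >= 0.90


class TestGenExpression:
    def test_unknown_set_rejected(self, design48):
        with pytest.raises(ValueError, match="VII"):
            synthgen.gen_expression(design48, 100, {"VII": 5}, seed=0)

    def test_zero_lfc_sets_are_null(self, design96):
        em, truth = synthgen.gen_expression(design96, 300, {"IV": 50}, lfc=0.0,
                                            n_legacy_main=0, seed=7)
        assert (truth.de_genes["lfc_drought_dry"] == 0).all()

    def test_planted_set_iv_group_means(self, design96):
        """Set IV genes: raw dry-legacy drought log2 ratio ~ lfc, wet ~ 0."""
        em, truth = synthgen.gen_expression(design96, 400, {"IV": 60}, lfc=2.0,
                                            n_legacy_main=0, seed=8)
        des = em.design
        planted = truth.de_genes.index[truth.de_genes["gene_set"] == "IV"]

        def ratio(legacy):
            m = des["legacy"] == legacy
            dr = m & (des["test_water"] == "drought")
            ct = m & (des["test_water"] == "control")
            c = em.counts.loc[planted]
            return np.log2(c.loc[:, dr.to_numpy()].mean(axis=1)
                           / c.loc[:, ct.to_numpy()].mean(axis=1)).mean()

        assert ratio("dry") == pytest.approx(2.0, abs=0.3)
        assert ratio("wet") == pytest.approx(0.0, abs=0.3)


class TestGenTraits:
    def test_drought_effect_one_noise_zero_s_is_one(self, design48):
        table, _ = synthgen.gen_traits(design48, 10, legacy_effect=1.0,
                                       drought_effect=1.0, noise_sd=0.0, seed=9)
        from legacyscope.sindex import s_index

        s = s_index(table)
        assert np.allclose(s.traits.to_numpy(), 1.0)

    def test_nonpositive_drought_effect_rejected(self, design48):
        with pytest.raises(ValueError):
            synthgen.gen_traits(design48, 5, drought_effect=0.0, seed=0)

    def test_no_legacy_shift_s_indistinguishable(self, design96):
        table, _ = synthgen.gen_traits(design96, 8, legacy_effect=1.0,
                                       drought_effect=0.7, noise_sd=0.2,
                                       seed=10)
        from legacyscope.sindex import s_index

        s = s_index(table, control_grouping=["cond_group"])
        vals = s.data
        p = stats.mannwhitneyu(
            vals.loc[vals["legacy"] == "dry", "trait01"],
            vals.loc[vals["legacy"] == "wet", "trait01"],
        ).pvalue
        assert p > 0.01


class TestGenIcpms:
    def test_reference_positions(self):
        run, _ = synthgen.gen_icpms_run(n_samples=25, ref_interval=9, seed=0)
        refs = run.meta.loc[run.meta["record_type"] == "reference", "position"]
        assert list(refs)[:3] == [0, 10, 20]

    def test_zero_drift_zero_noise_observed_equals_truth(self):
        run, truth = synthgen.gen_icpms_run(n_samples=8, n_elements=3,
                                            drift_slope=0.0, noise_sd=0.0,
                                            seed=1)
        refs = run.meta["record_type"] == "reference"
        ref_vals = run.intensities[refs.to_numpy()]
        assert np.allclose(ref_vals, ref_vals.iloc[0])


class TestGenGenotypes:
    def test_no_missing_passes_missing_filter(self, design48):
        from legacyscope.gea import filter_variants

        g, _ = synthgen.gen_genotypes(design48, 300, 0, 0.0, missing_rate=0.0,
                                      seed=2, low_qual_frac=0.0, mean_depth=40)
        filt = filter_variants(g, qual_min=0, maf_min=-1, depth_min=0)
        assert len(filt.snp_ids) == 300

    def test_dosage_range_and_determinism(self, design48):
        a, _ = synthgen.gen_genotypes(design48, 100, 5, 1.0, seed=3)
        b, _ = synthgen.gen_genotypes(design48, 100, 5, 1.0, seed=3)
        pd.testing.assert_frame_equal(a.dosage, b.dosage)
        vals = a.dosage.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        assert ok.all()

    def test_assoc_truth_ids_exist(self, design48):
        g, truth = synthgen.gen_genotypes(design48, 200, 10, 1.0, seed=4)
        assert set(truth.assoc_snps) <= set(g.snp_ids)
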