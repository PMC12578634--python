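"""NB differential analysis, normalization and the interaction classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from legacyscope import degenes, synthgen


class TestSizeFactors:
    def test_identical_columns_unit(self):
        col = [10, 20, 5, 40]
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        sf = degenes.size_factors(counts, mode="median_ratio")
        assert np.allclose(sf, sf.iloc[0])

    def test_doubled_column_ratio_two(self):
        col = np.array([10, 20, 5, 40])
        counts = pd.DataFrame({"a": col, "b": col, "c": 2 * col})
        sf = degenes.size_factors(counts, mode="median_ratio")
        assert sf["c"] / sf["a"] == pytest.approx(2.0)

    def test_no_allpositive_feature_guides_to_cpm(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError, match="cpm"):
            degenes.size_factors(counts, mode="median_ratio")

    def test_cpm_tpm_column_sums(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(30, 4)))
        assert np.allclose(degenes.cpm(counts).sum(axis=0), 1e6)
        lengths = pd.Series(rng.integers(200, 5000, 30), index=counts.index)
        assert np.allclose(degenes.tpm(counts, lengths).sum(axis=0), 1e6)


class TestNbGlmWald:
    def test_poisson_limit_matches_poisson_glm(self, rng):
        """dispersion -> 0, large counts: estimates match an independent
        Poisson GLM fit within 1e-3."""
        import statsmodels.api as sm

        n = 40
        g = np.repeat([0, 1], n // 2)
        mu = 2000 * 2.0 ** (1.5 * g)
        counts = pd.DataFrame(
            rng.poisson(np.tile(mu, (25, 1))),
            columns=[f"s{i}" for i in range(n)],
        )
        design = pd.DataFrame({"grp": np.where(g == 1, "b", "a")},
                              index=counts.columns)
        ones = pd.Series(1.0, index=counts.columns)
        de = degenes.nb_glm_wald(counts, design, ["grp"], "grp[b]", sf=ones)
        x = np.column_stack([np.ones(n), g])
        for i in range(len(counts)):
            ref = sm.GLM(counts.iloc[i].to_numpy(), x,
                         family=sm.families.Poisson()).fit()
            assert de["log2fc"].iloc[i] == pytest.approx(
                ref.params[1] / np.log(2), abs=1e-3
            )

    def test_all_zero_feature_is_na(self, rng):
        counts = pd.DataFrame(
            np.vstack([np.zeros(8), rng.poisson(30, 8)]).astype(int),
            index=["z", "ok"], columns=[f"s{i}" for i in range(8)],
        )
        design = pd.DataFrame({"grp": ["a", "b"] * 4}, index=counts.columns)
        de = degenes.nb_glm_wald(counts, design, ["grp"], "grp[b]",
                                 sf=pd.Series(1.0, index=counts.columns))
        assert np.isnan(de.loc["z", "log2fc"])
        assert np.isfinite(de.loc["ok", "log2fc"])

    def test_rank_deficient_design_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(3, 8)),
                              columns=[f"s{i}" for i in range(8)])
        design = pd.DataFrame({
            "g1": ["a", "b"] * 4, "g2": ["a", "b"] * 4,
        }, index=counts.columns)
        with pytest.raises(ValueError, match="aliased"):
            degenes.nb_glm_wald(counts, design, ["g1", "g2"], "g1[b]",
                                sf=pd.Series(1.0, index=counts.columns))

    def test_q_at_least_p(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(50, 12)),
                              columns=[f"s{i}" for i in range(12)])
        design = pd.DataFrame({"grp": ["a", "b"] * 6}, index=counts.columns)
        de = degenes.nb_glm_wald(counts, design, ["grp"], "grp[b]")
        ok = de.dropna()
        assert (ok["q"] >= ok["p"] - 1e-12).all()


class TestDroughtResponseByLegacy:
    def test_symmetric_effects_cis_overlap(self, design96):
        em, _ = synthgen.gen_expression(
            design96, 120, {"V": 0}, lfc=0.0, n_legacy_main=0, seed=21
        )
        # plant +2 in both groups by hand: scale drought columns of all genes
        drought = (em.design["test_water"] == "drought").to_numpy()
        counts = em.counts.copy()
        counts.loc[:, drought] = (counts.loc[:, drought] * 4).astype(int)
        # unit size factors: the planted global x4 must appear as biology,
        # not be absorbed by median-ratio normalization
        ones = pd.Series(1.0, index=counts.columns)
        res = degenes.drought_response_by_legacy(counts, em.design, sf=ones)
        calls = degenes.classify_interaction(res)
        assert calls["interacting"].mean() < 0.1
        assert res["lfc_dry"].mean() == pytest.approx(2.0, abs=0.15)
        assert res["lfc_wet"].mean() == pytest.approx(2.0, abs=0.15)

    def test_zero_count_feature_na(self, design48):
        em, _ = synthgen.gen_expression(design48, 5, None, n_legacy_main=0,
                                        seed=22)
        counts = em.counts.copy()
        counts.iloc[0] = 0
        res = degenes.drought_response_by_legacy(counts, em.design)
        assert np.isnan(res["lfc_dry"].iloc[0])


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "ci_dry,ci_wet,interacting,label",
        [
            ((-0.5, 0.5), (-3.0, -1.0), True, "I"),
            ((-0.5, 0.5), (1.0, 3.0), True, "II"),
            ((-3.0, -1.0), (-0.5, 0.5), True, "III"),
            ((1.0, 2.0), (-0.4, 0.4), True, "IV"),
            ((3.0, 4.0), (1.0, 2.0), True, "V"),
            ((1.0, 2.0), (-2.0, -1.0), True, "VI"),
            ((1.0, 2.0), (1.0, 2.0), False, "none"),
            ((-1.0, 1.0), (-0.5, 0.5), False, "none"),
        ],
    )
    def test_rule_table(self, ci_dry, ci_wet, interacting, label):
        got = degenes._classify_one(ci_dry, ci_wet)
        assert got == (interacting, label)

    @given(
        lo_d=st.floats(-4, 4), w_d=st.floats(0.01, 3),
        lo_w=st.floats(-4, 4), w_w=st.floats(0.01, 3),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_label_swap_symmetry(self, lo_d, w_d, lo_w, w_w):
        """Swapping the groups maps I<->III, II<->IV, keeps V, VI, none."""
        ci_d, ci_w = (lo_d, lo_d + w_d), (lo_w, lo_w + w_w)
        f1, l1 = degenes._classify_one(ci_d, ci_w)
        f2, l2 = degenes._classify_one(ci_w, ci_d)
        assert f1 == f2
        swap = {"I": "III", "II": "IV", "III": "I", "IV": "II",
                "V": "V", "VI": "VI", "none": "none"}
        assert l2 == swap[l1]

    def test_non_finite_ci_rejected(self):
        with pytest.raises(ValueError):
            degenes._classify_one((np.nan, 1.0), (0.0, 1.0))


class TestCallEnriched:
    def test_threshold_rules(self):
        de = pd.DataFrame({
            "q": [0.04, 0.04, 0.2], "log2fc": [2.5, 1.9, 3.0],
        }, index=["hit", "small", "weak"])
        assert list(degenes.call_enriched(de, 0.05, 2.0)) == ["hit"]

    def test_empty_input(self):
        de = pd.DataFrame(columns=["q", "log2fc"])
        assert len(degenes.call_enriched(de)) == 0


class TestClrInteractionLm:
    def test_two_asv_mirror_q_equals_p(self, rng):
        # with two ASVs the CLR values mirror each other, both rows carry the
        # same P and BH leaves q = P (a single-ASV table is degenerate: its
        # CLR is identically 0)
        counts = pd.DataFrame(rng.poisson(50, size=(2, 40)),
                              columns=[f"s{i}" for i in range(40)])
        design = pd.DataFrame({
            "legacy": ["dry", "wet"] * 20,
            "test_water": ["drought"] * 20 + ["control"] * 20,
        }, index=counts.columns)
        res = degenes.clr_interaction_lm(counts, design)
        assert res["p"].iloc[0] == pytest.approx(res["p"].iloc[1])
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_planted_interactions_recovered(self, rng):
        """10 of 500 ASVs get a multiplicative legacy x water interaction;
        most are recovered at q <= 0.05 and the null false-call rate stays
        low (CLR spillover from the planted block is shared by all nulls)."""
        n_cell = 30
        legacy = np.repeat(["dry", "wet"], 2 * n_cell)
        water = np.tile(np.repeat(["drought", "control"], n_cell), 2)
        base = rng.lognormal(np.log(100), 0.6, 500)
        mu = np.tile(base[:, None], (1, 4 * n_cell))
        inter = (legacy == "dry") & (water == "drought")
        mu[:10, inter] *= 6.0
        counts = pd.DataFrame(rng.poisson(mu),
                              columns=[f"s{i}" for i in range(4 * n_cell)])
        design = pd.DataFrame({"legacy": legacy, "test_water": water},
                              index=counts.columns)
        res = degenes.clr_interaction_lm(counts, design)
        assert (res["q"].iloc[:10] <= 0.05).sum() >= 8
        assert (res["q"].iloc[10:] <= 0.05).mean() <= 0.05
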