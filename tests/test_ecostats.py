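"""Diversity, dissimilarity, ordination and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from legacyscope import ecostats


class TestShannonEffective:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], 4.0),  # uniform over 4 taxa
            ([9, 0, 0], 1.0),  # single taxon
            ([1, 1, 2], 2.0**1.5),  # closed form: prod p_i^(-p_i)
        ],
    )
    def test_values(self, counts, expected):
        assert ecostats.shannon_effective(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ecostats.shannon_effective([0, 0])


class TestBrayCurtis:
    def test_hand_example(self):
        t = pd.DataFrame([[2, 0, 1], [1, 1, 1]], index=["a", "b"])
        assert ecostats.bray_curtis(t).loc["a", "b"] == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        t = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]], index=list("abc"))
        d = ecostats.bray_curtis(t)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_zero_sum_row_named(self):
        t = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            ecostats.bray_curtis(t)


class TestZscore:
    def test_hand(self):
        out = ecostats.zscore(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["v"], [-1, 0, 1])

    def test_constant_raises_or_drops(self):
        df = pd.DataFrame({"c": [2.0, 2.0], "v": [1.0, 3.0]})
        with pytest.raises(ValueError, match="c"):
            ecostats.zscore(df)
        with pytest.warns(UserWarning):
            out = ecostats.zscore(df, on_constant="drop")
        assert list(out.columns) == ["v"]

    def test_idempotent_on_standardized(self):
        z = ecostats.zscore(pd.DataFrame({"v": [1.0, 2.0, 4.0]}))
        assert np.allclose(ecostats.zscore(z), z)


class TestPcoa:
    def test_euclidean_roundtrip(self, euclid_points):
        _, d = euclid_points
        res = ecostats.pcoa(d, k=2)
        back = squareform(pdist(res.scores.to_numpy()))
        assert np.abs(back - d.to_numpy()).max() <= 1e-8

    def test_equilateral_axis_fraction(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = ecostats.pcoa(d, k=2)
        assert res.proportion_explained[0] == pytest.approx(0.5)

    def test_duplicated_sample_coincident(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4]])
        d = pd.DataFrame(squareform(pdist(pts)))
        res = ecostats.pcoa(d, k=2)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_k_out_of_range(self, euclid_points):
        _, d = euclid_points
        with pytest.raises(ValueError):
            ecostats.pcoa(d, k=len(d))


class TestPermanova:
    def test_perfect_separation_r2(self):
        x = np.array([[0.0, 0]] * 5 + [[10.0, 10]] * 5)
        d = pd.DataFrame(squareform(pdist(x)))
        meta = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=d.index)
        res = ecostats.permanova(d, meta, ["g"], n_perm=99, seed=1)
        assert res.loc["g", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_r2_sums_to_one(self, rng):
        x = rng.normal(size=(16, 3))
        d = pd.DataFrame(squareform(pdist(x)))
        meta = pd.DataFrame({
            "g": ["a", "b"] * 8,
            "h": ["u"] * 8 + ["v"] * 8,
            "x": rng.normal(size=16),
        }, index=d.index)
        res = ecostats.permanova(d, meta, ["g", "h", "x"], n_perm=49, seed=2)
        assert res["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-10)

    def test_null_p_uniform(self, rng):
        """With random labels the permutation P is ~Uniform(0, 1]."""
        from scipy import stats

        pvals = []
        for _ in range(120):
            x = rng.normal(size=(12, 2))
            d = pd.DataFrame(squareform(pdist(x)))
            meta = pd.DataFrame({"g": rng.permutation(["a"] * 6 + ["b"] * 6)},
                                index=d.index)
            res = ecostats.permanova(d, meta, ["g"], n_perm=99,
                                     seed=int(rng.integers(2**31)))
            pvals.append(res.loc["g", "P"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_level_term_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(4))
        meta = pd.DataFrame({"g": ["a"] * 4}, index=d.index)
        with pytest.raises(ValueError):
            ecostats.permanova(d, meta, ["g"], n_perm=9, seed=0)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=(10, 2))
        d = pd.DataFrame(squareform(pdist(x)))
        meta = pd.DataFrame({"g": ["a", "b"] * 5}, index=d.index)
        a = ecostats.permanova(d, meta, ["g"], n_perm=199, seed=5)
        b = ecostats.permanova(d, meta, ["g"], n_perm=199, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestMantel:
    def test_self_and_scale_invariance(self, euclid_points):
        _, d = euclid_points
        r, _ = ecostats.mantel(d, d, n_perm=49, seed=1)
        assert r == pytest.approx(1.0)
        r2, _ = ecostats.mantel(d, 2.0 * d, n_perm=49, seed=1)
        assert r2 == pytest.approx(1.0)

    def test_independent_matrices_r_near_zero(self, rng):
        rs = []
        for _ in range(200):
            d1 = pd.DataFrame(squareform(pdist(rng.normal(size=(8, 2)))))
            d2 = pd.DataFrame(squareform(pdist(rng.normal(size=(8, 2)))))
            r, _ = ecostats.mantel(d1, d2, n_perm=9, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_constant_triangle_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(4))
        with pytest.raises(ValueError):
            ecostats.mantel(d, d, n_perm=9, seed=0)


class TestBetadispersion:
    def test_identical_points_zero_distance(self):
        pts = np.array([[0.0, 0]] * 3 + [[5.0, 5]] * 3)
        d = pd.DataFrame(squareform(pdist(pts)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.index)
        dist, _, _ = ecostats.betadispersion(d, groups, n_perm=49, seed=1)
        assert np.allclose(dist, 0.0, atol=1e-10)

    def test_detects_scaled_group(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) * 3.0
        d = pd.DataFrame(squareform(pdist(np.vstack([a, b]))))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=d.index)
        _, f, p = ecostats.betadispersion(d, groups, n_perm=199, seed=1)
        assert p < 0.05

    def test_type_one_error_controlled(self, rng):
        hits = 0
        reps = 120
        for _ in range(reps):
            x = rng.normal(size=(16, 2))
            d = pd.DataFrame(squareform(pdist(x)))
            groups = pd.Series(["a"] * 8 + ["b"] * 8, index=d.index)
            _, _, p = ecostats.betadispersion(d, groups, n_perm=49,
                                              seed=int(rng.integers(2**31)))
            hits += p <= 0.05
        # binomial(120, 0.05): 3 sd band around 6
        assert hits <= 14

    def test_small_group_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        groups = pd.Series(["a", "a", "b"], index=d.index)
        with pytest.raises(ValueError):
            ecostats.betadispersion(d, groups, n_perm=9, seed=0)


class TestPartialRDA:
    def test_univariate_anova_identity(self, rng):
        """Constrained-variance fraction equals between-group SS / total SS."""
        y = rng.normal(size=40)
        g = np.array(["a", "b"] * 20)
        y[g == "b"] += 1.5
        resp = pd.DataFrame({"y": y})
        cons = pd.DataFrame({"g": g})
        res = ecostats.partial_constrained_ordination(resp, cons, None,
                                                      n_perm=49, seed=1)
        yc = y - y.mean()
        ss_total = (yc**2).sum()
        ss_between = sum(
            (y[g == lev].mean() - y.mean()) ** 2 * (g == lev).sum()
            for lev in ("a", "b")
        )
        assert res.term_stats.loc["Overall", "R2"] == pytest.approx(
            ss_between / ss_total
        )

    def test_constant_conditions_equal_plain(self, rng):
        resp = pd.DataFrame(rng.normal(size=(30, 4)))
        cons = pd.DataFrame({"g": ["a", "b", "c"] * 10})
        a = ecostats.partial_constrained_ordination(resp, cons, None,
                                                    n_perm=29, seed=3)
        const = pd.DataFrame({"z": ["k"] * 30})
        b = ecostats.partial_constrained_ordination(resp, cons, const,
                                                    n_perm=29, seed=3)
        assert a.term_stats.loc["Overall", "R2"] == pytest.approx(
            b.term_stats.loc["Overall", "R2"]
        )

    def test_null_p_uniform(self, rng):
        from scipy import stats

        pvals = []
        for _ in range(100):
            resp = pd.DataFrame(rng.normal(size=(16, 3)))
            cons = pd.DataFrame({"g": rng.permutation(["a"] * 8 + ["b"] * 8)})
            res = ecostats.partial_constrained_ordination(
                resp, cons, None, n_perm=49, seed=int(rng.integers(2**31))
            )
            pvals.append(res.term_stats.loc["Overall", "P"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_conditioning_removes_confound(self, rng):
        """A constraint collinear with the condition explains ~nothing after
        partialling."""
        block = np.repeat(["u", "v"], 15)
        y = rng.normal(size=(30, 3)) + (block == "v")[:, None] * 2.0
        resp = pd.DataFrame(y)
        cons = pd.DataFrame({"g": block})
        cond = pd.DataFrame({"block": block})
        with pytest.raises(ValueError):
            ecostats.partial_constrained_ordination(resp, cons, cond,
                                                    n_perm=29, seed=1)


class TestClr:
    def test_hand_example(self):
        out = ecostats.clr_transform(pd.DataFrame([[1.0, 3.0]]), pseudocount=0.0)
        assert np.allclose(out.to_numpy()[0],
                           [-np.log(3) / 2, np.log(3) / 2])

    def test_equal_counts_zero(self):
        out = ecostats.clr_transform(pd.DataFrame([[4, 4, 4]]), pseudocount=0.5)
        assert np.allclose(out, 0.0)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2,
                    max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rows_sum_to_zero(self, counts):
        out = ecostats.clr_transform(pd.DataFrame([counts]), pseudocount=0.5)
        assert abs(out.to_numpy().sum()) < 1e-9


class TestRarefy:
    def test_depth_and_determinism(self):
        counts = pd.DataFrame([[10, 30], [20, 5], [5, 40]],
                              columns=["s1", "s2"])
        a = ecostats.rarefy(counts, seed=4)
        b = ecostats.rarefy(counts, seed=4)
        assert (a.sum(axis=0) == min(counts.sum(axis=0))).all()
        assert a.equals(b)
        assert (a <= counts).all().all()
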