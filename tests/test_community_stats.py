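import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from famtrack.core_data import FeatureTable, ValidationError
from famtrack.community_stats import (
    anosim,
    beta_distance,
    family_pairs,
    kruskal_wallis_screen,
    pairwise_anosim,
    pcoa,
    rank_sum_compare,
    shannon,
)
from tests.conftest import WORKED_TREE


def _table(rows, ids=None, cols=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = cols or list("ABCD")[: rows.shape[1]]
    return FeatureTable(pd.DataFrame(rows, index=ids, columns=cols))


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], 2.0),  # uniform over 4 taxa, base 2
            ([9, 0, 0], 0.0),  # single taxon
            ([2, 1, 1], 1.5),  # -0.5*log2(0.5) - 2*0.25*log2(0.25)
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_natural_log_base(self):
        assert shannon([1, 1], base=math.e) == pytest.approx(math.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestBetaDistance:
    def test_bray_curtis_closed_forms(self):
        t = _table([[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]], cols=["a", "b", "c"])
        dm = beta_distance(t, "bray_curtis")
        assert dm["s0", "s2"] == pytest.approx(0.0)  # identical
        assert dm["s0", "s1"] == pytest.approx(0.5)
        assert dm["s1", "s3"] == pytest.approx(1.0)  # disjoint supports

    def test_unifrac_disjoint_clades_is_one(self):
        t = _table([[1, 1, 0, 0], [0, 0, 1, 1]])
        dm = beta_distance(t, "unweighted_unifrac", tree=WORKED_TREE)
        assert dm["s0", "s1"] == pytest.approx(1.0)

    def test_unifrac_partial_overlap_hand_value(self):
        # {A,B} vs {A,C}: unique branches B, C, (C,D)-stem of 5 observed -> 3/5
        t = _table([[1, 1, 0, 0], [1, 0, 1, 0]])
        dm = beta_distance(t, "unweighted_unifrac", tree=WORKED_TREE)
        assert dm["s0", "s1"] == pytest.approx(0.6)

    def test_unifrac_presence_absence_only(self):
        t1 = _table([[1, 1, 0, 0], [1, 0, 1, 0]])
        t2 = _table([[9, 2, 0, 0], [3, 0, 7, 0]])
        d1 = beta_distance(t1, "unweighted_unifrac", tree=WORKED_TREE)
        d2 = beta_distance(t2, "unweighted_unifrac", tree=WORKED_TREE)
        assert d1["s0", "s1"] == pytest.approx(d2["s0", "s1"])

    def test_missing_tips_listed(self):
        t = _table([[1, 1], [1, 0]], cols=["A", "Zmissing"])
        with pytest.raises(ValidationError, match="Zmissing"):
            beta_distance(t, "unweighted_unifrac", tree=WORKED_TREE)

    def test_unifrac_requires_tree(self):
        with pytest.raises(ValidationError, match="tree"):
            beta_distance(_table([[1, 1], [1, 0]]), "unweighted_unifrac")


def _brute_force_anosim(dm, labels):
    """Independent oracle: R over every distinct label arrangement."""
    n = len(labels)
    cond = dm.condensed_form()
    ranks = squareform(stats.rankdata(cond))
    m = n * (n - 1) / 2

    def r_of(lab):
        w, b = [], []
        for i, k in itertools.combinations(range(n), 2):
            (w if lab[i] == lab[k] else b).append(ranks[i, k])
        return (np.mean(b) - np.mean(w)) / (m / 2)

    r_obs = r_of(labels)
    r_all = [r_of(p) for p in set(itertools.permutations(labels))]
    return r_obs, np.mean([r >= r_obs - 1e-12 for r in r_all])


class TestAnosim:
    def test_maximal_separation_gives_r_one(self):
        # group a points clustered at 0, group b at 100
        pts = np.array([[0.0], [0.1], [0.2], [100.0], [100.1], [100.2]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        r, p = anosim(dm, labels, n_perm="exact")
        assert r == pytest.approx(1.0)
        # of the 20 distinct splits only the true one and its label swap reach R=1
        assert p == pytest.approx(2 / 20)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.0
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        r_oracle, p_oracle = _brute_force_anosim(dm, labels)
        r, p = anosim(dm, labels, n_perm="exact")
        assert r == pytest.approx(r_oracle)
        assert p == pytest.approx(p_oracle)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(0)
        pts = rng.random((10, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        ours, _ = anosim(dm, labels, n_perm=9, seed=0)
        ref = sk_anosim(dm, grouping=list(labels), permutations=9)
        assert ours == pytest.approx(ref["test statistic"])

    def test_null_r_centred_at_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        rs = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            r, _ = anosim(dm, labels, n_perm=1, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
        assert min(rs) >= -1.0 and max(rs) <= 1.0

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.arange(4)[:, None])), ids=list("wxyz"))
        with pytest.raises(ValidationError, match="b"):
            anosim(dm, ["a", "a", "a", "b"])

    def test_pairwise_mode_covers_all_pairs(self):
        rng = np.random.default_rng(2)
        pts = rng.random((9, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(9)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = pairwise_anosim(dm, labels, n_perm=19, seed=0)
        assert set(map(tuple, out[["group_a", "group_b"]].values)) == {
            ("a", "b"), ("a", "c"), ("b", "c"),
        }


class TestKruskalWallis:
    def test_h_matches_hand_ranked_oracle(self):
        g1, g2, g3 = [1.2, 3.4, 2.2, 5.1], [4.8, 6.0, 7.1, 5.5], [0.2, 1.1, 0.9, 2.5]
        frame = pd.DataFrame({"f": g1 + g2 + g3})
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        result, _ = kruskal_wallis_screen(frame, groups)
        values = np.array(g1 + g2 + g3)
        ranks = stats.rankdata(values)
        n = len(values)
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (ranks[i * 4 : (i + 1) * 4].mean() - (n + 1) / 2) ** 2
            for i, g in enumerate([g1, g2, g3])
        )
        assert result["H"].iloc[0] == pytest.approx(h)

    def test_constant_feature_skipped(self):
        frame = pd.DataFrame({"const": [1.0] * 6, "var": [1, 2, 3, 4, 5, 6]})
        result, skipped = kruskal_wallis_screen(frame, ["a"] * 3 + ["b"] * 3)
        assert skipped == ["const"]
        assert list(result["feature"]) == ["var"]

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis_screen(pd.DataFrame({"f": [1, 2]}), ["a", "a"])

    def test_bh_correction_flag(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.random((30, 20)), columns=[f"f{i}" for i in range(20)])
        res_raw, _ = kruskal_wallis_screen(frame, ["a"] * 15 + ["b"] * 15)
        res_bh, _ = kruskal_wallis_screen(frame, ["a"] * 15 + ["b"] * 15, correction="bh")
        assert "p_adj" in res_bh.columns
        assert res_bh["significant"].sum() <= res_raw["significant"].sum()


class TestRankSum:
    def test_exact_one_sided_enumeration_value(self):
        _, p = rank_sum_compare([1, 2], [3, 4], "less")
        assert p == pytest.approx(1 / 6)

    def test_identical_multisets_two_sided_p_one(self):
        _, p = rank_sum_compare([1, 2, 3], [1, 2, 3], "two_sided")
        assert p == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_compare([], [1.0])

    def test_couple_distances_detect_household_effect(self, cohort, rarefied_tables):
        dm = beta_distance(rarefied_tables["skin"], "bray_curtis")
        within, between, counts = family_pairs(dm, cohort.metadata, "couple")
        assert counts["within"] > 10
        _, p = rank_sum_compare(within, between, "less")
        assert p < 0.05


class TestPcoa:
    def test_points_on_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        dm = DistanceMatrix(np.abs(x[:, None] - x[None, :]), ids=list("abcd"))
        res = pcoa(dm, k=2)
        axis = res.coordinates["PC1"].to_numpy()
        # first axis reproduces the line up to sign and ordering
        got = np.abs(np.diff(np.sort(axis)))
        assert np.allclose(np.sort(got), np.sort(np.diff(x)), atol=1e-8)

    def test_identical_samples_identical_coordinates(self):
        t = _table([[1, 2, 3], [1, 2, 3], [9, 1, 0]], cols=["a", "b", "c"])
        dm = beta_distance(t, "bray_curtis")
        res = pcoa(dm, k=2)
        np.testing.assert_allclose(
            res.coordinates.loc["s0"], res.coordinates.loc["s1"], atol=1e-9
        )

    def test_explained_proportions_non_increasing(self, rarefied_tables):
        dm = beta_distance(rarefied_tables["gut"], "bray_curtis")
        res = pcoa(dm, k=4)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_k_too_large_rejected(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValidationError):
            pcoa(dm, k=3)
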