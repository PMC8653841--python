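import numpy as np
import pandas as pd
import pytest

from famtrack.core_data import ValidationError
from famtrack.association import (
    child_member_similarity,
    diet_effect_screen,
    familytime_similarity,
    picky_transmission_test,
    spearman_screen,
    transmissible_overlap,
)
from famtrack.transmission import ContributionSummary


def _contrib_from_transmitted(frame: pd.DataFrame) -> ContributionSummary:
    means = frame.groupby("niche")["transmitted_fraction"].mean()
    return ContributionSummary(
        per_child=pd.DataFrame(), role_means=pd.DataFrame(),
        transmitted=frame, transmitted_means=means,
    )


class TestSpearmanScreen:
    def test_monotone_pairs_hit_plus_minus_one(self):
        idx = [f"s{i}" for i in range(10)]
        x = np.arange(10.0)
        abundance = pd.DataFrame({"up": x, "down": -x}, index=idx)
        indices = pd.DataFrame({"IgA": x**3}, index=idx)  # monotone transform
        edges = spearman_screen(abundance, indices)
        by_feature = edges.set_index("feature_id")
        assert by_feature.loc["up", "rho"] == pytest.approx(1.0)
        assert by_feature.loc["down", "rho"] == pytest.approx(-1.0)
        assert bool(by_feature.loc["up", "passes_strong_threshold"])

    def test_rank_based_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(20)]
        abundance = pd.DataFrame(rng.random((20, 5)), index=idx,
                                 columns=[f"f{i}" for i in range(5)])
        indices = pd.DataFrame({"IgG": rng.random(20)}, index=idx)
        a = spearman_screen(abundance, indices, r_min=0.0, p_max=1.01)
        b = spearman_screen(np.log(abundance + 1e-9), indices, r_min=0.0, p_max=1.01)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_feature_skipped(self):
        idx = [f"s{i}" for i in range(8)]
        abundance = pd.DataFrame({"const": np.ones(8), "var": np.arange(8.0)}, index=idx)
        indices = pd.DataFrame({"IgA": np.arange(8.0)}, index=idx)
        edges = spearman_screen(abundance, indices, r_min=0.0, p_max=1.01)
        assert set(edges["feature_id"]) == {"var"}

    def test_too_few_observations_rejected(self):
        idx = ["a", "b", "c"]
        with pytest.raises(ValidationError):
            spearman_screen(
                pd.DataFrame({"f": [1, 2, 3]}, index=idx),
                pd.DataFrame({"i": [1, 2, 3]}, index=idx),
            )


class TestTransmissibleOverlap:
    def test_disjoint_and_subset_fractions(self):
        edges = pd.DataFrame({"feature_id": ["a", "b"], "index_name": ["IgA"] * 2,
                              "rho": [0.5, 0.6], "p": [0.01] * 2, "sign": [1, 1],
                              "passes_strong_threshold": [False, True]})
        assert transmissible_overlap(edges, {"x", "y"}).fraction == 0.0
        assert transmissible_overlap(edges, {"a", "b", "c"}).fraction == 1.0

    def test_cohort_scale_arithmetic(self):
        # 415 features with edges, 353 of them transmissible -> 85.06%
        features = [f"f{i}" for i in range(415)]
        edges = pd.DataFrame({
            "feature_id": features, "index_name": ["IgA"] * 415,
            "rho": [0.4] * 415, "p": [0.01] * 415, "sign": [1] * 415,
            "passes_strong_threshold": [False] * 415,
        })
        out = transmissible_overlap(edges, set(features[:353]))
        assert out.n_overlap == 353
        assert out.fraction == pytest.approx(0.8506, abs=5e-5)


class TestDietScreen:
    def test_food_without_both_groups_skipped(self):
        idx = [f"s{i}" for i in range(10)]
        abundance = pd.DataFrame({"t": np.arange(10.0)}, index=idx)
        flags = pd.DataFrame({"milk": ["Y"] * 10, "meat": ["Y"] * 5 + ["N"] * 5}, index=idx)
        res, skipped = diet_effect_screen(abundance, flags)
        assert skipped == ["milk"]
        assert set(res["food"]) == {"meat"}

    def test_antibiotic_subjects_excluded(self):
        idx = [f"s{i}" for i in range(8)]
        abundance = pd.DataFrame({"t": [0, 0, 0, 0, 9, 9, 9, 9.0]}, index=idx)
        flags = pd.DataFrame({"meat": ["Y", "Y", "Y", "Y", "N", "N", "N", "N"]}, index=idx)
        anti = pd.Series(["N"] * 4 + ["Y"] * 4, index=idx)
        res, _ = diet_effect_screen(abundance, flags, antibiotics=anti)
        assert res.empty  # the N group vanished with the exposed subjects

    def test_null_features_flag_near_alpha(self):
        rng = np.random.default_rng(1)
        n, m = 40, 400
        idx = [f"s{i}" for i in range(n)]
        abundance = pd.DataFrame(rng.random((n, m)), index=idx,
                                 columns=[f"t{i}" for i in range(m)])
        flags = pd.DataFrame({"meat": rng.choice(["Y", "N"], size=n)}, index=idx)
        res, _ = diet_effect_screen(abundance, flags)
        rate = res["significant"].mean()
        assert abs(rate - 0.05) < 0.035  # ~4 binomial sd at m=400

    def test_planted_fold_effects_recovered(self, cohort):
        md = cohort.metadata
        kids = md.samples_in_niche("gut")
        kids = kids[kids["role"] == "C"]
        rel = cohort.tables["gut"].relative_abundance().loc[kids.index]
        rel.index = pd.Index(kids["subject_id"])
        res, _ = diet_effect_screen(rel, md.diet_frame(list(kids["subject_id"])),
                                    antibiotics=md.subjects["antibiotics"])
        for key, targets in cohort.truth.diet_responsive.items():
            food = key.split("|")[0]
            sub = res[(res["food"] == food) & (res["taxon"].isin(targets))]
            assert sub["significant"].mean() >= 0.8


class TestPickyTest:
    def test_identical_groups_p_one_difference_zero(self):
        frame = pd.DataFrame({
            "child": [f"c{i}" for i in range(6)],
            "household": ["H"] * 6,
            "niche": ["gut"] * 6,
            "transmitted_fraction": [0.4, 0.5, 0.6, 0.4, 0.5, 0.6],
        })
        flags = pd.DataFrame({"milk": ["Y", "Y", "Y", "N", "N", "N"]},
                             index=[f"c{i}" for i in range(6)])
        res = picky_transmission_test(_contrib_from_transmitted(frame), flags)
        assert res["difference"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_power_for_planted_shift(self):
        # +0.2 family-proportion shift in non-consumers (n=15/15, sd 0.1)
        rng = np.random.default_rng(2)
        hits = 0
        reps = 50
        for _ in range(reps):
            yes = rng.normal(0.5, 0.1, 15)
            no = rng.normal(0.7, 0.1, 15)
            children = [f"c{i}" for i in range(30)]
            frame = pd.DataFrame({
                "child": children, "household": ["H"] * 30, "niche": ["gut"] * 30,
                "transmitted_fraction": np.concatenate([yes, no]),
            })
            flags = pd.DataFrame({"milk": ["Y"] * 15 + ["N"] * 15}, index=children)
            res = picky_transmission_test(_contrib_from_transmitted(frame), flags)
            if res["p"].iloc[0] < 0.05 and res["difference"].iloc[0] > 0:
                hits += 1
        assert hits / reps >= 0.9

    def test_small_group_skipped(self):
        frame = pd.DataFrame({
            "child": ["c0", "c1", "c2"], "household": ["H"] * 3, "niche": ["gut"] * 3,
            "transmitted_fraction": [0.4, 0.5, 0.6],
        })
        flags = pd.DataFrame({"milk": ["Y", "N", "N"]}, index=["c0", "c1", "c2"])
        res = picky_transmission_test(_contrib_from_transmitted(frame), flags)
        assert res.empty


class TestFamilyTime:
    def test_zero_variance_hours_reported_undefined(self):
        pairs = pd.DataFrame({
            "child": ["c"] * 5, "member": [f"m{i}" for i in range(5)],
            "role": ["M", "F", "PGM", "PGF", "MGM"], "niche": ["gut"] * 5,
            "similarity": [0.1, 0.5, 0.3, 0.2, 0.4], "family_time": [8.0] * 5,
        })
        out = familytime_similarity(pairs)
        assert np.isnan(out.correlations["rho"].iloc[0])

    def test_planted_time_alpha_relation_recovered(self, cohort, rarefied_tables):
        pairs = child_member_similarity(rarefied_tables, cohort.metadata)
        assert ((pairs["similarity"] >= 0) & (pairs["similarity"] <= 1)).all()
        out = familytime_similarity(pairs)
        by_niche = out.correlations.set_index("niche")
        assert (by_niche["rho"] > 0).all()
        assert (by_niche["p"] < 0.05).all()
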