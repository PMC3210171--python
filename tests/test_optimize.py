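"""Feature screening, grid search and bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

from actc.optimize import (
    BoundGrid,
    ObjectiveConfig,
    SearchSpace,
    bootstrap_stability,
    grid_search,
    rank_features,
)
from actc.survival import cox_hr, dichotomize
from actc.synthetic import FeatureCohortConfig, simulate_feature_cohort

SPACE = SearchSpace(
    {
        "ck_std": BoundGrid("gt", (20.0, 35.0, 50.0, 65.0)),
        "cd45_peak": BoundGrid("lt", (30.0, 60.0, 90.0, 120.0)),
    }
)


def winner_bounds(result):
    return {
        feat: (rule.gt if rule.gt is not None else rule.lt)
        for feat, rule in result.classifier.rules.items()
    }


class TestRankFeatures:
    def test_prognostic_feature_outranks_noise(self):
        wins = 0
        for seed in range(20):
            # screening needs cohort-scale power: risk-independent nuisance
            # objects dilute the single-feature counts, so use 400 patients
            sim = simulate_feature_cohort(
                FeatureCohortConfig(n_patients=400, rng_seed=seed)
            )
            feats, cohort = sim["baseline"]
            ranking = rank_features(
                feats, cohort, candidate_features=["ck_std", "dapi_peak", "size_px"]
            )
            order = list(ranking["feature"])
            wins += order.index("ck_std") < order.index("dapi_peak")
        assert wins >= 18  # >= 90% of replicates

    def test_duplicated_feature_excluded_by_correlation(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=1))
        feats, cohort = sim["baseline"]
        feats = feats.copy()
        feats["ck_std_copy"] = feats["ck_std"]
        ranking = rank_features(
            feats, cohort, candidate_features=["ck_std", "ck_std_copy"]
        )
        assert ranking["selected"].sum() == 1

    def test_single_feature_returned_unconditionally(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=1))
        feats, cohort = sim["baseline"]
        ranking = rank_features(feats, cohort, candidate_features=["ck_std"])
        assert list(ranking["feature"]) == ["ck_std"]
        assert ranking["selected"].all()

    def test_constant_feature_ranks_last(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=1))
        feats, cohort = sim["baseline"]
        feats = feats.copy()
        feats["flat"] = 1.0
        ranking = rank_features(
            feats, cohort, candidate_features=["ck_std", "flat"]
        )
        assert list(ranking["feature"])[-1] == "flat"
        assert not ranking.set_index("feature").loc["flat", "selected"]


class TestGridSearch:
    def test_single_candidate_space_returns_it(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=0))
        space = SearchSpace({"ck_std": BoundGrid("gt", (50.0,))})
        res = grid_search(
            space, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        assert res.n_candidates == 1
        if res.classifier is not None:
            assert res.classifier.rules["ck_std"].gt == 50.0
            assert np.isfinite(res.objective.score)

    def test_winner_score_dominates_all_feasible(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=2))
        res = grid_search(
            SPACE, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        feasible = res.table[res.table["feasible"]]
        assert res.objective.score >= feasible["score"].max() - 1e-12

    def test_winner_matches_independent_reevaluation(self):
        """Exhaustiveness: re-evaluate a coarse grid by a literal per-sample
        pandas filter + full Cox fit and compare the winning score."""
        sim = simulate_feature_cohort(FeatureCohortConfig(n_patients=120, rng_seed=4))
        space = SearchSpace(
            {
                "ck_std": BoundGrid("gt", (35.0, 50.0, 65.0)),
                "cd45_peak": BoundGrid("lt", (30.0, 60.0, 90.0)),
            }
        )
        res = grid_search(
            space, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )

        def brute_hr(feats, cohort, ck, cd):
            counts = []
            for sid in cohort["sample_id"]:
                sub = feats[feats["sample_id"] == sid]
                counts.append(
                    int(((sub["ck_std"] > ck) & (sub["cd45_peak"] < cd)).sum())
                )
            group, _ = dichotomize(np.asarray(counts))
            if group.all() or not group.any():
                return float("nan")
            summ = cox_hr(cohort["os_months"], cohort["event"], group)
            return summ.hr if summ.converged else float("nan")

        best = None
        for ck in (35.0, 50.0, 65.0):
            for cd in (30.0, 60.0, 90.0):
                hr_b = brute_hr(*sim["baseline"], ck, cd)
                hr_f = brute_hr(*sim["followup"], ck, cd)
                ctl = sim["controls"]
                ctl_total = int(
                    ((ctl["ck_std"] > ck) & (ctl["cd45_peak"] < cd)).sum()
                )
                mean_b = np.mean(
                    [
                        ((sim["baseline"][0]["sample_id"] == sid)
                         & (sim["baseline"][0]["ck_std"] > ck)
                         & (sim["baseline"][0]["cd45_peak"] < cd)).sum()
                        for sid in sim["baseline"][1]["sample_id"]
                    ]
                )
                rel = (ctl_total / sim["n_control_samples"]) / mean_b if mean_b else np.inf
                cfg = ObjectiveConfig()
                if (
                    np.isfinite(hr_b) and np.isfinite(hr_f) and hr_f > hr_b
                    and ctl_total <= cfg.max_control_total
                    and rel <= cfg.max_control_relative
                ):
                    score = hr_b + hr_f
                    if best is None or score > best:
                        best = score
        if best is None:
            assert res.classifier is None
        else:
            # both routes iterate to ~1e-8 in beta; compare at that scale
            assert res.objective.score == pytest.approx(best, rel=1e-6)

    def test_dominated_duplicate_candidate_never_changes_winner(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=3))
        base = SearchSpace({"ck_std": BoundGrid("gt", (35.0, 50.0))})
        padded = SearchSpace({"ck_std": BoundGrid("gt", (35.0, 50.0, 50.0))})
        res_a = grid_search(
            base, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        res_b = grid_search(
            padded, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        assert (res_a.classifier is None) == (res_b.classifier is None)
        if res_a.classifier is not None:
            assert res_a.classifier.rules == res_b.classifier.rules

    def test_patient_order_invariance(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=5))
        feats, cohort = sim["baseline"]
        perm = cohort.sample(frac=1.0, random_state=11).reset_index(drop=True)
        res_a = grid_search(
            SPACE, (feats, cohort), sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        res_b = grid_search(
            SPACE, (feats, perm), sim["followup"], sim["controls"],
            sim["n_control_samples"],
        )
        assert res_a.classifier == res_b.classifier

    def test_mismatched_patient_ids_rejected(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=0))
        feats, cohort = sim["followup"]
        other = cohort.copy()
        other["sample_id"] = other["sample_id"] + "_x"
        with pytest.raises(ValueError):
            grid_search(
                SPACE, sim["baseline"], (feats, other), sim["controls"],
                sim["n_control_samples"],
            )

    def test_null_cohort_yields_no_feasible_classifier_with_margin(self):
        sim = simulate_feature_cohort(
            FeatureCohortConfig(rng_seed=8, true_hr=1.0)
        )
        res = grid_search(
            SPACE, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"],
            objective=ObjectiveConfig(followup_margin=0.5),
        )
        assert res.classifier is None
        hrs = res.table[["hr_baseline", "hr_followup"]].to_numpy(float)
        finite = hrs[np.isfinite(hrs)]
        assert np.nanmedian(finite) == pytest.approx(1.0, abs=0.35)


class TestBootstrapStability:
    def test_identity_resample_reproduces_full_data_winner(self):
        # use the first simulated cohort on which the full-data search is
        # feasible at all, then check the identity resample reproduces it
        for seed in range(10):
            sim = simulate_feature_cohort(FeatureCohortConfig(rng_seed=seed))
            full = grid_search(
                SPACE, sim["baseline"], sim["followup"], sim["controls"],
                sim["n_control_samples"],
            )
            if full.classifier is not None:
                break
        else:
            pytest.fail("no feasible cohort found in 10 seeds")
        boot = bootstrap_stability(
            SPACE, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"], n_boot=1, seed=0, identity_first=True,
        )
        assert len(boot.bounds) == 1
        row = boot.bounds.iloc[0]
        assert row["ck_std"] == winner_bounds(full)["ck_std"]
        assert row["cd45_peak"] == winner_bounds(full)["cd45_peak"]

    def test_fixed_seed_is_deterministic(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(n_patients=80, rng_seed=7))
        kwargs = dict(n_boot=4, seed=13)
        a = bootstrap_stability(
            SPACE, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"], **kwargs,
        )
        b = bootstrap_stability(
            SPACE, sim["baseline"], sim["followup"], sim["controls"],
            sim["n_control_samples"], **kwargs,
        )
        pd.testing.assert_frame_equal(a.bounds, b.bounds)
        assert a.n_skipped == b.n_skipped

    def test_n_boot_validated(self):
        sim = simulate_feature_cohort(FeatureCohortConfig(n_patients=40, rng_seed=0))
        with pytest.raises(ValueError):
            bootstrap_stability(
                SPACE, sim["baseline"], sim["followup"], sim["controls"],
                sim["n_control_samples"], n_boot=0, seed=0,
            )
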