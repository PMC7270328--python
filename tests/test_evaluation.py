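import numpy as np
import pandas as pd
import pytest

from connharm.errors import DataError, LeakageError, UsageError
from connharm.evaluation import (
    compute_metrics,
    filter_subgroup,
    interaction_diagnostics,
    permutation_test,
    run_independent_site,
    run_kfold,
    run_loocv,
    run_loso,
    stratified_folds,
)
from connharm.experiments import _shifted_site_cohorts
from connharm.synthetic_data import SyntheticConfig, generate_fc_cohort


class TestStratifiedFolds:
    def test_single_stratum_even_split(self):
        ph = pd.DataFrame({"id": [f"s{i}" for i in range(18)], "diagnosis": "HC"})
        plan = stratified_folds(ph, 9, keys=("diagnosis",), rng=np.random.default_rng(0))
        sizes = [len(plan.fold_ids(f)) for f in range(9)]
        assert sizes == [2] * 9

    def test_per_stratum_counts_differ_by_at_most_one(self):
        ph = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(18)],
                "diagnosis": ["HC"] * 10 + ["MDD"] * 8,
            }
        )
        plan = stratified_folds(ph, 9, keys=("diagnosis",), rng=np.random.default_rng(1))
        for dx in ("HC", "MDD"):
            ids = set(ph.loc[ph["diagnosis"] == dx, "id"])
            counts = [len(ids & set(plan.fold_ids(f))) for f in range(9)]
            assert max(counts) - min(counts) <= 1

    def test_seed_determinism(self, biased_cohort):
        ph = biased_cohort.phenotypes
        a = stratified_folds(ph, 5, rng=np.random.default_rng(3))
        b = stratified_folds(ph, 5, rng=np.random.default_rng(3))
        assert a.assignments == b.assignments

    def test_k_larger_than_n_rejected(self):
        ph = pd.DataFrame({"id": ["a", "b"], "diagnosis": ["HC", "MDD"]})
        with pytest.raises(UsageError):
            stratified_folds(ph, 5, keys=("diagnosis",))


class TestComputeMetrics:
    def test_counting_definitions(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert m["accuracy"] == 0.75
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 1.0

    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1], [1, 0, 1], scores=[0.9, 0.1, 0.8])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0
        assert m["auc"] == 1.0

    def test_auc_rank_definition(self):
        y = [1, 1, 0, 0]
        assert compute_metrics(y, y, scores=[1, 1, 0, 0])["auc"] == 1.0
        assert compute_metrics(y, y, scores=[0.5] * 4)["auc"] == 0.5

    def test_single_class_flagged_undefined(self):
        m = compute_metrics([1, 1], [1, 0])
        assert np.isnan(m["specificity"])
        assert "specificity" in m["undefined"]

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            compute_metrics([], [])


class TestLoocv:
    def test_easy_cohort_high_accuracy(self, easy_cohort):
        rep = run_loocv(easy_cohort, algorithm="svm", rng=np.random.default_rng(0))
        assert rep.accuracy >= 0.9
        assert len(rep.detail) == len(easy_cohort.phenotypes)

    def test_null_cohort_near_chance(self, null_cohort):
        rep = run_loocv(null_cohort, algorithm="svm", rng=np.random.default_rng(0))
        assert 0.35 <= rep.accuracy <= 0.65


class TestKfold:
    def test_report_reconciles_with_details(self, easy_cohort):
        rep = run_kfold(easy_cohort, k=5, rng=np.random.default_rng(0))
        n = sum(d["n"] for d in rep.detail)
        assert n == len(easy_cohort.phenotypes)
        assert rep.accuracy >= 0.85

    def test_deterministic_given_seed(self, easy_cohort):
        a = run_kfold(easy_cohort, k=5, rng=np.random.default_rng(7))
        b = run_kfold(easy_cohort, k=5, rng=np.random.default_rng(7))
        assert a.accuracy == b.accuracy
        assert a.detail == b.detail


class TestLoso:
    def test_one_report_per_site(self, biased_cohort):
        reports = run_loso(biased_cohort, rng=np.random.default_rng(0))
        assert len(reports) == 4
        assert all(r.auc is not None for r in reports)

    def test_strong_site_bias_degenerates_somewhere(self):
        cfg = SyntheticConfig(
            n_sites=4, n_hc_per_site=12, n_mdd_per_site=12, n_rois=12,
            effect_size=1.0, effect_fraction=0.05, site_offset_sd=4.0, seed=51,
        )
        c = generate_fc_cohort(cfg)
        reports = run_loso(c, rng=np.random.default_rng(0))
        degenerate = [
            min(r.sensitivity, r.specificity) <= 0.2 and max(r.sensitivity, r.specificity) >= 0.8
            for r in reports
        ]
        assert any(degenerate)

    def test_no_site_bias_matches_pooled_accuracy(self):
        cfg = SyntheticConfig(
            n_sites=4, n_hc_per_site=8, n_mdd_per_site=8, n_rois=12,
            effect_size=2.0, effect_fraction=0.1, site_offset_sd=0.0, seed=52,
        )
        c = generate_fc_cohort(cfg)
        pooled = run_loocv(c, rng=np.random.default_rng(0)).accuracy
        reports = run_loso(c, rng=np.random.default_rng(0))
        for r in reports:
            assert abs(r.accuracy - pooled) <= 0.1

    def test_single_site_rejected(self):
        cfg = SyntheticConfig(n_sites=1, n_hc_per_site=5, n_mdd_per_site=5, n_rois=8, seed=53)
        with pytest.raises(UsageError):
            run_loso(generate_fc_cohort(cfg))


class TestIndependentSite:
    def test_repeat_structure_and_balance(self):
        train, test = _shifted_site_cohorts(60, site_shift_sd=1.0)
        rep = run_independent_site(
            train, test, n_repeats=10, rng=np.random.default_rng(0)
        )
        assert len(rep.detail) == 10
        assert "accuracy" in rep.summary_sd
        n_mdd = int((test.phenotypes["diagnosis"] == "MDD").sum())
        assert all(d["n_test"] == 2 * n_mdd for d in rep.detail)
        assert rep.config["uncalibrated"]["accuracy"] is not None

    def test_calibration_beats_uncalibrated_under_shift(self):
        # one strongly shifted site, seeded so the shift crosses the boundary
        train, test = _shifted_site_cohorts(2, site_shift_sd=2.0)
        rep = run_independent_site(train, test, n_repeats=30, rng=np.random.default_rng(2))
        gain = rep.accuracy - rep.config["uncalibrated"]["accuracy"]
        assert gain >= 0.15

    def test_training_site_as_test_site_rejected(self, biased_cohort):
        X = np.asarray(biased_cohort.features)
        ph = biased_cohort.phenotypes
        m = (ph["site"] == "site01").to_numpy()
        with pytest.raises(UsageError):
            run_independent_site(
                (X[~m], ph[~m].reset_index(drop=True)),
                (X[m], ph[m].reset_index(drop=True).assign(site="site02")),
                n_repeats=2,
            )

    def test_planted_shared_subject_triggers_leakage_guard(self):
        train, test = _shifted_site_cohorts(61)
        ph = test.phenotypes.copy()
        ph.loc[ph.index[0], "id"] = train.phenotypes["id"].iloc[0]  # marked subject
        with pytest.raises(LeakageError):
            run_independent_site(
                train, (np.asarray(test.features), ph), n_repeats=2,
                rng=np.random.default_rng(0),
            )


class TestPermutationTest:
    def test_p_value_floor(self, easy_cohort):
        res = permutation_test(
            easy_cohort, protocol="kfold", n_permutations=5,
            rng=np.random.default_rng(0), k=5,
        )
        assert res.p_value >= 1 / 6
        assert len(res.null_accuracies) == 5

    def test_easy_cohort_attains_minimum_p(self, easy_cohort):
        res = permutation_test(
            easy_cohort, protocol="kfold", n_permutations=20,
            rng=np.random.default_rng(1), k=5,
        )
        assert res.p_value == pytest.approx(1 / 21)

    def test_unknown_protocol_rejected(self, easy_cohort):
        with pytest.raises(UsageError):
            permutation_test(easy_cohort, protocol="bootstrap", n_permutations=1)


class TestFilterSubgroup:
    def test_melancholic_partition(self):
        ph = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(30)],
                "diagnosis": ["HC"] * 10 + ["MDD"] * 20,
                "melancholic": [False] * 10 + [True] * 10 + [False] * 10,
            }
        )
        keep, transfer = filter_subgroup(ph, "melancholic")
        assert len(keep) == 20  # all HC + 10 melancholic
        assert len(transfer) == 10
        assert (ph.iloc[transfer]["diagnosis"] == "MDD").all()
        assert not ph.iloc[transfer]["melancholic"].any()

    def test_all_is_identity(self):
        ph = pd.DataFrame({"id": ["a", "b"], "diagnosis": ["HC", "MDD"],
                           "melancholic": [False, True]})
        keep, transfer = filter_subgroup(ph, "all")
        assert keep.tolist() == [0, 1] and len(transfer) == 0

    def test_empty_subgroup_rejected(self):
        ph = pd.DataFrame({"id": ["a", "b"], "diagnosis": ["HC", "MDD"],
                           "melancholic": [False, False]})
        with pytest.raises(DataError):
            filter_subgroup(ph, "melancholic")


class TestInteractionDiagnostics:
    @staticmethod
    def _cohort(seed, inject=False):
        cfg = SyntheticConfig(
            n_sites=3, n_hc_per_site=30, n_mdd_per_site=30, n_rois=12,
            effect_size=0.0, effect_fraction=0.0, site_offset_sd=0.5, seed=seed,
        )
        c = generate_fc_cohort(cfg)
        X = np.asarray(c.features).copy()
        if inject:
            rng = np.random.default_rng(seed)
            n_edges = X.shape[1]
            edges = rng.choice(n_edges, size=int(0.3 * n_edges), replace=False)
            age_c = c.phenotypes["age"].to_numpy() - c.phenotypes["age"].mean()
            site2 = (c.phenotypes["site"] == "site02").to_numpy()
            X[np.ix_(site2, edges)] += 0.1 * age_c[site2][:, None]
        return X, c.phenotypes

    def test_histogram_partitions_all_edges(self):
        X, ph = self._cohort(70)
        out = interaction_diagnostics(X, ph, n_bins=20)
        assert out["histogram"].sum() == X.shape[1]

    def test_null_interactions_look_uniform(self):
        X, ph = self._cohort(71)
        out = interaction_diagnostics(X, ph, n_bins=10)
        assert out["gof_p"] > 0.01

    def test_injected_interactions_detected(self):
        X, ph = self._cohort(72, inject=True)
        out = interaction_diagnostics(X, ph, n_bins=20)
        assert out["gof_p"] < 1e-3

    def test_single_site_rejected(self):
        X, ph = self._cohort(73)
        with pytest.raises(UsageError):
            interaction_diagnostics(X, ph[ph["site"] == "site01"], n_bins=10)
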