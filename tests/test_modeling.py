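"""Bootstrap prediction, null baselines, significance, transfer, audit."""

import numpy as np
import pytest

from connaudit import (
    GroupMask,
    PredictionResult,
    SplitSpec,
    SyntheticSpec,
    bootstrap_predict,
    compare_to_null,
    confound_audit,
    generate_cohort,
    transfer_evaluate,
    within_group_predict,
)
from connaudit.exceptions import DataError, IncompatibleMapsError, RequestError
from connaudit.modeling import _split_indices, _standardize


def make_result(metrics, nulls, kind="regression"):
    return PredictionResult(
        task_kind=kind,
        metric_name="rmse" if kind == "regression" else "accuracy",
        metrics=np.array(metrics, dtype=float),
        null_metrics=np.array(nulls, dtype=float),
    )


class TestBootstrapPredict:
    def test_noiseless_linear_target_nearly_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 50))
        w = rng.normal(size=50)
        y = X @ w
        res = bootstrap_predict(X, y, "ridge", SplitSpec(seed=1))
        assert res.mean < 0.05 * res.null_mean

    def test_permuted_target_indistinguishable_from_null(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 30))
        y = rng.permutation(X @ rng.normal(size=30))
        res = bootstrap_predict(X, y, "ridge", SplitSpec(seed=2), tune=True)
        assert abs(res.mean - res.null_mean) < 2 * max(res.null_sd, 1e-9)
        assert not res.verdict.significant

    def test_majority_null_accuracy_from_class_sizes(self):
        """Two groups of 407 and 326: majority baseline is 407/733 ~ 55%."""
        y = np.r_[np.zeros(407), np.ones(326)]
        rng = np.random.default_rng(3)
        X = rng.normal(size=(733, 5))  # uninformative features
        res = bootstrap_predict(X, y, "logistic", SplitSpec(seed=3))
        assert res.null_mean == pytest.approx(407 / 733, abs=0.01)

    def test_reproducible_bitwise(self, confound_cohort):
        X = confound_cohort.connectivity["rest"].values
        y = confound_cohort.phenotypes.data["race_code"].to_numpy()
        a = bootstrap_predict(X, y, "logistic", SplitSpec(seed=11))
        b = bootstrap_predict(X, y, "logistic", SplitSpec(seed=11))
        assert np.array_equal(a.metrics, b.metrics)
        assert a.to_json() == b.to_json()

    def test_null_rmse_is_test_sd_around_train_mean(self):
        """Recompute each repetition's null from the same seeded split stream."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 10))
        y = rng.normal(loc=5.0, scale=2.0, size=80)
        spec = SplitSpec(repetitions=5, seed=7)
        res = bootstrap_predict(X, y, "ridge", spec)
        stream = np.random.default_rng(spec.seed)
        for rep in range(5):
            tr, te = _split_indices(stream, y, spec.test_fraction, stratify=False)
            expected = np.sqrt(np.mean((y[te] - y[tr].mean()) ** 2))
            assert res.null_metrics[rep] == pytest.approx(expected, abs=1e-12)

    def test_stratified_splits_preserve_class_shares(self):
        y = np.r_[np.zeros(70), np.ones(30)]
        rng = np.random.default_rng(5)
        for _ in range(10):
            tr, te = _split_indices(rng, y, 0.2, stratify=True)
            assert abs((y[te] == 1).sum() - 0.2 * 30) <= 1
            assert abs((y[te] == 0).sum() - 0.2 * 70) <= 1
            assert len(tr) + len(te) == 100

    def test_top_k_larger_than_features_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(RequestError):
            bootstrap_predict(
                rng.normal(size=(50, 5)), rng.normal(size=50), "ridge",
                SplitSpec(seed=0), top_k=6,
            )

    def test_standardization_uses_training_statistics_only(self):
        train = np.array([[0.0, 10.0], [2.0, 30.0]])
        test = np.array([[1.0, 20.0]])
        tr, te = _standardize(train, test)
        np.testing.assert_allclose(tr.mean(axis=0), 0, atol=1e-15)
        np.testing.assert_allclose(te, [[0.0, 0.0]])  # midpoint of training


class TestCompareToNull:
    def test_identical_to_null_not_significant(self):
        res = make_result([1.0] * 20, [1.0] * 20)
        verdict = compare_to_null(res)
        assert not verdict.significant
        assert verdict.p_value == 1.0

    def test_uniform_wins_significant_at_exact_scale(self):
        """20 consistent wins: exact one-sided signed-rank p = 2^-20."""
        res = make_result(1.0 - np.linspace(0.1, 0.3, 20), np.ones(20))
        verdict = compare_to_null(res)
        assert verdict.significant
        assert verdict.p_value == pytest.approx(2.0 ** -20, rel=1e-6)

    def test_symmetric_alternation_not_significant(self):
        diffs = np.tile([0.1, -0.1], 10)
        res = make_result(1.0 - diffs, np.ones(20))
        assert not compare_to_null(res).significant

    def test_procedure_recorded(self):
        res = make_result([0.9, 0.8], [1.0, 1.0])
        assert "wilcoxon" in compare_to_null(res).procedure


class TestWithinGroup:
    def test_whole_cohort_group_equals_plain_bootstrap(self, confound_cohort):
        X = confound_cohort.connectivity["rest"].values
        y = confound_cohort.phenotypes.data["wrat"].to_numpy()
        spec = SplitSpec(repetitions=5, seed=9)
        whole = GroupMask(np.ones(len(y), dtype=bool), "all")
        grouped = within_group_predict(X, y, {"all": whole}, "ridge", spec)
        plain = bootstrap_predict(X, y, "ridge", spec)
        np.testing.assert_array_equal(grouped["all"].metrics, plain.metrics)

    def test_undersized_group_skipped(self, confound_cohort):
        X = confound_cohort.connectivity["rest"].values
        y = confound_cohort.phenotypes.data["wrat"].to_numpy()
        tiny = GroupMask(np.arange(len(y)) < 5, "tiny")
        out = within_group_predict(X, y, {"tiny": tiny}, "ridge", SplitSpec(seed=0))
        assert out["tiny"] is None


class TestTransfer:
    @staticmethod
    def cohort_pair():
        edges = tuple(range(40))
        train = generate_cohort(SyntheticSpec(
            n=400, scenario="confound", race_edges=edges,
            edge_effect=0.15, sigma_z=0.3, seed=10))
        test = generate_cohort(SyntheticSpec(
            n=400, scenario="confound", race_edges=edges,
            edge_effect=0.15, sigma_z=0.45, seed=11))
        return train, test

    def test_self_transfer_matches_within_cohort_accuracy(self):
        train, _ = self.cohort_pair()
        X = train.connectivity["rest"].values
        y = train.phenotypes.data["race_code"].to_numpy()
        res = transfer_evaluate(X, y, X.copy(), y.copy(), SplitSpec(seed=1))
        within = bootstrap_predict(X, y, "logistic", SplitSpec(seed=1))
        assert res["all"].mean == pytest.approx(within.mean, abs=0.1)

    def test_label_swap_symmetry(self):
        train, test = self.cohort_pair()
        Xtr = train.connectivity["rest"].values
        ytr = train.phenotypes.data["race_code"].to_numpy()
        Xte = test.connectivity["rest"].values
        yte = test.phenotypes.data["race_code"].to_numpy()
        res = transfer_evaluate(Xtr, ytr, Xte, yte, SplitSpec(seed=2))
        flipped = transfer_evaluate(Xtr, ytr, Xte, 1 - yte, SplitSpec(seed=2))
        assert flipped["all"].mean == pytest.approx(1 - res["all"].mean, abs=1e-12)

    def test_subgroup_results_reported(self):
        train, test = self.cohort_pair()
        sub = GroupMask(
            (test.phenotypes.data["race"] == "A").to_numpy(), 'race == "A"'
        )
        res = transfer_evaluate(
            train.connectivity["rest"].values,
            train.phenotypes.data["race_code"].to_numpy(),
            test.connectivity["rest"].values,
            test.phenotypes.data["race_code"].to_numpy(),
            SplitSpec(seed=3),
            subgroups={"A": sub},
        )
        assert set(res) == {"all", "A"}
        assert res["A"].model_desc["n_test"] == sub.n_selected

    def test_parcellation_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(IncompatibleMapsError):
            transfer_evaluate(
                rng.normal(size=(50, 10)), (rng.random(50) < 0.5).astype(float),
                rng.normal(size=(50, 15)), (rng.random(50) < 0.5).astype(float),
            )


class TestConfoundAudit:
    def test_target_independent_of_everything_is_inconclusive(self, null_cohort):
        report = confound_audit(
            null_cohort, "wrat", "race", "rest", SplitSpec(repetitions=10, seed=0)
        )
        assert report.verdict == "inconclusive"

    def test_report_serializes_and_verdict_rederivable(self, confound_cohort):
        report = confound_audit(
            confound_cohort, "wrat", "race", "rest", SplitSpec(repetitions=10, seed=0)
        )
        payload = report.to_json()
        assert '"verdict"' in payload
        assert report.verdict == report.derive_verdict()
        assert set(report.per_group) == {"A", "B"}
        assert report.group_summary["n"].sum() == confound_cohort.n_subjects

    def test_mismatched_repetition_counts_rejected(self):
        with pytest.raises(DataError):
            make_result([1.0, 2.0], [1.0])
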