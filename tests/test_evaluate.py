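"""Metrics, toy reference models, and the degrade-and-compare harness."""

import math

import numpy as np
import pytest

from hapshuffle import (
    ModelAdapter,
    PermutationLevel,
    StatisticUndefinedError,
    confusion,
    make_afs_model,
    make_count_model,
    make_h1_model,
    rmse,
    roc_auc,
    run_suite,
    spearman_rho,
)

L = PermutationLevel


# --- independent AUC oracle: trapezoidal ROC integration ----------------


def auc_trapezoid(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    tpr = [(scores[labels] >= t).mean() for t in thresholds]
    fpr = [(scores[~labels] >= t).mean() for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


class TestMetrics:
    def test_auc_worked_examples(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
        assert roc_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75
        with pytest.raises(StatisticUndefinedError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_auc_equals_trapezoidal_roc_integration(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # force some ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_trapezoid(scores, labels), abs=1e-12
            )

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(18)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(
            float(sk.roc_auc_score(labels, scores)), abs=1e-12
        )

    def test_confusion_examples(self):
        perfect = confusion(["a", "b"], ["a", "b"], ["a", "b"])
        assert np.array_equal(perfect, [[1, 0], [0, 1]])
        all_first = confusion(["a", "a", "a"], ["a", "b", "b"], ["a", "b"])
        assert np.array_equal(all_first, [[1, 0], [2, 0]])
        cm = confusion(["a", "b", "b"], ["a", "a", "b"], ["a", "b"])
        assert np.array_equal(cm, [[1, 1], [0, 1]])
        with pytest.raises(ValueError):
            confusion(["c"], ["a"], ["a", "b"])

    def test_spearman_examples(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
        with pytest.raises(StatisticUndefinedError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_rmse_examples(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt(12.5))
        assert rmse([5.0], [2.0]) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            rmse([1, 2], [1])


class TestToyModels:
    def test_count_model_score_invariant_to_every_level(self, sweep_dataset):
        model = make_count_model(sweep_dataset)
        from hapshuffle import apply_level

        m = sweep_dataset.matrices[0]
        base = model.predict_scores([m])[0]
        for level in L:
            assert model.predict_scores([apply_level(m, level, 5)])[0] == base

    def test_h1_model_tracks_garud_h1(self, sweep_dataset):
        from hapshuffle import garud_h

        model = make_h1_model(sweep_dataset)
        m = sweep_dataset.matrices[0]
        assert model.predict_scores([m])[0] == garud_h(m)[0]

    def test_h1_score_rises_toward_one_under_grouping(self, sweep_dataset):
        from hapshuffle import group_alleles

        model = make_h1_model(sweep_dataset)
        neutral = sweep_dataset.matrices[0]  # K >= n_hap on this fixture
        assert neutral.region.sum() >= neutral.n_hap
        grouped = group_alleles(neutral, "keep_padding")
        assert model.predict_scores([grouped])[0] > model.predict_scores([neutral])[0]

    def test_afs_model_invariant_to_within_column_shuffles(self, regression_dataset):
        from hapshuffle import permute_within_columns

        model = make_afs_model(regression_dataset)
        m = regression_dataset.matrices[0]
        a = model.predict_scores([m])[0]
        b = model.predict_scores([permute_within_columns(m, 9)])[0]
        assert np.array_equal(a, b)

    def test_task_mismatch_rejected(self, sweep_dataset, regression_dataset):
        with pytest.raises(ValueError):
            make_afs_model(sweep_dataset)
        with pytest.raises(ValueError):
            make_count_model(regression_dataset)
        model = make_count_model(sweep_dataset)
        with pytest.raises(ValueError):
            run_suite(model, regression_dataset)


@pytest.fixture(scope="module")
def count_profile(sweep_dataset):
    model = make_count_model(sweep_dataset)
    return run_suite(model, sweep_dataset, seeds=(0, 1))


class TestRunSuite:
    def test_profile_covers_every_level_and_seed(self, count_profile):
        t = count_profile.table
        assert set(t["level"]) == {l.value for l in L}
        assert set(t["seed"]) == {0, 1}

    def test_count_model_metrics_identical_across_all_levels(self, count_profile):
        t = count_profile.table
        for metric in ("auc", "accuracy", "mean_predicted_class"):
            vals = t[t.metric == metric]["value"]
            assert vals.nunique() == 1

    def test_deterministic_given_seeds(self, sweep_dataset):
        model = make_count_model(sweep_dataset)
        a = run_suite(model, sweep_dataset, levels=[L.COLS], seeds=(3,))
        b = run_suite(model, sweep_dataset, levels=[L.COLS], seeds=(3,))
        assert a.table.equals(b.table)

    def test_column_sum_models_identical_through_cols_within(self, regression_dataset):
        model = make_afs_model(regression_dataset)
        profile = run_suite(
            model, regression_dataset, levels=[L.COLS, L.COLS_WITHIN], seeds=(0,)
        )
        for metric in ("spearman_rho", "rmse"):
            for name in ("N0", "N1", "N2"):
                orig = profile.value(L.ORIGINAL, metric, name)
                assert profile.value(L.COLS, metric, name) == orig
                assert profile.value(L.COLS_WITHIN, metric, name) == orig

    def test_undefined_metrics_recorded_as_nan_not_zero(self, regression_dataset):
        model = make_afs_model(regression_dataset)
        profile = run_suite(model, regression_dataset, levels=[], seeds=(0,))
        t1_rho = profile.value(L.ORIGINAL, "spearman_rho", "T1")
        assert math.isnan(t1_rho)  # constant estimate -> undefined, not 0

    def test_prediction_count_mismatch_is_an_error(self, sweep_dataset):
        bad = ModelAdapter(
            name="bad", task="classification",
            score_fn=lambda ms: np.zeros(len(ms) + 1),
            class_names=list(sweep_dataset.label_names),
            thresholds=np.array([0.5, 1.5]),
        )
        with pytest.raises(ValueError, match="wrong number"):
            run_suite(bad, sweep_dataset, levels=[L.ORIGINAL], seeds=(0,))


class TestExternalModel:
    def test_subprocess_contract_round_trip(self, sweep_dataset):
        from hapshuffle.external import subprocess_model

        # external "model": negated count of 1 characters per matrix block
        script = (
            "import sys\n"
            "total = None\n"
            "for line in sys.stdin:\n"
            "    if line.startswith('#hapmatrix'):\n"
            "        if total is not None: print(-total)\n"
            "        total = 0\n"
            "    elif not line.startswith('#'):\n"
            "        total += line.count('1')\n"
            "if total is not None: print(-total)\n"
        )
        import shlex, sys

        cmd = f"{shlex.quote(sys.executable)} -c {shlex.quote(script)}"
        external = subprocess_model(cmd, sweep_dataset)
        builtin = make_count_model(sweep_dataset)
        a = external.predict_scores(sweep_dataset.matrices[:5])
        b = builtin.predict_scores(sweep_dataset.matrices[:5])
        assert np.array_equal(a, b)
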