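import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_curve

from keyslice.curation import OrganLabels
from keyslice.errors import CalibrationError, ConfigError, InputError, ShapeError
from keyslice.organ_calibration import (
    OrganThresholds,
    build_organ_prompts,
    calibrate_threshold,
    classify_organ_presence,
    evaluate_organ_awareness,
)
from keyslice.pipeline import calibrate_from_scores, evaluate_organs, organ_scores
from keyslice.synthetic import make_fixture_cohort
from keyslice.pipeline import oracle_from_cohort


def brute_force_youden(pos, neg):
    """Independent scan: enter every gap between consecutive pooled scores."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    pooled = np.unique(np.concatenate([pos, neg]))
    best_j = -np.inf
    for t in pooled[:-1] + 1e-9:
        j = np.mean(pos >= t) - np.mean(neg >= t)
        best_j = max(best_j, j)
    return best_j


class TestCalibrateThreshold:
    def test_perfectly_separable(self):
        t, j = calibrate_threshold([0.8, 0.9], [0.1, 0.2])
        assert t == pytest.approx(0.5)
        assert j == pytest.approx(1.0)

    def test_worked_overlapping_case(self):
        # candidates 0.4 / 0.55 / 0.65 / 0.75 give J = 1/3, 2/3, 1/6, 1/2
        t, j = calibrate_threshold([0.8, 0.6], [0.5, 0.3, 0.7])
        assert t == pytest.approx(0.55)
        assert j == pytest.approx(2 / 3)

    def test_identical_scores_are_noninformative(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([0.5], [0.5])

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            calibrate_threshold([], [0.1])

    @given(seed=st.integers(0, 300))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.6, 0.3, rng.integers(1, 50))
        neg = rng.normal(0.3, 0.3, rng.integers(1, 50))
        t, j = calibrate_threshold(pos, neg)
        assert j == pytest.approx(brute_force_youden(pos, neg), abs=1e-9)
        # optimality: J at the returned threshold >= J at every midpoint candidate
        pooled = np.unique(np.concatenate([pos, neg]))
        for c in (pooled[:-1] + pooled[1:]) / 2:
            jc = np.mean(pos >= c) - np.mean(neg >= c)
            assert j >= jc - 1e-12

    @given(seed=st.integers(0, 100))
    def test_max_youden_agrees_with_sklearn_roc(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.6, 0.25, 30)
        neg = rng.normal(0.3, 0.25, 40)
        _, j = calibrate_threshold(pos, neg)
        y = np.r_[np.ones(30), np.zeros(40)]
        fpr, tpr, _ = roc_curve(y, np.r_[pos, neg])
        assert j == pytest.approx(float(np.max(tpr - fpr)), abs=1e-9)


class TestClassify:
    def test_elementwise_rule(self):
        out = classify_organ_presence(np.array([0.2, 0.6, 0.9]), 0.5)
        np.testing.assert_array_equal(out, [False, True, True])

    def test_threshold_below_min_all_positive(self):
        out = classify_organ_presence(np.array([0.2, 0.6]), -1.0)
        assert out.all()

    @given(seed=st.integers(0, 100), t=st.floats(-1, 1))
    def test_matches_comparison_oracle(self, seed, t):
        scores = np.random.default_rng(seed).uniform(-1, 1, 20)
        np.testing.assert_array_equal(
            classify_organ_presence(scores, t), [s >= t for s in scores]
        )

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(InputError):
            classify_organ_presence(np.array([0.1]), np.nan)


class TestPrompts:
    def test_word_mode_capitalizes(self):
        assert build_organ_prompts(["heart"], mode="word") == ["Heart"]

    def test_sentence_mode_template(self):
        assert build_organ_prompts(["heart"], mode="sentence") == [
            "This CT image includes the heart"
        ]

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigError):
            build_organ_prompts([], mode="word")


class TestEvaluateOrganAwareness:
    def truth(self, presence, organs=("a", "b")):
        return OrganLabels("s", list(organs), np.asarray(presence, dtype=bool))

    def test_perfect_predictions(self):
        t = self.truth([[1, 0], [0, 1]])
        m = evaluate_organ_awareness(
            {"a": np.array([True, False]), "b": np.array([False, True])}, t
        )
        assert m.macro_accuracy == 1.0 and m.macro_f1 == 1.0

    def test_confusion_matrix_arithmetic(self):
        t = self.truth([[1], [1], [0], [0]], organs=("a",))
        m = evaluate_organ_awareness({"a": np.array([True, False, False, True])}, t)
        assert m.per_organ["a"]["accuracy"] == pytest.approx(0.5)
        assert m.per_organ["a"]["precision"] == pytest.approx(0.5)
        assert m.per_organ["a"]["recall"] == pytest.approx(0.5)
        assert m.per_organ["a"]["f1"] == pytest.approx(0.5)

    def test_vacuous_organ_f1_is_one(self):
        t = self.truth([[0], [0]], organs=("a",))
        m = evaluate_organ_awareness({"a": np.array([False, False])}, t)
        assert m.per_organ["a"]["f1"] == 1.0

    def test_dim_mismatch(self):
        with pytest.raises(ShapeError):
            evaluate_organ_awareness(
                {"a": np.array([True])}, self.truth([[0], [0]], organs=("a",))
            )


class TestPhantomCalibration:
    def test_oracle_f1_perfect_at_calibrated_thresholds(
        self, oracle, cohort, oracle_embeddings
    ):
        """Noiseless phantoms: validation-calibrated cutoffs generalize exactly."""
        scores = organ_scores(oracle, cohort, split="val", embeddings=oracle_embeddings)
        thresholds = calibrate_from_scores(scores)
        metrics = evaluate_organs(
            oracle, cohort, thresholds, split="test", embeddings=oracle_embeddings
        )
        assert metrics.macro_f1 == 1.0
        assert all(m["f1"] == 1.0 for m in metrics.per_organ.values())

    def test_thresholds_json_round_trip(self, tmp_path, oracle, cohort, oracle_embeddings):
        scores = organ_scores(oracle, cohort, split="val", embeddings=oracle_embeddings)
        thresholds = calibrate_from_scores(scores)
        path = thresholds.to_json(tmp_path / "thr.json")
        back = OrganThresholds.from_json(path)
        assert back.per_organ == thresholds.per_organ
        assert back.prompt_mode == thresholds.prompt_mode

    def test_noise_degrades_macro_f1_monotonically(self):
        """More HU noise never helps organ classification (in expectation)."""
        f1_by_noise = []
        for noise_sd in (0.0, 100.0, 250.0):
            f1s = []
            for seed in (21, 22, 23):
                c = make_fixture_cohort(6, seed=seed, noise_sd=noise_sd)
                model = oracle_from_cohort(c)
                try:
                    scores = organ_scores(model, c, split="val")
                    thr = calibrate_from_scores(scores)
                    f1s.append(evaluate_organs(model, c, thr, split="test").macro_f1)
                except CalibrationError:
                    f1s.append(0.0)  # fully non-informative scores
            f1_by_noise.append(np.mean(f1s))
        assert f1_by_noise[0] >= f1_by_noise[1] - 1e-9
        assert f1_by_noise[1] >= f1_by_noise[2] - 1e-9
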