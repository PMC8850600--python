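"""Confusion-matrix metrics: worked examples, NA semantics, Kappa banding,
and equivalence with brute-force counting over raw label pairs."""

import numpy as np
import pytest

import grazemetrics as gm
from grazemetrics.behaviors import BEHAVIORS
from grazemetrics.metrics import (
    ConfusionMatrix,
    class_metrics,
    confusion_matrix,
    kappa_band,
    overall_metrics,
)


def brute_force_class_counts(observed, predicted, cls):
    """TP/FN/FP/TN by explicit iteration over the raw pairs."""
    tp = sum(1 for o, p in zip(observed, predicted) if o == cls and p == cls)
    fn = sum(1 for o, p in zip(observed, predicted) if o == cls and p != cls)
    fp = sum(1 for o, p in zip(observed, predicted) if o != cls and p == cls)
    tn = sum(1 for o, p in zip(observed, predicted) if o != cls and p != cls)
    return tp, fn, fp, tn


def brute_force_kappa(observed, predicted):
    n = len(observed)
    p_o = sum(1 for o, p in zip(observed, predicted) if o == p) / n
    p_e = sum(
        (observed.count(c) / n) * (predicted.count(c) / n) for c in BEHAVIORS
    )
    return None if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)


class TestConfusionMatrix:
    def test_perfect_single_class_is_diagonal(self):
        cm = confusion_matrix(["grazing"] * 10, ["grazing"] * 10)
        assert cm.counts[0, 0] == 10 and cm.total == 10

    def test_hand_tally(self):
        cm = confusion_matrix(
            ["grazing", "grazing", "ruminating", "ruminating"],
            ["grazing", "ruminating", "ruminating", "ruminating"],
        )
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[1, 1] == 2

    def test_empty_sequences_make_a_zero_matrix(self):
        assert confusion_matrix([], []).total == 0

    def test_length_mismatch_and_unknown_labels_raise(self):
        with pytest.raises(ValueError):
            confusion_matrix(["grazing"], [])
        with pytest.raises(ValueError):
            confusion_matrix(["grazing"], ["walking"])

    def test_one_vs_rest_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        obs = rng.choice(BEHAVIORS, 200)
        pred = rng.choice(BEHAVIORS, 200)
        cm = confusion_matrix(obs, pred)
        for cls in BEHAVIORS:
            assert sum(cm.one_vs_rest(cls)) == cm.total


class TestClassMetrics:
    def test_sensitivity_specificity_precision_arithmetic(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 8   # TP grazing
        counts[0, 2] = 2   # FN grazing (called lying-standing)
        counts[2, 2] = 90  # rest
        counts[2, 0] = 10  # FP grazing
        m = class_metrics(ConfusionMatrix(counts), "grazing")
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.precision == pytest.approx(8 / 18)

    def test_never_predicted_class_has_na_precision(self):
        cm = confusion_matrix(["drinking", "grazing"], ["grazing", "grazing"])
        m = class_metrics(cm, "drinking")
        assert m.precision is None  # NA, not zero and not an exception
        assert m.sensitivity == 0.0

    def test_unknown_class_raises(self):
        cm = confusion_matrix([], [])
        with pytest.raises(ValueError):
            class_metrics(cm, "walking")


class TestOverallMetrics:
    def test_perfect_prediction(self):
        cm = confusion_matrix(list(BEHAVIORS), list(BEHAVIORS))
        summary = overall_metrics(cm)
        assert summary.accuracy == 1.0 and summary.kappa == 1.0

    def test_two_class_hand_computation(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0], counts[0, 1] = 50, 20
        counts[1, 0], counts[1, 1] = 10, 20
        summary = overall_metrics(ConfusionMatrix(counts))
        assert summary.accuracy == pytest.approx(0.70)
        assert summary.kappa == pytest.approx((0.70 - 0.54) / (1 - 0.54), abs=1e-9)
        assert summary.kappa == pytest.approx(0.3478, abs=1e-4)

    def test_chance_level_predictions_give_near_zero_kappa(self):
        rng = np.random.default_rng(1)
        obs = rng.choice(BEHAVIORS, 20000)
        pred = rng.choice(BEHAVIORS, 20000)
        summary = overall_metrics(confusion_matrix(obs, pred))
        assert summary.kappa == pytest.approx(0.0, abs=0.05)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            overall_metrics(confusion_matrix([], []))

    def test_accuracy_is_not_mean_one_vs_rest_accuracy_in_multiclass(self):
        """Negative control: the multi-class accuracy equals the mean of the
        per-class one-vs-rest accuracies only in the 2-class case."""
        rng = np.random.default_rng(2)
        obs = rng.choice(BEHAVIORS, 500)
        pred = rng.choice(BEHAVIORS, 500)
        cm = confusion_matrix(obs, pred)
        summary = overall_metrics(cm)
        ovr = np.mean(
            [
                (tp + tn) / cm.total
                for tp, _, _, tn in (cm.one_vs_rest(c) for c in BEHAVIORS)
            ]
        )
        assert abs(summary.accuracy - ovr) > 0.01
        # 2-class case: equality holds exactly
        two = confusion_matrix(
            ["grazing", "grazing", "eating", "eating"],
            ["grazing", "eating", "eating", "eating"],
            classes=("grazing", "eating"),
        )
        s2 = overall_metrics(two)
        ovr2 = np.mean(
            [
                (tp + tn) / two.total
                for tp, _, _, tn in (two.one_vs_rest(c) for c in ("grazing", "eating"))
            ]
        )
        assert s2.accuracy == pytest.approx(ovr2)

    def test_kappa_below_accuracy_when_above_chance(self):
        counts = np.diag([50, 30, 60, 10, 20, 10]).astype(int)
        counts[0, 2] = 15
        summary = overall_metrics(ConfusionMatrix(counts))
        assert summary.kappa < summary.accuracy

    def test_agrees_with_brute_force_and_library_kappa(self):
        """Oracle equivalence on random label-pair sequences, including NA
        cases where a class is never predicted."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for trial in range(200):
            n = int(rng.integers(5, 60))
            obs = list(rng.choice(BEHAVIORS, n))
            pred = list(rng.choice(BEHAVIORS[: int(rng.integers(2, 7))], n))
            cm = confusion_matrix(obs, pred)
            for cls in BEHAVIORS:
                tp, fn, fp, tn = brute_force_class_counts(obs, pred, cls)
                m = class_metrics(cm, cls)
                assert m.sensitivity == (None if tp + fn == 0 else pytest.approx(tp / (tp + fn)))
                assert m.specificity == (None if tn + fp == 0 else pytest.approx(tn / (tn + fp)))
                assert m.precision == (None if tp + fp == 0 else pytest.approx(tp / (tp + fp)))
            summary = overall_metrics(cm)
            expected_kappa = brute_force_kappa(obs, pred)
            if expected_kappa is None:
                assert summary.kappa is None
            else:
                assert summary.kappa == pytest.approx(expected_kappa, abs=1e-12)
                labels = list(BEHAVIORS)
                assert summary.kappa == pytest.approx(
                    cohen_kappa_score(obs, pred, labels=labels), abs=1e-9
                )


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.704, "substantial"),
            (-0.1, "poor"),
            (1.0, "almost_perfect"),
            (0.0, "slight"),
            (0.2, "slight"),
            (0.4, "fair"),
            (0.6, "moderate"),
            (0.8, "substantial"),
            (0.81, "almost_perfect"),
        ],
    )
    def test_landis_koch_cut_points(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.2)

    def test_na_serializes_as_string_in_reports(self):
        cm = confusion_matrix(["drinking", "grazing"], ["grazing", "grazing"])
        report = overall_metrics(cm).to_dict()
        assert report["per_class"]["drinking"]["precision"] == "NA"
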