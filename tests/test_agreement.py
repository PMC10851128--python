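"""Confusion metrics and Bland-Altman statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sordkit import (
    ConfusionMatrix,
    EpochSeries,
    bland_altman,
    class_metrics,
    confusion,
    get_taxonomy,
    percent_time,
    validate_session_set,
)

TAX3 = get_taxonomy("model3")


def series(labels):
    return EpochSeries(np.asarray(labels, dtype=object))


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        rng = np.random.default_rng(1)
        labs = rng.choice(TAX3.classes, size=100)
        cm = confusion(series(labs), series(labs), TAX3)
        assert cm.total == 100
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_single_off_diagonal_cell(self):
        cm = confusion(series(["standing"] * 20), series(["sitting"] * 20), TAX3)
        # rows = predicted, columns = actual
        i, j = TAX3.class_index("standing"), TAX3.class_index("sitting")
        assert cm.counts[i, j] == 20
        assert cm.total == 20

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        pred = rng.choice(TAX3.classes, size=500)
        truth = rng.choice(TAX3.classes, size=500)
        cm = confusion(series(pred), series(truth), TAX3)
        for i, ci in enumerate(TAX3.classes):
            for j, cj in enumerate(TAX3.classes):
                naive = sum(1 for p, t in zip(pred, truth) if p == ci and t == cj)
                assert cm.counts[i, j] == naive

    def test_unknown_epochs_excluded_pairwise(self):
        pred = series(["sitting", "unknown", "walking"])
        truth = series(["sitting", "sitting", "unknown"])
        cm = confusion(pred, truth, TAX3)
        assert cm.total == 1

    def test_base_activities_mapped_through_taxonomy(self):
        tax1 = get_taxonomy("model1")
        pred = series(["sedentary", "sedentary"])
        truth = series(["lying", "reclining"])  # both map to sedentary
        cm = confusion(pred, truth, tax1)
        k = tax1.class_index("sedentary")
        assert cm.counts[k, k] == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            confusion(series(["sitting"]), series(["sitting", "sitting"]), TAX3)


def brute_force_metrics(counts, k):
    """One-vs-rest tally by explicit enumeration of every (pred, actual) pair."""
    tp = fn = fp = tn = 0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            n = counts[i, j]
            if i == k and j == k:
                tp += n
            elif j == k:
                fn += n
            elif i == k:
                fp += n
            else:
                tn += n
    total = counts.sum()
    return (
        (tp + tn) / total,
        tp / (tp + fn) if tp + fn else np.nan,
        tn / (tn + fp) if tn + fp else np.nan,
    )


class TestClassMetrics:
    def test_perfect_diagonal_gives_all_ones(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), TAX3.classes)
        for m in class_metrics(cm).values():
            assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_hand_arithmetic_2x2(self):
        # rows = predicted: TP=8, FP=1 / FN=2, TN=9
        cm = ConfusionMatrix(np.array([[8, 1], [2, 9]]), ("pos", "neg"))
        m = class_metrics(cm)["pos"]
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_two_class_duality(self):
        cm = ConfusionMatrix(np.array([[8, 1], [2, 9]]), ("pos", "neg"))
        m = class_metrics(cm)
        assert m["pos"]["sensitivity"] == pytest.approx(m["neg"]["specificity"])
        assert m["neg"]["sensitivity"] == pytest.approx(m["pos"]["specificity"])

    def test_absent_class_flagged_nan(self):
        # "pos" never occurs in truth (its column is empty) → TP+FN = 0
        cm = ConfusionMatrix(np.array([[0, 3], [0, 9]]), ("pos", "neg"))
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = class_metrics(cm)
        assert np.isnan(m["pos"]["sensitivity"])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ).filter(lambda rows: sum(map(sum, rows)) > 0)
    )
    def test_agrees_with_brute_force_on_random_matrices(self, rows):
        counts = np.array(rows)
        cm = ConfusionMatrix(counts, TAX3.classes)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = class_metrics(cm)
        for k, cls in enumerate(TAX3.classes):
            acc, sens, spec = brute_force_metrics(counts, k)
            assert m[cls]["accuracy"] == pytest.approx(acc)
            np.testing.assert_equal(np.isnan(m[cls]["sensitivity"]), np.isnan(sens))
            if not np.isnan(sens):
                assert m[cls]["sensitivity"] == pytest.approx(sens)
            if not np.isnan(spec):
                assert m[cls]["specificity"] == pytest.approx(spec)


class TestPercentTime:
    def test_half_sitting(self):
        labs = ["sitting"] * 300 + ["standing"] * 300
        assert percent_time(series(labs), "sitting") == 50.0

    def test_absent_class_is_zero(self):
        assert percent_time(series(["sitting"] * 10), "walking") == 0.0

    def test_sums_to_100(self):
        rng = np.random.default_rng(3)
        s = series(rng.choice(TAX3.classes, size=777))
        total = sum(percent_time(s, c) for c in TAX3.classes)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_time(series(["unknown"] * 5), "sitting")


class TestBlandAltman:
    def test_identical_vectors(self):
        x = [10.0, 20.0, 30.0]
        ba = bland_altman(x, x)
        assert ba.mean_bias == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)
        assert ba.acceptable

    def test_constant_offset_zero_variance(self):
        ba = bland_altman([10.0, 20.0, 30.0], [12.0, 22.0, 32.0])
        assert ba.mean_bias == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(2.0)
        assert ba.loa_high == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # differences {−1, 0, 1, 2}: mean 0.5, sample SD sqrt(5/3) = 1.29099
        ba = bland_altman([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0])
        assert ba.mean_bias == pytest.approx(0.5)
        sd = np.sqrt(5.0 / 3.0)
        assert ba.loa_low == pytest.approx(0.5 - 1.96 * sd, abs=1e-3)
        assert ba.loa_high == pytest.approx(0.5 + 1.96 * sd, abs=1e-3)
        assert ba.loa_low == pytest.approx(-2.030, abs=1e-3)
        assert ba.loa_high == pytest.approx(3.030, abs=1e-3)

    def test_positive_bias_means_index_underestimates(self):
        ba = bland_altman(index=[40.0, 42.0], reference=[50.0, 52.0])
        assert ba.mean_bias == pytest.approx(10.0)

    def test_swapping_roles_negates_bias_and_mirrors_loa(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(50, 5, 10), rng.normal(52, 5, 10)
        ab, ba = bland_altman(x, y), bland_altman(y, x)
        assert ab.mean_bias == pytest.approx(-ba.mean_bias)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_high == pytest.approx(-ba.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman([1.0], [2.0])

    def test_acceptability_band(self):
        wide = bland_altman([0.0, 0.0, 0.0], [0.0, 15.0, -15.0])
        assert not wide.acceptable


class TestValidateSessionSet:
    def test_perfect_predictions_give_zero_bias_and_diagonal_confusion(self):
        rng = np.random.default_rng(6)
        pred, truth = {}, {}
        for pid in ("P0", "P1", "P2"):
            labs = rng.choice(TAX3.classes, size=240)
            pred[pid] = series(labs)
            truth[pid] = series(labs.copy())
        report = validate_session_set(pred, truth, TAX3)
        off_diag = report.confusion.counts - np.diag(np.diag(report.confusion.counts))
        assert off_diag.sum() == 0
        for ba in report.agreement.values():
            assert ba.mean_bias == 0.0
            assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_pooled_confusion_is_sum_of_per_participant(self):
        rng = np.random.default_rng(7)
        pred, truth = {}, {}
        per = []
        for pid in ("P0", "P1"):
            p = rng.choice(TAX3.classes, size=100)
            t = rng.choice(TAX3.classes, size=100)
            pred[pid], truth[pid] = series(p), series(t)
            per.append(confusion(series(p), series(t), TAX3))
        report = validate_session_set(pred, truth, TAX3)
        np.testing.assert_array_equal(
            report.confusion.counts, per[0].counts + per[1].counts
        )

    def test_statistics_match_independent_formula_application(self):
        """Cross-check the full report against direct per-formula computation."""
        rng = np.random.default_rng(11)
        pred, truth = {}, {}
        for pid in [f"P{i:02d}" for i in range(15)]:
            t = rng.choice(TAX3.classes, size=600)
            p = t.copy()
            flip = rng.uniform(size=600) < 0.05
            p[flip] = rng.choice(TAX3.classes, size=int(flip.sum()))
            pred[pid], truth[pid] = series(p), series(t)
        report = validate_session_set(pred, truth, TAX3)
        for cls in TAX3.classes:
            diffs = []
            for pid in pred:
                pp = 100.0 * np.mean(pred[pid].labels == cls)
                tt = 100.0 * np.mean(truth[pid].labels == cls)
                diffs.append(tt - pp)
            diffs = np.array(diffs)
            ba = report.agreement[cls]
            assert ba.mean_bias == pytest.approx(diffs.mean(), abs=1e-9)
            assert ba.loa_high == pytest.approx(
                diffs.mean() + 1.96 * diffs.std(ddof=1), abs=1e-9
            )

    def test_single_participant_skips_bland_altman(self):
        labs = series(["sitting"] * 60)
        with pytest.warns(UserWarning, match="single participant"):
            report = validate_session_set({"P0": labs}, {"P0": labs}, TAX3)
        assert report.agreement is None
        assert report.metrics["sitting"]["accuracy"] == 1.0
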