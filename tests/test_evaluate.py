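"""Metric formulas against independent tallies and hand-worked examples."""

import numpy as np
import pytest

from insightsleep.evaluate import (
    accuracy,
    cohens_kappa,
    confusion_matrix,
    correlate_parameters,
    metric_report,
    per_class_f1,
    rejection_breakdown,
    sleep_parameters,
    weighted_f1,
    SleepParameters,
)
from insightsleep.labels import FourClassLabels


def _tally_metrics(pred, truth):
    """Independent per-epoch tally (no confusion matrix)."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    acc = float((pred == truth).mean())
    pe = sum(
        (truth == k).mean() * (pred == k).mean() for k in range(4)
    )
    kappa = (acc - pe) / (1 - pe)
    f1s, supports = [], []
    for k in range(4):
        tp = ((pred == k) & (truth == k)).sum()
        fp = ((pred == k) & (truth != k)).sum()
        fn = ((pred != k) & (truth == k)).sum()
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
        supports.append((truth == k).sum())
    wf1 = float(np.average(f1s, weights=supports))
    return acc, kappa, wf1


class TestConfusion:
    def test_perfect_diagonal(self):
        truth = np.repeat(np.arange(4), 2)
        cm = confusion_matrix(truth, truth)
        np.testing.assert_array_equal(cm, np.diag([2, 2, 2, 2]))

    def test_all_rejected_gives_zero_matrix(self):
        truth = np.repeat(np.arange(4), 2)
        cm = confusion_matrix(truth, truth, accepted=np.zeros(8, bool))
        assert cm.sum() == 0

    def test_hand_built_off_diagonal(self):
        truth = np.array([0, 0, 1, 1, 2, 3])
        pred = np.array([0, 1, 1, 1, 2, 3])
        cm = confusion_matrix(pred, truth)
        assert cm[0, 1] == 1 and np.trace(cm) == 5

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.zeros(3, int), np.zeros(4, int))


class TestMetrics:
    def test_perfect_prediction(self):
        cm = np.diag([5, 3, 2, 4])
        assert accuracy(cm) == 1.0
        assert cohens_kappa(cm) == 1.0
        assert weighted_f1(cm) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_kappa_20_over_26(self):
        truth = np.array([0, 0, 1, 1, 2, 3])
        pred = np.array([0, 1, 1, 1, 2, 3])
        cm = confusion_matrix(pred, truth)
        assert accuracy(cm) == pytest.approx(5 / 6)
        assert cohens_kappa(cm) == pytest.approx(20 / 26)

    def test_independent_prediction_gives_zero_kappa(self):
        row = np.array([4, 3, 2, 1])
        col = np.array([1, 2, 3, 4])
        cm = np.outer(row, col)  # product form => Pr(a) == Pr(e)
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(20, 200)
            truth = rng.integers(0, 4, n)
            pred = np.where(rng.random(n) < 0.6, truth, rng.integers(0, 4, n))
            if len(np.unique(truth)) < 2:
                continue
            cm = confusion_matrix(pred, truth)
            acc, kappa, wf1 = _tally_metrics(pred, truth)
            assert accuracy(cm) == pytest.approx(acc, abs=1e-12)
            assert cohens_kappa(cm) == pytest.approx(kappa, abs=1e-12)
            assert weighted_f1(cm) == pytest.approx(wf1, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score, f1_score

        rng = np.random.default_rng(7)
        truth = rng.integers(0, 4, 500)
        pred = np.where(rng.random(500) < 0.7, truth, rng.integers(0, 4, 500))
        cm = confusion_matrix(pred, truth)
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)
        assert weighted_f1(cm) == pytest.approx(
            f1_score(truth, pred, average="weighted"), abs=1e-12
        )

    def test_weighted_f1_between_class_extremes(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 4, 300)
        pred = np.where(rng.random(300) < 0.5, truth, rng.integers(0, 4, 300))
        cm = confusion_matrix(pred, truth)
        f1s = per_class_f1(cm)
        assert f1s.min() - 1e-12 <= weighted_f1(cm) <= f1s.max() + 1e-12

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((4, 4), int))


class TestRejectionBreakdown:
    def test_no_rejections_all_zero(self):
        truth = np.repeat(np.arange(4), 3)
        rates = rejection_breakdown(truth, truth, np.ones(12, bool), np.ones(12, bool))
        assert np.nansum(rates) == 0.0

    def test_all_rejections_defined_cells_one(self):
        truth = np.repeat(np.arange(4), 3)
        rates = rejection_breakdown(truth, truth, np.ones(12, bool), np.zeros(12, bool))
        np.testing.assert_allclose(np.diag(rates), 1.0)

    def test_partial_rejection_rate(self):
        truth = np.array([0] * 5 + [1] * 5)
        pred = truth.copy()
        accepted = np.ones(10, bool)
        accepted[[0, 1]] = False  # 2 of 5 (wake, wake) epochs rejected
        rates = rejection_breakdown(pred, truth, np.ones(10, bool), accepted)
        assert rates[0, 0] == pytest.approx(0.4)
        assert rates[1, 1] == 0.0


class TestSleepParameters:
    def test_all_wake_night_is_flagged(self):
        sp = sleep_parameters(np.zeros(100, int))
        assert sp.tst_minutes == 0.0 and not sp.defined

    def test_counts_to_minutes_and_fractions(self):
        lab = np.concatenate([np.full(100, 1), np.full(20, 2), np.full(40, 3)])
        sp = sleep_parameters(lab)
        assert sp.tst_minutes == 80.0
        assert sp.fr_light == pytest.approx(62.5)
        assert sp.fr_deep == pytest.approx(12.5)
        assert sp.fr_rem == pytest.approx(25.0)
        assert sp.fr_light + sp.fr_deep + sp.fr_rem == pytest.approx(100.0)

    def test_rejected_epochs_are_excluded(self):
        lab = np.concatenate([np.full(100, 1), np.full(20, 2), np.full(40, 3)])
        accepted = np.ones(160, bool)
        accepted[:40] = False  # drop 40 light epochs
        sp = sleep_parameters(lab, accepted=accepted)
        assert sp.tst_minutes == 60.0
        assert sp.fr_light == pytest.approx(50.0)

    def test_mask_taken_from_fourclasslabels(self):
        lab = FourClassLabels(
            np.array([1, 1, 2, -1]), np.array([True, True, True, False])
        )
        assert sleep_parameters(lab).tst_minutes == 1.5


class TestCorrelation:
    def _params(self, rows):
        return [SleepParameters(*r) for r in rows]

    def test_identity_gives_r_one(self):
        truths = self._params([(300, 50, 20, 30), (200, 60, 15, 25), (400, 40, 30, 30), (350, 55, 20, 25)])
        out = correlate_parameters(truths, truths)
        for r, r2 in out.values():
            assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_constant_offset_keeps_r_one(self):
        truths = self._params([(300, 50, 20, 30), (200, 60, 15, 25), (400, 40, 30, 30)])
        est = self._params([(310, 52, 22, 32), (210, 62, 17, 27), (410, 42, 32, 32)])
        for r, _ in correlate_parameters(est, truths).values():
            assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        a = rng.random((4, 4)) * 100
        b = a + rng.random((4, 4)) * 10
        est, tru = self._params(a), self._params(b)
        out = correlate_parameters(est, tru)
        for j, name in enumerate(out):
            x, y = a[:, j], b[:, j]
            r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert out[name][0] == pytest.approx(r_direct, abs=1e-12)

    def test_too_few_subjects_rejected(self):
        p = self._params([(300, 50, 20, 30), (200, 60, 15, 25)])
        with pytest.raises(ValueError):
            correlate_parameters(p, p)


def test_report_coverage_plus_rejection_is_one():
    rng = np.random.default_rng(11)
    truth = rng.integers(0, 4, 200)
    pred = rng.integers(0, 4, 200)
    mask = rng.random(200) < 0.9
    accepted = (rng.random(200) < 0.8) & mask
    rep = metric_report(pred, truth, mask, accepted)
    rejected_frac = ((mask & ~accepted).sum()) / mask.sum()
    assert rep.coverage + rejected_frac == pytest.approx(1.0)
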