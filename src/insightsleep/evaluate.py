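"""Hypnogram metrics, rejection breakdowns, and sleep-parameter estimation.

Accuracy is multiclass trace accuracy; Cohen's kappa uses
Pr(a) = accuracy and Pr(e) = sum_k row_k * col_k / total^2; the weighted F1
averages per-class F1 = 2TP / (2TP + FP + FN) by class support. Pooled
metrics are epoch-pooled across subjects (subject-averaging is available
through per-subject reports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

N_CLASSES = 4
EPOCH_MINUTES = 0.5  # one 30-s epoch


@dataclass
class MetricReport:
    accuracy: float
    kappa: float
    weighted_f1: float
    per_class_f1: np.ndarray
    confusion: np.ndarray
    coverage: float


@dataclass
class SleepParameters:
    """Total sleep time in minutes plus stage fractions (% of TST).

    An all-wake night has TST 0; the fractions are reported as 0 with
    `defined=False` rather than raising, so batch evaluation stays total.
    """

    tst_minutes: float
    fr_light: float
    fr_deep: float
    fr_rem: float
    defined: bool = True

    def as_vector(self) -> np.ndarray:
        return np.array([self.tst_minutes, self.fr_light, self.fr_deep, self.fr_rem])


PARAMETER_NAMES = ("tst_minutes", "fr_light", "fr_deep", "fr_rem")


def _aligned(*arrays):
    arrays = [np.asarray(a) for a in arrays]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("misaligned sequence lengths")
    return arrays


def confusion_matrix(pred, truth, mask=None, accepted=None) -> np.ndarray:
    """4x4 counts over masked-in AND accepted epochs; rows=truth, cols=pred."""
    pred, truth = _aligned(pred, truth)
    use = np.ones(len(pred), dtype=bool)
    if mask is not None:
        (mask,) = _aligned(mask)
        if len(mask) != len(pred):
            raise ValueError("misaligned mask")
        use &= mask.astype(bool)
    if accepted is not None:
        accepted = np.asarray(accepted, dtype=bool)
        if len(accepted) != len(pred):
            raise ValueError("misaligned accepted flags")
        use &= accepted
    t, p = truth[use], pred[use]
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def cohens_kappa(confusion: np.ndarray) -> float:
    """(Pr(a) - Pr(e)) / (1 - Pr(e)); returns nan when Pr(e) == 1
    (degenerate single-cell agreement), documented sentinel."""
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    pr_a = np.trace(confusion) / total
    pr_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum()) / total**2
    if pr_e >= 1.0 - 1e-15:
        return float("nan")
    return float((pr_a - pr_e) / (1.0 - pr_e))


def per_class_f1(confusion: np.ndarray) -> np.ndarray:
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    out = np.zeros(N_CLASSES)
    nz = denom > 0
    out[nz] = 2 * tp[nz] / denom[nz]
    return out


def weighted_f1(confusion: np.ndarray) -> float:
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    support = confusion.sum(axis=1)
    return float((support / total) @ per_class_f1(confusion))


def metric_report(pred, truth, mask=None, accepted=None) -> MetricReport:
    cm = confusion_matrix(pred, truth, mask, accepted)
    if mask is None:
        mask = np.ones(len(np.asarray(pred)), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    cov = 1.0 if accepted is None else float(
        (np.asarray(accepted, dtype=bool) & mask).sum() / max(1, mask.sum())
    )
    return MetricReport(
        accuracy=accuracy(cm),
        kappa=cohens_kappa(cm),
        weighted_f1=weighted_f1(cm),
        per_class_f1=per_class_f1(cm),
        confusion=cm,
        coverage=cov,
    )


def rejection_breakdown(pred, truth, mask, accepted) -> np.ndarray:
    """Cell (t, p): fraction of pre-rejection (truth t, predicted p) epochs
    that were rejected; nan where the pre-rejection cell is empty."""
    before = confusion_matrix(pred, truth, mask)
    after = confusion_matrix(pred, truth, mask, accepted)
    rejected = before - after
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(before > 0, rejected / np.maximum(before, 1), np.nan)
    return rates


def sleep_parameters(labels, mask=None, accepted=None) -> SleepParameters:
    """TST = 0.5 min x (# light + deep + REM epochs); FR_stage = stage/TST x 100.

    Counts run over masked-in epochs, further restricted to accepted epochs
    when an acceptance vector is given (rejected epochs are excluded).
    """
    lab = np.asarray(getattr(labels, "labels", labels))
    use = np.ones(lab.shape[0], dtype=bool)
    if mask is None and hasattr(labels, "epoch_mask"):
        mask = labels.epoch_mask
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    if accepted is not None:
        use &= np.asarray(accepted, dtype=bool)
    lab = lab[use]
    n_light = int((lab == 1).sum())
    n_deep = int((lab == 2).sum())
    n_rem = int((lab == 3).sum())
    n_sleep = n_light + n_deep + n_rem
    if n_sleep == 0:
        return SleepParameters(0.0, 0.0, 0.0, 0.0, defined=False)
    return SleepParameters(
        tst_minutes=EPOCH_MINUTES * n_sleep,
        fr_light=100.0 * n_light / n_sleep,
        fr_deep=100.0 * n_deep / n_sleep,
        fr_rem=100.0 * n_rem / n_sleep,
    )


def correlate_parameters(estimates, truths) -> dict:
    """Pearson r and r^2 per sleep parameter across subjects."""
    if len(estimates) != len(truths):
        raise ValueError("estimate/truth subject counts differ")
    if len(estimates) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    est = np.array([e.as_vector() for e in estimates])
    tru = np.array([t.as_vector() for t in truths])
    out = {}
    for j, name in enumerate(PARAMETER_NAMES):
        if est[:, j].std() == 0 or tru[:, j].std() == 0:
            raise ValueError(f"degenerate variance for {name}")
        r = float(stats.pearsonr(est[:, j], tru[:, j]).statistic)
        out[name] = (r, r * r)
    return out
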