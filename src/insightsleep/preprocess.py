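"""Signal conditioning: low-pass filter, polynomial detrend, unit rescale,
resampling onto the 1024-samples-per-epoch grid, and length standardization.

The pipeline order is filter -> detrend -> min-max -> resample -> standardize.
Polyphase resampling can overshoot the unit interval slightly (filter ringing),
so the min-max rescale is re-applied after resampling; the rescale is
idempotent on range, so this changes nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import PPGRecord

EPOCH_SECONDS = 30
SAMPLES_PER_EPOCH = 1024
TARGET_EPOCHS = 1200
#: effective post-resampling rate: 1024 samples per 30 s
TARGET_FS = SAMPLES_PER_EPOCH / EPOCH_SECONDS


@dataclass
class EpochizedInput:
    """Fixed-shape model input: (n_epochs x 1024) values in [0,1] plus a
    prefix-true epoch mask (padding is appended at the end)."""

    values: np.ndarray
    epoch_mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.epoch_mask = np.asarray(self.epoch_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_epochs, samples_per_epoch)")
        if self.epoch_mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must equal the number of epochs")
        n_true = int(self.epoch_mask.sum())
        if not np.all(self.epoch_mask[:n_true]) or self.epoch_mask[n_true:].any():
            raise ValueError("mask must be a prefix-true pattern")

    @property
    def n_valid_epochs(self) -> int:
        return int(self.epoch_mask.sum())


def lowpass_filter(record: PPGRecord) -> PPGRecord:
    """8th-order zero-phase Chebyshev-II low-pass, 8 Hz cutoff, 40 dB stopband."""
    if record.fs <= 16:
        raise ValueError("sampling rate must exceed 16 Hz (cutoff below Nyquist)")
    sos = sps.cheby2(8, 40, 8.0, btype="lowpass", fs=record.fs, output="sos")
    return record.with_signal(sps.sosfiltfilt(sos, record.signal))


def detrend_polynomial(record: PPGRecord, order: int = 10) -> PPGRecord:
    """Subtract the least-squares degree-`order` polynomial fit.

    The abscissa is rescaled to [-1, 1] before fitting; raw sample indices
    would make the degree-10 design matrix numerically singular.
    """
    x = record.signal
    if x.size <= order + 1:
        raise ValueError("record too short for the requested polynomial order")
    t = np.linspace(-1.0, 1.0, x.size)
    coeffs = np.polynomial.polynomial.polyfit(t, x, order)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    return record.with_signal(x - trend)


def minmax_normalize(record: PPGRecord) -> PPGRecord:
    """(x - min) / (max - min) over the whole recording."""
    x = record.signal
    lo, hi = x.min(), x.max()
    if not hi > lo:
        raise ValueError("constant signal: min-max normalization is undefined")
    return record.with_signal((x - lo) / (hi - lo))


def resample_to_epoch_grid(record: PPGRecord) -> PPGRecord:
    """Polyphase-resample so each 30-s epoch holds exactly 1024 samples.

    A trailing partial epoch (< 30 s) is discarded before resampling.
    """
    if record.fs < TARGET_FS:
        raise ValueError("sampling rate below the target epoch-grid rate")
    spe_in = round(EPOCH_SECONDS * record.fs)
    if abs(spe_in - EPOCH_SECONDS * record.fs) > 1e-6:
        raise ValueError("30 s must correspond to an integer number of samples")
    n_epochs = record.signal.size // spe_in
    if n_epochs < 1:
        raise ValueError("record shorter than one 30-s epoch")
    x = record.signal[: n_epochs * spe_in]
    frac = Fraction(SAMPLES_PER_EPOCH, spe_in)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    assert y.size == n_epochs * SAMPLES_PER_EPOCH
    return record.with_signal(y, fs=TARGET_FS)


def standardize_length(record: PPGRecord, n_epochs: int = TARGET_EPOCHS) -> EpochizedInput:
    """Truncate to the first `n_epochs` epochs or zero-pad at the end."""
    x = record.signal
    if x.size % SAMPLES_PER_EPOCH:
        raise ValueError("signal must be on the 1024-samples-per-epoch grid")
    have = x.size // SAMPLES_PER_EPOCH
    keep = min(have, n_epochs)
    values = np.zeros((n_epochs, SAMPLES_PER_EPOCH))
    values[:keep] = x[: keep * SAMPLES_PER_EPOCH].reshape(keep, SAMPLES_PER_EPOCH)
    mask = np.arange(n_epochs) < keep
    return EpochizedInput(values, mask, subject_id=record.subject_id)


def preprocess_pipeline(record: PPGRecord, n_epochs: int = TARGET_EPOCHS) -> EpochizedInput:
    """filter -> detrend -> min-max -> resample (rescale re-applied) -> standardize."""
    r = lowpass_filter(record)
    r = detrend_polynomial(r)
    r = minmax_normalize(r)
    r = resample_to_epoch_grid(r)
    r = minmax_normalize(r)
    return standardize_length(r, n_epochs=n_epochs)
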