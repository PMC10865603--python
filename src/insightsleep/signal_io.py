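"""Reading PPG channels and sleep-stage annotations; writing predictions.

EDF reading goes through :mod:`mne`; writing uses a small 16-bit EDF writer
(integer sampling rates, whole-second signals) so that synthetic recordings
can round-trip through the same reader the real data would use.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

RK6_STAGES = ("W", "S1", "S2", "S3", "S4", "R")
FOUR_STAGES = ("wake", "light", "deep", "rem")
UNSCORED = "?"

_TOKEN_ALIASES = {
    "W": "W", "WAKE": "W",
    "S1": "S1", "N1": "S1",
    "S2": "S2", "N2": "S2",
    "S3": "S3",
    "S4": "S4",
    "R": "R", "REM": "R",
    "?": UNSCORED, "U": UNSCORED, "UNSCORED": UNSCORED, "MT": UNSCORED,
}


@dataclass
class PPGRecord:
    """A single-channel photoplethysmography recording."""

    subject_id: str
    signal: np.ndarray
    fs: float
    start_time: object = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.signal.size / self.fs

    def with_signal(self, signal, fs=None) -> "PPGRecord":
        return replace(self, signal=np.asarray(signal, dtype=np.float64),
                       fs=self.fs if fs is None else fs)


@dataclass
class StageSequence:
    """Per-epoch sleep-stage labels on a fixed 30-s grid."""

    labels: tuple
    scheme: str = "RK6"
    epoch_seconds: int = 30

    def __post_init__(self):
        if self.epoch_seconds != 30:
            raise ValueError("epochs are fixed at 30 s")
        if self.scheme not in ("RK6", "FOUR"):
            raise ValueError("scheme must be 'RK6' or 'FOUR'")
        valid = set(RK6_STAGES if self.scheme == "RK6" else FOUR_STAGES) | {UNSCORED}
        bad = [l for l in self.labels if l not in valid]
        if bad:
            raise ValueError(f"labels outside the {self.scheme} scheme: {bad[:5]}")
        self.labels = tuple(self.labels)

    def __len__(self):
        return len(self.labels)


class ChannelNotFoundError(KeyError):
    pass


def _repair_nonfinite(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over isolated dropouts; >5% non-finite is rejected."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.mean() > 0.05:
        raise ValueError(
            f"{bad.mean():.1%} of samples are non-finite; record rejected"
        )
    idx = np.arange(x.size)
    x = x.copy()
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def read_edf_ppg(path, channel: str) -> PPGRecord:
    """Read one plethysmography channel from an EDF/EDF+ file."""
    import mne

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such EDF file: {path}")
    header = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in header.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name}; available: {header.ch_names}"
        )
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    signal = raw.get_data(picks=[channel])[0]
    signal = _repair_nonfinite(signal)
    return PPGRecord(
        subject_id=path.stem,
        signal=signal,
        fs=float(raw.info["sfreq"]),
        start_time=raw.info.get("meas_date"),
    )


def write_edf(path, record: PPGRecord, channel: str = "Pleth") -> None:
    """Minimal single-channel 16-bit EDF writer (integer fs, 1-s records).

    The signal is padded with its last value to a whole number of seconds;
    whole-second inputs round-trip sample-exactly.
    """
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = record.signal
    n_rec = math.ceil(x.size / fs)
    pad = n_rec * fs - x.size
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1])])
    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = digital.clip(dmin, dmax).astype("<i2")

    def f(s, n):
        s = str(s)[:n]
        return s.ljust(n).encode("ascii")

    def fnum(v, n=8):
        for prec in range(6, 0, -1):
            s = f"{v:.{prec}g}"
            if len(s) <= n:
                return f(s, n)
        raise ValueError(f"cannot format {v} in {n} chars")

    header = b"".join([
        f("0", 8),
        f("X X X X", 80),
        f(record.subject_id, 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 + 256, 8),          # header bytes: fixed + one signal
        f("", 44),
        f(n_rec, 8),
        f("1", 8),                # record duration, seconds
        f("1", 4),                # number of signals
        # per-signal fields
        f(channel, 16),
        f("PPG", 80),
        f("a.u.", 8),
        fnum(pmin), fnum(pmax),
        f(dmin, 8), f(dmax, 8),
        f("", 80),
        f(fs, 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _label_from_token(tok: str) -> str:
    key = tok.strip().upper()
    if key not in _TOKEN_ALIASES:
        raise ValueError(f"unknown sleep-stage token {tok!r}")
    return _TOKEN_ALIASES[key]


def _read_csv_epochs(path) -> StageSequence:
    labels = []
    for line in Path(path).read_text().splitlines():
        for tok in line.split(","):
            if tok.strip():
                labels.append(_label_from_token(tok))
    return StageSequence(tuple(labels))


def _read_event_xml(path) -> StageSequence:
    root = ET.parse(path).getroot()
    events = []
    for ev in root.iter("ScoredEvent"):
        stage = _label_from_token(ev.findtext("Stage", "").strip())
        start = float(ev.findtext("Start"))
        dur = float(ev.findtext("Duration"))
        events.append((start, start + dur, stage))
    if not events:
        raise ValueError("no ScoredEvent entries found")
    events.sort()
    for (s1, e1, g1), (s2, e2, g2) in zip(events, events[1:]):
        if s2 < e1 - 1e-9 and g1 != g2:
            raise ValueError(
                f"overlapping contradictory events at {s2:.1f} s ({g1} vs {g2})"
            )
    n_epochs = int(math.floor(max(e for _, e, _ in events) / 30.0))
    labels = []
    for i in range(n_epochs):
        lo, hi = 30.0 * i, 30.0 * (i + 1)
        cover = {}
        order = {}
        for start, end, stage in events:
            ov = min(hi, end) - max(lo, start)
            if ov > 0:
                cover[stage] = cover.get(stage, 0.0) + ov
                order.setdefault(stage, start)
        # label covering >= 15 s wins; ties go to the earlier event
        best = UNSCORED
        best_key = None
        for stage, ov in cover.items():
            if ov >= 15.0 - 1e-9:
                key = (-ov, order[stage])
                if best_key is None or key < best_key:
                    best_key, best = key, stage
        labels.append(best)
    return StageSequence(tuple(labels))


def read_stage_annotations(path, dialect: str = "csv") -> StageSequence:
    """Parse per-epoch R&K annotations. dialect: 'csv' (one label per line)
    or 'xml' (scored-event list with Start/Duration in seconds)."""
    if dialect == "csv":
        return _read_csv_epochs(path)
    if dialect == "xml":
        return _read_event_xml(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_predictions(result, path, attention: np.ndarray | None = None) -> None:
    """Write a SelectiveResult as RFC-4180 CSV; rejected epochs are rendered
    with the literal token REJECT in the predicted_stage column."""
    n = len(result.predicted)
    if n < 1:
        raise ValueError("empty result")
    att = np.zeros(n) if attention is None else np.asarray(attention, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "predicted_stage", "energy", "accepted", "attention_score"])
        for i in range(n):
            if not result.mask[i]:
                continue
            stage = (
                FOUR_STAGES[result.predicted[i]] if result.accepted[i] else "REJECT"
            )
            w.writerow([
                i,
                stage,
                f"{result.energy[i]:.6f}",
                str(bool(result.accepted[i])).lower(),
                f"{att[i]:.6f}",
            ])


def read_predictions(path):
    """Round-trip reader for :func:`write_predictions` (audit/tests)."""
    import pandas as pd

    return pd.read_csv(path)
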