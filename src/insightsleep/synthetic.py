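"""Synthetic overnight PPG with stage-dependent pulse dynamics.

The generator emulates the physiology that makes PPG informative for sleep
staging: heart rate and its variability change with sleep stage (slow and
regular in deep sleep, faster and more variable in wake and REM), and pulse
amplitude is modulated by respiration. Hypnograms come from a first-order
Markov chain over the six R&K stages with strong self-transitions, so bouts
have realistic persistence. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import PPGRecord, StageSequence, RK6_STAGES, write_edf

#: 4-class pulse dynamics per stage group: mean beat rate (bpm),
#: beat-interval coefficient of variation, respiratory amplitude-modulation
#: depth (deeper in non-REM). Direction-faithful to sleep physiology; the
#: values are generator configuration, not measured claims.
STAGE_PULSE_PARAMS = {
    "wake": {"bpm": 72.0, "cv": 0.10, "resp_depth": 0.10},
    "light": {"bpm": 62.0, "cv": 0.06, "resp_depth": 0.20},
    "deep": {"bpm": 56.0, "cv": 0.03, "resp_depth": 0.25},
    "rem": {"bpm": 68.0, "cv": 0.12, "resp_depth": 0.08},
}

_RK6_TO_GROUP = {"W": "wake", "S1": "light", "S2": "light",
                 "S3": "deep", "S4": "deep", "R": "rem"}

#: long-run occupancy aimed near overnight cohort medians
#: (wake ~34%, light ~39%, deep ~12%, REM ~11%); matched loosely.
_TARGET_OCCUPANCY = {"W": 0.34, "S1": 0.13, "S2": 0.26,
                     "S3": 0.06, "S4": 0.06, "R": 0.11}


def default_transition_matrix(self_prob: float = 0.90) -> np.ndarray:
    """Row-stochastic 6x6 over (W, S1, S2, S3, S4, R): stay with probability
    `self_prob`, otherwise jump proportionally to the target occupancy."""
    pi = np.array([_TARGET_OCCUPANCY[s] for s in RK6_STAGES])
    pi = pi / pi.sum()
    P = np.zeros((6, 6))
    for i in range(6):
        off = pi.copy()
        off[i] = 0.0
        off /= off.sum()
        P[i] = (1.0 - self_prob) * off
        P[i, i] = self_prob
    return P


@dataclass
class SynthConfig:
    n_subjects: int = 16
    duration_hours: float | None = None   # None: draw uniformly from 8-10 h
    fs: int = 128
    seed: int = 7
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    stage_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in STAGE_PULSE_PARAMS.items()
    })
    noise_sd: float = 0.02
    wander_amp: float = 0.05
    wander_period_s: float = 60.0
    resp_rate_hz: float = 0.25

    def __post_init__(self):
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (6, 6) or (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 6x6 row-stochastic")
        self.transition = P
        for name, p in self.stage_params.items():
            if not 30.0 <= p["bpm"] <= 120.0:
                raise ValueError(f"{name}: beat rate outside 30-120 bpm")
        if self.fs not in (128, 256):
            raise ValueError("fs must be 128 or 256 Hz")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


def generate_hypnogram(config: SynthConfig, n_epochs: int,
                       rng: np.random.Generator | None = None) -> StageSequence:
    """First-order Markov chain over the six R&K stages, starting in wake."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    P = config.transition
    state = 0  # wake
    out = []
    for _ in range(n_epochs):
        out.append(RK6_STAGES[state])
        state = int(rng.choice(6, p=P[state]))
    return StageSequence(tuple(out))


def _pulse_template(fs: int) -> tuple[np.ndarray, int]:
    """Asymmetric pulse: systolic peak plus a dicrotic shoulder; returns the
    waveform and the index of its peak sample."""
    t = np.arange(int(round(0.9 * fs))) / fs
    wave = np.exp(-0.5 * ((t - 0.18) / 0.045) ** 2)
    wave += 0.45 * np.exp(-0.5 * ((t - 0.42) / 0.08) ** 2)
    return wave, int(np.argmax(wave))


def generate_ppg(hypnogram: StageSequence, config: SynthConfig,
                 rng: np.random.Generator | None = None,
                 subject_id: str = "synth"):
    """Render the hypnogram as a pulse waveform.

    Returns ``(PPGRecord, meta)`` where meta carries the generator's own beat
    log: peak sample indices, beat intervals in seconds, and the stage group
    of each beat (used by attention and interval-statistics tests).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fs = config.fs
    spe = 30 * fs
    n = len(hypnogram) * spe
    x = np.zeros(n)
    template, peak_off = _pulse_template(fs)
    groups = [_RK6_TO_GROUP[s] for s in hypnogram.labels]

    peaks, intervals, beat_groups = [], [], []
    t_cur = 0.0
    while True:
        onset = int(round(t_cur * fs))
        if onset >= n:
            break
        group = groups[min(onset // spe, len(groups) - 1)]
        p = config.stage_params[group]
        mean_iv = 60.0 / p["bpm"]
        iv = mean_iv if p["cv"] == 0 else max(0.3, rng.normal(mean_iv, p["cv"] * mean_iv))
        amp = 1.0 + p["resp_depth"] * np.sin(2 * np.pi * config.resp_rate_hz * t_cur)
        seg = template * amp
        end = min(n, onset + seg.size)
        x[onset:end] += seg[: end - onset]
        if onset + peak_off < n:
            peaks.append(onset + peak_off)
            intervals.append(iv)
            beat_groups.append(group)
        t_cur += iv
    tt = np.arange(n) / fs
    if config.wander_amp:
        x += config.wander_amp * np.sin(2 * np.pi * tt / config.wander_period_s)
    if config.noise_sd:
        x += rng.normal(0.0, config.noise_sd, n)
    record = PPGRecord(subject_id=subject_id, signal=x, fs=float(fs))
    meta = {
        "peak_indices": np.array(peaks, dtype=np.int64),
        "intervals_s": np.array(intervals),
        "beat_stage_group": beat_groups,
    }
    return record, meta


def _draw_duration_hours(config: SynthConfig, rng) -> float:
    if config.duration_hours is not None:
        return float(config.duration_hours)
    return float(rng.uniform(8.0, 10.0))


def generate_subject(config: SynthConfig, subject_id: str,
                     rng: np.random.Generator):
    hours = _draw_duration_hours(config, rng)
    n_epochs = int(round(hours * 3600 / 30))
    hyp = generate_hypnogram(config, n_epochs, rng)
    record, meta = generate_ppg(hyp, config, rng, subject_id=subject_id)
    return record, hyp, meta


def make_dataset(config: SynthConfig, out_dir) -> Path:
    """Write one EDF + one label CSV per subject plus a manifest CSV; returns
    the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_subjects):
        sid = f"synth{i:03d}"
        record, hyp, _ = generate_subject(config, sid, rng)
        edf_path = out / f"{sid}.edf"
        lab_path = out / f"{sid}_stages.csv"
        write_edf(edf_path, record)
        lab_path.write_text("\n".join(hyp.labels) + "\n")
        rows.append({"subject_id": sid, "edf_path": str(edf_path),
                     "labels_path": str(lab_path)})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
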