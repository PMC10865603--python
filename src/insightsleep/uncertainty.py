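"""Energy-score uncertainty and selective prediction with rejection.

The energy of an epoch's logits f is E(x;f) = -T * log sum_i exp(f_i / T):
low for inputs resembling the training distribution, high for unfamiliar
ones. Epochs whose energy exceeds a threshold tau (calibrated as a quantile
of the training energy distribution) are rejected ("don't know").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import LogitsGrid
from .nn.losses import softmax as _softmax

PRESET_KEEP_FRACTIONS = (0.80, 0.85, 0.90, 0.95)


@dataclass(frozen=True)
class EnergyConfig:
    temperature: float = 1.0
    keep_fraction: float = 0.90

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")


@dataclass
class SelectiveResult:
    """Per-epoch prediction, energy, accept flag, and the threshold used.

    Rejected epochs keep their argmax prediction for audit but are excluded
    from downstream metrics; masked-out epochs are neither accepted nor
    rejected.
    """

    predicted: np.ndarray
    energy: np.ndarray
    accepted: np.ndarray
    mask: np.ndarray
    threshold: float

    @property
    def coverage(self) -> float:
        m = self.mask
        return float(self.accepted[m].sum() / m.sum()) if m.any() else 0.0


def energy_score(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """E = -T * logsumexp(f / T) along the last axis (overflow-safe)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    return -temperature * logsumexp(logits / temperature, axis=-1)


def softmax_with_temperature(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return _softmax(np.asarray(logits, dtype=np.float64) / temperature, axis=-1)


def calibrate_threshold(train_energies, keep_fraction: float) -> float:
    """tau = lower empirical quantile: the order statistic at
    ceil(keep_fraction * n), so >= keep_fraction of training epochs have
    E <= tau."""
    e = np.sort(np.asarray(train_energies, dtype=np.float64).ravel())
    if e.size == 0:
        raise ValueError("empty energy sample")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    k = max(1, math.ceil(keep_fraction * e.size))
    return float(e[k - 1])


def selective_predict(
    logits_grid: LogitsGrid | np.ndarray,
    mask: np.ndarray,
    config: EnergyConfig,
    threshold: float,
) -> SelectiveResult:
    """Accept an epoch iff its energy is <= threshold (Gibbs selector)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    logits = logits_grid.values if isinstance(logits_grid, LogitsGrid) else np.asarray(logits_grid)
    mask = np.asarray(mask, dtype=bool)
    energy = energy_score(logits, config.temperature)
    predicted = logits.argmax(axis=-1)
    accepted = (energy <= threshold) & mask
    return SelectiveResult(predicted, energy, accepted, mask, float(threshold))


def save_threshold(path, threshold: float, config: EnergyConfig) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "threshold": threshold,
                "keep_fraction": config.keep_fraction,
                "temperature": config.temperature,
            },
            fh,
        )


def load_threshold(path):
    with open(path) as fh:
        d = json.load(fh)
    return d["threshold"], EnergyConfig(d["temperature"], d["keep_fraction"])
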