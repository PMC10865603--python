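"""R&K six-class to four-class label mapping and training class weights.

Frozen integer encoding: wake=0, light=1, deep=2, rem=3; masked-out or
unscored epochs carry the ignore sentinel -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import StageSequence, UNSCORED

IGNORE = -1
WAKE, LIGHT, DEEP, REM = 0, 1, 2, 3
CLASS_NAMES = ("wake", "light", "deep", "rem")

_RK6_TO_FOUR = {"W": WAKE, "S1": LIGHT, "S2": LIGHT, "S3": DEEP, "S4": DEEP, "R": REM}
_FOUR_TO_FOUR = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class FourClassLabels:
    labels: np.ndarray          # int, IGNORE where unscored/padded
    epoch_mask: np.ndarray      # bool, aligned to EpochizedInput

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.epoch_mask = np.asarray(self.epoch_mask, dtype=bool)
        if self.labels.shape != self.epoch_mask.shape:
            raise ValueError("labels and mask must be aligned")
        lab = self.labels[self.epoch_mask]
        if lab.size and ((lab < 0) | (lab > 3)).any():
            raise ValueError("masked-in labels must be in {0,1,2,3}")
        if not np.all(self.labels[~self.epoch_mask] == IGNORE):
            raise ValueError("masked-out entries must carry the ignore sentinel")

    def __len__(self):
        return len(self.labels)


def map_rk_to_four(stages: StageSequence, n_epochs: int | None = None) -> FourClassLabels:
    """W -> wake, S1/S2 -> light, S3/S4 -> deep, REM -> rem.

    Unscored epochs map to the ignore sentinel with mask False. FOUR-scheme
    input passes through unchanged (the mapping is idempotent). When
    `n_epochs` is given, the sequence is truncated or padded (ignore/False)
    to align with an EpochizedInput.
    """
    table = _RK6_TO_FOUR if stages.scheme == "RK6" else _FOUR_TO_FOUR
    labels = [IGNORE if s == UNSCORED else table[s] for s in stages.labels]
    mask = [s != UNSCORED for s in stages.labels]
    if n_epochs is not None:
        labels = labels[:n_epochs] + [IGNORE] * max(0, n_epochs - len(labels))
        mask = mask[:n_epochs] + [False] * max(0, n_epochs - len(mask))
    return FourClassLabels(np.array(labels), np.array(mask))


def class_weights(labels: FourClassLabels | list) -> np.ndarray:
    """Inverse-frequency weights w_k = N_total / (4 * N_k) over masked-in
    epochs, pooled across recordings; satisfies sum_k w_k * N_k == N_total."""
    if isinstance(labels, FourClassLabels):
        labels = [labels]
    pooled = np.concatenate([l.labels[l.epoch_mask] for l in labels])
    counts = np.bincount(pooled, minlength=4)[:4]
    if (counts == 0).any():
        missing = [CLASS_NAMES[k] for k in np.flatnonzero(counts == 0)]
        raise ValueError(f"absent class(es) in training labels: {missing}")
    return pooled.size / (4.0 * counts)
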