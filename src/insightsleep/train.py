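"""Class-weighted, mask-aware training: whole-night batches, RMSprop/Adam,
and transfer fine-tuning with nothing frozen.

One training example is one full recording (the small batch sizes reported
for this architecture imply whole-night samples); gradients accumulate over
the recordings of a mini-batch and are averaged before the optimizer step.
Zero-padded epochs contribute nothing to the loss or its gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import FourClassLabels, class_weights as _class_weights, map_rk_to_four
from .model import InsightSleepNet, load_checkpoint, save_checkpoint
from .nn.losses import masked_weighted_nll, masked_weighted_nll_with_grad
from .nn.optim import make_optimizer
from .preprocess import EpochizedInput, preprocess_pipeline
from .signal_io import read_edf_ppg, read_stage_annotations


@dataclass
class TrainConfig:
    optimizer: str = "rmsprop"          # 'rmsprop' or 'adam'
    lr: float = 1e-3
    batch_size: int = 2
    max_epochs: int = 100
    seed: int = 0
    class_weights: np.ndarray | None = None
    transfer_from: str | None = None

    def __post_init__(self):
        if not self.lr >= 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.optimizer.lower() not in ("rmsprop", "adam"):
            raise ValueError("optimizer must be 'rmsprop' or 'adam'")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    final_state: dict
    weights: np.ndarray


def _dataset_loss(model: InsightSleepNet, dataset, weights) -> float:
    losses, sizes = [], []
    for epochized, labels in dataset:
        logits = model.forward_values(epochized.values, training=False)
        mask = labels.epoch_mask & epochized.epoch_mask
        logp = logits - np.logaddexp.reduce(logits, axis=1, keepdims=True)
        losses.append(masked_weighted_nll(logp, labels.labels, mask, weights))
        sizes.append(mask.sum())
    sizes = np.asarray(sizes, dtype=float)
    return float(np.average(losses, weights=sizes))


def train_loop(
    model: InsightSleepNet,
    dataset,
    config: TrainConfig,
    val_dataset=None,
) -> TrainResult:
    """Mini-batch optimization; fixed seed gives a reproducible trajectory.

    `dataset` is a sequence of ``(EpochizedInput, FourClassLabels)`` pairs.
    When a validation set is given, the state with the best validation loss
    is checkpointed; otherwise the final state is the best state.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    weights = (
        np.asarray(config.class_weights, dtype=float)
        if config.class_weights is not None
        else _class_weights([lab for _, lab in dataset])
    )
    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(config.seed + 1000)
    opt = make_optimizer(config.optimizer, model.parameters(), config.lr)
    rows = []
    best_val = np.inf
    best_state = model.state_dict()
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(dataset))
        epoch_losses, epoch_sizes = [], []
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo : lo + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                epochized, labels = dataset[idx]
                logits = model.forward_values(epochized.values, training=True)
                mask = labels.epoch_mask & epochized.epoch_mask
                loss, dlogits = masked_weighted_nll_with_grad(
                    logits, labels.labels, mask, weights
                )
                model.backward(dlogits / len(batch))
                epoch_losses.append(loss)
                epoch_sizes.append(mask.sum())
            opt.step()
        train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
        row = {"epoch": epoch, "train_loss": train_loss}
        if val_dataset is not None:
            val_loss = _dataset_loss(model, val_dataset, weights)
            row["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state_dict()
        rows.append(row)
    if val_dataset is None:
        best_state = model.state_dict()
    return TrainResult(
        history=pd.DataFrame(rows),
        best_state=best_state,
        final_state=model.state_dict(),
        weights=weights,
    )


def transfer_finetune(
    base_checkpoint,
    dataset,
    config: TrainConfig,
    val_dataset=None,
) -> tuple[InsightSleepNet, TrainResult]:
    """Initialize every weight from the checkpoint, then train all of them
    (no freezing)."""
    model = load_checkpoint(base_checkpoint)
    result = train_loop(model, dataset, config, val_dataset=val_dataset)
    return model, result


# -- manifest handling --------------------------------------------------------

def save_epochized(path, epochized: EpochizedInput) -> None:
    np.savez(
        path,
        values=epochized.values,
        epoch_mask=epochized.epoch_mask,
        subject_id=np.array(epochized.subject_id),
    )


def load_epochized(path) -> EpochizedInput:
    with np.load(path) as d:
        return EpochizedInput(
            d["values"], d["epoch_mask"], subject_id=str(d["subject_id"])
        )


def load_training_data(manifest_path, n_epochs: int, channel: str = "Pleth"):
    """Materialize (EpochizedInput, FourClassLabels) pairs from a manifest.

    Accepts either preprocessed recordings (`epochized_path` column, .npz)
    or raw ones (`edf_path` column, preprocessed on the fly); labels come
    from per-epoch CSV files referenced by `labels_path`.
    """
    df = pd.read_csv(manifest_path)
    if "labels_path" not in df.columns:
        raise ValueError("manifest needs a labels_path column")
    dataset = []
    for _, row in df.iterrows():
        if "epochized_path" in df.columns and isinstance(row.get("epochized_path"), str):
            epochized = load_epochized(row["epochized_path"])
        elif "edf_path" in df.columns:
            record = read_edf_ppg(row["edf_path"], channel)
            epochized = preprocess_pipeline(record, n_epochs=n_epochs)
        else:
            raise ValueError("manifest needs an epochized_path or edf_path column")
        if epochized.values.shape[0] != n_epochs:
            raise ValueError(
                f"{row.get('subject_id', '?')}: expected {n_epochs} epochs, "
                f"got {epochized.values.shape[0]}"
            )
        stages = read_stage_annotations(row["labels_path"], dialect="csv")
        labels = map_rk_to_four(stages, n_epochs=n_epochs)
        dataset.append((epochized, labels))
    return dataset


def split_by_subject(dataset, val_fraction: float = 0.2, seed: int = 0):
    """Seed-controlled 80/20 subject split for checkpoint selection."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset)))) if len(dataset) > 1 else 0
    val_idx = set(order[:n_val].tolist())
    train = [d for i, d in enumerate(dataset) if i not in val_idx]
    val = [d for i, d in enumerate(dataset) if i in val_idx]
    return train, val
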