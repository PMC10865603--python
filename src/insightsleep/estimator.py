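"""scikit-learn-compatible estimator facade over the network and trainer.

``SleepStageClassifier`` treats one recording as one sample: X has shape
``(n_recordings, n_epochs, epoch_len)`` (values in [0, 1], zero-padded
epochs allowed) and y has shape ``(n_recordings, n_epochs)`` with integer
stages 0..3 and -1 for epochs to ignore. It composes with sklearn model
selection through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .labels import FourClassLabels, IGNORE
from .model import InsightSleepNet, ModelConfig, count_trainable_parameters
from .preprocess import EpochizedInput
from .train import TrainConfig, train_loop
from .uncertainty import (
    EnergyConfig,
    calibrate_threshold,
    energy_score,
    selective_predict,
)


def _as_epochized(x: np.ndarray) -> EpochizedInput:
    x = np.asarray(x, dtype=np.float64)
    nonzero = np.flatnonzero(np.abs(x).sum(axis=1) > 0)
    n_valid = int(nonzero[-1]) + 1 if nonzero.size else 0
    mask = np.arange(x.shape[0]) < n_valid
    return EpochizedInput(x, mask)


class SleepStageClassifier(ClassifierMixin, BaseEstimator):
    """4-class sleep staging from epochized continuous PPG.

    Parameters mirror the architecture and optimizer settings; `config`
    overrides the architecture wholesale when given. After `fit`:

    - ``network_`` : the trained network
    - ``classes_`` : array([0, 1, 2, 3])
    - ``history_`` : per-epoch loss log (DataFrame)
    - ``energy_threshold_`` : tau calibrated on the training energies at
      ``keep_fraction``
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        reduced: bool = True,
        optimizer: str = "rmsprop",
        lr: float = 1e-3,
        batch_size: int = 2,
        max_epochs: int = 100,
        keep_fraction: float = 0.90,
        temperature: float = 1.0,
        seed: int = 0,
    ):
        self.config = config
        self.reduced = reduced
        self.optimizer = optimizer
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.keep_fraction = keep_fraction
        self.temperature = temperature
        self.seed = seed

    # -- internals -----------------------------------------------------------
    def _resolve_config(self, n_epochs: int, epoch_len: int) -> ModelConfig:
        if self.config is not None:
            cfg = self.config
        elif self.reduced:
            cfg = ModelConfig.reduced(n_epochs=n_epochs, seed=self.seed)
        else:
            cfg = ModelConfig(n_epochs=n_epochs, seed=self.seed)
        if (cfg.n_epochs, cfg.epoch_len) != (n_epochs, epoch_len):
            raise ValueError(
                f"config grid ({cfg.n_epochs}, {cfg.epoch_len}) does not match "
                f"data grid ({n_epochs}, {epoch_len})"
            )
        return cfg

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_recordings, n_epochs, epoch_len)")
        return X

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != X.shape[:2]:
            raise ValueError("y must be (n_recordings, n_epochs)")
        cfg = self._resolve_config(X.shape[1], X.shape[2])
        dataset = []
        for xi, yi in zip(X, y):
            epochized = _as_epochized(xi)
            mask = (yi != IGNORE) & epochized.epoch_mask
            lab = np.where(mask, yi, IGNORE)
            dataset.append((epochized, FourClassLabels(lab, mask)))
        self.network_ = InsightSleepNet(cfg)
        tc = TrainConfig(
            optimizer=self.optimizer,
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )
        result = train_loop(self.network_, dataset, tc)
        self.history_ = result.history
        self.class_weights_ = result.weights
        self.classes_ = np.arange(cfg.n_classes)
        self.n_parameters_ = count_trainable_parameters(self.network_)
        train_energies = np.concatenate(
            [
                energy_score(self.network_.forward_values(e.values), self.temperature)[
                    l.epoch_mask
                ]
                for e, l in dataset
            ]
        )
        self.train_energies_ = train_energies
        self.energy_threshold_ = calibrate_threshold(train_energies, self.keep_fraction)
        return self

    def decision_function(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        X = self._check_X(X)
        return np.stack([self.network_.forward_values(xi) for xi in X])

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X).argmax(axis=-1)

    def predict_selective(self, X, keep_fraction: float | None = None):
        """Per-recording SelectiveResults under the calibrated threshold."""
        logits = self.decision_function(X)
        kf = self.keep_fraction if keep_fraction is None else keep_fraction
        cfg = EnergyConfig(self.temperature, kf)
        tau = calibrate_threshold(self.train_energies_, kf)
        X = self._check_X(X)
        return [
            selective_predict(lg, _as_epochized(xi).epoch_mask, cfg, tau)
            for lg, xi in zip(logits, X)
        ]

    def score(self, X, y) -> float:
        """Masked epoch accuracy (ignores -1 labels)."""
        y = np.asarray(y, dtype=np.int64)
        pred = self.predict(X)
        mask = y != IGNORE
        return float((pred[mask] == y[mask]).mean())
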