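"""Shared fixtures: a synthetic study set and models trained on it.

The study conditions are fixed here once: 16 synthetic subjects with 2-h
recordings at 128 Hz (240 epochs), 12 used for training and 4 held out,
reduced-width architecture, whole-night batches of 2.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from insightsleep.labels import map_rk_to_four
from insightsleep.model import InsightSleepNet, ModelConfig
from insightsleep.preprocess import preprocess_pipeline
from insightsleep.synthetic import SynthConfig, generate_subject
from insightsleep.train import TrainConfig, train_loop

N_EPOCHS = 240
N_TRAIN_SUBJECTS = 12
SMOKE_TRAIN_EPOCHS = 20
DATA_SEED = 11
MODEL_SEED = 5


@pytest.fixture(scope="session")
def synth_study():
    """16 preprocessed recordings + labels + generator beat metadata."""
    cfg = SynthConfig(n_subjects=16, duration_hours=2.0, fs=128, seed=DATA_SEED)
    rng = np.random.default_rng(cfg.seed)
    dataset, metas = [], []
    for i in range(cfg.n_subjects):
        record, hyp, meta = generate_subject(cfg, f"s{i:02d}", rng)
        epochized = preprocess_pipeline(record, n_epochs=N_EPOCHS)
        labels = map_rk_to_four(hyp, n_epochs=N_EPOCHS)
        dataset.append((epochized, labels))
        metas.append(meta)
    return {"dataset": dataset, "metas": metas, "config": cfg}


@pytest.fixture(scope="session")
def train_test_split(synth_study):
    data = synth_study["dataset"]
    return data[:N_TRAIN_SUBJECTS], data[N_TRAIN_SUBJECTS:]


@pytest.fixture(scope="session")
def trained_model(train_test_split):
    """Reduced-width network after the 20-epoch smoke-test training run."""
    train, _ = train_test_split
    model = InsightSleepNet(ModelConfig.reduced(n_epochs=N_EPOCHS, seed=MODEL_SEED))
    result = train_loop(
        model, train, TrainConfig(max_epochs=SMOKE_TRAIN_EPOCHS, seed=MODEL_SEED)
    )
    return model, result


@pytest.fixture(scope="session")
def converged_model(train_test_split):
    """Reduced-width network trained to convergence (40 epochs) for the
    energy-calibration experiments."""
    train, _ = train_test_split
    model = InsightSleepNet(ModelConfig.reduced(n_epochs=N_EPOCHS, seed=MODEL_SEED))
    result = train_loop(model, train, TrainConfig(max_epochs=40, seed=MODEL_SEED))
    return model, result


@pytest.fixture()
def tiny_config():
    """A miniature architecture for gradient and causality probes."""
    return ModelConfig(
        n_epochs=5,
        epoch_len=40,
        attention_channels=2,
        stem_channels=4,
        inception_filters=(1, 1, 2, 2, 2, 2),
        inception_bottleneck=(1, 1, 1, 1, 2, 2),
        inception_out_channels=4,
        tdd_width=6,
        tcn_channels=4,
        tcn_dropout=0.0,
        seed=3,
    )
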