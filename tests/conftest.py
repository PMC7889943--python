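import numpy as np
import pytest

from drilldetect.features import StftConfig
from drilldetect.model import ModelSpec, TrainingConfig
from drilldetect.simulate import SimConfig, simulate_recordings


@pytest.fixture(scope="session")
def stft_cfg_100ms() -> StftConfig:
    return StftConfig.for_window_ms(100)


@pytest.fixture(scope="session")
def tiny_sim_cfg() -> SimConfig:
    """Short recordings for fast end-to-end tests."""
    return SimConfig(recording_length=1.0)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_sim_cfg):
    """Twelve 1 s labeled recordings, enough for grouped 2-fold CV."""
    return simulate_recordings(tiny_sim_cfg, 12, seed=7)


@pytest.fixture(scope="session")
def tiny_detector(tiny_corpus, stft_cfg_100ms):
    """A detector trained on the tiny corpus, shared by streaming/CLI tests."""
    from drilldetect.evaluation import make_folds, train_fold

    folds = make_folds(tiny_corpus, k=2, seed=0)
    train_recs = [r for r, f in zip(tiny_corpus, folds) if f != 0]
    val_recs = [r for r, f in zip(tiny_corpus, folds) if f == 0]
    result, metrics = train_fold(
        train_recs,
        val_recs,
        stft_cfg_100ms,
        ModelSpec.reduced(),
        TrainingConfig(epochs=2, folds=2, seed=0),
        fold_seed=0,
    )
    return result, metrics


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
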