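"""Shared fixtures.

The expensive fixture is ``trained_setup``: a 12-class model trained on
500 synthetic clips per label (100 per label held out), shared across the
classifier, hub and acceptance tests. Training this corpus converges within
a few epochs, so the fixture caps at 8.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from adlsound import features as F
from adlsound.classifier import ModelConfig, build_model, train
from adlsound.synth import LABELS, generate_pool


@pytest.fixture(scope="session")
def filterbank() -> np.ndarray:
    return F.mel_filterbank()


def pool_features(pool: dict, fb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = sorted(pool)
    X = np.stack([F.extract(c.samples, fb) for l in labels for c in pool[l]])
    y = np.concatenate([np.full(len(pool[l]), i) for i, l in enumerate(labels)])
    return X, y


@pytest.fixture(scope="session")
def trained_setup(filterbank) -> SimpleNamespace:
    train_pool = generate_pool(LABELS, n_per_label=500, seed=101)
    test_pool = generate_pool(LABELS, n_per_label=100, seed=707)
    X_train, y_train = pool_features(train_pool, filterbank)
    X_test, y_test = pool_features(test_pool, filterbank)
    config = ModelConfig(n_classes=len(LABELS), epochs=8, seed=1)
    model = build_model(config)
    history = train(model, X_train, y_train, config)
    return SimpleNamespace(
        model=model,
        config=config,
        history=history,
        X_train=X_train,
        y_train=y_train,
        X_test=X_test,
        y_test=y_test,
        labels=tuple(sorted(LABELS)),
    )
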