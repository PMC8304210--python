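"""Shared fixtures.

The expensive fixtures (synthetic cell datasets, the smoke-trained
classifier) are session-scoped so the cost is paid once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from aplscreen.compact_net import CANONICAL_CONFIG
from aplscreen.synthetic_smear import generate_cell_dataset
from aplscreen.train_eval import TrainConfig, stratified_kfold, train_model

# Table of per-cell classification counts on the clinical test data
# (rows: true class, columns: predicted class, both in canonical order).
CLINICAL_TEST_CONFUSION = np.array([
    [190,   0,   0,   0,   0,   0],
    [  1, 210,   1,   0,   0,   0],
    [  0,   0, 191,   2,   2,   0],
    [  0,   0,   1, 180,   1,   0],
    [  0,   0,   0,   1, 125,   0],
    [  0,   0,   0,   2,   0, 454],
])

CLINICAL_CLASS_SIZES = (953, 1063, 976, 912, 628, 2282)


@pytest.fixture(scope="session")
def clinical_confusion() -> np.ndarray:
    return CLINICAL_TEST_CONFUSION.copy()


@pytest.fixture(scope="session")
def small_cell_dataset():
    """20 crops per class at full resolution (feature-separability checks)."""
    return generate_cell_dataset(20, seed=1)


@pytest.fixture(scope="session")
def smoke_dataset():
    """The 100-per-class smoke-training dataset."""
    return generate_cell_dataset(100, seed=42)


@pytest.fixture(scope="session")
def smoke_training(smoke_dataset):
    """Train the canonical classifier from scratch on the smoke dataset.

    Follows the fold protocol: three folds train, one validates, one is
    held out for testing. Training stops as soon as the validation
    accuracy target is reached.
    """
    crops, labels = smoke_dataset
    split = stratified_kfold(labels, 5, seed=0)
    train_idx = np.flatnonzero(np.isin(split.fold_of_sample, (0, 1, 2)))
    val_idx = np.flatnonzero(split.fold_of_sample == 3)
    test_idx = np.flatnonzero(split.fold_of_sample == 4)
    tc = TrainConfig(seed=0, epochs=20, batch_size=8, early_stop_val_acc=0.95)
    model, log = train_model(CANONICAL_CONFIG, tc, crops[train_idx], labels[train_idx],
                             crops[val_idx], labels[val_idx])
    return {"model": model, "log": log, "crops": crops, "labels": labels,
            "train_idx": train_idx, "val_idx": val_idx, "test_idx": test_idx}
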