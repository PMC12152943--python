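"""Shared fixtures: small synthetic datasets and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from dicpred import BinaryMatrix, GeneratorSpec, LabeledDataset, make_binary_dataset


@pytest.fixture(scope="session")
def small_signal_dataset() -> LabeledDataset:
    """~200 compounds, 3:1 imbalance, a few strongly informative bits."""
    spec = GeneratorSpec(
        n_pos=50,
        n_neg=150,
        blocks=(("substructure", 30, 0.2), ("target", 10, 0.05)),
        informative=(("substructure", 0.8, 0.2, 3),),
        seed=11,
    )
    return make_binary_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset() -> LabeledDataset:
    """Zero-signal dataset: every bit i.i.d. regardless of class."""
    spec = GeneratorSpec(
        n_pos=50,
        n_neg=150,
        blocks=(("substructure", 30, 0.2),),
        informative=(),
        seed=5,
    )
    return make_binary_dataset(spec)


@pytest.fixture()
def toy_matrix() -> BinaryMatrix:
    frame = pd.DataFrame(
        [[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 0]],
        index=["c1", "c2", "c3", "c4"],
        columns=["t1", "t2", "t3"],
    )
    return BinaryMatrix(frame, "target")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
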