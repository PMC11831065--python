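"""Shared fixtures: toy montages, recordings and epoch sets built in memory."""

import numpy as np
import pytest

from neurocoh.montage import Montage, default_montage
from neurocoh.preprocessing import EpochSet
from neurocoh.synthetic import Recording


def toy_montage(n: int, region: str = "central") -> Montage:
    """n generically-labeled channels on a line, all tagged with one region."""
    return Montage(
        labels=tuple(f"ch{i:02d}" for i in range(n)),
        positions=tuple((float(i), 0.0) for i in range(n)),
        regions=tuple(region for _ in range(n)),
    )


def make_recording(
    data: np.ndarray,
    fs: float = 250.0,
    montage: Montage | None = None,
    annotations=None,
    group: str = "control",
) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if montage is None:
        montage = toy_montage(data.shape[0])
    if annotations is None:
        half = data.shape[1] // 2
        annotations = [("EO", 0, half), ("EC", half, data.shape[1])]
    return Recording(
        subject_id="test-00", group=group, data=data, fs=fs,
        montage=montage, annotations=annotations,
    )


def make_epochset(
    epochs, fs: float = 250.0, montage: Montage | None = None, condition: str = "EO",
    group: str = "control",
) -> EpochSet:
    epochs = [np.atleast_2d(np.asarray(e, dtype=float)) for e in epochs]
    if montage is None:
        montage = toy_montage(epochs[0].shape[0])
    return EpochSet(
        subject_id="test-00", group=group, condition=condition,
        epochs=epochs, fs=fs, montage=montage,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def montage32() -> Montage:
    return default_montage()
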