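from __future__ import annotations

import numpy as np
import pytest

from plastiscan import (
    DistortionRanges,
    LabeledSpectraSet,
    WavenumberAxis,
    default_axis,
    make_reference_library,
)


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    return default_axis()


@pytest.fixture(scope="session")
def tiny_axis() -> WavenumberAxis:
    """A short 16-band grid for fast unit tests."""
    return WavenumberAxis(1250.0 + 4.0 * np.arange(16))


def separable_set(
    n_classes: int = 4,
    n_per_class: int = 20,
    n_bands: int = 16,
    seed: int = 0,
    flip_fraction: float = 0.0,
) -> LabeledSpectraSet:
    """Linearly separable spectra: class c has value ~1 on band c, else ~0.

    Noise is small enough (sigma 0.01 against a unit step) that classes
    are perfectly separable by a single band threshold. Optionally flips
    a fraction of labels (uniformly to another class) to emulate
    annotation errors; flipped indices are stored on the returned set as
    ``flipped_indices``.
    """
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = rng.normal(0.0, 0.01, size=(n, n_bands))
    X[np.arange(n), y] += 1.0
    flipped = np.array([], dtype=int)
    if flip_fraction > 0:
        k = int(round(flip_fraction * n))
        flipped = rng.choice(n, size=k, replace=False)
        y = y.copy()
        for i in flipped:
            y[i] = (y[i] + int(rng.integers(1, n_classes))) % n_classes
    data = LabeledSpectraSet(
        spectra=X, labels=y, axis=WavenumberAxis(1250.0 + 4.0 * np.arange(n_bands))
    )
    data.flipped_indices = np.sort(flipped)  # type: ignore[attr-defined]
    return data


@pytest.fixture(scope="session")
def small_library() -> LabeledSpectraSet:
    """22-class synthetic reference library at unit-test scale."""
    X, y = make_reference_library(n_per_class=12, seed=42)
    return LabeledSpectraSet(spectra=X, labels=y, axis=default_axis())


@pytest.fixture(scope="session")
def quiet_ranges() -> DistortionRanges:
    """Distortion ranges with all pathologies switched off."""
    return DistortionRanges(
        mie_amplitude=(0.0, 0.0), baseline_slope=(0.0, 0.0),
        ta_ceiling=(1e9, 1e9), noise_sigma=0.0,
    )
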