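"""Shared fixtures: small deterministic volumes, masks, and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from hgpradiomics.synthetic_cohort import CohortConfig, generate_cohort


def ball_mask(shape=(24, 64, 64), center=None, radii=(6, 10, 10)) -> np.ndarray:
    """Ellipsoidal test mask."""
    if center is None:
        center = tuple(s / 2 for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


@pytest.fixture(scope="session")
def textured_volume():
    """Noisy volume + ellipsoid mask reused by the feature-bank tests."""
    rng = np.random.default_rng(42)
    vol = rng.normal(100.0, 10.0, size=(24, 64, 64))
    return vol, ball_mask()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort, shared across fast structural tests."""
    return generate_cohort(
        CohortConfig(n_patients=12, seed=7, shape=(16, 48, 48))
    )


@pytest.fixture(scope="session")
def calibration_cohort():
    """A larger cohort for the DSC-calibration checks (>= 50 lesions)."""
    return generate_cohort(
        CohortConfig(n_patients=50, seed=11, shape=(16, 48, 48))
    )
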