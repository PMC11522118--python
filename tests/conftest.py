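"""Shared fixtures: deterministic lesion-region factories."""

from __future__ import annotations

import numpy as np
import pytest

from hetrad.io import LesionRegion

# voxel volume at the default (0.7, 0.7, 1.5) mm spacing
VOXEL_MM3 = 0.7 * 0.7 * 1.5


@pytest.fixture
def make_region():
    """Factory for a cuboid lesion with given intensities."""

    def _make(intensities, shape=None, voxel_volume_mm3=VOXEL_MM3, patient_id="p1",
              lesion_id=1):
        intensities = np.asarray(intensities, dtype=float).ravel()
        if shape is None:
            shape = (1, intensities.size, 1)
        coords = np.argwhere(np.ones(shape, dtype=bool))
        assert len(coords) == intensities.size
        return LesionRegion(
            lesion_id=lesion_id,
            patient_id=patient_id,
            voxel_intensities=intensities,
            voxel_coordinates=coords,
            voxel_volume_mm3=voxel_volume_mm3,
        )

    return _make


@pytest.fixture
def random_region(make_region):
    """A reproducible 6x6x6 lesion with rough CT-like intensities."""
    rng = np.random.default_rng(7)
    shape = (6, 6, 6)
    return make_region(rng.normal(90.0, 30.0, size=int(np.prod(shape))), shape=shape)
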