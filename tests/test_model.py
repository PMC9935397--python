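"""Data-model validation and coordinate conventions."""

import numpy as np
import pytest

from leafletscope.model import (CylindricalCoords, DensityMap3D,
                                RadialProfile, TubuleSnapshot,
                                ValidationError, ZoneSpec,
                                circular_distance_deg)
from leafletscope.templates import DEFAULT_TEMPLATES


def _single_lipid_snapshot(species="CHOL"):
    order = DEFAULT_TEMPLATES[species].bead_order()
    n = len(order)
    return TubuleSnapshot(species=np.full(n, species, dtype=object),
                          lipid_id=np.zeros(n, dtype=int),
                          bead=np.array(order, dtype=object),
                          xyz=np.random.default_rng(0).normal(size=(n, 3)))


def test_snapshot_rejects_inconsistent_lengths():
    with pytest.raises(ValidationError):
        TubuleSnapshot(species=np.array(["SDPC"], dtype=object),
                       lipid_id=np.array([0, 1]),
                       bead=np.array(["PO4"], dtype=object),
                       xyz=np.zeros((1, 3)))


def test_snapshot_validates_bead_multiset():
    snap = _single_lipid_snapshot()
    snap.validate_against(DEFAULT_TEMPLATES)
    bad = _single_lipid_snapshot()
    bad.bead[0] = "XXX"
    with pytest.raises(ValidationError):
        bad.validate_against(DEFAULT_TEMPLATES)


def test_phosphate_mask_excludes_sterols_by_default():
    snap = _single_lipid_snapshot("CHOL")
    assert snap.phosphate_mask(DEFAULT_TEMPLATES).sum() == 0
    assert snap.phosphate_mask(DEFAULT_TEMPLATES,
                               phospholipids_only=False).sum() == 1


def test_cylindrical_roundtrip():
    rng = np.random.default_rng(1)
    center = (3.0, -2.0)
    r = rng.uniform(5, 50, 100)
    theta = rng.uniform(0, 360, 100)
    z = rng.uniform(0, 100, 100)
    c = CylindricalCoords(r=r, theta=theta, z=z, center=center)
    xyz = c.to_cartesian()
    back_r = np.hypot(xyz[:, 0] - center[0], xyz[:, 1] - center[1])
    back_t = np.degrees(np.arctan2(xyz[:, 1] - center[1],
                                   xyz[:, 0] - center[0])) % 360.0
    assert np.allclose(back_r, r)
    assert np.allclose(circular_distance_deg(back_t, theta), 0, atol=1e-9)


def test_cylindrical_rejects_negative_radius():
    with pytest.raises(ValidationError):
        CylindricalCoords(r=np.array([-1.0]), theta=np.array([0.0]),
                          z=np.array([0.0]), center=(0, 0))


def test_radial_profile_requires_increasing_grid():
    with pytest.raises(ValidationError):
        RadialProfile(np.array([0.0, 1.0, 0.5]), np.zeros(3))
    with pytest.raises(ValidationError):
        RadialProfile(np.arange(3.0), np.zeros(2))


def test_density_map_shape_and_voxel_checks():
    with pytest.raises(ValidationError):
        DensityMap3D(np.zeros((4, 16, 16)), voxel_size=1.0)
    with pytest.raises(ValidationError):
        DensityMap3D(np.zeros((16, 16, 16)), voxel_size=0.0)


def test_zone_spec_rejects_overlapping_wedges():
    ZoneSpec(wedge_halfwidth=15.0, gap_offset=180.0)  # fine
    with pytest.raises(ValidationError):
        ZoneSpec(wedge_halfwidth=30.0, gap_offset=30.0)


def test_circular_distance_wraps():
    assert circular_distance_deg(359.0, 1.0) == pytest.approx(2.0)
    assert circular_distance_deg(180.0, -180.0) == pytest.approx(0.0)
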