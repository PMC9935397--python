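"""Center fitting, leaflet clustering, sterol assignment and zones."""

import numpy as np
import pytest

from conftest import labels_from_truth
from leafletscope import geometry, synthetic
from leafletscope.geometry import DegenerateGeometryError
from leafletscope.model import CONTACT, GAP, INNER, OTHER, OUTER, ZoneSpec


def _helix(radius=55.0, center=(0.0, 0.0), n=34, rise=3.0, turn=17):
    k = np.arange(n)
    th = 2 * np.pi * k / turn
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th),
                            rise * k])


def test_center_fit_exact_on_clean_anchors():
    center = (4.2, -7.9)
    got = geometry.fit_tubule_center(_helix(center=center))
    assert np.hypot(got[0] - center[0], got[1] - center[1]) < 1e-9


def test_center_fit_robust_to_jitter():
    rng = np.random.default_rng(12)
    anchors = _helix(center=(1.0, 2.0)) + rng.normal(0, 1.0, (34, 3))
    got = geometry.fit_tubule_center(anchors)
    assert np.hypot(got[0] - 1.0, got[1] - 2.0) < 0.5


def test_center_fit_rejects_collinear_anchors():
    xy = np.column_stack([np.arange(10.0), 2 * np.arange(10.0),
                          np.zeros(10)])
    with pytest.raises(DegenerateGeometryError):
        geometry.fit_tubule_center(xy)


def test_leaflet_assignment_matches_ground_truth(analyzed_frame):
    snap, coords, labels, truth = analyzed_frame
    assert not labels.degenerate
    assert labels.leaflet == truth.leaflet


def test_cholesterol_follows_nearest_phosphate(default_spec, analyzed_frame):
    snap, coords, labels, truth = analyzed_frame
    chol_ids = {int(i) for i, s in snap.species_of_lipids().items()
                if s == "CHOL"}
    assert chol_ids
    for i in chol_ids:
        assert labels.leaflet[i] == truth.leaflet[i]


def test_zone_assignment_matches_ground_truth(analyzed_frame):
    snap, coords, labels, truth = analyzed_frame
    mismatches = [i for i in truth.zone if labels.zone[i] != truth.zone[i]]
    assert not mismatches


def test_zone_wedges_are_disjoint_and_cover_other():
    anchors = _helix()
    theta = np.arange(0.0, 360.0, 1.0)
    z = np.full_like(theta, 51.0)
    zones = geometry.zone_of_points(theta, z, anchors, (0.0, 0.0), ZoneSpec())
    counts = {zone: int((zones == zone).sum())
              for zone in (CONTACT, GAP, OTHER)}
    # 30 deg contact wedge + 30 deg gap wedge + the rest
    assert counts[CONTACT] in (30, 31)
    assert counts[GAP] in (30, 31)
    assert sum(counts.values()) == len(theta)


def test_zone_follows_helix_rotation():
    anchors = _helix()
    spec = ZoneSpec(follow_helix=True)
    # the contact centerline rotates by twist/rise deg per Angstrom of z
    rate = (360.0 / 17) / 3.0
    for z0 in (30.0, 60.0):
        th_c = rate * z0
        zones = geometry.zone_of_points(np.array([th_c % 360.0]),
                                        np.array([z0]), anchors,
                                        (0.0, 0.0), spec)
        assert zones[0] == CONTACT


def test_points_outside_anchor_span_are_other():
    anchors = _helix()
    zones = geometry.zone_of_points(np.array([0.0]), np.array([500.0]),
                                    anchors, (0.0, 0.0), ZoneSpec())
    assert zones[0] == OTHER


def test_analyze_frame_center_close_to_truth(default_spec, snapshot_truth):
    snap, truth = snapshot_truth
    center, coords, labels = geometry.analyze_frame(
        snap, default_spec.templates, ZoneSpec())
    assert np.hypot(center[0] - default_spec.axis_offset[0],
                    center[1] - default_spec.axis_offset[1]) < 0.5
    assert set(labels.leaflet.values()) == {INNER, OUTER}


def test_ground_truth_labels_container(small_snapshot_truth):
    snap, truth = small_snapshot_truth
    labels = labels_from_truth(truth)
    assert set(labels.leaflet) == set(truth.leaflet)
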