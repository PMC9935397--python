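"""Shared fixtures: small synthetic tubules, analyzed frames, map specs."""

import numpy as np
import pytest

from leafletscope import geometry, synthetic
from leafletscope.model import LeafletLabels, ZoneSpec


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.TubuleSpec(seed=101)


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.TubuleSpec(seed=102, n_lipids_total=260, tube_length=51.0)


@pytest.fixture(scope="session")
def snapshot_truth(default_spec):
    return synthetic.generate_tubule_snapshot(
        default_spec, rng=np.random.default_rng(1001))


@pytest.fixture(scope="session")
def analyzed_frame(default_spec, snapshot_truth):
    snap, truth = snapshot_truth
    center, coords, labels = geometry.analyze_frame(
        snap, default_spec.templates, ZoneSpec())
    return snap, coords, labels, truth


@pytest.fixture(scope="session")
def small_snapshot_truth(small_spec):
    return synthetic.generate_tubule_snapshot(
        small_spec, rng=np.random.default_rng(1002))


@pytest.fixture(scope="session")
def small_map_spec():
    """A compact map (fast to voxelize) with the same shell structure."""
    return synthetic.MapSpec(seed=77, shape=(112, 112, 24),
                             shells=((18.0, 2.0, 1.0), (23.0, 2.5, -0.35),
                                     (28.0, 2.0, 1.0)),
                             protein_shell=(38.0, 2.0, 2.5),
                             leaflet_radii={"inner": 18.0, "outer": 28.0},
                             leaflet_widths={"inner": 2.0, "outer": 2.0})


def labels_from_truth(truth) -> LeafletLabels:
    """Ground-truth labels in the analysis container (bypasses clustering)."""
    return LeafletLabels(leaflet=dict(truth.leaflet), zone=dict(truth.zone))
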