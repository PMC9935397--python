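"""Generator invariants: counts, determinism, furrow, trajectories, maps."""

import numpy as np
import pytest

from leafletscope import synthetic
from leafletscope.model import INNER, OUTER, ValidationError
from leafletscope.synthetic import (FurrowSpec, MapSpec, TubuleSpec,
                                    largest_remainder_counts)


def test_largest_remainder_is_exact_and_deterministic():
    fractions = {"A": 0.582, "B": 0.18, "C": 0.175, "D": 0.063}
    counts = largest_remainder_counts(fractions, 1300)
    assert sum(counts.values()) == 1300
    assert counts == largest_remainder_counts(fractions, 1300)
    # each count within 1 of its exact quota
    for s, f in fractions.items():
        assert abs(counts[s] - f * 1300) < 1.0


def test_snapshot_species_counts_match_ground_truth(snapshot_truth,
                                                    default_spec):
    snap, truth = snapshot_truth
    species_of = snap.species_of_lipids()
    for leaflet in (INNER, OUTER):
        ids = [i for i, lf in truth.leaflet.items() if lf == leaflet]
        got = {}
        for i in ids:
            got[species_of[i]] = got.get(species_of[i], 0) + 1
        assert got == truth.species_counts[leaflet]


def test_snapshot_is_deterministic(default_spec):
    a, _ = synthetic.generate_tubule_snapshot(
        default_spec, rng=np.random.default_rng(5))
    b, _ = synthetic.generate_tubule_snapshot(
        default_spec, rng=np.random.default_rng(5))
    assert np.array_equal(a.xyz, b.xyz)
    assert (a.species == b.species).all()


def test_snapshot_validates_against_templates(snapshot_truth, default_spec):
    snap, _ = snapshot_truth
    snap.validate_against(default_spec.templates)


def test_leaflet_radii_separated(snapshot_truth, default_spec):
    snap, truth = snapshot_truth
    mask = snap.phosphate_mask(default_spec.templates)
    r = np.hypot(snap.xyz[mask, 0], snap.xyz[mask, 1])
    lf = np.array([truth.leaflet[int(i)] for i in snap.lipid_id[mask]])
    assert r[lf == INNER].max() < r[lf == OUTER].min()


def test_furrow_clears_contact_wedge_headgroups():
    spec = TubuleSpec(seed=9, furrow=FurrowSpec())
    snap, truth = synthetic.generate_tubule_snapshot(
        spec, rng=np.random.default_rng(9))
    assert truth.in_furrow
    hw = spec.furrow_halfwidth_deg
    # outer-leaflet headgroup reference beads must sit outside the wedge
    for name, tpl in spec.templates.items():
        if tpl.headgroup_reference_bead is None:
            continue
        mask = ((snap.species == name)
                & (snap.bead == tpl.headgroup_reference_bead))
        for i, pos in zip(snap.lipid_id[mask], snap.xyz[mask]):
            if truth.leaflet[int(i)] != OUTER:
                continue
            theta = np.degrees(np.arctan2(pos[1], pos[0])) % 360.0
            theta_c = spec.theta_centerline(pos[2])
            d = abs((theta - theta_c + 180.0) % 360.0 - 180.0)
            # headgroup beads sit slightly off the phosphate in z, and the
            # centerline rotates ~7 deg per Angstrom, so allow a few degrees
            assert d > hw - 4.0


def test_backflipped_terminals_reach_anchor_radius():
    spec = TubuleSpec(seed=9, furrow=FurrowSpec(backflip_fraction=1.0))
    snap, truth = synthetic.generate_tubule_snapshot(
        spec, rng=np.random.default_rng(9))
    assert truth.backflipped <= truth.in_furrow
    assert truth.backflipped
    for i in truth.backflipped:
        name = snap.species_of_lipids()[i]
        terminal = spec.templates[name].tail_terminal_beads[-1]
        mask = (snap.lipid_id == i) & (snap.bead == terminal)
        r = np.hypot(snap.xyz[mask, 0], snap.xyz[mask, 1])
        assert r.max() > spec.r_outer


def test_trajectory_first_frame_matches_snapshot_layout():
    spec = TubuleSpec(seed=10, n_lipids_total=260, tube_length=51.0)
    frames, truth = synthetic.generate_trajectory(spec, n_frames=4)
    assert len(frames) == 4
    for k, f in enumerate(frames):
        assert f.frame_index == k
        assert f.n_lipids == 260
    # species labels never change over time
    for f in frames[1:]:
        assert (f.species == frames[0].species).all()


def test_frozen_trajectory_is_static():
    spec = TubuleSpec(seed=10, n_lipids_total=260, tube_length=51.0)
    frames, _ = synthetic.generate_trajectory(spec, n_frames=5,
                                              diffusion=0.0)
    for f in frames[1:]:
        assert np.array_equal(f.xyz, frames[0].xyz)


def test_trajectory_z_stays_in_tube():
    spec = TubuleSpec(seed=11, n_lipids_total=260, tube_length=51.0)
    frames, _ = synthetic.generate_trajectory(spec, n_frames=50,
                                              diffusion=5.0)
    for f in frames:
        assert f.xyz[:, 2].min() > -20.0
        assert f.xyz[:, 2].max() < spec.tube_length + 20.0


def test_map_family_shares_deterministic_terms():
    spec = MapSpec(seed=13)
    fam = synthetic.generate_map_family(spec)
    assert set(fam) == {"reference", "SDPC", "POPS", "CHOL", "PIP2"}
    # noise-free: variant minus reference equals the bromine term only
    clean = MapSpec(seed=13, noise_sigma=0.0)
    fam0 = synthetic.generate_map_family(clean)
    diff = fam0["CHOL"].voxels - fam0["reference"].voxels
    assert np.all(np.isfinite(diff))
    assert diff.max() > 0  # bromine adds density
    # the difference is azimuthally symmetric: rotating 90 deg changes nothing
    assert np.allclose(diff, np.rot90(diff, axes=(0, 1)), atol=1e-5)


def test_map_matches_analytic_radial_model():
    spec = MapSpec(seed=14, noise_sigma=0.0)
    dmap = synthetic.generate_density_map(spec, seed=14)
    from leafletscope import emanalysis
    prof = emanalysis.radial_average(dmap)
    model = synthetic.analytic_radial_model(spec, prof.r_grid)
    sel = prof.r_grid < 62.0  # membrane region (bilinear ring sampling
    # resolves the narrow protein shell less accurately)
    assert np.abs(prof.values[sel] - model[sel]).max() < 0.02


def test_map_spec_rejects_shells_outside_grid():
    with pytest.raises(ValidationError):
        MapSpec(shape=(64, 64, 16))  # half-extent 32 A < protein at 68 A


def test_tubule_spec_rejects_bad_geometry():
    with pytest.raises(ValidationError):
        TubuleSpec(r_inner=45.0, r_outer=25.0)
    with pytest.raises(ValidationError):
        TubuleSpec(tube_length=10.0)  # less than one helix turn
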