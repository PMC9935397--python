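"""Simulation-frame analysis: profiles, maps, tilts, composition, dynamics."""

import numpy as np
import pandas as pd
import pytest

from conftest import labels_from_truth
from leafletscope import geometry, simanalysis, synthetic
from leafletscope.model import (INNER, OUTER, RadialProfile, TubuleSnapshot,
                                ValidationError, ZoneSpec)
from leafletscope.simanalysis import Selection
from leafletscope.templates import DEFAULT_TEMPLATES


def _tail_terminals(templates):
    return {b for t in templates.values()
            for tail in t.tail_beads() for b in tail[-1:]}


@pytest.fixture(scope="module")
def frames(default_spec):
    out = []
    for k in range(3):
        snap, _ = synthetic.generate_tubule_snapshot(
            default_spec, frame_index=k, rng=np.random.default_rng(700 + k))
        _, coords, labels = geometry.analyze_frame(
            snap, default_spec.templates, ZoneSpec())
        out.append((snap, coords, labels))
    return out


def test_radial_profile_conserves_bead_count(frames):
    sel = Selection.of(beads={"PO4"}, leaflet=OUTER)
    prof = simanalysis.radial_density_profile(frames, sel)
    integral = np.trapezoid(prof.values * 2 * np.pi * prof.r_grid,
                            prof.r_grid)
    snap, coords, labels = frames[0]
    mask = (snap.bead == "PO4") & (labels.leaflet_array(snap.lipid_id)
                                   == OUTER)
    n_expected = mask.sum()  # same per frame (frames share topology)
    assert abs(integral - n_expected) / n_expected < 0.01


def test_radial_profile_peaks_at_leaflet_radius(frames, default_spec):
    sel = Selection.of(beads={"PO4"}, leaflet=OUTER)
    prof = simanalysis.radial_density_profile(frames, sel)
    peak_r = prof.r_grid[np.argmax(prof.values)]
    assert abs(peak_r - default_spec.r_outer) < 1.0


def test_empty_selection_gives_zero_profile(frames):
    sel = Selection.of(species={"SDPC"}, beads={"ROH"})  # no such combo
    with pytest.warns(UserWarning):
        prof = simanalysis.radial_density_profile(frames, sel)
    assert np.all(prof.values == 0)


def test_headgroup_map_normalized_range(frames, default_spec):
    pts = [simanalysis.headgroup_points(s, c, l, default_spec.templates)
           for s, c, l in frames]
    m = simanalysis.headgroup_density_map(
        pts, (0.0, default_spec.tube_length))
    assert m.values.min() == pytest.approx(0.0)
    assert m.values.max() == pytest.approx(1.0)
    assert m.values.shape == (len(m.theta_grid), len(m.z_grid))


def test_mirror_padding_suppresses_edge_artifact():
    # uniform synthetic (theta, z) points: without padding the KDE sags at
    # the z borders; with padding edge rows stay within 1% of the interior
    rng = np.random.default_rng(42)
    z_hi = 100.0
    n = 30000
    bw = (8.0, 4.0)  # wide kernel keeps shot noise below the 1% budget
    grid = dict(theta_spacing=5.0, z_spacing=2.0)
    pts = np.column_stack([rng.uniform(0, 360, n),
                           rng.uniform(0, z_hi, n)])
    m = simanalysis.headgroup_density_map([pts], (0.0, z_hi), bandwidth=bw,
                                          normalize=False, **grid)
    interior = m.values[:, 5:-5].mean()
    edges = np.concatenate([m.values[:, 0], m.values[:, -1]]).mean()
    assert abs(edges - interior) / interior < 0.01
    m_raw = simanalysis.headgroup_density_map([pts], (0.0, z_hi),
                                              bandwidth=bw,
                                              mirror_fraction=0.0,
                                              normalize=False, **grid)
    edges_raw = np.concatenate([m_raw.values[:, 0],
                                m_raw.values[:, -1]]).mean()
    assert abs(edges_raw - interior) / interior > 0.1


def test_tilt_distribution_integrates_to_one(frames, default_spec):
    dist = simanalysis.tilt_angle_distribution(frames,
                                               default_spec.templates)
    assert dist.density
    for key, dens in dist.density.items():
        area = np.trapezoid(dens, dist.angle_grid)
        assert area == pytest.approx(1.0, abs=1e-3), key


def test_tilt_mode_recovers_generator_mean(frames, default_spec):
    dist = simanalysis.tilt_angle_distribution(frames,
                                               default_spec.templates)
    pooled = [dist.mode(key) for key in dist.density
              if key[2] in (INNER, OUTER)]
    assert abs(np.median(pooled) - default_spec.tilt_outer.mean_deg) < 2.0


def test_tilt_sign_convention_is_leaflet_symmetric():
    # a hand-built pair: one inner and one outer POPS at the same (theta, z)
    # with radially mirrored tails must give exactly equal tilt angles
    tpl = DEFAULT_TEMPLATES["POPS"]
    order = tpl.bead_order()
    r_mid = 35.0
    xyz = []
    species, lipid_id, bead = [], [], []
    for lid, (r0, direction) in enumerate([(25.0, +1.0), (45.0, -1.0)]):
        for j, b in enumerate(order):
            species.append("POPS")
            lipid_id.append(lid)
            bead.append(b)
            if b == tpl.phosphate_bead:
                rr = r0
            elif b in tpl.headgroup_beads:
                rr = r0 - direction * 2.0
            else:
                rr = r0 + direction * (1.0 + 0.5 * j)
            # tilt purely in the (r, z) plane: offset z along the tail
            zz = 10.0 + (0.3 * j if b not in tpl.headgroup_beads else 0.0)
            xyz.append([rr, 0.0, zz])
    snap = TubuleSnapshot(species=np.array(species, dtype=object),
                          lipid_id=np.array(lipid_id),
                          bead=np.array(bead, dtype=object),
                          xyz=np.array(xyz))
    coords = geometry.to_cylindrical(snap.xyz, (0.0, 0.0))
    from leafletscope.model import LeafletLabels
    labels = LeafletLabels(leaflet={0: INNER, 1: OUTER},
                           zone={0: "other", 1: "other"})
    groups, skipped = simanalysis.tilt_angles(snap, coords, labels,
                                              DEFAULT_TEMPLATES)
    assert skipped == 0
    by_leaflet = {}
    for (sp, tail, leaflet, zone), angles in groups.items():
        by_leaflet.setdefault(leaflet, []).extend(angles)
    assert by_leaflet[INNER] == by_leaflet[OUTER]


def test_zone_composition_closure(frames, default_spec):
    comp = simanalysis.zone_composition(frames, default_spec.templates)
    filled = comp[~comp["empty_zone"]]
    sums = filled.groupby(["leaflet", "zone"])["molar_percent"].sum()
    assert np.allclose(sums.values, 100.0, atol=0.01)


def test_zone_composition_matches_generator(frames, default_spec):
    comp = simanalysis.zone_composition(frames, default_spec.templates)
    truth = default_spec.composition_outer
    got = comp[(comp.leaflet == OUTER) & (comp.zone == "other")]
    for _, row in got.iterrows():
        assert abs(row.molar_percent - 100 * truth[row.species]) < 2.0


def test_thickness_planes_bracket_midplane(frames, default_spec):
    tpl = default_spec.templates
    profs = {}
    for leaflet in (INNER, OUTER):
        for part, beads in (("glycerol", {"GL1", "GL2"}),
                            ("tails", _tail_terminals(tpl))):
            profs[(part, leaflet)] = simanalysis.radial_density_profile(
                frames, Selection.of(beads=beads, leaflet=leaflet))
    th = simanalysis.leaflet_thickness_sim(
        profs[("glycerol", INNER)], profs[("glycerol", OUTER)],
        profs[("tails", INNER)], profs[("tails", OUTER)])
    assert (th["glycerol_plane_inner"] < th["midplane"]
            < th["glycerol_plane_outer"])
    assert th["thickness_bilayer"] == pytest.approx(
        th["thickness_inner"] + th["thickness_outer"])
    # the generator is leaflet-symmetric: thicknesses within 1 A
    assert abs(th["thickness_inner"] - th["thickness_outer"]) < 1.0


def test_diffusion_frozen_trajectory_is_zero():
    spec = synthetic.TubuleSpec(seed=20, n_lipids_total=260,
                                tube_length=51.0)
    traj, truth = synthetic.generate_trajectory(spec, n_frames=60,
                                                diffusion=0.0)
    D = simanalysis.lateral_diffusion(traj, labels_from_truth(truth),
                                      spec.templates)
    assert D[INNER] == 0.0
    assert D[OUTER] == 0.0


def test_diffusion_orders_leaflets_correctly():
    spec = synthetic.TubuleSpec(seed=21, n_lipids_total=650,
                                tube_length=51.0)
    traj, truth = synthetic.generate_trajectory(
        spec, n_frames=120, diffusion={INNER: 0.2, OUTER: 1.0})
    D = simanalysis.lateral_diffusion(traj, labels_from_truth(truth),
                                      spec.templates)
    assert D[OUTER] > D[INNER] > 0


def test_average_replicates_profiles():
    grid = np.arange(0.0, 5.0, 0.5)
    p1 = RadialProfile(grid, np.ones(10))
    p2 = RadialProfile(grid, 3 * np.ones(10))
    avg = simanalysis.average_replicates([p1, p2])
    assert np.allclose(avg.values, 2.0)
    assert np.allclose(avg.uncertainty, np.sqrt(2.0))
    single = simanalysis.average_replicates([p1])
    assert np.all(np.isnan(single.uncertainty))
    with pytest.raises(ValidationError):
        simanalysis.average_replicates([])
    with pytest.raises(ValidationError):
        simanalysis.average_replicates(
            [p1, RadialProfile(grid + 1.0, np.ones(10))])


def test_average_replicates_dataframes():
    d1 = pd.DataFrame({"species": ["A", "B"], "molpct": [60.0, 40.0]})
    d2 = pd.DataFrame({"species": ["A", "B"], "molpct": [62.0, 38.0]})
    avg = simanalysis.average_replicates([d1, d2])
    assert avg.loc[0, "molpct"] == pytest.approx(61.0)
    assert avg.loc[0, "molpct_sd"] == pytest.approx(np.sqrt(2.0))
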