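"""EM map analysis: normalization, alignment, fitting, composition."""

import numpy as np
import pandas as pd
import pytest

from leafletscope import emanalysis, synthetic
from leafletscope.model import DensityMap3D, RadialProfile, ValidationError


@pytest.fixture(scope="module")
def clean_spec():
    return synthetic.MapSpec(seed=50, noise_sigma=0.0)


@pytest.fixture(scope="module")
def clean_map(clean_spec):
    return synthetic.generate_density_map(clean_spec, seed=50)


@pytest.fixture(scope="module")
def clean_profile(clean_map):
    return emanalysis.membrane_profile(clean_map, (64.0, 72.0))


def test_radial_average_of_uniform_rings():
    # a synthetic 2D image with a single bright ring
    n = 128
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(xx - (n - 1) / 2, yy - (n - 1) / 2)
    img = np.exp(-((r - 30.0) ** 2) / (2 * 2.0 ** 2))
    prof = emanalysis.radial_average(img)
    # bins are centered at (k + 0.5) pixels, so the peak can be half a
    # bin away
    assert abs(prof.r_grid[np.argmax(prof.values)] - 30.0) <= 0.5
    assert prof.values.max() == pytest.approx(1.0, abs=0.05)


def test_normalization_sets_protein_to_one(clean_map):
    norm = emanalysis.normalize_map_to_protein(clean_map, (64.0, 72.0))
    prof = emanalysis.radial_average(norm)
    sel = (prof.r_grid >= 64.0) & (prof.r_grid <= 72.0)
    assert prof.values[sel].mean() == pytest.approx(1.0, abs=1e-6)
    solvent = prof.r_grid > 80.0
    assert abs(prof.values[solvent].mean()) < 0.02


def test_normalization_is_gain_and_offset_invariant(clean_map):
    scaled = DensityMap3D(3.7 * clean_map.voxels + 0.4,
                          clean_map.voxel_size,
                          helical_twist=clean_map.helical_twist,
                          helical_rise=clean_map.helical_rise)
    a = emanalysis.normalize_map_to_protein(clean_map, (64.0, 72.0))
    b = emanalysis.normalize_map_to_protein(scaled, (64.0, 72.0))
    assert np.abs(a.voxels - b.voxels).max() < 1e-4


def test_normalization_rejects_inverted_contrast(clean_map):
    inverted = DensityMap3D(-clean_map.voxels, clean_map.voxel_size)
    with pytest.raises(ValidationError):
        emanalysis.normalize_map_to_protein(inverted, (64.0, 72.0))


def test_alignment_requires_helical_metadata():
    dmap = DensityMap3D(np.zeros((16, 16, 16)), 1.0)
    with pytest.raises(ValidationError):
        emanalysis.align_slices_by_contact_sites(dmap)


def test_alignment_stacks_contact_sites():
    spec = synthetic.MapSpec(seed=51, noise_sigma=0.0, contact_amplitude=1.0)
    dmap = synthetic.generate_density_map(spec, seed=51)
    aligned = emanalysis.align_slices_by_contact_sites(dmap)
    from scipy.ndimage import map_coordinates

    def peak_theta(vox, k, radius=56.8):
        cx, cy = (vox.shape[0] - 1) / 2, (vox.shape[1] - 1) / 2
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        v = map_coordinates(vox[:, :, k].astype(float),
                            [cx + radius * np.cos(th),
                             cy + radius * np.sin(th)], order=1)
        return np.degrees(th[np.argmax(v)])

    peaks = [peak_theta(aligned.voxels, k) for k in (6, 18, 30, 42)]
    spread = max(peaks) - min(peaks)
    assert spread < 6.0


def test_central_projection_uses_central_slices():
    vox = np.zeros((16, 16, 20))
    vox[:, :, 9:11] = 1.0  # only central slices carry signal
    dmap = DensityMap3D(vox, 1.0)
    img = emanalysis.central_projection(dmap, 0.2)
    assert img.mean() == pytest.approx(0.5, abs=0.26)
    img_all = emanalysis.central_projection(dmap, 1.0)
    assert img_all.mean() == pytest.approx(0.1, abs=0.01)


def test_three_gaussian_fit_recovers_shell_parameters(clean_spec,
                                                      clean_profile):
    fit = emanalysis.fit_three_gaussians(clean_profile, (28.0, 60.0))
    truth = [s[0] for s in clean_spec.shells]
    for got, want in zip(fit.centers, truth):
        assert abs(got - want) < 0.3
    assert fit.amplitudes[1] > 0  # trough amplitude stored positive


def test_fit_rejects_window_without_trough(clean_profile):
    with pytest.raises(ValidationError):
        emanalysis.fit_three_gaussians(clean_profile, (30.0, 40.0))


def test_leaflet_areas_split_at_trough(clean_profile):
    # bound the outer zero-crossing search below the protein shell, which
    # stays positive all the way to the grid edge
    areas = emanalysis.leaflet_areas(clean_profile, split=45.0,
                                     search_lo=28.0, search_hi=62.0)
    assert areas["inner"] > 0
    assert areas["outer"] > 0
    # equal-amplitude shells, equal widths: outer leaflet covers more area
    # only through its slightly wider radial support
    total = areas["inner"] + areas["outer"]
    assert 0.3 < areas["inner"] / total < 0.7


def test_bromine_composition_recovers_truth_noise_free(clean_spec):
    fam = synthetic.generate_map_family(clean_spec)
    prr = (64.0, 72.0)
    ref = emanalysis.membrane_profile(fam["reference"], prr)
    profiles = {s: emanalysis.membrane_profile(fam[s], prr)
                for s in fam if s != "reference"}
    comp = emanalysis.bromine_composition(profiles, ref,
                                          clean_spec.br_atoms, split=45.0)
    for leaflet, truth in clean_spec.leaflet_compositions.items():
        sub = comp[comp.leaflet == leaflet]
        assert sub.molar_percent.sum() == pytest.approx(100.0, abs=1e-6)
        for _, row in sub.iterrows():
            assert abs(row.molar_percent - 100 * truth[row.species]) < 2.0


def test_bromine_composition_rejects_all_zero_excess(clean_spec):
    fam = synthetic.generate_map_family(clean_spec)
    ref = emanalysis.membrane_profile(fam["reference"], (64.0, 72.0))
    with pytest.raises(ValidationError):
        emanalysis.bromine_composition({"SDPC": ref}, ref,
                                       clean_spec.br_atoms, split=45.0)


def test_halfmap_uncertainty_dataframe():
    a = pd.DataFrame({"q": ["x", "y"], "value": [1.0, 2.0]})
    b = pd.DataFrame({"q": ["x", "y"], "value": [3.0, 4.0]})
    out = emanalysis.halfmap_uncertainty(a, b)
    assert out["value"].tolist() == [2.0, 3.0]
    assert np.allclose(out["value_sd"], np.sqrt(2.0))
    with pytest.raises(ValidationError):
        emanalysis.halfmap_uncertainty(
            a, pd.DataFrame({"q": ["x", "z"], "value": [1.0, 1.0]}))


def test_line_profiles_slice_where_expected(clean_map):
    prof = emanalysis.line_profile(clean_map, "radial_at_theta", {"theta": 0.0})
    peak = prof.r_grid[np.argmax(prof.values)]
    assert abs(peak - 68.0) < 1.5  # protein shell dominates raw intensity
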