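"""Leaflet thickness and composition from cryo-EM density maps.

The pipeline normalizes maps to the protein-shell intensity (solvent mapped
to 0), optionally rotation-aligns z slices so that the helical
membrane-protein contact sites stack axially, projects the central fraction
of the tubule, radially averages, fits the membrane annulus with three
Gaussians (two leaflet peaks and an aliphatic trough), and quantifies
per-leaflet lipid amounts from brominated-minus-reference leaflet areas
normalized by bromine atoms per molecule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .model import DensityMap3D, RadialProfile, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Radial averages and line profiles
# ---------------------------------------------------------------------------

def radial_average(data: np.ndarray | DensityMap3D,
                   center: tuple[float, float] | None = None,
                   dr: float | None = None,
                   n_theta: int = 360) -> RadialProfile:
    """Mean intensity per annulus about the filament axis.

    Accepts a 2D image or a 3D map (averaged over z).  Rings are sampled at
    ``n_theta`` azimuths with bilinear interpolation; the profile is
    truncated at the largest radius whose ring lies fully inside the grid.
    Distances are in Angstrom when a map is given, pixels otherwise.
    """
    if isinstance(data, DensityMap3D):
        img = data.voxels.mean(axis=2)
        scale = data.voxel_size
        if center is None:
            center = data.xy_center()
    else:
        img = np.asarray(data, dtype=float)
        scale = 1.0
        if center is None:
            center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    if dr is None:
        dr = scale
    if not (0 <= center[0] < img.shape[0] and 0 <= center[1] < img.shape[1]):
        raise ValidationError("center lies outside the image")

    r_max_pix = min(center[0], img.shape[0] - 1 - center[0],
                    center[1], img.shape[1] - 1 - center[1])
    dr_pix = dr / scale
    n_bins = int(np.floor(r_max_pix / dr_pix))
    radii_pix = (np.arange(n_bins) + 0.5) * dr_pix
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ci = center[0] + radii_pix[:, None] * np.cos(theta)[None, :]
    cj = center[1] + radii_pix[:, None] * np.sin(theta)[None, :]
    samples = ndimage.map_coordinates(img, [ci.ravel(), cj.ravel()], order=1)
    values = samples.reshape(n_bins, n_theta).mean(axis=1)
    return RadialProfile(radii_pix * scale, values, label="radial_average")


def line_profile(dmap: DensityMap3D, direction: str,
                 position: dict) -> RadialProfile:
    """1D intensity profile through the map.

    ``direction="radial_at_theta"`` samples along radius at fixed azimuth
    (keys: ``theta`` degrees, optional ``z`` Angstrom, defaults to the map
    center slice).  ``direction="axial_at_r_theta"`` samples along z at a
    fixed (r, theta) point (keys: ``r``, ``theta``).
    """
    vox = dmap.voxels.astype(float)
    vs = dmap.voxel_size
    cx, cy = dmap.xy_center()
    nz = vox.shape[2]
    if direction == "radial_at_theta":
        th = np.deg2rad(position["theta"])
        zi = position.get("z", (nz - 1) / 2.0 * vs) / vs
        zi = min(max(zi, 0), nz - 1)
        r_max = min(cx, cy) * vs
        r = np.arange(0, r_max, vs)
        ci = cx + (r / vs) * np.cos(th)
        cj = cy + (r / vs) * np.sin(th)
        vals = ndimage.map_coordinates(vox, [ci, cj, np.full_like(ci, zi)],
                                       order=1)
        return RadialProfile(r, vals,
                             label=f"radial@theta={position['theta']:.1f}")
    if direction == "axial_at_r_theta":
        th = np.deg2rad(position["theta"])
        ci = cx + (position["r"] / vs) * np.cos(th)
        cj = cy + (position["r"] / vs) * np.sin(th)
        if not (0 <= ci <= vox.shape[0] - 1 and 0 <= cj <= vox.shape[1] - 1):
            raise ValidationError("line exits the grid")
        z = np.arange(nz) * vs
        vals = ndimage.map_coordinates(
            vox, [np.full(nz, ci), np.full(nz, cj), np.arange(nz)], order=1)
        return RadialProfile(z, vals, label="axial")
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Normalization and alignment
# ---------------------------------------------------------------------------

def normalize_map_to_protein(dmap: DensityMap3D,
                             protein_r_range: tuple[float, float],
                             solvent_r_min: float | None = None) -> DensityMap3D:
    """Scale so the protein shell averages 1 and the solvent plateau is 0.

    The solvent plateau is the mean radial intensity beyond ``solvent_r_min``
    (default: the outermost 10% of usable radii).
    """
    prof = radial_average(dmap)
    r = prof.r_grid
    if solvent_r_min is None:
        solvent_r_min = r[-1] - 0.1 * (r[-1] - r[0])
    solvent = prof.values[r >= solvent_r_min].mean()
    in_protein = (r >= protein_r_range[0]) & (r <= protein_r_range[1])
    if not in_protein.any():
        raise ValidationError("protein radius range outside the grid")
    protein = prof.values[in_protein].mean()
    if protein <= solvent:
        raise ValidationError(
            f"protein shell mean ({protein:.4g}) <= solvent mean "
            f"({solvent:.4g}); normalization undefined")
    scaled = (dmap.voxels - solvent) / (protein - solvent)
    return DensityMap3D(scaled.astype(np.float32), dmap.voxel_size,
                        origin=dmap.origin, helical_twist=dmap.helical_twist,
                        helical_rise=dmap.helical_rise,
                        subunits_per_turn=dmap.subunits_per_turn)


def align_slices_by_contact_sites(dmap: DensityMap3D,
                                  z_ref: float | None = None) -> DensityMap3D:
    """Rotate each z slice so the helical contact sites stack axially.

    Slice at height z is rotated in-plane by ``-(twist/rise) * (z - z_ref)``
    about the grid center (bilinear interpolation); afterwards the
    contact-site azimuth is z-independent.  ``z_ref`` defaults to the center
    slice.
    """
    if dmap.helical_twist is None or dmap.helical_rise is None:
        raise ValidationError("map lacks helical twist/rise parameters")
    vs = dmap.voxel_size
    nz = dmap.voxels.shape[2]
    if z_ref is None:
        z_ref = (nz - 1) / 2.0 * vs
    out = np.empty_like(dmap.voxels, dtype=float)
    rate = dmap.helical_twist / dmap.helical_rise  # deg per Angstrom
    for k in range(nz):
        angle = -rate * (k * vs - z_ref)
        # scipy rotates about the array center in the (x, y) plane
        out[:, :, k] = ndimage.rotate(dmap.voxels[:, :, k].astype(float),
                                      angle, reshape=False, order=1,
                                      mode="nearest")
    return DensityMap3D(out.astype(np.float32), vs, origin=dmap.origin,
                        helical_twist=dmap.helical_twist,
                        helical_rise=dmap.helical_rise,
                        subunits_per_turn=dmap.subunits_per_turn)


def central_projection(dmap: DensityMap3D, fraction: float = 0.30) -> np.ndarray:
    """Mean of the central ``fraction`` of z slices (at least one)."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    nz = dmap.voxels.shape[2]
    n = max(int(np.floor(fraction * nz)), 1)
    lo = (nz - n) // 2
    return dmap.voxels[:, :, lo:lo + n].mean(axis=2).astype(float)


# ---------------------------------------------------------------------------
# Three-Gaussian leaflet-thickness fit
# ---------------------------------------------------------------------------

@dataclass
class GaussianFitResult:
    """Peak-trough-peak decomposition of a membrane radial profile.

    Components ordered by center: inner-leaflet peak (+), aliphatic trough
    (-), outer-leaflet peak (+).  Leaflet thicknesses are peak-to-trough
    distances.
    """

    amplitudes: tuple[float, float, float]
    centers: tuple[float, float, float]
    widths: tuple[float, float, float]
    window: tuple[float, float]
    residual_norm: float

    def __post_init__(self) -> None:
        mu1, mu2, mu3 = self.centers
        if not (mu1 < mu2 < mu3):
            raise ValidationError(
                f"fit ordering violated: centers {self.centers}")
        if any(w <= 0 for w in self.widths):
            raise ValidationError("fit widths must be positive")

    @property
    def thickness_inner(self) -> float:
        return self.centers[1] - self.centers[0]

    @property
    def thickness_outer(self) -> float:
        return self.centers[2] - self.centers[1]

    @property
    def asymmetry(self) -> float:
        """Outer-minus-inner leaflet thickness (positive = inner thinner)."""
        return self.thickness_outer - self.thickness_inner


def _three_gauss(r, a1, m1, s1, a2, m2, s2, a3, m3, s3):
    g = lambda a, m, s: a * np.exp(-((r - m) ** 2) / (2 * s ** 2))
    return g(a1, m1, s1) - g(a2, m2, s2) + g(a3, m3, s3)


def fit_three_gaussians(profile: RadialProfile,
                        window: tuple[float, float]) -> GaussianFitResult:
    """Least-squares peak - trough + peak fit of the membrane annulus.

    Initialized from the window's argmax / argmin / argmax structure; all
    amplitudes are constrained positive (the trough enters with a negative
    sign).  Centers are bounded by that structure (each peak stays on its
    side of the trough) and widths are capped at a membrane-scale 8 A, so
    the outer peak cannot widen to absorb density rising toward the protein
    shell at the window edge.
    """
    r, v = profile.r_grid, profile.values
    m = (r >= window[0]) & (r <= window[1])
    if m.sum() < 9:
        raise ValidationError("fit window contains too few profile points")
    rw, vw = r[m], v[m]
    i_min = int(np.argmin(vw))
    if i_min <= 1 or i_min >= len(vw) - 2:
        raise ValidationError(
            "fit window does not contain two maxima flanking a minimum")
    i_lo = int(np.argmax(vw[:i_min]))
    i_hi = i_min + 1 + int(np.argmax(vw[i_min + 1:]))
    p0 = [max(vw[i_lo], 1e-3), rw[i_lo], 3.0,
          max(vw[i_lo] - vw[i_min], 1e-3), rw[i_min], 3.0,
          max(vw[i_hi], 1e-3), rw[i_hi], 3.0]
    w_max = min(8.0, window[1] - window[0])
    lb = [0, window[0], 0.3,
          0, rw[i_lo], 0.3,
          0, rw[i_min], 0.3]
    ub = [np.inf, rw[i_min], w_max,
          np.inf, rw[i_hi], w_max,
          np.inf, window[1], w_max]
    try:
        popt, _ = curve_fit(_three_gauss, rw, vw, p0=p0, bounds=(lb, ub),
                            maxfev=20000)
    except RuntimeError as exc:
        raise ValidationError(f"three-Gaussian fit did not converge: {exc}")
    resid = float(np.linalg.norm(_three_gauss(rw, *popt) - vw))
    return GaussianFitResult(
        amplitudes=(popt[0], popt[3], popt[6]),
        centers=(popt[1], popt[4], popt[7]),
        widths=(popt[2], popt[5], popt[8]),
        window=window, residual_norm=resid)


# ---------------------------------------------------------------------------
# Leaflet areas and bromine-difference composition
# ---------------------------------------------------------------------------

def leaflet_areas(profile: RadialProfile, split: float,
                  search_lo: float | None = None,
                  search_hi: float | None = None) -> dict[str, float]:
    """Area of each leaflet's curve above 0, split at the trough radius.

    The inner area integrates max(value, 0) from the zero crossing below the
    inner peak up to ``split``; the outer area from ``split`` to the zero
    crossing above the outer peak (trapezoidal rule on the profile grid).
    ``search_lo``/``search_hi`` bound the zero-crossing search (default: the
    profile ends).
    """
    r, v = profile.r_grid, profile.values
    if not (r[0] <= split <= r[-1]):
        raise ValidationError("split radius outside the profile")
    lo_bound = search_lo if search_lo is not None else r[0]
    hi_bound = search_hi if search_hi is not None else r[-1]

    def zero_below(idx_peak):
        for i in range(idx_peak, -1, -1):
            if v[i] <= 0 or r[i] < lo_bound:
                return i
        return 0

    def zero_above(idx_peak):
        for i in range(idx_peak, len(v)):
            if v[i] <= 0 or r[i] > hi_bound:
                return i
        return len(v) - 1

    i_split = int(np.searchsorted(r, split))
    inner_side = v[:i_split]
    outer_side = v[i_split:]
    out = {"inner": 0.0, "outer": 0.0}
    if inner_side.size and np.any(inner_side > 0):
        i_peak = int(np.argmax(inner_side))
        i0 = zero_below(i_peak)
        seg = slice(i0, i_split + 1)
        out["inner"] = float(np.trapezoid(np.maximum(v[seg], 0.0), r[seg]))
    else:
        logger.warning("no positive region on the inner side; area 0")
    if outer_side.size and np.any(outer_side > 0):
        i_peak = i_split + int(np.argmax(outer_side))
        i1 = zero_above(i_peak)
        seg = slice(i_split, i1 + 1)
        out["outer"] = float(np.trapezoid(np.maximum(v[seg], 0.0), r[seg]))
    else:
        logger.warning("no positive region on the outer side; area 0")
    return out


def bromine_composition(profiles: dict[str, RadialProfile],
                        reference: RadialProfile,
                        br_atoms: dict[str, float],
                        split: float) -> pd.DataFrame:
    """Per-leaflet molar composition from bromine excess areas.

    For each brominated species the per-leaflet area above zero of its
    profile, minus the same leaflet's area in the unbrominated reference, is
    the excess scattering attributable to its bromine atoms.  Excesses are
    normalized by bromine atoms per molecule and expressed as percentages
    summing to 100 mol% within each leaflet.  Negative excesses are clamped
    to zero (logged).  All profiles must already be normalized to the
    protein intensity.
    """
    ref_areas = leaflet_areas(reference, split)
    rows = []
    for leaflet in ("inner", "outer"):
        amounts = {}
        for sp, prof in profiles.items():
            if br_atoms.get(sp, 0.0) <= 0:
                raise ValidationError(f"{sp}: bromine count must be positive")
            excess = leaflet_areas(prof, split)[leaflet] - ref_areas[leaflet]
            if excess < 0:
                logger.warning("negative bromine excess for %s/%s (%.3g); "
                               "clamped to 0", sp, leaflet, excess)
                excess = 0.0
            amounts[sp] = excess / br_atoms[sp]
        total = sum(amounts.values())
        if total == 0:
            raise ValidationError(
                f"all bromine amounts are zero in the {leaflet} leaflet; "
                "composition undefined")
        for sp, amt in amounts.items():
            rows.append({"leaflet": leaflet, "species": sp,
                         "excess_area": amt * br_atoms[sp],
                         "br_normalized_amount": amt,
                         "molar_percent": 100.0 * amt / total})
    return pd.DataFrame(rows)


def halfmap_uncertainty(result_a, result_b):
    """Cellwise mean and sample sd between two half-map analyses."""
    if isinstance(result_a, pd.DataFrame):
        keys = [c for c in result_a.columns
                if not pd.api.types.is_numeric_dtype(result_a[c])]
        if list(result_a.columns) != list(result_b.columns) or \
                not result_a[keys].equals(result_b[keys]):
            raise ValidationError("half-map result tables are not congruent")
        out = result_a[keys].copy()
        for c in result_a.columns:
            if c in keys:
                continue
            stack = np.stack([result_a[c].to_numpy(dtype=float),
                              result_b[c].to_numpy(dtype=float)])
            out[c] = stack.mean(axis=0)
            out[c + "_sd"] = stack.std(axis=0, ddof=1)
        return out
    a = np.asarray(result_a, dtype=float)
    b = np.asarray(result_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("half-map results have mismatched shapes")
    stack = np.stack([a, b])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# End-to-end map pipeline helpers
# ---------------------------------------------------------------------------

def membrane_profile(dmap: DensityMap3D,
                     protein_r_range: tuple[float, float],
                     align_contacts: bool = False,
                     projection_fraction: float = 0.30) -> RadialProfile:
    """Normalize, optionally align, project and radially average one map."""
    dmap = normalize_map_to_protein(dmap, protein_r_range)
    if align_contacts:
        dmap = align_slices_by_contact_sites(dmap)
    image = central_projection(dmap, projection_fraction)
    prof = radial_average(image, center=dmap.xy_center())
    return RadialProfile(prof.r_grid * dmap.voxel_size, prof.values,
                         label="membrane_profile")
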