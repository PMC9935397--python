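"""Simulation-derived observables of the tubule bilayer.

Radial bead-density profiles (volume-corrected Gaussian KDE), 2D headgroup
surface-density maps with mirror padding, tail tilt-angle distributions
against the signed radial normal, zone-resolved molar compositions,
leaflet-thickness estimates from component densities, lateral diffusion from
surface mean-squared displacements, and replicate averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

from . import geometry
from .model import (CONTACT, GAP, INNER, OTHER, OUTER, CylindricalCoords,
                    LeafletLabels, RadialProfile, TubuleSnapshot,
                    ValidationError, ZoneSpec)
from .templates import LipidTemplate

LEAFLETS = (INNER, OUTER)
ZONES = (CONTACT, GAP, OTHER)


# ---------------------------------------------------------------------------
# Radial density profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Bead selection for radial profiles: species, bead labels, leaflet, zone.

    ``None`` fields are wildcards.  ``zone=None`` selects all zones.
    """

    species: frozenset[str] | None = None
    beads: frozenset[str] | None = None
    leaflet: str | None = None
    zone: str | None = None

    @staticmethod
    def of(species=None, beads=None, leaflet=None, zone=None) -> "Selection":
        f = lambda v: None if v is None else frozenset(
            [v] if isinstance(v, str) else v)
        return Selection(f(species), f(beads), leaflet, zone)


def _selection_mask(snapshot: TubuleSnapshot, labels: LeafletLabels,
                    sel: Selection) -> np.ndarray:
    mask = np.ones(snapshot.n_beads, dtype=bool)
    if sel.species is not None:
        mask &= np.isin(snapshot.species.astype(str), list(sel.species))
    if sel.beads is not None:
        mask &= np.isin(snapshot.bead.astype(str), list(sel.beads))
    if sel.leaflet is not None:
        mask &= labels.leaflet_array(snapshot.lipid_id) == sel.leaflet
    if sel.zone is not None:
        mask &= labels.zone_array(snapshot.lipid_id) == sel.zone
    return mask


def _kde_1d(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE with an absolute bandwidth, evaluated on ``grid``."""
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(values.reshape(-1, 1))
    return np.exp(kde.score_samples(grid.reshape(-1, 1)))


def radial_density_profile(
    frames: list[tuple[TubuleSnapshot, CylindricalCoords, LeafletLabels]],
    selection: Selection,
    kde_bandwidth: float = 0.5,
    r_max: float = 80.0,
    dr: float = 0.2,
    label: str = "",
) -> RadialProfile:
    """Volume-corrected radial density of the selected beads.

    A Gaussian KDE (bandwidth in Angstrom) over the pooled radial coordinates
    is converted to an expected bead count per radial bin (mean per frame),
    then divided by the annular volume factor 2*pi*r*dr, so that
    ``sum(rho * 2*pi*r*dr)`` recovers the per-frame selected bead count up to
    KDE truncation at the grid bounds.  The grid starts at the first positive
    point (r = 0 has zero annular volume).
    """
    r_grid = np.arange(dr, r_max + dr / 2, dr)
    r_values = []
    for snapshot, coords, labels in frames:
        mask = _selection_mask(snapshot, labels, selection)
        r_values.append(coords.r[mask])
    r_all = np.concatenate(r_values) if r_values else np.empty(0)
    n_per_frame = len(r_all) / max(len(frames), 1)
    if len(r_all) == 0:
        warnings.warn(f"empty selection {selection}; zero profile", stacklevel=2)
        return RadialProfile(r_grid, np.zeros_like(r_grid), label=label)
    pdf = _kde_1d(r_all, r_grid, kde_bandwidth)
    rho = n_per_frame * pdf * dr / (2 * np.pi * r_grid * dr)
    return RadialProfile(r_grid, rho, label=label)


# ---------------------------------------------------------------------------
# Headgroup surface-density maps
# ---------------------------------------------------------------------------

@dataclass
class SurfaceDensityMap:
    """Normalized headgroup density on the (theta, z) tubule surface."""

    theta_grid: np.ndarray   # degrees, 1 deg spacing
    z_grid: np.ndarray       # Angstrom, 0.835 A spacing
    values: np.ndarray       # (n_theta, n_z), min-max normalized to [0, 1]

    def mean_inside_wedge(self, theta_centerline, halfwidth_deg: float
                          ) -> tuple[float, float]:
        """Mean map value inside vs outside a helical wedge (for furrow checks)."""
        tc = np.asarray(theta_centerline(self.z_grid), dtype=float)
        d = geometry.circular_distance_deg(self.theta_grid[:, None], tc[None, :])
        inside = d <= halfwidth_deg
        return float(self.values[inside].mean()), float(self.values[~inside].mean())


def headgroup_points(snapshot: TubuleSnapshot, coords: CylindricalCoords,
                     labels: LeafletLabels, templates: dict[str, LipidTemplate],
                     species: set[str] | None = None,
                     leaflet: str = OUTER) -> np.ndarray:
    """(theta, z) of headgroup reference beads of the selected leaflet."""
    mask = np.zeros(snapshot.n_beads, dtype=bool)
    for name, tpl in templates.items():
        if tpl.headgroup_reference_bead is None:
            continue
        if species is not None and name not in species:
            continue
        mask |= ((snapshot.species == name)
                 & (snapshot.bead == tpl.headgroup_reference_bead))
    mask &= labels.leaflet_array(snapshot.lipid_id) == leaflet
    return np.column_stack([coords.theta[mask], coords.z[mask]])


def _mirror_pad(points: np.ndarray, lo: float, hi: float, axis: int,
                fraction: float) -> np.ndarray:
    band = fraction * (hi - lo)
    near_lo = points[points[:, axis] <= lo + band].copy()
    near_lo[:, axis] = 2 * lo - near_lo[:, axis]
    near_hi = points[points[:, axis] >= hi - band].copy()
    near_hi[:, axis] = 2 * hi - near_hi[:, axis]
    return np.vstack([points, near_lo, near_hi])


def headgroup_density_map(
    points_per_replicate: list[np.ndarray],
    z_range: tuple[float, float],
    theta_spacing: float = 1.0,
    z_spacing: float = 0.835,
    mirror_fraction: float = 0.15,
    bandwidth: tuple[float, float] | None = None,
    normalize: bool = True,
) -> SurfaceDensityMap:
    """2D KDE of headgroup (theta, z) positions, replicate-averaged.

    Positions within ``mirror_fraction`` of each border are mirrored outward
    before the KDE to suppress edge artifacts, and the evaluated map is
    trimmed back to the original box.  The default bandwidth is two grid
    spacings in theta and 1.5 in z (the axes are treated independently in
    their own units): wide enough to smooth shot noise, narrow enough to
    resolve a helical depletion stripe whose z-thickness is only a few
    angstroms given the steep helix pitch, which a global plug-in rule such
    as Silverman's oversmooths on these near-uniform angular data.  The
    averaged map is min-max normalized to [0, 1] unless ``normalize`` is
    False (raw densities are needed e.g. to quantify edge artifacts).
    """
    theta_grid = np.arange(0.0, 360.0, theta_spacing)
    z_lo, z_hi = z_range
    z_grid = np.arange(z_lo, z_hi + 1e-9, z_spacing)
    mesh = np.column_stack([g.ravel() for g in
                            np.meshgrid(theta_grid, z_grid, indexing="ij")])

    maps = []
    for pts in points_per_replicate:
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 10:
            warnings.warn(f"only {len(pts)} headgroup points; map is noisy",
                          stacklevel=2)
        if len(pts) == 0:
            maps.append(np.zeros((len(theta_grid), len(z_grid))))
            continue
        exp_pts = _mirror_pad(pts, 0.0, 360.0, 0, mirror_fraction)
        exp_pts = _mirror_pad(exp_pts, z_lo, z_hi, 1, mirror_fraction)
        bw = (2.0 * theta_spacing, 1.5 * z_spacing) if bandwidth is None \
            else bandwidth
        scaled = exp_pts / np.asarray(bw)
        kde = KernelDensity(kernel="gaussian", bandwidth=1.0).fit(scaled)
        dens = np.exp(kde.score_samples(mesh / np.asarray(bw)))
        maps.append(dens.reshape(len(theta_grid), len(z_grid)))

    mean_map = np.mean(maps, axis=0)
    if normalize:
        lo, hi = mean_map.min(), mean_map.max()
        mean_map = ((mean_map - lo) / (hi - lo) if hi > lo
                    else np.zeros_like(mean_map))
    return SurfaceDensityMap(theta_grid, z_grid, mean_map)


# ---------------------------------------------------------------------------
# Tilt-angle distributions
# ---------------------------------------------------------------------------

@dataclass
class TiltDistribution:
    """Tail tilt-angle densities per (species, tail index, leaflet, zone).

    Angles are measured between each tail vector (phosphate bead -> last tail
    bead) and the signed radial membrane normal: +r for the inner leaflet,
    -r for the outer, so 0 deg means membrane-normal in both leaflets.
    Densities are Gaussian-KDE estimates renormalized to integrate to 1 on
    the evaluation grid.
    """

    angle_grid: np.ndarray
    density: dict[tuple[str, int, str, str], np.ndarray] = field(default_factory=dict)
    mean_angle: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    n_skipped: int = 0

    def mode(self, key) -> float:
        """Grid mode with a 3-point parabolic refinement."""
        d = self.density[key]
        i = int(np.argmax(d))
        if 0 < i < len(d) - 1:
            y0, y1, y2 = d[i - 1], d[i], d[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            step = self.angle_grid[1] - self.angle_grid[0]
            return float(self.angle_grid[i] + np.clip(shift, -1, 1) * step)
        return float(self.angle_grid[i])


def tilt_angles(snapshot: TubuleSnapshot, coords: CylindricalCoords,
                labels: LeafletLabels, templates: dict[str, LipidTemplate],
                ) -> tuple[dict[tuple[str, int, str, str], list[float]], int]:
    """Raw tilt angles grouped by (species, tail, leaflet, zone)."""
    groups: dict[tuple[str, int, str, str], list[float]] = {}
    skipped = 0
    theta_rad = np.deg2rad(coords.theta)
    rhat = np.column_stack([np.cos(theta_rad), np.sin(theta_rad),
                            np.zeros_like(theta_rad)])
    xyz = coords.to_cartesian()

    for name, tpl in templates.items():
        if tpl.is_sterol:
            continue
        ref_idx = np.flatnonzero((snapshot.species == name)
                                 & (snapshot.bead == tpl.phosphate_bead))
        ref_by_lid = {int(snapshot.lipid_id[i]): i for i in ref_idx}
        for ti, terminal in enumerate(tpl.tail_terminal_beads):
            term_idx = np.flatnonzero((snapshot.species == name)
                                      & (snapshot.bead == terminal))
            for j in term_idx:
                lid = int(snapshot.lipid_id[j])
                i = ref_by_lid.get(lid)
                if i is None:
                    continue
                v = xyz[j] - xyz[i]
                norm = np.linalg.norm(v)
                if norm < 1e-12:
                    skipped += 1
                    continue
                leaflet = labels.leaflet.get(lid)
                if leaflet is None:
                    continue
                sign = 1.0 if leaflet == INNER else -1.0
                cosang = np.clip(np.dot(v / norm, sign * rhat[i]), -1.0, 1.0)
                angle = float(np.degrees(np.arccos(cosang)))
                zone = labels.zone.get(lid, OTHER)
                groups.setdefault((name, ti, leaflet, zone), []).append(angle)
    return groups, skipped


def tilt_angle_distribution(
    frames: list[tuple[TubuleSnapshot, CylindricalCoords, LeafletLabels]],
    templates: dict[str, LipidTemplate],
    kde_bandwidth: float = 0.05,
    grid_max: float = 180.0,
    grid_step: float = 0.9,
) -> TiltDistribution:
    """Per-group tilt KDE on a 0-180 deg grid, pooled over frames.

    Each group's density is renormalized to integrate to 1 (trapezoid) on the
    grid, which keeps the stated probability-density convention valid for any
    bandwidth/grid combination.
    """
    grid = np.arange(0.0, grid_max + grid_step / 2, grid_step)
    pooled: dict[tuple, list[float]] = {}
    skipped = 0
    for snapshot, coords, labels in frames:
        groups, sk = tilt_angles(snapshot, coords, labels, templates)
        skipped += sk
        for k, v in groups.items():
            pooled.setdefault(k, []).extend(v)

    dist = TiltDistribution(angle_grid=grid, n_skipped=skipped)
    for key, angles in pooled.items():
        a = np.asarray(angles)
        dens = _kde_1d(a, grid, kde_bandwidth)
        total = np.trapezoid(dens, grid)
        dist.density[key] = dens / total if total > 0 else dens
        dist.mean_angle[key] = float(a.mean())
    return dist


# ---------------------------------------------------------------------------
# Zone-resolved molar composition
# ---------------------------------------------------------------------------

def zone_composition(
    frames: list[tuple[TubuleSnapshot, CylindricalCoords, LeafletLabels]],
    templates: dict[str, LipidTemplate],
    zone_spec: ZoneSpec = ZoneSpec(),
) -> pd.DataFrame:
    """Per (leaflet, zone, species) molar composition from bead counts.

    All non-headgroup beads are gathered per zone at the bead level (each
    bead's own position decides its zone); counts are divided by the
    species' non-headgroup bead count to obtain lipid equivalents and
    normalized to 100 mol% within each (leaflet, zone).  Counts are averaged
    over frames before normalization.
    """
    counts: dict[tuple[str, str, str], float] = {}
    for snapshot, coords, labels in frames:
        leaflet_by_bead = labels.leaflet_array(snapshot.lipid_id)
        for name, tpl in templates.items():
            mask = ((snapshot.species == name)
                    & np.isin(snapshot.bead.astype(str),
                              list(tpl.nonheadgroup_beads())))
            if not mask.any():
                continue
            zones = geometry.zone_of_points(
                coords.theta[mask], coords.z[mask], snapshot.anchor_xyz,
                coords.center, zone_spec)
            for leaflet, zone in zip(leaflet_by_bead[mask], zones):
                if leaflet not in LEAFLETS:
                    continue
                key = (str(leaflet), str(zone), name)
                counts[key] = counts.get(key, 0.0) + 1.0

    n_frames = max(len(frames), 1)
    rows = []
    species_names = sorted(templates)
    for leaflet in LEAFLETS:
        for zone in ZONES:
            equiv = {s: counts.get((leaflet, zone, s), 0.0) / n_frames
                     / templates[s].nonheadgroup_bead_count
                     for s in species_names}
            total = sum(equiv.values())
            for s in species_names:
                rows.append({
                    "leaflet": leaflet, "zone": zone, "species": s,
                    "bead_count": counts.get((leaflet, zone, s), 0.0) / n_frames,
                    "lipid_equivalents": equiv[s],
                    "molar_percent": (100.0 * equiv[s] / total if total > 0
                                      else np.nan),
                    "empty_zone": total == 0,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leaflet thickness from component densities
# ---------------------------------------------------------------------------

def leaflet_thickness_sim(glycerol_inner: RadialProfile,
                          glycerol_outer: RadialProfile,
                          tails_inner: RadialProfile,
                          tails_outer: RadialProfile) -> dict[str, float]:
    """Leaflet thicknesses from glycerol planes and the tail-density midplane.

    The glycerol plane of each leaflet is the density-weighted mean radius of
    its glycerol beads; the midplane is the radius between the two planes at
    which the terminal-tail densities of the opposing leaflets cross.  Each
    tail profile is normalized to unit bead count first, so the crossing
    reflects where one leaflet's tails hand over to the other's rather than
    the (geometry-driven) difference in leaflet populations.
    """
    def plane(p: RadialProfile) -> float:
        w = p.values * p.r_grid  # bead count per bin ~ rho * 2*pi*r*dr
        if w.sum() <= 0:
            raise ValidationError("empty glycerol profile")
        return float(np.sum(p.r_grid * w) / np.sum(w))

    r_in, r_out = plane(glycerol_inner), plane(glycerol_outer)
    if not np.array_equal(tails_inner.r_grid, tails_outer.r_grid):
        raise ValidationError("tail profiles on different grids")
    g = tails_inner.r_grid
    window = (g > r_in) & (g < r_out)

    def unit(p: RadialProfile) -> np.ndarray:
        total = np.trapezoid(p.values * 2.0 * np.pi * p.r_grid, p.r_grid)
        if total <= 0:
            raise ValidationError("empty tail profile")
        return p.values / total

    diff = unit(tails_inner) - unit(tails_outer)
    dw = diff[window]
    gw = g[window]
    sign_change = np.flatnonzero(np.diff(np.sign(dw)) != 0)
    # the physical crossing is where the inner-tail density hands over to the
    # outer-tail density; take the crossing nearest the window midpoint
    if len(sign_change) == 0:
        raise ValidationError(
            "terminal-tail densities do not cross between the glycerol planes")
    mid_target = 0.5 * (r_in + r_out)
    i = sign_change[np.argmin(np.abs(gw[sign_change] - mid_target))]
    # linear interpolation of the zero
    x0, x1, y0, y1 = gw[i], gw[i + 1], dw[i], dw[i + 1]
    r_mid = float(x0 - y0 * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x0)
    return {
        "glycerol_plane_inner": r_in,
        "glycerol_plane_outer": r_out,
        "midplane": r_mid,
        "thickness_inner": r_mid - r_in,
        "thickness_outer": r_out - r_mid,
        "thickness_bilayer": r_out - r_in,
    }


# ---------------------------------------------------------------------------
# Lateral diffusion
# ---------------------------------------------------------------------------

def lateral_diffusion(
    frames: list[TubuleSnapshot],
    labels: LeafletLabels,
    templates: dict[str, LipidTemplate],
    frame_dt: float = 1.0,
    center: tuple[float, float] | None = None,
    lag_window: tuple[float, float] = (0.02, 0.20),
    max_lags: int = 40,
) -> dict[str, float]:
    """Per-leaflet lateral diffusion coefficient (A^2/ns) from surface MSD.

    Each lipid's reference bead is tracked as the surface displacement
    (Rbar * dtheta, dz) with Rbar its time-mean radius and theta unwrapped
    over time.  When the frames carry a finite box z length, z is unwrapped
    with that period as well (periodic-boundary trajectories).  MSD(tau) is
    averaged over lipids and all time origins, and D = slope/4 of a
    straight-line fit over the lag window (fractions of the trajectory
    length), weighted by 1/tau: with overlapping time origins the MSD
    variance grows roughly linearly in the lag, so short-to-intermediate
    lags carry the most information.
    """
    n_frames = len(frames)
    if n_frames < 50:
        raise ValidationError("need at least 50 frames for diffusion")
    first = frames[0]
    if center is None:
        center = (fit := geometry.fit_tubule_center(first.anchor_xyz)) \
            if len(first.anchor_xyz) >= 3 else (0.0, 0.0)
    ref_mask = first.phosphate_mask(templates, phospholipids_only=False)
    lids = first.lipid_id[ref_mask]
    order = np.argsort(lids)
    lids = lids[order]

    theta = np.empty((n_frames, len(lids)))
    z = np.empty((n_frames, len(lids)))
    r = np.empty((n_frames, len(lids)))
    for t, f in enumerate(frames):
        m = f.phosphate_mask(templates, phospholipids_only=False)
        o = np.argsort(f.lipid_id[m])
        xyz = f.xyz[m][o]
        dx, dy = xyz[:, 0] - center[0], xyz[:, 1] - center[1]
        theta[t] = np.arctan2(dy, dx)
        r[t] = np.hypot(dx, dy)
        z[t] = xyz[:, 2]
    theta = np.unwrap(theta, axis=0)
    box_z = float(first.box[2])
    if np.isfinite(box_z) and box_z > 0:
        z = np.unwrap(z, axis=0, period=box_z)
    rbar = r.mean(axis=0)
    x_surf = theta * rbar[None, :]

    lag_lo = max(1, int(lag_window[0] * n_frames))
    lag_hi = max(lag_lo + 1, int(lag_window[1] * n_frames))
    if lag_hi >= n_frames:
        raise ValidationError("lag window exceeds trajectory length")
    lags = np.unique(np.linspace(lag_lo, lag_hi, max_lags).astype(int))

    out: dict[str, float] = {}
    leaflet_of = labels.leaflet_array(lids)
    for leaflet in LEAFLETS:
        cols = leaflet_of == leaflet
        if not cols.any():
            continue
        msd = np.empty(len(lags))
        for i, lag in enumerate(lags):
            dxs = x_surf[lag:, cols] - x_surf[:-lag, cols]
            dzs = z[lag:, cols] - z[:-lag, cols]
            msd[i] = np.mean(dxs ** 2 + dzs ** 2)
        tau = lags * frame_dt
        slope, _ = np.polyfit(tau, msd, 1, w=1.0 / np.sqrt(tau))
        out[leaflet] = float(slope / 4.0)
    return out


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(results: list):
    """Pointwise/cellwise mean and sample standard deviation (n-1).

    Accepts a list of congruent ndarrays, RadialProfiles, or DataFrames
    sharing their non-numeric key columns.  A single replicate yields its own
    values with NaN standard deviation.
    """
    if len(results) == 0:
        raise ValidationError("no replicates")
    first = results[0]

    if isinstance(first, RadialProfile):
        for p in results[1:]:
            if not np.array_equal(p.r_grid, first.r_grid):
                raise ValidationError("replicate profiles on different grids")
        stack = np.vstack([p.values for p in results])
        sd = (np.std(stack, axis=0, ddof=1) if len(results) > 1
              else np.full(stack.shape[1], np.nan))
        return RadialProfile(first.r_grid, stack.mean(axis=0), uncertainty=sd,
                             label=first.label)

    if isinstance(first, pd.DataFrame):
        keys = [c for c in first.columns
                if not pd.api.types.is_numeric_dtype(first[c])]
        num = [c for c in first.columns if c not in keys]
        for df in results[1:]:
            if not df[keys].equals(first[keys]):
                raise ValidationError("replicate tables have mismatched keys")
        out = first[keys].copy()
        stack = np.stack([df[num].to_numpy(dtype=float) for df in results])
        for j, c in enumerate(num):
            out[c] = stack[:, :, j].mean(axis=0)
            out[c + "_sd"] = (stack[:, :, j].std(axis=0, ddof=1)
                              if len(results) > 1 else np.nan)
        return out

    stack = np.stack([np.asarray(x, dtype=float) for x in results])
    if any(np.asarray(x).shape != stack.shape[1:] for x in results):
        raise ValidationError("replicates have mismatched shapes")
    sd = (stack.std(axis=0, ddof=1) if len(results) > 1
          else np.full(stack.shape[1:], np.nan))
    return stack.mean(axis=0), sd
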