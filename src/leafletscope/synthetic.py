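"""Ground-truth synthetic tubules, trajectories and density maps.

The generator emulates the statistical structure that the analysis stages
assume: two concentric cylindrical leaflets with per-leaflet species
compositions, a helical lattice of protein anchor points (the
membrane-inserted Phe pair of each coat subunit), an optional
headgroup-exclusion furrow co-rotating with the anchor helix, per-leaflet
tail-tilt distributions, diffusive in-leaflet motion, and voxelized two-shell
density maps with optional per-species bromine contrast.  Every generated
object is accompanied by its ground-truth labels so downstream accuracy is
measurable by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (CONTACT, GAP, INNER, OTHER, OUTER, DensityMap3D,
                    TubuleSnapshot, ValidationError, circular_distance_deg)
from .templates import DEFAULT_TEMPLATES, LipidTemplate

# geometric constants of the bead-builder (Angstrom)
TAIL_BEAD_SPACING = 2.2
GLYCEROL_OFFSET = 2.0
HEADGROUP_SPACING = 2.0
INTERNAL_JITTER = 0.3

#: starting bulk mixture of the tubule experiments (molar fractions)
COMPOSITION_1 = {"SDPC": 0.582, "CHOL": 0.18, "POPS": 0.175, "PIP2": 0.063}
#: leaflet-enriched mixture measured on the assembled nanotube
COMPOSITION_17 = {"SDPC": 0.26, "CHOL": 0.22, "POPS": 0.32, "PIP2": 0.20}


@dataclass(frozen=True)
class TiltModel:
    """Von Mises model of tail tilt away from the membrane normal."""

    mean_deg: float = 30.0
    kappa: float = 50.0


@dataclass(frozen=True)
class FurrowSpec:
    """Helical headgroup-exclusion stripe on the outer leaflet."""

    exclusion_halfwidth_deg: float = 12.0
    exclusion_halfwidth_z: float = 1.0
    backflip_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.exclusion_halfwidth_deg < 0 or self.exclusion_halfwidth_z < 0:
            raise ValidationError("furrow halfwidths must be >= 0")
        if not 0 <= self.backflip_fraction <= 1:
            raise ValidationError("backflip_fraction must be in [0, 1]")


@dataclass
class TubuleSpec:
    """Parameters of a synthetic lipid nanotube.

    Defaults follow the constricted nanotube: reference-bead radii 25/45 A
    (lumen diameter ~40 A with an ~20 A leaflet-to-leaflet gap), a 17
    subunits-per-turn anchor helix at 55 A, 1,300 lipids with the starting
    bulk mixture in both leaflets, and 30 deg mean tail tilt.
    """

    r_inner: float = 25.0
    r_outer: float = 45.0
    tube_length: float = 102.0
    composition_inner: dict[str, float] = field(
        default_factory=lambda: dict(COMPOSITION_1))
    composition_outer: dict[str, float] = field(
        default_factory=lambda: dict(COMPOSITION_1))
    n_lipids_total: int = 1300
    subunits_per_turn: int = 17
    rise_per_subunit: float = 3.0
    anchor_radius: float = 55.0
    anchor_theta0: float = 0.0
    furrow: FurrowSpec | None = None
    tilt_inner: TiltModel = TiltModel()
    tilt_outer: TiltModel = TiltModel()
    axis_offset: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 1.0
    seed: int = 0
    templates: dict[str, LipidTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValidationError("require 0 < r_inner < r_outer")
        if self.n_lipids_total < 10:
            raise ValidationError("n_lipids_total must be >= 10")
        for name, comp in (("inner", self.composition_inner),
                           ("outer", self.composition_outer)):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} leaflet fractions must sum to 1")
        max_tail = max(
            (len(t) * TAIL_BEAD_SPACING + GLYCEROL_OFFSET
             for tpl in self.templates.values() for t in tpl.tail_beads()),
            default=0.0)
        if self.r_outer - self.r_inner < max_tail:
            raise ValidationError(
                f"leaflet gap {self.r_outer - self.r_inner:.1f} A is smaller "
                f"than the maximum tail extent {max_tail:.1f} A")
        if self.rise_per_subunit <= 0:
            raise ValidationError("rise_per_subunit must be positive")
        if self.subunits_per_turn < 3:
            raise ValidationError("subunits_per_turn must be >= 3")
        if self.tube_length < self.subunits_per_turn * self.rise_per_subunit:
            raise ValidationError("tube_length must cover at least one helix turn")

    @property
    def helix_pitch(self) -> float:
        return self.subunits_per_turn * self.rise_per_subunit

    def theta_centerline(self, z) -> np.ndarray:
        """Azimuth of the anchor helix as a function of z (degrees)."""
        return np.mod(self.anchor_theta0 + 360.0 * np.asarray(z) / self.helix_pitch,
                      360.0)

    @property
    def furrow_halfwidth_deg(self) -> float:
        """Effective angular halfwidth of the furrow stripe.

        The z halfwidth is converted to degrees through the helix slope and
        added to the angular halfwidth.
        """
        if self.furrow is None:
            return 0.0
        slope = 360.0 / self.helix_pitch
        return (self.furrow.exclusion_halfwidth_deg
                + slope * self.furrow.exclusion_halfwidth_z)


@dataclass
class TubuleGroundTruth:
    """Labels and parameters the generator built into a snapshot."""

    leaflet: dict[int, str]
    zone: dict[int, str]
    species_counts: dict[str, dict[str, int]]   # leaflet -> species -> count
    tilt_deg: dict[tuple[int, int], float]      # (lipid_id, tail index) -> angle
    in_furrow: set[int]
    backflipped: set[int]


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n items to categories matching fractions exactly.

    Integer parts are assigned first; the remaining items go to the largest
    fractional remainders (ties broken by category name for determinism).
    """
    names = sorted(fractions)
    quotas = np.array([fractions[s] * n for s in names])
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n - int(base.sum())
    order = sorted(range(len(names)), key=lambda i: (-rem[i], names[i]))
    for i in order[:short]:
        base[i] += 1
    return {s: int(c) for s, c in zip(names, base)}


def generate_anchor_helix(spec: TubuleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Anchor positions on the helical lattice.

    Returns (positions (n, 3), subunit indices).  Anchor k sits at azimuth
    ``theta0 + k * 360 / subunits_per_turn`` and height ``k * rise``.
    """
    if spec.rise_per_subunit <= 0:
        raise ValidationError("rise_per_subunit must be positive")
    if spec.subunits_per_turn < 3:
        raise ValidationError("subunits_per_turn must be >= 3")
    n = int(math.floor(spec.tube_length / spec.rise_per_subunit))
    if n < spec.subunits_per_turn:
        raise ValidationError("tube_length must cover at least one helix turn")
    k = np.arange(n)
    theta = np.deg2rad(spec.anchor_theta0 + k * 360.0 / spec.subunits_per_turn)
    x = spec.axis_offset[0] + spec.anchor_radius * np.cos(theta)
    y = spec.axis_offset[1] + spec.anchor_radius * np.sin(theta)
    z = k * spec.rise_per_subunit
    return np.column_stack([x, y, z]), k


def _sample_tilt(rng: np.random.Generator, model: TiltModel, size: int) -> np.ndarray:
    """Tilt angles (degrees in [0, 180]) from a von Mises about the mean."""
    dev = rng.vonmises(0.0, model.kappa, size=size)
    return np.clip(model.mean_deg + np.rad2deg(dev), 0.0, 180.0)


def _lattice_sites(rng: np.random.Generator, n: int, r_ref: float,
                   tube_length: float, sigma: float) -> np.ndarray:
    """n jittered (theta_deg, z) lattice sites on a cylinder of radius r_ref.

    A near-square lattice sized to the surface aspect ratio is filled with a
    random subset of cells, in random order (so consecutive lipids — which
    are grouped by species — land at uncorrelated positions).  Sites are
    jittered by ``sigma`` (converted to degrees along theta) and z wraps
    periodically.
    """
    circumference = 2.0 * math.pi * r_ref
    n_z = max(1, int(round(math.sqrt(n * tube_length / circumference))))
    n_th = max(1, int(math.ceil(n / n_z)))
    th_c = (np.arange(n_th) + 0.5) * 360.0 / n_th
    z_c = (np.arange(n_z) + 0.5) * tube_length / n_z
    cells = np.stack(np.meshgrid(th_c, z_c, indexing="ij"),
                     axis=-1).reshape(-1, 2)
    chosen = cells[rng.permutation(len(cells))[:n]]
    theta = chosen[:, 0] + rng.normal(0.0, np.degrees(sigma / r_ref), n)
    z = np.mod(chosen[:, 1] + rng.normal(0.0, sigma, n), tube_length)
    return np.column_stack([np.mod(theta, 360.0), z])


def generate_tubule_snapshot(
    spec: TubuleSpec, frame_index: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[TubuleSnapshot, TubuleGroundTruth]:
    """Build one tubule frame with ground-truth labels.

    Lipids are placed with reference beads on their leaflet cylinder plus
    Gaussian radial/positional jitter; per-leaflet species counts follow the
    requested fractions exactly (largest-remainder rounding), so they do not
    change with the seed.  Within a leaflet, lipids occupy a jittered
    near-square (theta, z) lattice: membranes pack at near-uniform area
    density (excluded volume), and fully random placement would leave
    Poisson voids larger than the inter-leaflet gap, which no real bilayer
    exhibits.  Species are assigned to lattice sites in random order, so
    zone compositions remain random samples of the mixture.  Tails extend
    toward the bilayer midplane with per-tail tilt sampled from the
    leaflet's tilt model.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    anchors, subunits = generate_anchor_helix(spec)

    n_outer = int(round(spec.n_lipids_total
                        * spec.r_outer / (spec.r_inner + spec.r_outer)))
    counts = {
        INNER: largest_remainder_counts(spec.composition_inner,
                                        spec.n_lipids_total - n_outer),
        OUTER: largest_remainder_counts(spec.composition_outer, n_outer),
    }

    species_l, lipid_l, bead_l, xyz_l = [], [], [], []
    gt_leaflet: dict[int, str] = {}
    tilt_gt: dict[tuple[int, int], float] = {}
    in_furrow: set[int] = set()
    backflipped: set[int] = set()
    x0, y0 = spec.axis_offset
    lid = 0

    for leaflet in (INNER, OUTER):
        r_ref = spec.r_inner if leaflet == INNER else spec.r_outer
        sign_mid = 1.0 if leaflet == INNER else -1.0  # midplane-ward radial sign
        tilt_model = spec.tilt_inner if leaflet == INNER else spec.tilt_outer
        n_leaf = sum(counts[leaflet].values())
        sites = _lattice_sites(rng, n_leaf, r_ref, spec.tube_length,
                               spec.noise_sigma)
        site_idx = 0
        for sp_name in sorted(counts[leaflet]):
            tpl = spec.templates[sp_name]
            tails = tpl.tail_beads()
            for _ in range(counts[leaflet][sp_name]):
                lid += 1
                gt_leaflet[lid] = leaflet
                theta, z = sites[site_idx]
                site_idx += 1
                r0 = r_ref + rng.normal(0.0, spec.noise_sigma)
                t = math.radians(theta)
                rhat = np.array([math.cos(t), math.sin(t), 0.0])
                that = np.array([-math.sin(t), math.cos(t), 0.0])
                zhat = np.array([0.0, 0.0, 1.0])
                ref_pos = np.array([x0, y0, z]) + r0 * rhat
                n_mid = sign_mid * rhat

                pos: dict[str, np.ndarray] = {tpl.phosphate_bead: ref_pos}
                # headgroup beads stack away from the midplane
                heads = [b for b in tpl.bead_order() if b in tpl.headgroup_beads]
                for j, b in enumerate(heads, start=1):
                    pos[b] = (ref_pos - j * HEADGROUP_SPACING * n_mid
                              + rng.normal(0.0, INTERNAL_JITTER, 3))
                # glycerol backbone toward the midplane
                glyc = [b for b in tpl.bead_order() if b in tpl.glycerol_beads]
                for j, b in enumerate(glyc, start=1):
                    pos[b] = (ref_pos + (j * GLYCEROL_OFFSET / max(len(glyc), 1)
                                         + GLYCEROL_OFFSET / 2) * n_mid
                              + rng.normal(0.0, INTERNAL_JITTER, 3))
                if tpl.is_sterol:
                    body = [b for b in tpl.bead_order() if b != tpl.phosphate_bead]
                    for j, b in enumerate(body, start=1):
                        pos[b] = (ref_pos + j * 1.6 * n_mid
                                  + rng.normal(0.0, INTERNAL_JITTER, 3))
                else:
                    # tails emanate from the phosphate bead along the tilted
                    # direction so that the phosphate -> terminal-bead chord
                    # realizes the sampled tilt angle exactly
                    for ti, tail in enumerate(tails):
                        alpha = float(_sample_tilt(rng, tilt_model, 1)[0])
                        tilt_gt[(lid, ti)] = alpha
                        phi = rng.uniform(0.0, 2 * math.pi)
                        d = (math.cos(math.radians(alpha)) * n_mid
                             + math.sin(math.radians(alpha))
                             * (math.cos(phi) * that + math.sin(phi) * zhat))
                        for j, b in enumerate(tail, start=1):
                            jitter = (rng.normal(0.0, INTERNAL_JITTER, 3)
                                      if j < len(tail) else 0.0)
                            pos[b] = (ref_pos + (GLYCEROL_OFFSET
                                      + j * TAIL_BEAD_SPACING) * d + jitter)

                for b in tpl.bead_order():
                    species_l.append(sp_name)
                    lipid_l.append(lid)
                    bead_l.append(b)
                    xyz_l.append(pos[b])

    species = np.array(species_l, dtype=object)
    lipid_id = np.array(lipid_l, dtype=int)
    bead = np.array(bead_l, dtype=object)
    xyz = np.array(xyz_l, dtype=float)

    if spec.furrow is not None:
        _apply_furrow(spec, species, lipid_id, bead, xyz, gt_leaflet,
                      in_furrow, backflipped, rng)

    gt_zone = _ground_truth_zones(spec, species, lipid_id, bead, xyz, gt_leaflet)
    box = np.array([2 * (spec.anchor_radius + 20.0),
                    2 * (spec.anchor_radius + 20.0), spec.tube_length])
    snap = TubuleSnapshot(species, lipid_id, bead, xyz,
                          anchor_xyz=anchors, anchor_subunit=subunits,
                          box=box, frame_index=frame_index)
    gt = TubuleGroundTruth(leaflet=gt_leaflet, zone=gt_zone,
                           species_counts={L: counts[L] for L in counts},
                           tilt_deg=tilt_gt, in_furrow=in_furrow,
                           backflipped=backflipped)
    return snap, gt


def _apply_furrow(spec, species, lipid_id, bead, xyz, gt_leaflet,
                  in_furrow, backflipped, rng) -> None:
    """Displace headgroups out of the helical wedge; backflip some sn-2 tails."""
    fur = spec.furrow
    x0, y0 = spec.axis_offset
    halfwidth = spec.furrow_halfwidth_deg

    for tpl_name, tpl in spec.templates.items():
        if tpl.is_sterol:
            continue
        ref_mask = (species == tpl_name) & (bead == tpl.phosphate_bead)
        for i in np.flatnonzero(ref_mask):
            lid = int(lipid_id[i])
            if gt_leaflet[lid] != OUTER:
                continue
            x, y, z = xyz[i]
            theta = math.degrees(math.atan2(y - y0, x - x0)) % 360.0
            theta_c = float(spec.theta_centerline(z))
            dtheta = float(circular_distance_deg(theta, theta_c))
            if dtheta > halfwidth:
                continue
            in_furrow.add(lid)
            # displace headgroup beads out of the wedge, spread over a band
            # beyond the boundary (piling them all at the rim is neither
            # physical nor resolvable)
            side = 1.0 if (theta - theta_c + 180.0) % 360.0 - 180.0 >= 0 else -1.0
            new_theta = math.radians(
                theta_c + side * (halfwidth + 1.0 + rng.uniform(0.0, 15.0)))
            head_mask = ((lipid_id == lid)
                         & np.isin(bead.astype(str), list(tpl.headgroup_beads)))
            for j in np.flatnonzero(head_mask):
                rj = math.hypot(xyz[j, 0] - x0, xyz[j, 1] - y0)
                xyz[j, 0] = x0 + rj * math.cos(new_theta)
                xyz[j, 1] = y0 + rj * math.sin(new_theta)
            if rng.uniform() < fur.backflip_fraction and len(
                    tpl.tail_terminal_beads) > 1:
                backflipped.add(lid)
                term = tpl.tail_terminal_beads[1]  # sn-2
                k = np.flatnonzero((lipid_id == lid) & (bead == term))[0]
                r_out = spec.anchor_radius + 2.0 + rng.normal(0.0, 0.5)
                xyz[k, 0] = x0 + r_out * math.cos(math.radians(theta))
                xyz[k, 1] = y0 + r_out * math.sin(math.radians(theta))


def _ground_truth_zones(spec, species, lipid_id, bead, xyz, gt_leaflet,
                        halfwidth: float = 15.0) -> dict[int, str]:
    """Zone of each lipid from its reference bead, by construction."""
    x0, y0 = spec.axis_offset
    zones: dict[int, str] = {}
    for tpl_name, tpl in spec.templates.items():
        ref_mask = (species == tpl_name) & (bead == tpl.phosphate_bead)
        for i in np.flatnonzero(ref_mask):
            lid = int(lipid_id[i])
            x, y, z = xyz[i]
            theta = math.degrees(math.atan2(y - y0, x - x0)) % 360.0
            theta_c = float(spec.theta_centerline(z))
            if circular_distance_deg(theta, theta_c) <= halfwidth:
                zones[lid] = CONTACT
            elif circular_distance_deg(theta, theta_c + 180.0) <= halfwidth:
                zones[lid] = GAP
            else:
                zones[lid] = OTHER
    return zones


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def generate_trajectory(
    spec: TubuleSpec, n_frames: int,
    diffusion: dict[str, float] | float = 1.0,
    frame_dt: float = 1.0,
) -> tuple[list[TubuleSnapshot], TubuleGroundTruth]:
    """Brownian surface dynamics on per-leaflet cylinders.

    Each lipid moves rigidly on its leaflet cylinder: per frame, the surface
    displacement (R*dtheta, dz) is drawn from Normal(0, sqrt(2 D dt)) per
    coordinate, with the leaflet's diffusion coefficient D (A^2/ns).  Both
    coordinates are periodic, as in an MD tubule with periodic boundaries
    along the axis; z wraps per lipid (molecules stay whole), and the box
    z length carries the period so displacement analyses can unwrap it.
    Reflecting walls would bias mean-squared displacements downward at long
    lags; periodic wrapping keeps them exact.
    """
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    if np.isscalar(diffusion):
        diffusion = {INNER: float(diffusion), OUTER: float(diffusion)}
    if any(d < 0 for d in diffusion.values()):
        raise ValidationError("diffusion coefficients must be >= 0")

    rng = np.random.default_rng(spec.seed)
    snap0, gt = generate_tubule_snapshot(spec, rng=rng)
    x0, y0 = spec.axis_offset
    lids = snap0.lipid_ids()
    lid_index = {int(l): i for i, l in enumerate(lids)}
    bead_lipid_row = np.array([lid_index[int(l)] for l in snap0.lipid_id])
    radius = np.array([spec.r_inner if gt.leaflet[int(l)] == INNER
                       else spec.r_outer for l in lids])
    sigma = np.array([math.sqrt(2 * diffusion[gt.leaflet[int(l)]] * frame_dt)
                      for l in lids])

    # bead coordinates relative to the axis, in cylindrical form
    dx = snap0.xyz[:, 0] - x0
    dy = snap0.xyz[:, 1] - y0
    r_b = np.hypot(dx, dy)
    th_b = np.arctan2(dy, dx)
    z_b = snap0.xyz[:, 2].copy()
    # per-lipid anchor z for whole-molecule periodic wrapping
    first_bead = np.array([np.argmax(bead_lipid_row == i)
                           for i in range(len(lids))])
    z_lip0 = z_b[first_bead]

    frames = [snap0]
    dth_tot = np.zeros(len(lids))
    dz_tot = np.zeros(len(lids))
    # lipids with D = 0 keep their exact frame-0 coordinates (no trig
    # round trip), so a frozen trajectory yields D = 0 exactly
    frozen_beads = (sigma == 0.0)[bead_lipid_row]
    for fi in range(1, n_frames):
        dth_tot += rng.normal(0.0, sigma) / radius          # radians
        dz_step = rng.normal(0.0, sigma)
        dz_tot += dz_step
        th = th_b + dth_tot[bead_lipid_row]
        # wrap the whole lipid by its reference bead so molecules stay intact
        L = spec.tube_length
        dz_wrapped = np.mod(z_lip0 + dz_tot, L) - z_lip0
        z = z_b + dz_wrapped[bead_lipid_row]
        xyz = np.column_stack([x0 + r_b * np.cos(th), y0 + r_b * np.sin(th), z])
        xyz[frozen_beads] = snap0.xyz[frozen_beads]
        frames.append(TubuleSnapshot(
            snap0.species, snap0.lipid_id, snap0.bead, xyz,
            anchor_xyz=snap0.anchor_xyz, anchor_subunit=snap0.anchor_subunit,
            box=snap0.box, frame_index=fi))
    return frames, gt


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class MapSpec:
    """Parameters of a synthetic two-shell density map.

    The default radial structure places the inner-leaflet peak at 36.8 A,
    the aliphatic trough at 45.0 A (a negative shell) and the outer-leaflet
    peak at 56.8 A, i.e. an inner leaflet 3.6 A thinner than the outer, with
    a bright protein shell outside the membrane.
    """

    shape: tuple[int, int, int] = (176, 176, 48)
    voxel_size: float = 1.0
    # (radius A, gaussian width A, amplitude); negative amplitude = trough
    shells: tuple[tuple[float, float, float], ...] = (
        (36.8, 3.0, 1.0), (45.0, 4.0, -0.35), (56.8, 3.0, 1.0))
    # narrow shell: the protein density is well separated from the membrane
    # in sharpened maps, and a wide Gaussian here would bleed into the
    # outer-leaflet region
    protein_shell: tuple[float, float, float] = (68.0, 2.5, 2.5)
    leaflet_radii: dict[str, float] = field(
        default_factory=lambda: {INNER: 36.8, OUTER: 56.8})
    leaflet_widths: dict[str, float] = field(
        default_factory=lambda: {INNER: 3.0, OUTER: 3.0})
    leaflet_compositions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            INNER: {"SDPC": 0.20, "CHOL": 0.35, "POPS": 0.30, "PIP2": 0.15},
            OUTER: {"SDPC": 0.30, "CHOL": 0.10, "POPS": 0.30, "PIP2": 0.30},
        })
    br_atoms: dict[str, float] = field(default_factory=lambda: {
        "SDPC": 12.0, "POPS": 2.0, "CHOL": 2.0, "PIP2": 4.0})
    bromine_amplitude: float = 0.03
    # helical contact-site hot spot (set amplitude 0 to disable)
    contact_amplitude: float = 0.0
    contact_radius: float = 56.8
    contact_sigma_deg: float = 12.0
    contact_sigma_r: float = 3.0
    helical_twist: float = 360.0 / 17
    helical_rise: float = 3.0
    subunits_per_turn: int = 17
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        half = min(self.shape[0], self.shape[1]) / 2.0 * self.voxel_size
        # require clean solvent beyond the outermost shell: the analysis
        # estimates its zero level there, and a shell tail reaching the grid
        # edge biases the normalization baseline
        margin = max((r + 3.0 * w + 5.0
                      for r, w, _ in self.shells + (self.protein_shell,)))
        if margin >= half:
            raise ValidationError(
                f"grid half-extent {half:.1f} A leaves no solvent margin "
                f"beyond the outermost shell (need > {margin:.1f} A)")
        for r, w, a in self.shells + (self.protein_shell,):
            if w <= 0:
                raise ValidationError("shell widths must be positive")
            if not np.isfinite(a):
                raise ValidationError("shell amplitudes must be finite")

    @property
    def pitch(self) -> float:
        return self.subunits_per_turn * self.helical_rise


def analytic_radial_model(spec: MapSpec, r: np.ndarray,
                          bromine_species: str | None = None) -> np.ndarray:
    """Closed-form azimuthally averaged radial intensity of a noise-free map."""
    r = np.asarray(r, dtype=float)
    v = np.zeros_like(r)
    for r_s, w_s, a_s in spec.shells + (spec.protein_shell,):
        v += a_s * np.exp(-((r - r_s) ** 2) / (2 * w_s ** 2))
    if bromine_species is not None:
        v += _bromine_radial(spec, r, bromine_species)
    return v


def _bromine_radial(spec: MapSpec, r: np.ndarray, species: str) -> np.ndarray:
    out = np.zeros_like(np.asarray(r, dtype=float))
    for leaflet in (INNER, OUTER):
        frac = spec.leaflet_compositions[leaflet].get(species, 0.0)
        amp = spec.bromine_amplitude * frac * spec.br_atoms[species]
        r_l, w_l = spec.leaflet_radii[leaflet], spec.leaflet_widths[leaflet]
        out += amp * np.exp(-((r - r_l) ** 2) / (2 * w_l ** 2))
    return out


def generate_density_map(spec: MapSpec,
                         bromine_species: str | None = None,
                         seed: int | None = None) -> DensityMap3D:
    """Voxelize the radial shell model (plus optional bromine term and noise).

    All non-bromine terms are deterministic functions of the spec, so a
    brominated variant differs from the reference only in its bromine term
    (and its independent noise realization).
    """
    nx, ny, nz = spec.shape
    vs = spec.voxel_size
    cx, cy = (nx - 1) / 2.0 * vs, (ny - 1) / 2.0 * vs
    x = np.arange(nx) * vs - cx
    y = np.arange(ny) * vs - cy
    r2d = np.hypot(x[:, None], y[None, :])

    plane = np.zeros((nx, ny))
    for r_s, w_s, a_s in spec.shells + (spec.protein_shell,):
        plane += a_s * np.exp(-((r2d - r_s) ** 2) / (2 * w_s ** 2))
    if bromine_species is not None:
        plane += _bromine_radial(spec, r2d, bromine_species)
    vox = np.repeat(plane[:, :, None], nz, axis=2)

    if spec.contact_amplitude != 0.0:
        theta = np.rad2deg(np.arctan2(y[None, :], x[:, None]))  # (nx, ny)
        z = np.arange(nz) * vs
        theta_c = np.mod(360.0 * z / spec.pitch, 360.0)          # (nz,)
        dth = circular_distance_deg(theta[:, :, None], theta_c[None, None, :])
        radial = np.exp(-((r2d - spec.contact_radius) ** 2)
                        / (2 * spec.contact_sigma_r ** 2))
        vox = vox + (spec.contact_amplitude * radial[:, :, None]
                     * np.exp(-dth ** 2 / (2 * spec.contact_sigma_deg ** 2)))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        vox = vox + rng.normal(0.0, spec.noise_sigma, vox.shape)

    return DensityMap3D(voxels=vox.astype(np.float32), voxel_size=vs,
                        helical_twist=spec.helical_twist,
                        helical_rise=spec.helical_rise,
                        subunits_per_turn=spec.subunits_per_turn)


def generate_map_family(spec: MapSpec) -> dict[str, DensityMap3D]:
    """Reference map plus one brominated variant per species.

    Keys: ``"reference"`` and each species name.  Noise realizations are
    independent per map (derived from the spec seed).
    """
    maps = {"reference": generate_density_map(spec, None, seed=spec.seed)}
    for i, sp in enumerate(sorted(spec.br_atoms), start=1):
        maps[sp] = generate_density_map(spec, sp, seed=spec.seed + i)
    return maps
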