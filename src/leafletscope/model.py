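"""Core domain containers shared by all analysis stages.

Coordinates are stored internally in Angstrom throughout; unit conversion
(e.g. GRO files in nm) happens only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .templates import LipidTemplate


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


@dataclass
class TubuleSnapshot:
    """One frame of a lipid-nanotube system.

    Attributes
    ----------
    species : (n_beads,) str array — species name per bead
    lipid_id : (n_beads,) int array — molecule identifier per bead
    bead : (n_beads,) str array — bead label per bead
    xyz : (n_beads, 3) float array, Angstrom
    anchor_xyz : (n_anchors, 3) float array — protein contact-residue
        positions (the membrane-inserted Phe pair of each coat subunit)
    anchor_subunit : (n_anchors,) int array
    box : (3,) float array, Angstrom
    frame_index : int
    """

    species: np.ndarray
    lipid_id: np.ndarray
    bead: np.ndarray
    xyz: np.ndarray
    anchor_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anchor_subunit: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    box: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.lipid_id = np.asarray(self.lipid_id, dtype=int)
        self.bead = np.asarray(self.bead, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.anchor_xyz = np.asarray(self.anchor_xyz, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.species)
        if not (len(self.lipid_id) == len(self.bead) == self.xyz.shape[0] == n):
            raise ValidationError("bead arrays have inconsistent lengths")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValidationError("xyz must be (n, 3)")

    @property
    def n_beads(self) -> int:
        return len(self.species)

    @property
    def n_lipids(self) -> int:
        return len(np.unique(self.lipid_id))

    def lipid_ids(self) -> np.ndarray:
        """Unique lipid ids in ascending order."""
        return np.unique(self.lipid_id)

    def species_of_lipids(self) -> dict[int, str]:
        ids, first = np.unique(self.lipid_id, return_index=True)
        return {int(i): str(self.species[j]) for i, j in zip(ids, first)}

    def select(self, species: str | None = None, bead: str | set[str] | None = None) -> np.ndarray:
        """Boolean mask over beads."""
        mask = np.ones(self.n_beads, dtype=bool)
        if species is not None:
            mask &= self.species == species
        if bead is not None:
            beads = {bead} if isinstance(bead, str) else set(bead)
            mask &= np.isin(self.bead.astype(str), list(beads))
        return mask

    def validate_against(self, templates: dict[str, LipidTemplate]) -> None:
        """Check every lipid's bead multiset against its species template."""
        for name in np.unique(self.species.astype(str)):
            if name not in templates:
                raise ValidationError(f"no template for species {name!r}")
        order = np.lexsort((self.lipid_id,))
        lid = self.lipid_id[order]
        boundaries = np.flatnonzero(np.diff(lid)) + 1
        for group in np.split(order, boundaries):
            name = str(self.species[group[0]])
            expected = sorted(templates[name].bead_order())
            got = sorted(str(b) for b in self.bead[group])
            if got != expected:
                raise ValidationError(
                    f"lipid {int(lid[group[0] if group[0] < len(lid) else 0])} "
                    f"({name}): bead set {got} does not match template {expected}"
                )

    def phosphate_mask(self, templates: dict[str, LipidTemplate],
                       phospholipids_only: bool = True) -> np.ndarray:
        """Mask of reference (phosphate / sterol-anchor) beads."""
        mask = np.zeros(self.n_beads, dtype=bool)
        for name, tpl in templates.items():
            if phospholipids_only and tpl.is_sterol:
                continue
            mask |= (self.species == name) & (self.bead == tpl.phosphate_bead)
        return mask


@dataclass
class CylindricalCoords:
    """Per-bead cylindrical coordinates about the fitted tubule axis.

    r in Angstrom (>= 0), theta in degrees in [0, 360), z in Angstrom.
    """

    r: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    center: tuple[float, float]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.mod(np.asarray(self.theta, dtype=float), 360.0)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.r < 0):
            raise ValidationError("radius must be non-negative")

    def to_cartesian(self) -> np.ndarray:
        t = np.deg2rad(self.theta)
        x = self.center[0] + self.r * np.cos(t)
        y = self.center[1] + self.r * np.sin(t)
        return np.column_stack([x, y, self.z])


INNER, OUTER = "inner", "outer"
CONTACT, GAP, OTHER = "contact", "gap", "other"


@dataclass
class LeafletLabels:
    """Per-lipid leaflet ({inner, outer}) and zone ({contact, gap, other})."""

    leaflet: dict[int, str]
    zone: dict[int, str] = field(default_factory=dict)
    degenerate: bool = False  # set when clustering looked non-bilayer-like

    def leaflet_array(self, lipid_id: np.ndarray) -> np.ndarray:
        return np.array([self.leaflet.get(int(i), "") for i in lipid_id], dtype=object)

    def zone_array(self, lipid_id: np.ndarray) -> np.ndarray:
        return np.array([self.zone.get(int(i), OTHER) for i in lipid_id], dtype=object)


@dataclass
class RadialProfile:
    """Intensity or bead density versus radius on a uniform r grid."""

    r_grid: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.r_grid):
            raise ValidationError("values and r_grid length mismatch")
        if len(self.r_grid) > 1 and not np.all(np.diff(self.r_grid) > 0):
            raise ValidationError("r_grid must be strictly increasing")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if len(self.uncertainty) != len(self.r_grid):
                raise ValidationError("uncertainty length mismatch")

    @property
    def dr(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0]) if len(self.r_grid) > 1 else np.nan


@dataclass
class DensityMap3D:
    """Voxelized 3D density with optional helical-symmetry metadata.

    voxels are indexed ``[ix, iy, iz]``; the tubule axis is z.
    """

    voxels: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    helical_twist: float | None = None   # degrees per subunit
    helical_rise: float | None = None    # Angstrom per subunit
    subunits_per_turn: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 8:
            raise ValidationError("voxel array must be 3D with every axis >= 8")
        if self.helical_twist is not None and self.subunits_per_turn:
            total = abs(self.helical_twist) * self.subunits_per_turn
            if abs(total - 360.0) > 5.0:
                warnings.warn(
                    f"twist * subunits_per_turn = {total:.1f} deg, expected ~360",
                    stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def xy_center(self) -> tuple[float, float]:
        """Geometric xy center of the grid in voxel units."""
        nx, ny, _ = self.voxels.shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)


@dataclass(frozen=True)
class ZoneSpec:
    """Angular wedges defining the Phe contact site and the opposing gap.

    The contact zone is the wedge of ``2 * wedge_halfwidth`` degrees centered
    on the anchor azimuth; the gap is the same-width wedge centered
    ``gap_offset`` degrees across.  With ``follow_helix`` the contact
    centerline co-rotates with the anchor helix as a function of z.
    """

    wedge_halfwidth: float = 15.0
    gap_offset: float = 180.0
    follow_helix: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.wedge_halfwidth <= 90:
            raise ValidationError("wedge_halfwidth must be in (0, 90]")
        # circular separation between contact and gap centerlines
        sep = abs((self.gap_offset + 180.0) % 360.0 - 180.0)
        if sep < 2 * self.wedge_halfwidth:
            raise ValidationError("contact and gap wedges overlap")


def circular_distance_deg(a, b):
    """Smallest absolute angular separation in degrees."""
    d = np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0
    return np.abs(d)
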