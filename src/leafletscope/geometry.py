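"""Leaflet assignment, tubule-frame fitting and angular zone assignment.

Leaflets are separated by single-linkage agglomerative clustering of the
phospholipid phosphate beads (cut at two clusters); sterols inherit the
leaflet of their nearest phosphate.  The tubule center is a least-squares
circle fit to the protein anchor points in the xy plane, after which all
coordinates are expressed cylindrically.  Zones (Phe contact site / gap /
other) are angular wedges about the anchor-helix centerline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .model import (CONTACT, GAP, INNER, OTHER, OUTER, CylindricalCoords,
                    LeafletLabels, TubuleSnapshot, ValidationError, ZoneSpec,
                    circular_distance_deg)
from .templates import LipidTemplate


class DegenerateGeometryError(ValueError):
    """The coordinates do not look like a two-leaflet tubule."""


def fit_tubule_center(anchors_xy: np.ndarray) -> tuple[float, float]:
    """Least-squares circle fit: the center that places all anchors
    equidistant from the axis.

    Minimizes sum_i (|a_i - c| - rbar(c))^2 over the center c, with rbar the
    mean anchor radius, via Gauss-Newton started from the anchor centroid.
    """
    pts = np.asarray(anchors_xy, dtype=float)[:, :2]
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 anchors for a circle fit")
    # collinearity check via the smaller singular value of centered points
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
                "anchors are collinear; circle fit undefined")

    def residuals(c):
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return d - d.mean()

    sol = least_squares(residuals, x0=pts.mean(axis=0), method="lm",
                        xtol=1e-14, ftol=1e-14, max_nfev=200)
    if not sol.success:
        raise RuntimeError(
            f"circle fit did not converge: residual norm {np.linalg.norm(sol.fun):.3g}")
    return float(sol.x[0]), float(sol.x[1])


def to_cylindrical(xyz: np.ndarray, center: tuple[float, float]) -> CylindricalCoords:
    """Cartesian -> cylindrical about the vertical axis through ``center``.

    theta is measured from +x, in degrees in [0, 360); r = 0 maps to theta 0.
    """
    xyz = np.asarray(xyz, dtype=float)
    dx = xyz[:, 0] - center[0]
    dy = xyz[:, 1] - center[1]
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    theta = np.where(r == 0.0, 0.0, theta)
    return CylindricalCoords(r=r, theta=theta, z=xyz[:, 2], center=center)


def assign_leaflets(snapshot: TubuleSnapshot,
                    templates: dict[str, LipidTemplate],
                    center: tuple[float, float] | None = None) -> LeafletLabels:
    """Assign every phospholipid to the inner or outer leaflet.

    Single-linkage clustering of the phosphate-bead coordinates is cut at
    exactly two clusters; the cluster with the larger mean radius about the
    tubule center is the outer leaflet.
    """
    mask = snapshot.phosphate_mask(templates, phospholipids_only=True)
    if mask.sum() < 2:
        raise ValidationError("need at least 2 phospholipid phosphate beads")
    coords = snapshot.xyz[mask]
    lids = snapshot.lipid_id[mask]

    Z = linkage(coords, method="single")
    cluster = fcluster(Z, t=2, criterion="maxclust")
    sizes = np.bincount(cluster)[1:]
    if np.count_nonzero(sizes) < 2:
        raise DegenerateGeometryError("clustering produced fewer than 2 leaflets")
    degenerate = (sizes.max() / max(sizes.min(), 1)) > 50
    if degenerate:
        warnings.warn("leaflet cluster size ratio exceeds 50:1 — geometry may "
                      "not be a bilayer", stacklevel=2)

    if center is None:
        center = (fit_tubule_center(snapshot.anchor_xyz)
                  if len(snapshot.anchor_xyz) >= 3
                  else (float(coords[:, 0].mean()), float(coords[:, 1].mean())))
    radii = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    mean_r = [radii[cluster == k].mean() for k in (1, 2)]
    outer_k = 1 if mean_r[0] > mean_r[1] else 2

    leaflet = {int(l): (OUTER if c == outer_k else INNER)
               for l, c in zip(lids, cluster)}
    return LeafletLabels(leaflet=leaflet, degenerate=bool(degenerate))


def assign_cholesterol(snapshot: TubuleSnapshot, labels: LeafletLabels,
                       templates: dict[str, LipidTemplate]) -> LeafletLabels:
    """Give each sterol the leaflet of its nearest phospholipid phosphate.

    Distance ties are broken toward the phosphate of the smaller lipid id.
    """
    phos_mask = snapshot.phosphate_mask(templates, phospholipids_only=True)
    phos_xyz = snapshot.xyz[phos_mask]
    phos_lid = snapshot.lipid_id[phos_mask]
    # order phosphates by lipid id so that, on exact ties, the tree returns
    # the first (= smallest lipid id) entry
    order = np.argsort(phos_lid, kind="stable")
    tree = cKDTree(phos_xyz[order])
    phos_lid_sorted = phos_lid[order]

    for name, tpl in templates.items():
        if not tpl.is_sterol:
            continue
        if tpl.phosphate_bead not in tpl.bead_order():
            raise ValidationError(f"sterol {name} lacks an anchor bead")
        m = (snapshot.species == name) & (snapshot.bead == tpl.phosphate_bead)
        if not m.any():
            continue
        d, idx = tree.query(snapshot.xyz[m])
        # resolve near-ties deterministically: among all phosphates within
        # 1e-9 of the minimum distance, pick the smallest lipid id
        k = tree.query_ball_point(snapshot.xyz[m], d + 1e-9)
        for lid, nearest, cand in zip(snapshot.lipid_id[m], idx, k):
            j = min(cand) if cand else nearest
            labels.leaflet[int(lid)] = labels.leaflet[int(phos_lid_sorted[j])]
    return labels


def helix_centerline(anchor_xyz: np.ndarray,
                     center: tuple[float, float]) -> tuple[float, float]:
    """Fit theta_c(z) = slope * z + intercept (degrees) to the anchor helix.

    Anchor azimuths are unwrapped along z before the straight-line fit, which
    makes the estimate robust to missing subunits.
    """
    a = np.asarray(anchor_xyz, dtype=float)
    if len(a) < 2:
        raise ValidationError("need at least 2 anchors to fit the helix")
    order = np.argsort(a[:, 2])
    z = a[order, 2]
    theta = np.degrees(np.arctan2(a[order, 1] - center[1],
                                  a[order, 0] - center[0]))
    theta = np.degrees(np.unwrap(np.radians(theta)))
    slope, intercept = np.polyfit(z, theta, 1)
    return float(slope), float(intercept)


def zone_of_points(theta: np.ndarray, z: np.ndarray, anchor_xyz: np.ndarray,
                   center: tuple[float, float],
                   zone_spec: ZoneSpec = ZoneSpec()) -> np.ndarray:
    """Zone label (contact/gap/other) for arbitrary (theta, z) points.

    Contact: within ``wedge_halfwidth`` of the contact centerline; gap:
    within the same halfwidth of the centerline shifted by ``gap_offset``.
    With ``follow_helix`` the centerline co-rotates with the anchor helix;
    otherwise it is the circular-mean anchor azimuth.  Points more than one
    helical rise outside the anchor z-range are labeled ``other``.
    """
    anchor_xyz = np.asarray(anchor_xyz, dtype=float)
    if len(anchor_xyz) == 0:
        raise ValidationError("zone assignment requires anchor points")
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)

    a_th = np.degrees(np.arctan2(anchor_xyz[:, 1] - center[1],
                                 anchor_xyz[:, 0] - center[0]))
    z_lo, z_hi = anchor_xyz[:, 2].min(), anchor_xyz[:, 2].max()
    if zone_spec.follow_helix:
        slope, intercept = helix_centerline(anchor_xyz, center)
        theta_c = slope * z + intercept
    else:
        theta_c = np.full_like(z, np.degrees(np.angle(
            np.exp(1j * np.radians(a_th)).mean())))
    z_margin = (z_hi - z_lo) / max(len(anchor_xyz) - 1, 1)

    d_contact = circular_distance_deg(theta, theta_c)
    d_gap = circular_distance_deg(theta, theta_c + zone_spec.gap_offset)
    zones = np.full(len(theta), OTHER, dtype=object)
    zones[d_contact <= zone_spec.wedge_halfwidth] = CONTACT
    zones[d_gap <= zone_spec.wedge_halfwidth] = GAP
    zones[(z < z_lo - z_margin) | (z > z_hi + z_margin)] = OTHER
    return zones


def assign_zones(coords: CylindricalCoords, lipid_id: np.ndarray,
                 ref_mask: np.ndarray, anchor_xyz: np.ndarray,
                 zone_spec: ZoneSpec = ZoneSpec()) -> dict[int, str]:
    """Zone label per lipid, decided by its reference (phosphate) bead."""
    zones = zone_of_points(coords.theta[ref_mask], coords.z[ref_mask],
                           anchor_xyz, coords.center, zone_spec)
    return {int(l): str(zn) for l, zn in zip(lipid_id[ref_mask], zones)}


def analyze_frame(snapshot: TubuleSnapshot,
                  templates: dict[str, LipidTemplate],
                  zone_spec: ZoneSpec = ZoneSpec(),
                  center: tuple[float, float] | None = None,
                  ) -> tuple[tuple[float, float], CylindricalCoords, LeafletLabels]:
    """Full per-frame geometry: center fit, leaflets, sterols, zones."""
    if center is None:
        if len(snapshot.anchor_xyz) >= 3:
            center = fit_tubule_center(snapshot.anchor_xyz)
        else:
            mask = snapshot.phosphate_mask(templates)
            center = (float(snapshot.xyz[mask, 0].mean()),
                      float(snapshot.xyz[mask, 1].mean()))
    labels = assign_leaflets(snapshot, templates, center=center)
    labels = assign_cholesterol(snapshot, labels, templates)
    coords = to_cylindrical(snapshot.xyz, center)
    ref_mask = snapshot.phosphate_mask(templates, phospholipids_only=False)
    if len(snapshot.anchor_xyz) > 0:
        labels.zone = assign_zones(coords, snapshot.lipid_id, ref_mask,
                                   snapshot.anchor_xyz, zone_spec)
    else:
        labels.zone = {int(l): OTHER for l in snapshot.lipid_ids()}
    return center, coords, labels
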