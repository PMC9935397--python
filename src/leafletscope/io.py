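"""Readers and writers for coordinates, density maps and result tables.

GRO files are read and written through MDAnalysis (nm on disk, Angstrom in
memory); density maps go through gemmi (MRC2014/CCP4).  A plain tabular CSV
dialect is provided for multi-frame trajectories so that no binary trajectory
format is needed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .model import DensityMap3D, RadialProfile, TubuleSnapshot, ValidationError
from .templates import LipidTemplate

#: residue name under which protein anchor points travel in coordinate files
ANCHOR_RESNAME = "ANC"


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# GRO coordinates
# ---------------------------------------------------------------------------

def read_snapshot(
    path: str | Path,
    templates: dict[str, LipidTemplate],
    format: str = "gro",
    anchor_resname: str = ANCHOR_RESNAME,
    on_unknown_species: str = "fail",
    validate: bool = True,
) -> TubuleSnapshot:
    """Read one coordinate frame into a :class:`TubuleSnapshot`.

    Residue name maps to species, atom name to bead label and residue number
    to lipid id.  Residues named ``anchor_resname`` become protein anchor
    points instead of beads.  ``on_unknown_species`` is ``"fail"`` or
    ``"ignore"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gro":
        snap = _read_gro(path, anchor_resname)
    elif format == "tabular":
        frames = read_trajectory_tabular(path)
        if not frames:
            raise ParseError(f"{path}: no frames")
        snap = frames[0]
    else:
        raise ValueError(f"unknown format {format!r}")

    known = set(templates)
    unknown = sorted(set(snap.species.astype(str)) - known)
    if unknown:
        if on_unknown_species == "fail":
            raise ParseError(f"{path}: unknown species {unknown}")
        keep = ~np.isin(snap.species.astype(str), unknown)
        snap = TubuleSnapshot(
            snap.species[keep], snap.lipid_id[keep], snap.bead[keep],
            snap.xyz[keep], snap.anchor_xyz, snap.anchor_subunit,
            snap.box, snap.frame_index,
        )
    if validate:
        snap.validate_against(templates)
    return snap


def _read_gro(path: Path, anchor_resname: str) -> TubuleSnapshot:
    import MDAnalysis as mda

    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        resnames = u.atoms.resnames.astype(str)
        resids = u.atoms.resids.astype(int)
        names = u.atoms.names.astype(str)
        xyz = u.atoms.positions.astype(float)  # MDAnalysis converts nm -> A
        box = (u.dimensions[:3].astype(float)
               if u.dimensions is not None else np.full(3, np.nan))
    except (ValueError, IndexError, EOFError) as exc:
        raise ParseError(f"{path}: could not parse GRO file: {exc}") from exc

    is_anchor = resnames == anchor_resname
    return TubuleSnapshot(
        species=resnames[~is_anchor],
        lipid_id=resids[~is_anchor],
        bead=names[~is_anchor],
        xyz=xyz[~is_anchor],
        anchor_xyz=xyz[is_anchor],
        anchor_subunit=resids[is_anchor],
        box=box,
    )


def write_snapshot(snap: TubuleSnapshot, path: str | Path, format: str = "gro",
                   anchor_resname: str = ANCHOR_RESNAME) -> None:
    """Write a snapshot; anchors are appended as ``anchor_resname`` residues."""
    path = Path(path)
    if format == "tabular":
        write_trajectory_tabular([snap], path)
        return
    if format != "gro":
        raise ValueError(f"unknown format {format!r}")
    import MDAnalysis as mda

    n_a = len(snap.anchor_xyz)
    resnames = np.concatenate([snap.species.astype(str),
                               np.full(n_a, anchor_resname)])
    names = np.concatenate([snap.bead.astype(str), np.full(n_a, "SC1")])
    resids_raw = np.concatenate([snap.lipid_id,
                                 np.asarray(snap.anchor_subunit, dtype=int)])
    xyz = np.vstack([snap.xyz, snap.anchor_xyz]) if n_a else snap.xyz

    # map (raw resid, block) pairs to consecutive residue indices
    block = np.concatenate([np.zeros(len(snap.lipid_id), int), np.ones(n_a, int)])
    keys = list(zip(block.tolist(), resids_raw.tolist()))
    uniq: dict[tuple, int] = {}
    resindex = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        resindex[i] = uniq.setdefault(k, len(uniq))
    n_res = len(uniq)
    res_ids = np.empty(n_res, dtype=int)
    res_names = np.empty(n_res, dtype=object)
    for i, k in enumerate(keys):
        res_ids[resindex[i]] = k[1]
        res_names[resindex[i]] = resnames[i]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(len(keys), n_residues=n_res,
                               atom_resindex=resindex,
                               residue_segindex=np.zeros(n_res, int),
                               trajectory=True)
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", res_names.astype(str))
        u.add_TopologyAttr("resids", res_ids)
        u.atoms.positions = xyz
        box = snap.box if np.all(np.isfinite(snap.box)) else np.array([1., 1., 1.])
        u.dimensions = np.concatenate([box, [90.0, 90.0, 90.0]])
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Tabular trajectories (plain CSV, one row per bead/anchor per frame)
# ---------------------------------------------------------------------------

def write_trajectory_tabular(frames: list[TubuleSnapshot], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for f in frames:
        for sp, lid, bd, p in zip(f.species, f.lipid_id, f.bead, f.xyz):
            rows.append((f.frame_index, "bead", sp, int(lid), bd, *p))
        for su, p in zip(f.anchor_subunit, f.anchor_xyz):
            rows.append((f.frame_index, "anchor", ANCHOR_RESNAME, int(su), "SC1", *p))
    df = pd.DataFrame(rows, columns=["frame", "kind", "species", "lipid_id",
                                     "bead", "x", "y", "z"])
    box = frames[0].box
    with open(path, "w") as fh:
        fh.write(f"# box: {box[0]:.6f} {box[1]:.6f} {box[2]:.6f}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_trajectory_tabular(path: str | Path) -> list[TubuleSnapshot]:
    path = Path(path)
    box = np.full(3, np.nan)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# box:"):
        box = np.array([float(v) for v in first.split(":")[1].split()])
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = {"frame", "kind", "species", "lipid_id", "bead", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    frames = []
    for fi, sub in df.groupby("frame", sort=True):
        beads = sub[sub["kind"] == "bead"]
        anchors = sub[sub["kind"] == "anchor"]
        frames.append(TubuleSnapshot(
            species=beads["species"].to_numpy(dtype=object),
            lipid_id=beads["lipid_id"].to_numpy(dtype=int),
            bead=beads["bead"].to_numpy(dtype=object),
            xyz=beads[["x", "y", "z"]].to_numpy(dtype=float),
            anchor_xyz=anchors[["x", "y", "z"]].to_numpy(dtype=float),
            anchor_subunit=anchors["lipid_id"].to_numpy(dtype=int),
            box=box, frame_index=int(fi),
        ))
    return frames


# ---------------------------------------------------------------------------
# MRC / CCP4 density maps
# ---------------------------------------------------------------------------

def read_density_map(path: str | Path) -> DensityMap3D:
    """Read an MRC2014/CCP4 map; axes normalized to (x, y, z) order.

    Voxel size comes from the cell / axis sampling; the map origin honors the
    ORIGIN header words, falling back to NXSTART offsets when ORIGIN is zero.
    Anisotropic sampling beyond 1% is rejected.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2, 6):
        raise ParseError(f"{path}: unsupported MRC mode {mode}")
    nstart = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    origin_words = np.array([m.header_float(50), m.header_float(51),
                             m.header_float(52)])
    m.setup(float("nan"))  # reorder axes to XYZ, fill missing with NaN
    spacing = np.array(m.grid.spacing)
    vs = float(spacing.mean())
    if np.any(np.abs(spacing - vs) > 0.01 * vs):
        raise ValidationError(
            f"{path}: anisotropic voxel size {tuple(np.round(spacing, 4))}")
    if np.any(origin_words != 0.0):
        origin = origin_words
    else:
        origin = np.array(nstart, dtype=float) * vs
    voxels = np.array(m.grid.array, dtype=np.float32)  # indexed [x, y, z]
    return DensityMap3D(voxels=voxels, voxel_size=vs, origin=origin)


def write_density_map(dmap: DensityMap3D, path: str | Path) -> None:
    path = Path(path)
    nx, ny, nz = dmap.voxels.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid.array)[...] = dmap.voxels.astype(np.float32)
    grid.unit_cell = gemmi.UnitCell(nx * dmap.voxel_size, ny * dmap.voxel_size,
                                    nz * dmap.voxel_size, 90, 90, 90)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, w in enumerate((50, 51, 52)):
        m.set_header_float(w, float(dmap.origin[i]))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# PDB anchor extraction (thin optional reader)
# ---------------------------------------------------------------------------

def read_pdb_anchors(path: str | Path, residue_numbers: list[int],
                     atom_name: str = "CA",
                     chains: list[str] | None = None) -> np.ndarray:
    """Extract anchor coordinates (Angstrom) from an atomic model."""
    st = gemmi.read_structure(str(path))
    pts = []
    for model in st:
        for chain in model:
            if chains is not None and chain.name not in chains:
                continue
            for res in chain:
                if res.seqid.num in residue_numbers:
                    for atom in res:
                        if atom.name == atom_name:
                            pts.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    return np.asarray(pts, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Result tables and profiles
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_lines(metadata: dict | None) -> list[str]:
    meta = dict(metadata or {})
    return [f"# {k}: {meta[k]}" for k in sorted(meta)]


def write_results(result, path: str | Path, format: str = "csv",
                  metadata: dict | None = None,
                  allow_nan: bool = False, float_precision: int = 6) -> None:
    """Write a result table (DataFrame) or :class:`RadialProfile` to disk.

    Column order is deterministic, floats are fixed-precision, and a
    metadata comment block (config hash, seed, ...) precedes the data.
    NaN values are rejected unless ``allow_nan`` is set.
    """
    path = Path(path)
    if isinstance(result, RadialProfile):
        cols = {"r": result.r_grid, "value": result.values}
        if result.uncertainty is not None:
            cols["sd"] = result.uncertainty
        result = pd.DataFrame(cols)
    if not isinstance(result, pd.DataFrame):
        raise TypeError("result must be a DataFrame or RadialProfile")
    num = result.select_dtypes(include=[np.number])
    if not allow_nan and num.isna().any().any():
        bad = [c for c in num.columns if num[c].isna().any()]
        raise ValidationError(f"NaN values in columns {bad} without missing flag")
    if format == "csv":
        with open(path, "w") as fh:
            for line in _metadata_lines(metadata):
                fh.write(line + "\n")
            result.to_csv(fh, index=False, float_format=f"%.{float_precision}f")
    elif format == "json":
        payload = {"metadata": dict(metadata or {}),
                   "data": json.loads(result.to_json(orient="records"))}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}")
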