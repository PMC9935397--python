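"""End-to-end orchestration: configuration, staging, and result bundles.

A single YAML/TOML-style mapping drives all stages.  Defaults reproduce the
analysis parameters of the study: 0.5 A bandwidth / 0.2 A grid radial KDE to
80 A, 1 deg x 0.835 A surface grid with 15% mirror padding, 0.05 deg
bandwidth / 0.9 deg grid tilt KDE, 30 deg zone wedges, and central-30%
z projection for maps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emanalysis, geometry, io, simanalysis, synthetic
from .model import INNER, OUTER, ValidationError, ZoneSpec
from .templates import DEFAULT_TEMPLATES

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "zones": {"wedge_halfwidth": 15.0, "gap_offset": 180.0, "follow_helix": True},
    "kde": {"radial_bandwidth": 0.5, "radial_dr": 0.2, "radial_rmax": 80.0,
            "surface_dtheta": 1.0, "surface_dz": 0.835,
            "tilt_bandwidth": 0.05, "tilt_step": 0.9},
    "tubule": {},
    "trajectory": {"n_frames": 5, "frame_dt": 1.0,
                   "diffusion": {"inner": 1.0, "outer": 0.5}},
    "map": {},
    "em": {"protein_r_range": [64.0, 72.0], "projection_fraction": 0.30,
           "fit_window": [28.0, 60.0],
           "br_atoms": {s: t.br_atoms_per_molecule
                        for s, t in DEFAULT_TEMPLATES.items()}},
    "inputs": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_config(cfg: dict) -> ValidationReport:
    """Cross-check configuration consistency before any compute."""
    rep = ValidationReport()
    z = cfg.get("zones", {})
    try:
        ZoneSpec(z.get("wedge_halfwidth", 15.0), z.get("gap_offset", 180.0),
                 z.get("follow_helix", True))
    except (ValidationError, ValueError) as exc:
        rep.errors.append(f"zones: {exc}")
    tub = cfg.get("tubule", {})
    spt = tub.get("subunits_per_turn", 17)
    twist = cfg.get("map", {}).get("helical_twist", 360.0 / spt)
    if abs(twist * spt - 360.0) > 5.0:
        rep.warnings.append(
            f"twist * subunits_per_turn = {twist * spt:.1f} deg != 360")
    for sp, n in cfg.get("em", {}).get("br_atoms", {}).items():
        if n <= 0:
            rep.errors.append(f"em.br_atoms[{sp}] must be positive")
    for key, p in (cfg.get("inputs") or {}).items():
        paths = p.values() if isinstance(p, dict) else [p]
        for one in paths:
            if one and not Path(one).exists():
                rep.errors.append(f"inputs.{key}: missing file {one}")
    for name, comp in (("composition_inner", tub.get("composition_inner")),
                       ("composition_outer", tub.get("composition_outer"))):
        if comp is not None:
            for sp in comp:
                if sp not in DEFAULT_TEMPLATES and sp not in cfg.get(
                        "templates", {}):
                    rep.errors.append(f"tubule.{name}: no template for {sp}")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                rep.errors.append(f"tubule.{name} does not sum to 1")
    return rep


def _meta(cfg: dict, stage: str) -> dict:
    return {"config_hash": io.config_hash(cfg), "seed": cfg.get("seed", 0),
            "stage": stage, "software": "leafletscope 0.1.0"}


def simulate_stage(cfg: dict, outdir: Path) -> dict:
    """Generate tubule snapshot(s), trajectory, maps and ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    tub_cfg = dict(cfg.get("tubule", {}))
    fur = tub_cfg.pop("furrow", None)
    spec = synthetic.TubuleSpec(
        **tub_cfg, seed=cfg.get("seed", 0),
        furrow=synthetic.FurrowSpec(**fur) if fur else None)
    traj_cfg = cfg["trajectory"]
    frames, gt = synthetic.generate_trajectory(
        spec, traj_cfg["n_frames"],
        diffusion={INNER: traj_cfg["diffusion"]["inner"],
                   OUTER: traj_cfg["diffusion"]["outer"]},
        frame_dt=traj_cfg["frame_dt"])
    io.write_snapshot(frames[0], outdir / "snapshot.gro")
    io.write_trajectory_tabular(frames, outdir / "trajectory.csv")

    map_spec = synthetic.MapSpec(**cfg.get("map", {}), seed=cfg.get("seed", 0))
    maps = synthetic.generate_map_family(map_spec)
    for name, m in maps.items():
        io.write_density_map(m, outdir / f"map_{name}.mrc")

    truth = {
        "species_counts": gt.species_counts,
        "n_in_furrow": len(gt.in_furrow),
        "n_backflipped": len(gt.backflipped),
        "leaflet_compositions_map": map_spec.leaflet_compositions,
        "metadata": _meta(cfg, "simulate"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return {"frames": frames, "ground_truth": gt, "map_spec": map_spec}


def geometry_stage(cfg: dict, outdir: Path, snapshot=None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    if snapshot is None:
        snap_path = cfg["inputs"]["snapshot"]
        fmt = "tabular" if str(snap_path).endswith(".csv") else "gro"
        snapshot = io.read_snapshot(snap_path, DEFAULT_TEMPLATES, format=fmt)
    zspec = ZoneSpec(**cfg["zones"])
    center, coords, labels = geometry.analyze_frame(
        snapshot, DEFAULT_TEMPLATES, zone_spec=zspec)
    df = pd.DataFrame({
        "lipid_id": sorted(labels.leaflet),
        "leaflet": [labels.leaflet[l] for l in sorted(labels.leaflet)],
        "zone": [labels.zone.get(l, "other") for l in sorted(labels.leaflet)],
    })
    io.write_results(df, outdir / "labels.csv", metadata=_meta(cfg, "geometry"))
    return {"center": center, "coords": coords, "labels": labels,
            "snapshot": snapshot}


def simanalyze_stage(cfg: dict, outdir: Path, frames=None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    if frames is None:
        frames = io.read_trajectory_tabular(cfg["inputs"]["trajectory"])
    zspec = ZoneSpec(**cfg["zones"])
    kde = cfg["kde"]
    analyzed = []
    for f in frames:
        center, coords, labels = geometry.analyze_frame(
            f, DEFAULT_TEMPLATES, zone_spec=zspec)
        analyzed.append((f, coords, labels))

    comp = simanalysis.zone_composition(analyzed, DEFAULT_TEMPLATES, zspec)
    io.write_results(comp, outdir / "composition.csv", allow_nan=True,
                     metadata=_meta(cfg, "simanalyze"))

    profiles = {}
    for leaflet in (INNER, OUTER):
        for part, beads in (("glycerol", {"GL1", "GL2"}),
                            ("tails", None)):
            if beads is None:
                beads = {b for t in DEFAULT_TEMPLATES.values()
                         for tail in t.tail_beads() for b in tail[-1:]}
            sel = simanalysis.Selection.of(beads=beads, leaflet=leaflet)
            profiles[(part, leaflet)] = simanalysis.radial_density_profile(
                analyzed, sel, kde_bandwidth=kde["radial_bandwidth"],
                r_max=kde["radial_rmax"], dr=kde["radial_dr"],
                label=f"{part}_{leaflet}")
            io.write_results(profiles[(part, leaflet)],
                             outdir / f"profile_{part}_{leaflet}.csv",
                             metadata=_meta(cfg, "simanalyze"))
    thickness = simanalysis.leaflet_thickness_sim(
        profiles[("glycerol", INNER)], profiles[("glycerol", OUTER)],
        profiles[("tails", INNER)], profiles[("tails", OUTER)])
    (outdir / "thickness.json").write_text(json.dumps(
        {**thickness, "metadata": _meta(cfg, "simanalyze")}, indent=1))

    pts = [np.vstack([simanalysis.headgroup_points(
        f, c, l, DEFAULT_TEMPLATES) for f, c, l in analyzed])]
    z_hi = float(frames[0].box[2]) if np.isfinite(frames[0].box[2]) else float(
        max(f.xyz[:, 2].max() for f in frames))
    smap = simanalysis.headgroup_density_map(
        pts, (0.0, z_hi), theta_spacing=kde["surface_dtheta"],
        z_spacing=kde["surface_dz"])
    np.savetxt(outdir / "headgroup_map.csv", smap.values, delimiter=",")

    tilt = simanalysis.tilt_angle_distribution(
        analyzed, DEFAULT_TEMPLATES, kde_bandwidth=kde["tilt_bandwidth"],
        grid_step=kde["tilt_step"])
    tilt_df = pd.DataFrame(
        [{"species": k[0], "tail": k[1], "leaflet": k[2], "zone": k[3],
          "mean_angle": v, "mode_angle": tilt.mode(k)}
         for k, v in tilt.mean_angle.items()])
    io.write_results(tilt_df, outdir / "tilt_summary.csv",
                     metadata=_meta(cfg, "simanalyze"))
    return {"composition": comp, "thickness": thickness, "tilt": tilt,
            "surface_map": smap, "profiles": profiles}


def emanalyze_stage(cfg: dict, outdir: Path, maps=None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    em = cfg["em"]
    if maps is None:
        maps = {}
        for name, path in cfg["inputs"]["maps"].items():
            m = io.read_density_map(path)
            m.helical_twist = cfg.get("map", {}).get("helical_twist",
                                                     360.0 / 17)
            m.helical_rise = cfg.get("map", {}).get("helical_rise", 3.0)
            m.subunits_per_turn = cfg.get("map", {}).get("subunits_per_turn", 17)
            maps[name] = m
    prange = tuple(em["protein_r_range"])
    profiles = {name: emanalysis.membrane_profile(
        m, prange, align_contacts=False,
        projection_fraction=em["projection_fraction"])
        for name, m in maps.items()}

    fit = emanalysis.fit_three_gaussians(profiles["reference"],
                                         tuple(em["fit_window"]))
    (outdir / "thickness_em.json").write_text(json.dumps({
        "thickness_inner": fit.thickness_inner,
        "thickness_outer": fit.thickness_outer,
        "asymmetry": fit.asymmetry,
        "centers": list(fit.centers),
        "metadata": _meta(cfg, "emanalyze")}, indent=1))

    brominated = {k: v for k, v in profiles.items() if k != "reference"}
    comp = emanalysis.bromine_composition(
        brominated, profiles["reference"], em["br_atoms"], split=fit.centers[1])
    io.write_results(comp, outdir / "composition_em.csv",
                     metadata=_meta(cfg, "emanalyze"))
    for name, prof in profiles.items():
        io.write_results(prof, outdir / f"profile_em_{name}.csv",
                         metadata=_meta(cfg, "emanalyze"))
    return {"fit": fit, "composition": comp, "profiles": profiles}


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run simulate -> geometry -> simanalyze -> emanalyze in order.

    Deterministic stages are pure functions of (config, seed): rerunning
    with the same config and seed reproduces outputs bit for bit.
    """
    outdir = Path(outdir)
    report = validate_config(cfg)
    for w in report.warnings:
        logger.warning("config: %s", w)
    if not report.ok:
        raise ValidationError("; ".join(report.errors))
    results = {}
    stages = [
        ("simulate", lambda: simulate_stage(cfg, outdir / "simulate")),
        ("geometry", lambda: geometry_stage(
            cfg, outdir / "geometry",
            snapshot=results["simulate"]["frames"][0])),
        ("simanalyze", lambda: simanalyze_stage(
            cfg, outdir / "simanalyze",
            frames=results["simulate"]["frames"])),
        ("emanalyze", lambda: emanalyze_stage(
            cfg, outdir / "emanalyze",
            maps=synthetic.generate_map_family(
                results["simulate"]["map_spec"]))),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception:
            logger.error("stage %s failed; partial outputs kept in %s",
                         name, outdir)
            raise
        logger.info("stage %s finished in %.2f s", name,
                    time.perf_counter() - t0)
    return results
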