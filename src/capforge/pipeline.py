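"""Config-driven generation pipeline: path → membrane → supports → chip → STL.

A single structured config (TOML or JSON) describes one scaffold chip: the
centerline source, the capillary membrane parameters (under their customary
symbols ``ld``, ``pd``, ``ps`` or long aliases), one or more support
strategies, and the chip/base/nozzle dimensions.  ``run_pipeline`` writes
the STL set plus a JSON manifest of every derived quantity (u, v, pore
count, seam positions, support counts, checksums) and is deterministic
under a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chip import ChipSpec, assemble, build_base, build_nozzles, scaffold_footprint
from .errors import ConfigError
from .mesh import SurfaceMesh, decimate, export_stl, smooth
from .membrane import (CapillarySpec, cut_pores, elongate_side_pores,
                       subdivision_grid, sweep_shell, thicken)
from .pathgen import (CenterlinePath, compute_frames_at, helix_path,
                      hilbert_path, load_path_csv)
from .supports import (ConeSupportSpec, FOVLayout, LatticeSpec,
                       PolygonalSupportSpec, connectivity_check, cone_supports,
                       cull_struts, lattice_edges, pipe_struts,
                       polygonal_supports, predict_fov_seams, support_positions)

_ALIASES = {"ld": "lumen_diameter", "pd": "pore_diameter", "ps": "pore_spacing"}

_SCHEMA = {
    "seed": int,
    "path": {"source", "file", "units_scale", "order", "dims", "step",
             "layers", "layer_gap", "corner_fillet_radius", "radius", "pitch",
             "turns", "strands", "samples_per_turn", "degree", "elevation"},
    "capillary": {"lumen_diameter", "pore_diameter", "pore_spacing",
                  "membrane_thickness", "side_pore_elongation",
                  "smoothing_iterations", "ld", "pd", "ps"},
    "fov": {"fov_width", "overlap", "stitch_angle", "origin"},
    "supports": {"strategies", "polygonal", "lattice", "cone"},
    "chip": {"base_thickness", "base_margin", "nozzle_outer_diameter",
             "nozzle_bore", "nozzle_height", "retaining_wall_height",
             "retaining_wall_thickness", "decimate", "nozzles"},
    "output": {"dir"},
}


@dataclass
class ForgeConfig:
    """Validated pipeline configuration with defaults filled in."""

    path_source: str
    path_params: dict
    capillary: CapillarySpec
    fov: FOVLayout
    strategies: list[str]
    polygonal: PolygonalSupportSpec | None
    lattice_params: dict
    cone_params: dict
    chip: ChipSpec
    decimate_fraction: float
    with_nozzles: bool
    out_dir: Path
    seed: int = 0
    elevation: float | None = None
    raw: dict = field(default_factory=dict)


def _load_raw(file) -> dict:
    if isinstance(file, dict):
        return dict(file)
    p = Path(file)
    text = p.read_text()
    if p.suffix in (".json",):
        return json.loads(text)
    return tomllib.loads(text)


def validate_config(file) -> ForgeConfig:
    """Parse and validate a config file (TOML/JSON) or dict.

    All constraint violations are aggregated into one :class:`ConfigError`
    so a bad config reports every problem at once.
    """
    raw = _load_raw(file)
    problems: list[str] = []

    for key in raw:
        if key not in _SCHEMA:
            problems.append(f"unknown section or key '{key}'")
    for section in ("path", "capillary", "fov", "supports", "chip", "output"):
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            problems.append(f"section '{section}' must be a table")
            continue
        allowed = _SCHEMA[section]
        for k in sub:
            if k not in allowed:
                problems.append(f"unknown key '{section}.{k}'")

    path_cfg = dict(raw.get("path", {}))
    source = path_cfg.pop("source", None)
    if source not in ("csv", "hilbert", "helix"):
        problems.append("path.source must be one of csv|hilbert|helix")
    if source == "csv":
        f = path_cfg.get("file")
        if not f:
            problems.append("path.file is required for csv source")
        elif not Path(f).exists():
            problems.append(f"path.file '{f}' does not exist")

    cap_cfg = {_ALIASES.get(k, k): v for k, v in raw.get("capillary", {}).items()}
    capillary = None
    try:
        capillary = CapillarySpec(**{
            "lumen_diameter": cap_cfg.get("lumen_diameter", 40.0),
            "pore_diameter": cap_cfg.get("pore_diameter", 5.0),
            "pore_spacing": cap_cfg.get("pore_spacing", 8.0),
            "membrane_thickness": cap_cfg.get("membrane_thickness", 10.0),
            "side_pore_elongation": cap_cfg.get("side_pore_elongation", 1.5),
            "smoothing_iterations": cap_cfg.get("smoothing_iterations", 0),
        })
    except Exception as exc:
        problems.append(f"capillary: {exc}")

    fov_cfg = dict(raw.get("fov", {}))
    fov = None
    try:
        fov = FOVLayout(
            fov_width=fov_cfg.get("fov_width", 400.0),
            overlap=fov_cfg.get("overlap", 5.0),
            stitch_angle=fov_cfg.get("stitch_angle", 15.0),
            origin=tuple(fov_cfg.get("origin", (0.0, 0.0))),
        )
    except Exception as exc:
        problems.append(f"fov: {exc}")

    sup_cfg = dict(raw.get("supports", {}))
    strategies = sup_cfg.get("strategies", ["lattice"])
    if isinstance(strategies, str):
        strategies = [strategies]
    for s in strategies:
        if s not in ("polygonal", "lattice", "cone"):
            problems.append(f"unknown support strategy '{s}'")
    if not strategies:
        problems.append("at least one support strategy is required")

    polygonal = None
    if "polygonal" in strategies:
        try:
            polygonal = PolygonalSupportSpec(**sup_cfg.get("polygonal", {}))
        except Exception as exc:
            problems.append(f"supports.polygonal: {exc}")
    lattice_params = dict(sup_cfg.get("lattice", {}))
    if "lattice" in strategies:
        if lattice_params.get("cell_size", 0) <= 0:
            problems.append("supports.lattice.cell_size is required and > 0")
        if lattice_params.get("beam_diameter", 10.0) <= 0:
            problems.append("supports.lattice.beam_diameter must be > 0")
    cone_params = dict(sup_cfg.get("cone", {}))
    if "cone" in strategies and cone_params.get("taper_angle", 15.0) < 15.0:
        problems.append("supports.cone.taper_angle must be ≥ 15°")

    chip_cfg = dict(raw.get("chip", {}))
    dec = chip_cfg.pop("decimate", 0.0)
    with_nozzles = chip_cfg.pop("nozzles", True)
    chip = None
    try:
        if capillary is not None:
            chip_cfg.setdefault("nozzle_bore", capillary.lumen_diameter)
        chip = ChipSpec(**chip_cfg)
    except Exception as exc:
        problems.append(f"chip: {exc}")
    if dec and not (0.0 < dec < 1.0):
        problems.append("chip.decimate must be 0 (off) or in (0, 1)")

    if problems:
        raise ConfigError(problems)

    return ForgeConfig(
        path_source=source,
        path_params=path_cfg,
        capillary=capillary,
        fov=fov,
        strategies=list(strategies),
        polygonal=polygonal,
        lattice_params=lattice_params,
        cone_params=cone_params,
        chip=chip,
        decimate_fraction=float(dec or 0.0),
        with_nozzles=bool(with_nozzles),
        out_dir=Path(raw.get("output", {}).get("dir", "forge_out")),
        seed=int(raw.get("seed", 0)),
        elevation=raw.get("path", {}).get("elevation"),
        raw=raw,
    )


def build_path(cfg: ForgeConfig) -> CenterlinePath:
    p = dict(cfg.path_params)
    p.pop("elevation", None)
    if cfg.path_source == "csv":
        path = load_path_csv(p["file"], units_scale=p.get("units_scale", 1.0),
                             degree=p.get("degree", 1))
    elif cfg.path_source == "hilbert":
        fillet = p.get("corner_fillet_radius", cfg.capillary.lumen_radius)
        path = hilbert_path(order=p.get("order", 2), dims=p.get("dims", 2),
                            step=p.get("step", 100.0),
                            layers=p.get("layers", 1),
                            layer_gap=p.get("layer_gap", 100.0),
                            corner_fillet_radius=fillet)
    else:
        path = helix_path(radius=p.get("radius", 100.0),
                          pitch=p.get("pitch", 150.0),
                          turns=p.get("turns", 2.0),
                          strands=p.get("strands", 1),
                          samples_per_turn=p.get("samples_per_turn", 32))[0]
    # suspend the scaffold above the base plane (z = 0 is the base top)
    elev = cfg.elevation
    if elev is None:
        elev = cfg.capillary.lumen_radius + cfg.capillary.membrane_thickness + 40.0
    z_min = path.points[:, 2].min()
    return CenterlinePath(path.points + [0.0, 0.0, elev - z_min],
                          degree=path.degree, closed=path.closed)


def run_pipeline(config) -> dict:
    """Run the full design pipeline and write STL set + manifest.

    ``config`` is a path to a TOML/JSON file, a dict, or a ForgeConfig.
    Returns the manifest dict (also written to ``<out>/manifest.json``).
    """
    cfg = config if isinstance(config, ForgeConfig) else validate_config(config)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    path = build_path(cfg)
    spec = cfg.capillary
    grid = subdivision_grid(path.path_length, spec)
    shell = sweep_shell(path, grid, spec)
    pored = cut_pores(shell, grid, spec)
    pored = elongate_side_pores(pored, spec)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        membrane = thicken(pored, on_self_intersection="warn")
    if spec.smoothing_iterations:
        membrane = smooth(membrane, spec.smoothing_iterations)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "path": {"source": cfg.path_source,
                 "length_um": path.path_length,
                 "n_points": int(len(path.points))},
        "grid": {"u": grid.u, "v": grid.v, "s_l_um": grid.s_l,
                 "s_r_um": grid.s_r, "pore_count": grid.n_pores},
        "membrane": {"faces": membrane.n_faces,
                     "watertight": membrane.is_watertight(),
                     "euler_characteristic": membrane.euler_characteristic(),
                     "warnings": [str(w.message) for w in caught]},
    }

    seams = predict_fov_seams(cfg.fov, path)
    manifest["fov_seams"] = [{"s_um": s, "seam": sid} for s, sid in seams]

    support_meshes: list[SurfaceMesh] = []
    outer_d = spec.lumen_diameter + 2 * spec.membrane_thickness
    if "polygonal" in cfg.strategies:
        positions = support_positions(path, cfg.polygonal, cfg.fov)
        sup = polygonal_supports(path, cfg.polygonal, positions, outer_d)
        support_meshes.append(sup)
        manifest["polygonal_supports"] = {
            "positions_um": positions, "n_assemblies": len(positions)}
    if "lattice" in cfg.strategies:
        lp = cfg.lattice_params
        lo = membrane.bounds()[0] - lp.get("margin", 0.0)
        hi = membrane.bounds()[1] + lp.get("margin", 0.0)
        lo[2] = 0.0  # lattice grounds on the base top
        lspec = LatticeSpec(cell_size=lp["cell_size"],
                            beam_diameter=lp.get("beam_diameter", 10.0),
                            bounding_box=(tuple(lo), tuple(hi)),
                            clearance=lp.get("clearance", 2.0))
        edges = lattice_edges(lspec)
        kept = cull_struts(edges, membrane, clearance=lspec.clearance,
                           strut_radius=0.5 * lspec.beam_diameter)
        report = connectivity_check(kept, base_z=0.0,
                                    tol=max(lspec.cell_size * 1e-4, 0.1))
        piped = pipe_struts(kept, lspec.beam_diameter)
        support_meshes.append(piped)
        manifest["lattice"] = {
            "struts_total": len(edges), "struts_kept": len(kept),
            "struts_culled": len(edges) - len(kept),
            "connectivity": {k: v for k, v in report.items()
                             if k != "floating_struts"},
            "floating_struts": len(report["floating_struts"]),
        }
    if "cone" in cfg.strategies:
        cp = dict(cfg.cone_params)
        spacing = cp.pop("spacing", 150.0)
        if "positions" not in cp:
            n_anchor = max(int(path.path_length // spacing), 1)
            s_anchor = np.linspace(0, path.path_length, n_anchor + 1)
            pts = np.atleast_2d(path.point_at(s_anchor))
            cp["positions"] = tuple((float(x), float(y)) for x, y in pts[:, :2])
        else:
            cp["positions"] = tuple(tuple(p) for p in cp["positions"])
        cspec = ConeSupportSpec(**cp)
        cones = cone_supports(cspec, membrane, base_z=0.0)
        support_meshes.append(cones)
        manifest["cones"] = {
            "n_cones": cones.metadata["n_cones"],
            "missed_anchors": cones.metadata["missed_anchors"],
        }

    chip_parts = [membrane] + support_meshes
    footprint = scaffold_footprint(chip_parts, cfg.chip.base_margin)
    base = build_base(footprint, cfg.chip)
    chip_parts.append(base)
    if cfg.with_nozzles:
        ends = compute_frames_at(path, [0.0, path.path_length])
        try:
            nozzles = build_nozzles((ends[0], ends[1]), cfg.chip)
            chip_parts.append(nozzles)
        except Exception as exc:
            manifest["nozzles"] = {"skipped": str(exc)}
        else:
            manifest["nozzles"] = {"port_centres":
                                   nozzles.metadata["port_centres"]}

    chip_mesh = assemble(chip_parts)
    manifest["chip"] = {"faces": chip_mesh.n_faces,
                        "components": len(chip_parts)}
    if cfg.decimate_fraction:
        decimated = decimate(chip_mesh, cfg.decimate_fraction,
                             report_hausdorff=False)
        manifest["decimation"] = decimated.metadata["decimation"]
    else:
        decimated = None

    files = {"membrane.stl": membrane, "chip.stl": chip_mesh}
    if support_meshes:
        files["supports.stl"] = SurfaceMesh.concatenate(
            support_meshes, provenance="support")
    if decimated is not None:
        files["chip_decimated.stl"] = decimated
    checksums = {}
    for name, m in files.items():
        p = export_stl(m, out / name)
        checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest["outputs"] = {name: str(out / name) for name in files}
    manifest["checksums"] = checksums

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return manifest
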