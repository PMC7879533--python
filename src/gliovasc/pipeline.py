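"""End-to-end orchestration: simulate → restore → segment → vessels → walls
→ overlap → tcells → myeloid → stats, with cached artifacts and one report.

The configuration is a plain nested dict (YAML on disk), validated against
a declared schema before any stage runs: unknown keys are rejected so typos
fail fast. All randomness flows from one seed; reports are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import (
    histocytometry, infiltration, io, morphometry, overlap, restoration,
    segmentation, stats, synthetic, walls,
)

logger = logging.getLogger(__name__)

# schema: dict -> allowed keys (None = any scalar/list)
_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "input": {"path": None, "channels": None, "voxel_size": None},
    "scenario": {
        "extent": None,
        "voxel_size": None,
        "tree": {"n_primary": None, "n_secondary": None, "n_tertiary": None,
                 "trunk_radius": None, "branch_radius": None},
        "render": {"gap_fraction": None, "endo_coincidence": None,
                   "shell_thickness": None, "endo_thickness": None,
                   "n_nuclei": None, "nucleus_diameter": None,
                   "tcell_distances": None, "myeloid": {"n_cells": None},
                   "gfap_mode": None},
        "optics": {"psf_sigmas": None, "noise": None},
    },
    "stages": {
        "restore": {"enabled": None, "iterations": None, "psf_sigmas": None},
        "segment": {"min_unit_volume": None, "nucleus_diameter": None},
        "vessels": {"bins": None, "fusion_radius": None, "prune_factor": None,
                    "closing_radius": None},
        "walls": {"n_lines": None, "line_length": None, "keep_length": None,
                  "slice_thickness": None, "trace_inset": None},
        "overlap": {"dilation_tolerance": None},
        "tcells": {"contact_threshold": None, "expected_diameter": None},
        "myeloid": {"min_cell_volume": None, "smoothing": None,
                    "background_quantile": None},
    },
}


def validate_config(config: dict, schema: dict = _SCHEMA, path: str = "") -> None:
    """Reject unknown keys anywhere in the config tree."""
    if not isinstance(config, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    for key, value in config.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {here}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            validate_config(value, sub, here)
        elif isinstance(sub, dict) and value is not None and not isinstance(value, dict):
            raise ValueError(f"config key {here} must be a mapping")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def default_scenario() -> dict:
    """The shipped synthetic scenario: a branched vessel tree in a
    64×128×128 µm block at 0.5 µm voxels with all cellular content."""
    return {
        "seed": 7,
        "scenario": {
            "extent": [64.0, 128.0, 128.0],
            "voxel_size": [0.5, 0.5, 0.5],
            "tree": {"n_primary": 4, "n_secondary": 1, "n_tertiary": 1,
                     "trunk_radius": 4.0, "branch_radius": 2.5},
            "render": {
                "gap_fraction": 0.2,
                "endo_coincidence": 0.8,
                "shell_thickness": 1.0,
                "endo_thickness": 0.75,
                "n_nuclei": 150,
                "tcell_distances": [0.0, 2.0, 15.0, 30.0],
                "myeloid": {"n_cells": 60},
                "gfap_mode": "tumor_mass",
            },
            "optics": {"psf_sigmas": [0.75, 0.35, 0.35], "noise": [1.0, 2.0]},
        },
        "stages": {
            "restore": {"enabled": False},
            # fenestration gaps cluster, so the lumen seal needs twice the
            # 2-µm patch scale at gap fractions around 0.2
            "vessels": {"closing_radius": 4.0},
        },
    }


def simulate_from_config(cfg: dict, seed: int) -> tuple:
    """Build the tree, render, and apply optics per the scenario section."""
    sc = cfg["scenario"]
    extent = sc.get("extent", [64.0, 128.0, 128.0])
    tree_cfg = dict(sc.get("tree", {}))
    spec = synthetic.make_branching_tree(extent, **tree_cfg)
    tree = synthetic.build_vessel_tree(spec, seed=seed)
    rc = dict(sc.get("render", {}))
    myeloid_cfg = rc.pop("myeloid", None)
    mspec = synthetic.MyeloidSpec(**myeloid_cfg) if myeloid_cfg else None
    rc["tcell_distances"] = tuple(rc.get("tcell_distances", ()))
    params = synthetic.RenderParams(
        voxel_size=tuple(sc.get("voxel_size", (0.5, 0.5, 0.5))),
        myeloid_spec=mspec, **rc,
    )
    volume, gt = synthetic.render_volume(tree, params, seed=seed)
    optics = sc.get("optics")
    if optics:
        volume = synthetic.apply_optics(
            volume, optics.get("psf_sigmas", 0.0),
            tuple(optics.get("noise", (0.0, 0.0))), seed=seed,
        )
    return volume, gt, params


def _wall_trace_mask(vessel_mask: np.ndarray, voxel, z_index: int, inset_um: float,
                     closing_radius: float = 2.0) -> np.ndarray:
    """2D tracing mask for wall profiles: the filled vessel cross-section
    eroded so the contour runs mid-wall. The mask is closed at the
    fenestration scale first so gapped membranes still enclose a lumen."""
    closed = morphometry._edt_close(vessel_mask, closing_radius, float(min(voxel)))
    filled = ndimage.binary_fill_holes(closed) | vessel_mask
    sl = filled[z_index]
    it = max(1, int(round(inset_um / voxel[2])))
    return ndimage.binary_erosion(sl, iterations=it)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run every stage in dependency order; returns the report path."""
    validate_config(config)
    chash = config_hash(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_cfg = config.get("stages", {})
    outputs: dict = {}
    comments = {"config": chash, "seed": str(seed)}

    # --- input -------------------------------------------------------------
    if "scenario" in config:
        volume, gt, render_params = simulate_from_config(config, seed)
        io.write_volume(volume, out / "volume.ome.tif")
        outputs["simulate"] = {
            "ground_truth": gt.summary(),
            "extent_um": list(volume.extent),
            "voxel_size_um": list(volume.voxel_size),
        }
    elif "input" in config:
        inp = config["input"]
        volume = io.read_volume(inp["path"], inp["channels"],
                                voxel_size=inp.get("voxel_size"))
        gt = None
        outputs["simulate"] = {"status": "absent"}
    else:
        raise ValueError("config needs either a 'scenario' or an 'input' section")
    voxel = np.asarray(volume.voxel_size)

    # --- restoration (optional) --------------------------------------------
    rcfg = stage_cfg.get("restore", {})
    if rcfg.get("enabled", False):
        model = restoration.PSFModel(sigmas=tuple(rcfg.get("psf_sigmas", (0.75, 0.35, 0.35))))
        psf = restoration.gaussian_psf(model, volume.voxel_size)
        iters = int(rcfg.get("iterations", 10))
        volume = io.MultiChannelVolume(
            channels={n: restoration.deconvolve_rl(volume[n], psf, iters).astype(np.float32)
                      for n in volume.channel_names},
            voxel_size=volume.voxel_size,
        )
        outputs["restore"] = {"iterations": iters, "psf_sigmas": list(model.sigmas)}

    # --- segmentation -------------------------------------------------------
    scfg = stage_cfg.get("segment", {})
    min_unit = float(scfg.get("min_unit_volume", 50.0))
    nuc_d = float(scfg.get("nucleus_diameter", 7.0))
    coliv_mask = segmentation.make_mask(volume["COLIV"], voxel, min_unit_volume=min_unit,
                                        source_channel="COLIV")
    cd31_mask = segmentation.make_mask(volume["CD31"], voxel, min_unit_volume=min_unit,
                                       source_channel="CD31")
    coliv_stats = segmentation.surface_stats(coliv_mask)
    nuclei = segmentation.detect_nuclei(volume["DAPI"], voxel, expected_diameter=nuc_d)
    diss = segmentation.dissector_counts(nuclei, volume.extent, box_size=20.0, guard=2.0)
    io.export_stats(
        [{"z_um": s.centroid[0], "y_um": s.centroid[1], "x_um": s.centroid[2],
          "diameter_um": s.diameter, "intensity": s.intensity} for s in nuclei],
        out / "nuclei.csv", allow_empty=True,
        columns=["z_um", "y_um", "x_um", "diameter_um", "intensity"],
        comments=comments,
    )
    outputs["segment"] = {
        "coliv_units": coliv_stats.unit_count,
        "coliv_surface_um2": coliv_stats.surface_area_um2,
        "coliv_volume_um3": coliv_stats.volume_um3,
        "n_nuclei": len(nuclei),
        "dissector_mean": diss.mean,
        "dissector_sem": diss.sem,
        "threshold_coliv": coliv_mask.threshold,
        "threshold_cd31": cd31_mask.threshold,
    }

    # --- vessel morphometry --------------------------------------------------
    vcfg = stage_cfg.get("vessels", {})
    skel = morphometry.skeletonize_vessels(
        coliv_mask, prune_factor=float(vcfg.get("prune_factor", 1.5)),
        closing_radius=float(vcfg.get("closing_radius", 2.0)))
    if skel.edges:
        diam = morphometry.measure_diameters(skel, bins=tuple(vcfg.get("bins", (5.0, 10.0))))
        records, taxonomy = morphometry.classify_branch_points(
            skel, fusion_radius=float(vcfg.get("fusion_radius", 3.0)))
        flagged, silent_frac = morphometry.find_silent_collaterals(skel)
        io.export_stats(
            [{"edge": i, "length_um": e.length, "median_diameter_um": e.median_diameter,
              "silent_collateral": int(e.median_diameter <= morphometry.SILENT_COLLATERAL_MAX_DIAMETER)}
             for i, e in enumerate(skel.edges)],
            out / "vessel_edges.csv", allow_empty=True,
            columns=["edge", "length_um", "median_diameter_um", "silent_collateral"],
            comments=comments,
        )
        outputs["vessels"] = {
            "n_edges": len(skel.edges),
            "median_diameter_um": float(np.median(diam.per_edge_median)),
            "diameter_bins": diam.bin_counts,
            "branch_taxonomy": {k: taxonomy[k] for k in ("primary", "secondary", "tertiary")},
            "pct_single": taxonomy["pct_single"],
            "silent_collateral_fraction": silent_frac,
        }
    else:
        outputs["vessels"] = {"status": "absent", "reason": "no vessel skeleton"}

    # --- wall integrity -------------------------------------------------------
    wcfg = stage_cfg.get("walls", {})
    z_mid = volume.shape[0] // 2
    slc = walls.extract_optical_slice(volume, "COLIV", z_mid,
                                      slice_thickness=float(wcfg.get("slice_thickness", 1.0)))
    trace_mask = _wall_trace_mask(
        coliv_mask.binary, voxel, z_mid, float(wcfg.get("trace_inset", 0.75)),
        closing_radius=float(vcfg.get("closing_radius", 2.0)))
    lines = walls.trace_wall_lines(
        trace_mask, voxel[1:], n_lines=int(wcfg.get("n_lines", 5)),
        line_length=float(wcfg.get("line_length", 40.0)), seed=seed)
    profiles = [walls.profile_luminance(slc, ln, voxel[1:]) for ln in lines]
    keep = float(wcfg.get("keep_length", 27.0))
    profiles = [p for p in profiles if p.length >= keep]
    if profiles:
        matrix, _ = walls.harmonize_profiles(profiles, keep_length=keep)
        fen = walls.fenestration_metric(matrix)
        outputs["walls"] = {
            "n_profiles": len(profiles),
            "relative_sd_mean": fen.mean_sd,
            "relative_sd_sem": fen.sem_sd,
        }
    else:
        outputs["walls"] = {"status": "absent", "reason": "insufficient wall boundary"}

    # --- barrier overlap -------------------------------------------------------
    ocfg = stage_cfg.get("overlap", {})
    if coliv_mask.n_units and cd31_mask.n_units:
        ov = overlap.overlap_masks(coliv_mask, cd31_mask,
                                   dilation_tolerance=float(ocfg.get("dilation_tolerance", 0.0)))
        outputs["overlap"] = {
            "fraction_coliv": ov.overlap_fraction_A,
            "fraction_cd31": ov.overlap_fraction_B,
            "fraction_union": ov.overlap_fraction_union,
            "venn_um3": ov.venn_um3,
        }
    else:
        outputs["overlap"] = {"status": "absent", "reason": "empty mask"}

    # --- T cells -----------------------------------------------------------------
    tcfg = stage_cfg.get("tcells", {})
    tcells = infiltration.detect_tcells(
        volume["CD3"], volume["DAPI"], voxel,
        expected_diameter=float(tcfg.get("expected_diameter", 7.0)))
    if tcells and cd31_mask.n_units:
        infiltration.distance_to_endothelium(tcells, cd31_mask)
        tstats = infiltration.classify_infiltration(
            tcells, contact_threshold=float(tcfg.get("contact_threshold", 2.0)))
        io.export_stats(
            [{"z_um": r.centroid[0], "y_um": r.centroid[1], "x_um": r.centroid[2],
              "distance_um": r.distance_um, "status": r.status} for r in tcells],
            out / "tcells.csv", allow_empty=True,
            columns=["z_um", "y_um", "x_um", "distance_um", "status"],
            comments=comments,
        )
        outputs["tcells"] = {"n_tcells": len(tcells), **tstats}
    else:
        outputs["tcells"] = {"n_tcells": len(tcells), "status": "absent"}

    # --- myeloid histocytometry -----------------------------------------------
    mcfg = stage_cfg.get("myeloid", {})
    try:
        cells = histocytometry.segment_cells(
            volume, min_cell_volume=float(mcfg.get("min_cell_volume", 50.0)))
    except ValueError:
        cells = []
    niches = histocytometry.partition_niches(
        volume["GFAP"], volume["MHCII"], voxel,
        smoothing=float(mcfg.get("smoothing", 10.0)),
        background_quantile=float(mcfg.get("background_quantile", 0.5)))
    myeloid_out: dict = {"n_cells": len(cells)}
    if len(cells) >= 2:
        cells, high_frac = histocytometry.gate_mhc2(cells)
        myeloid_out["mhc2_high_fraction"] = high_frac
        io.export_stats(
            [{"cell": c.cell_id, "z_um": c.centroid[0], "y_um": c.centroid[1],
              "x_um": c.centroid[2], "volume_um3": c.volume_um3,
              "mean_MHCII": c.mean_intensity.get("MHCII"),
              "mean_IBA1": c.mean_intensity.get("IBA1"), "gate": c.gate}
             for c in cells],
            out / "myeloid_cells.csv", allow_empty=True,
            columns=["cell", "z_um", "y_um", "x_um", "volume_um3",
                     "mean_MHCII", "mean_IBA1", "gate"],
            comments=comments,
        )
    try:
        myeloid_out["tsr"] = histocytometry.tsr(niches)
    except ZeroDivisionError:
        myeloid_out["tsr"] = None
    myeloid_out["per_niche_vessels"] = histocytometry.per_niche_vessels(
        niches, coliv_mask, skel if skel.edges else None)
    outputs["myeloid"] = myeloid_out

    # --- stats: correlations over the per-cell table -----------------------------
    if len(cells) >= 3:
        import pandas as pd

        table = pd.DataFrame({
            "volume_um3": [c.volume_um3 for c in cells],
            "mean_MHCII": [c.mean_intensity.get("MHCII") for c in cells],
            "mean_IBA1": [c.mean_intensity.get("IBA1") for c in cells],
        })
        corr = stats.correlation_matrix(table)
        outputs["stats"] = {"correlations": corr.to_dict(orient="records")}

    report = stats.build_report(outputs, config=config, seed=seed)
    report["provenance"]["config_hash"] = chash
    path = io.write_json(report, out / "report.json")
    logger.info("pipeline report written to %s", path)
    return path
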