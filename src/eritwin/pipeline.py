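"""Case- and cohort-level orchestration.

``run_case`` drives the full chain for one case -- load or synthesize
the deployed geometry, sample the apposition field, reduce it to risk
features, compute the ERI -- and emits a deterministic JSON-serializable
report with provenance (config hash, seed, version).  ``run_cohort_eval``
turns per-case ERIs and observed labels into the diagnostic-accuracy
layer (confusion metrics at the 0.80 cutoff, ROC, group comparison).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .apposition import AnalysisRegion, radial_sampling
from .eri import DEFAULT_CUTOFF, compute_eri, select_cutoff_roc
from .features import DEFAULT_EPSILON, extract_features
from .fileio import load_centerline_points, load_mesh
from .geometry import reconstruct_tube, resample_centerline
from .mechanics import DEFAULT_WALL, OrthotropicMaterial, elastic_modulus_at_angle
from .stats import ConfusionCounts, compare_eri_groups, confusion_metrics
from .synthetic import SyntheticCaseSpec, generate_case
from .validation import DICE_GATE, HAUSDORFF_GATE_MM, dice_coefficient, hausdorff_distance, voxelize

log = logging.getLogger(__name__)

#: Analysis defaults: 0.5-mm slices over a 20-mm sealing region, 200
#: angles, ERI cutoff 0.80, apposition threshold 0.1 mm.
DEFAULTS = {
    "region": {"start": 0.25, "length": 20.0, "slice_spacing": 0.5, "n_angles": 200},
    "features": {"epsilon": DEFAULT_EPSILON, "sgs_mode": "mean",
                 "sgm_mode": "extent", "shared_center": True},
    "eri": {"cutoff": DEFAULT_CUTOFF},
    "validation": {"enabled": False, "voxel_spacing": 0.25, "hausdorff_samples": 2000},
}


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and case id."""


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_defaults(cfg)


def merge_defaults(cfg: dict) -> dict:
    out = {k: dict(v) for k, v in DEFAULTS.items()}
    for key, val in cfg.items():
        if key in out and isinstance(val, dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _material_from_config(cfg: dict) -> OrthotropicMaterial:
    m = cfg.get("material")
    if not m:
        return DEFAULT_WALL
    return OrthotropicMaterial(
        E_L=float(m["E_L"]), E_C=float(m["E_C"]),
        G_LC=float(m["G_LC"]), v_LC=float(m["v_LC"]),
    )


def run_case(config: dict | str, case_id: Optional[str] = None,
             return_field: bool = False):
    """Execute the full per-case pipeline and return the report dict.

    ``config`` is a YAML path or an already-merged dict containing either
    a ``synthetic`` spec block or an ``inputs`` block with mesh and
    centerline files.  With ``return_field=True`` the raw
    :class:`~eritwin.apposition.AppositionField` is returned alongside
    the report.
    """
    if isinstance(config, str):
        cfg = load_config(config)
    else:
        cfg = merge_defaults(config)
    case_id = case_id or cfg.get("case_id", "case")

    stage = "load-geometry"
    try:
        if "synthetic" in cfg:
            spec = SyntheticCaseSpec.from_dict(cfg["synthetic"])
            aorta, graft, path = generate_case(spec)
            seed = spec.seed
        elif "inputs" in cfg:
            inp = cfg["inputs"]
            aorta = load_mesh(inp["aorta"])
            graft = load_mesh(inp["graft"])
            seed = int(cfg.get("seed", 0))
            if inp.get("centerline"):
                pts = load_centerline_points(inp["centerline"])
                path = resample_centerline(pts, float(inp.get("centerline_spacing", 0.25)))
            else:
                from .geometry import centroid_centerline

                path = centroid_centerline(aorta, inp.get("axis_hint", [0.0, 0.0, 1.0]))
        else:
            raise PipelineError("config needs a 'synthetic' or 'inputs' block")

        stage = "apposition-analysis"
        rc = cfg["region"]
        region = AnalysisRegion(
            start=float(rc["start"]), length=float(rc["length"]),
            slice_spacing=float(rc["slice_spacing"]), n_angles=int(rc["n_angles"]),
        )
        field_ = radial_sampling(
            aorta, graft, path, region,
            shared_center=bool(cfg["features"].get("shared_center", True)),
        )
        expected = region.n_slices * region.n_angles * 2
        assert field_.n_measurements == expected, "measurement count mismatch"
        log.info("case %s: %d radius measurements", case_id, field_.n_measurements)

        stage = "feature-extraction"
        fc = cfg["features"]
        feats = extract_features(
            field_, epsilon=float(fc["epsilon"]),
            sgs_mode=fc["sgs_mode"], sgm_mode=fc["sgm_mode"],
        )

        stage = "risk-scoring"
        eri = compute_eri(feats, cutoff=float(cfg["eri"]["cutoff"]))

        stage = "geometric-validation"
        validation = None
        if cfg["validation"].get("enabled", False):
            spacing = float(cfg["validation"]["voxel_spacing"])
            recon = reconstruct_tube(aorta, path, spacing=region.slice_spacing,
                                     n_angles=region.n_angles)
            bounds = np.array([
                np.minimum(aorta.bounds[0], recon.bounds[0]) - spacing,
                np.maximum(aorta.bounds[1], recon.bounds[1]) + spacing,
            ])
            dice = dice_coefficient(
                voxelize(aorta, spacing, bounds), voxelize(recon, spacing, bounds)
            )
            hd = hausdorff_distance(
                aorta, recon,
                samples=int(cfg["validation"].get("hausdorff_samples", 2000)),
                seed=seed,
            )
            validation = {
                "dice": float(dice),
                "hausdorff_mm": float(hd),
                "dice_gate": DICE_GATE,
                "hausdorff_gate_mm": HAUSDORFF_GATE_MM,
                "passed": bool(dice > DICE_GATE and hd < HAUSDORFF_GATE_MM),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed for case '{case_id}': {exc}") from exc

    mat = _material_from_config(cfg)
    report = {
        "case_id": case_id,
        "software": {"name": "eritwin", "version": __version__},
        "provenance": {"config_sha256": _config_hash(cfg), "seed": int(seed)},
        "region": {
            "start_mm": region.start, "length_mm": region.length,
            "slice_spacing_mm": region.slice_spacing, "n_angles": region.n_angles,
            "n_slices": region.n_slices, "n_measurements": field_.n_measurements,
        },
        "r_g0_mm": field_.r_g0,
        "features": feats.as_dict(),
        "eri": eri.as_dict(),
        "material": {
            "E_L_MPa": mat.E_L, "E_C_MPa": mat.E_C, "G_LC_MPa": mat.G_LC,
            "v_LC": mat.v_LC,
            "E_theta_MPa": {
                "0": elastic_modulus_at_angle(mat, 0.0),
                "45": elastic_modulus_at_angle(mat, np.pi / 4),
                "90": elastic_modulus_at_angle(mat, np.pi / 2),
            },
        },
        "validation": validation,
    }
    if return_field:
        return report, field_
    return report


def write_report(report: dict, path: str) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_cohort_eval(
    eri_values, labels, cutoff: float = DEFAULT_CUTOFF
) -> dict:
    """Cohort-level evaluation of ERI predictions against observed labels.

    Returns confusion metrics at ``cutoff``, the continuous-score ROC
    with its Youden-optimal cutoff, and the ERI group comparison.
    """
    eri_values = np.asarray(eri_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2 or min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("cohort evaluation needs at least 2 cases per class")
    preds = (eri_values >= cutoff).astype(int)
    counts = ConfusionCounts.from_predictions(preds, labels)
    report = confusion_metrics(counts)
    roc = select_cutoff_roc(eri_values, labels)
    groups = compare_eri_groups(eri_values[labels == 1], eri_values[labels == 0])
    return {
        "cutoff": float(cutoff),
        "diagnostics": report.as_dict(),
        "diagnostics_table": report.format_table(),
        "roc": {"auc": roc.auc, "optimal_cutoff": roc.optimal_cutoff},
        "eri_groups": groups.as_dict(),
    }
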