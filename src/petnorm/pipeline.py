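"""End-to-end stages: generate -> train -> infer -> evaluate -> report.

Each stage reads its inputs from the run directory, writes its artifacts
plus a provenance record (config hash, seed, package version), and is
reproducible from (config, seed): rerunning a stage with unchanged
config and seed rewrites identical manifests and metrics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anomaly_map import extract_candidates, match_candidates, z_score_map
from .bnn_model import (
    ModelConfig,
    ScanRecord,
    build_unet,
    load_checkpoint,
    predict_volume,
    train,
)
from .config import RunConfig, config_hash, save_config, substream_seed
from .evaluation import (
    baseline_abs_error,
    baseline_suv_threshold,
    compare_methods,
    froc_curve,
    sensitivity_at_fp_rate,
    slice_records,
    slice_roc,
    voxel_roc,
)
from .io_volumes import Volume, VolumePair, read_volume, resample_isotropic, write_volume
from .phantom import LesionAnnotation, LesionInfo, generate_dataset

STAGES = ("generate", "train", "infer", "evaluate", "report")


class PrerequisiteError(RuntimeError):
    """A required artifact from an earlier stage is missing."""


def _dirs(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    return {
        "out": out,
        "dataset": out / "dataset",
        "models": out / "models",
        "inference": out / "inference",
        "evaluation": out / "evaluation",
        "report": out / "report",
    }


def _provenance(cfg: RunConfig, stage: str, path: Path) -> None:
    record = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "petnorm_version": __version__,
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PrerequisiteError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def stage_generate(cfg: RunConfig, overwrite: bool = True) -> Path:
    d = _dirs(cfg)
    d["out"].mkdir(parents=True, exist_ok=True)
    generate_dataset(cfg.phantom, d["dataset"], substream_seed(cfg.seed, "phantom"),
                     overwrite=overwrite)
    save_config(cfg, d["out"] / "config.yaml")
    _provenance(cfg, "generate", d["out"] / "provenance_generate.json")
    return d["dataset"]


def _load_pair(role_dir: Path, scan_id: str, target_mm: float) -> VolumePair:
    pair = VolumePair(
        anatomy=read_volume(role_dir / f"{scan_id}_ct.nii.gz"),
        function=read_volume(role_dir / f"{scan_id}_pet.nii.gz"),
    )
    return VolumePair(
        anatomy=resample_isotropic(pair.anatomy, target_mm, "linear"),
        function=resample_isotropic(pair.function, target_mm, "linear"),
    )


def _load_annotation(role_dir: Path, scan_id: str, lesions: pd.DataFrame,
                     target_mm: float) -> LesionAnnotation | None:
    mask_path = role_dir / f"{scan_id}_mask.nii.gz"
    if not mask_path.exists():
        return None
    mask = read_volume(mask_path)
    mask.data = mask.data.astype(np.uint8)
    mask = resample_isotropic(mask, target_mm, "nearest")
    rows = lesions[lesions.scan_id == scan_id]
    infos = [
        LesionInfo(
            lesion_id=int(r.lesion_id),
            centroid_mm=(r.centroid_x_mm, r.centroid_y_mm, r.centroid_z_mm),
            peak_added_suv=float(r.peak_added_suv),
            region_label=int(r.region_label),
        )
        for r in rows.itertuples()
    ]
    return LesionAnnotation(mask=mask, lesions=infos)


def load_scans(cfg: RunConfig, roles: tuple[str, ...]
               ) -> list[tuple[ScanRecord, LesionAnnotation | None]]:
    d = _dirs(cfg)
    manifest_path = _require(d["dataset"] / "manifest.csv", "generate")
    manifest = pd.read_csv(manifest_path)
    lesions_path = d["dataset"] / "lesions.csv"
    lesions = (
        pd.read_csv(lesions_path) if lesions_path.exists()
        else pd.DataFrame(columns=["scan_id"])
    )
    out = []
    for row in manifest.itertuples():
        if row.role not in roles:
            continue
        role_dir = d["dataset"] / row.role
        pair = _load_pair(role_dir, row.scan_id, cfg.resample_mm)
        ann = _load_annotation(role_dir, row.scan_id, lesions, cfg.resample_mm)
        out.append((ScanRecord(row.scan_id, row.role, pair), ann))
    return out


def stage_train(cfg: RunConfig) -> dict[str, Path]:
    d = _dirs(cfg)
    scans = [rec for rec, _ in load_scans(cfg, ("train",))]
    if not scans:
        raise PrerequisiteError("no training scans found; run 'generate' first")
    d["models"].mkdir(parents=True, exist_ok=True)

    tc = dataclasses.replace(cfg.train, seed=substream_seed(cfg.seed, "train"))
    model = build_unet(cfg.model, seed=substream_seed(cfg.seed, "init"))
    model, hist = train(model, scans, tc, checkpoint_path=d["models"] / "bnn.npz")

    base_cfg = dataclasses.replace(cfg.model, predict_variance=False)
    tc_b = dataclasses.replace(cfg.train,
                               seed=substream_seed(cfg.seed, "train_baseline"))
    baseline = build_unet(base_cfg, seed=substream_seed(cfg.seed, "init_baseline"))
    baseline, hist_b = train(baseline, scans, tc_b,
                             checkpoint_path=d["models"] / "baseline_mean.npz")

    (d["models"] / "history.json").write_text(json.dumps(
        {
            "bnn": {"train_loss": hist.train_loss, "val_loss": hist.val_loss},
            "baseline_mean": {"train_loss": hist_b.train_loss,
                              "val_loss": hist_b.val_loss},
        },
        indent=2,
    ))
    _provenance(cfg, "train", d["out"] / "provenance_train.json")
    return {"bnn": d["models"] / "bnn.npz",
            "baseline_mean": d["models"] / "baseline_mean.npz"}


def stage_infer(cfg: RunConfig) -> Path:
    d = _dirs(cfg)
    bnn = load_checkpoint(_require(d["models"] / "bnn.npz", "train"))
    baseline = load_checkpoint(_require(d["models"] / "baseline_mean.npz", "train"))
    scans = load_scans(cfg, ("eval_normal", "eval_abnormal"))
    if not scans:
        raise PrerequisiteError("no evaluation scans found; run 'generate' first")
    d["inference"].mkdir(parents=True, exist_ok=True)
    mc_rng = np.random.default_rng(substream_seed(cfg.seed, "mc"))
    for rec, _ in scans:
        pred = predict_volume(bnn, rec.pair.anatomy, cfg.anomaly.mc_samples, mc_rng)
        zmap = z_score_map(rec.pair.function.data, pred, cfg.anomaly.variance_floor)
        spacing = rec.pair.function.spacing
        origin = rec.pair.function.origin
        write_volume(Volume(zmap.z, spacing, origin),
                     d["inference"] / f"{rec.scan_id}_z.nii.gz")
        write_volume(Volume(pred.mean, spacing, origin),
                     d["inference"] / f"{rec.scan_id}_pred_mean.nii.gz")
        write_volume(Volume(pred.variance, spacing, origin),
                     d["inference"] / f"{rec.scan_id}_pred_var.nii.gz")
        base_mean = predict_volume(baseline, rec.pair.anatomy).mean
        write_volume(Volume(base_mean, spacing, origin),
                     d["inference"] / f"{rec.scan_id}_baseline_mean.nii.gz")
    _provenance(cfg, "infer", d["out"] / "provenance_infer.json")
    return d["inference"]


def stage_evaluate(cfg: RunConfig) -> Path:
    d = _dirs(cfg)
    scans = load_scans(cfg, ("eval_normal", "eval_abnormal"))
    if not scans:
        raise PrerequisiteError("no evaluation scans found; run 'generate' first")
    _require(d["models"] / "bnn.npz", "train")

    spacing = (cfg.resample_mm,) * 3
    z_vols, suv_vols, base_vols, masks, anns, ids = [], [], [], [], [], []
    for rec, ann in scans:
        z_path = _require(d["inference"] / f"{rec.scan_id}_z.nii.gz", "infer")
        z_vols.append(read_volume(z_path).data)
        base_path = d["inference"] / f"{rec.scan_id}_baseline_mean.nii.gz"
        base_vols.append(read_volume(_require(base_path, "infer")).data)
        suv_vols.append(rec.pair.function.data)
        masks.append(None if ann is None else ann.mask.data)
        anns.append(ann)
        ids.append(rec.scan_id)

    roc_z = voxel_roc(z_vols, masks)
    roc_suv = voxel_roc(suv_vols, masks)
    slice_recs = []
    for sid, suv, z, mask in zip(ids, suv_vols, z_vols, masks):
        slice_recs += slice_records(sid, suv, z, mask)
    sroc_z = slice_roc(slice_recs, "z")
    sroc_suv = slice_roc(slice_recs, "suv")

    results = []
    cand_rows = []
    for sid, z, ann in zip(ids, z_vols, anns):
        cands = extract_candidates(
            z, cfg.anomaly.z_threshold, cfg.anomaly.connectivity, spacing,
            scan_id=sid,
        )
        res = match_candidates(cands, ann, cfg.anomaly.radius_mm, scan_id=sid)
        results.append(res)
        for k, cand in enumerate(cands):
            cand_rows.append(
                {
                    "scan_id": sid,
                    "candidate_id": k,
                    "peak_score": cand.peak_score,
                    "centroid_x_mm": cand.centroid_mm[0],
                    "centroid_y_mm": cand.centroid_mm[1],
                    "centroid_z_mm": cand.centroid_mm[2],
                    "n_voxels": len(cand.voxels),
                    "matched_lesion_id": (
                        int(res.matched_lesion_id[k]) if res.candidate_is_tp[k] else ""
                    ),
                }
            )
    froc = froc_curve(results)

    baseline_points = []
    for t in cfg.eval.suv_thresholds:
        baseline_points.append(
            baseline_suv_threshold(suv_vols, anns, t, cfg.anomaly.radius_mm,
                                   spacing, cfg.anomaly.connectivity, ids)
        )
    for t in cfg.eval.abs_error_thresholds:
        baseline_points.append(
            baseline_abs_error(base_vols, suv_vols, anns, t, cfg.anomaly.radius_mm,
                               spacing, cfg.anomaly.connectivity, ids)
        )

    metrics = {
        "n_eval_scans": len(ids),
        "n_lesions": froc.n_lesions,
        "voxel_auroc": {"z": roc_z.auroc, "suv": roc_suv.auroc},
        "slice_auroc": {"z": sroc_z.auroc, "suv": sroc_suv.auroc},
        "froc": {
            "fps_per_scan": [float(v) for v in froc.fps_per_scan],
            "sensitivity": [float(v) for v in froc.sensitivity],
        },
        "sensitivity_at": {
            str(r): sensitivity_at_fp_rate(froc, r) for r in cfg.eval.fp_rates
        },
        "baselines": [
            {
                "method": p.method,
                "threshold": p.threshold,
                "fps_per_scan": p.fps_per_scan,
                "sensitivity": p.sensitivity,
            }
            for p in baseline_points
        ],
    }
    d["evaluation"].mkdir(parents=True, exist_ok=True)
    (d["evaluation"] / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True)
    )
    pd.DataFrame(
        cand_rows,
        columns=["scan_id", "candidate_id", "peak_score", "centroid_x_mm",
                 "centroid_y_mm", "centroid_z_mm", "n_voxels", "matched_lesion_id"],
    ).to_csv(d["evaluation"] / "candidates.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"fps_per_scan": froc.fps_per_scan, "sensitivity": froc.sensitivity}
    ).to_csv(d["evaluation"] / "froc_curve.csv", index=False, float_format="%.10g")
    _provenance(cfg, "evaluate", d["out"] / "provenance_evaluate.json")
    return d["evaluation"] / "metrics.json"


def stage_report(cfg: RunConfig) -> Path:
    d = _dirs(cfg)
    metrics_path = _require(d["evaluation"] / "metrics.json", "evaluate")
    metrics = json.loads(metrics_path.read_text())
    from .evaluation import FROCCurve, OperatingPoint  # local to avoid cycle noise

    froc = FROCCurve(
        fps_per_scan=np.array(metrics["froc"]["fps_per_scan"]),
        sensitivity=np.array(metrics["froc"]["sensitivity"]),
        n_scans=metrics["n_eval_scans"],
        n_lesions=metrics["n_lesions"],
    )
    points = [
        OperatingPoint(b["fps_per_scan"], b["sensitivity"], b["method"],
                       b["threshold"])
        for b in metrics["baselines"]
    ]
    report = compare_methods(
        froc,
        points,
        voxel_aurocs=metrics["voxel_auroc"],
        slice_aurocs=metrics["slice_auroc"],
        fp_rates=cfg.eval.fp_rates,
    )
    d["report"].mkdir(parents=True, exist_ok=True)
    (d["report"] / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    rows = [{"method": "bayesian_z", "fps_per_scan": f, "sensitivity": s}
            for f, s in zip(froc.fps_per_scan, froc.sensitivity)]
    rows += [{"method": p.method, "fps_per_scan": p.fps_per_scan,
              "sensitivity": p.sensitivity} for p in points]
    pd.DataFrame(rows).to_csv(d["report"] / "comparison_points.csv", index=False,
                              float_format="%.10g")
    _provenance(cfg, "report", d["out"] / "provenance_report.json")
    return d["report"] / "report.json"


def run(command: str, cfg: RunConfig) -> None:
    """Run one stage, or all of them in order."""
    if command == "all":
        for stage in STAGES:
            run(stage, cfg)
        return
    if command not in STAGES:
        raise ValueError(f"unknown command {command!r}; expected one of "
                         f"{STAGES + ('all',)}")
    {
        "generate": stage_generate,
        "train": stage_train,
        "infer": stage_infer,
        "evaluate": stage_evaluate,
        "report": stage_report,
    }[command](cfg)
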