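"""End-to-end cascade orchestration.

Runs phantom generation -> preprocessing -> segmentation training and
inference -> postprocessing -> segmentation metrics -> per-gland features ->
per-side classification, writing every artifact (plus a config snapshot)
under the work directory.  Stages can be run individually; the manual-vs-
automatic mask comparison (paired AUC test per side) is exposed as a
first-class operation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import pandas as pd

from . import classify as clf
from . import phantom as ph
from . import postprocess as post
from . import radiomics as rad
from . import seg_metrics as sm
from . import segnet
from .config import RunConfig
from .io import load_volume, save_volume, write_manifest
from .preprocess import PreprocessConfig, preprocess_pair

logger = logging.getLogger(__name__)

__all__ = ["run_cascade", "compare_manual_vs_auto", "CascadeError"]


class CascadeError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage_logger(workdir: Path, stage: str) -> logging.Logger:
    log = logging.getLogger(f"adrenalct.cascade.{stage}")
    logdir = workdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (logdir / f"{stage}.log").resolve()
        for h in log.handlers
    ):
        handler = logging.FileHandler(logdir / f"{stage}.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    return log


# -- individual stages ------------------------------------------------------

def stage_phantoms(config: RunConfig) -> pd.DataFrame:
    p = config["phantom"]
    manifest = ph.generate_cohort(
        n=int(p["n"]),
        prevalence=float(p["prevalence"]),
        laterality_weights=p["laterality_weights"],
        seed=config.seed_for("phantom"),
        out_dir=config.workdir / "cohort",
        dims=tuple(p["dims"]),
        spacing=tuple(p["spacing"]),
        contrast_range=tuple(p["contrast_range"]),
        noise_sigma=p.get("noise_sigma"),
    )
    manifest = ph.split_cohort(
        manifest, ratio=tuple(config["split"]["ratio"]), seed=config.seed_for("split")
    )
    write_manifest(
        manifest.to_dict("records"), config.workdir / "cohort" / "manifest.tsv"
    )
    return manifest


def stage_preprocess(config: RunConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    pc = _preprocess_config(config)
    out_dir = config.workdir / "preprocessed"
    rows = []
    for rec in manifest.to_dict("records"):
        vol = load_volume(rec["image"])
        msk = load_volume(rec["mask"], as_mask=True)
        vol, msk = preprocess_pair(vol, msk, pc)
        rec = dict(rec)
        rec["image"] = str(save_volume(vol, out_dir / Path(rec["image"]).name))
        rec["mask"] = str(save_volume(msk, out_dir / Path(rec["mask"]).name))
        rows.append(rec)
    df = pd.DataFrame(rows)
    write_manifest(rows, out_dir / "manifest.tsv")
    return df


def _preprocess_config(config: RunConfig) -> PreprocessConfig:
    p = config["preprocess"]
    s = config["segnet"]
    return PreprocessConfig(
        target_orientation=p["target_orientation"],
        target_spacing=tuple(p["target_spacing"]),
        window_width=float(p["window_width"]),
        window_level=float(p["window_level"]),
        patch_size=tuple(s["patch_size"]),
        seed=config.seed_for("preprocess"),
    )


def _load_pairs(manifest: pd.DataFrame, split: str):
    sub = manifest[manifest["split"] == split]
    return [
        (load_volume(r["image"]), load_volume(r["mask"], as_mask=True))
        for r in sub.to_dict("records")
    ]


def stage_train_seg(config: RunConfig, manifest: pd.DataFrame):
    s = config["segnet"]
    model = segnet.build_model(
        tuple(s["channel_plan"]), int(s["n_classes"]), bool(s["residual"]),
        seed=config.seed_for("segnet"),
    )
    tc = segnet.TrainConfig(
        lr0=float(s["lr0"]),
        epochs=int(s["epochs"]),
        decay_factor=float(s["decay_factor"]),
        decay_every=int(s["decay_every"]),
        loss_weights=tuple(s["loss_weights"]),
        focal_gamma=float(s["focal_gamma"]),
        focal_alpha=float(s["focal_alpha"]),
        patches_per_epoch=int(s["patches_per_epoch"]),
        patch_size=tuple(s["patch_size"]),
        foreground_bias=float(s["foreground_bias"]),
        noise_sigma_aug=float(s["noise_sigma_aug"]),
        rotation_range_deg=float(s["rotation_range_deg"]),
        seed=config.seed_for("segnet"),
    )
    train_pairs = _load_pairs(manifest, "train")
    valid_pairs = _load_pairs(manifest, "valid")
    if model.n_classes == 2:
        binarize = lambda pairs: [
            (v, m.with_voxels((m.voxels > 0).astype(m.voxels.dtype)))
            for v, m in pairs
        ]
        train_pairs = binarize(train_pairs)
        valid_pairs = binarize(valid_pairs)
    model, history = segnet.train(model, train_pairs, valid_pairs, tc)
    ckpt = config.workdir / "segmodel.npz"
    segnet.save_checkpoint(model, ckpt, history, tc)
    return model, history


def stage_infer_seg(config: RunConfig, manifest: pd.DataFrame, model) -> pd.DataFrame:
    s = config["segnet"]
    pp = config["postprocess"]
    out_dir = config.workdir / "pred_masks"
    rows = []
    for rec in manifest.to_dict("records"):
        vol = load_volume(rec["image"])
        probs = segnet.sliding_window_infer(
            model, vol, tuple(s["patch_size"]), float(s["overlap"])
        )
        pred = segnet.predicted_mask(probs, like=vol)
        if model.n_classes == 2:
            # adrenal-vs-background mode: recover sides geometrically
            pred = post.assign_laterality(pred, vol)
        pred = post.clean_mask(
            pred,
            policy=pp["policy"],
            min_size=int(pp["min_size"]),
            noise_connectivity=int(pp["noise_connectivity"]),
            hole_connectivity=int(pp["hole_connectivity"]),
        )
        rec = dict(rec)
        rec["pred_mask"] = str(
            save_volume(pred, out_dir / Path(rec["mask"]).name.replace("mask", "pred"))
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def stage_eval_seg(config: RunConfig, inferred: pd.DataFrame,
                   split: str = "valid") -> pd.DataFrame:
    reports = []
    for rec in inferred[inferred["split"] == split].to_dict("records"):
        pred = load_volume(rec["pred_mask"], as_mask=True)
        truth = load_volume(rec["mask"], as_mask=True)
        reports.append(sm.evaluate_segmentation(pred, truth))
    agg = sm.aggregate_reports(reports)
    agg.to_csv(config.workdir / f"seg_metrics_{split}.tsv", sep="\t", index=False)
    return agg


def stage_features(config: RunConfig, inferred: pd.DataFrame) -> pd.DataFrame:
    r = config["radiomics"]
    mask_col = "pred_mask" if r["mask_source"] == "auto" else "mask"
    cases = []
    for rec in inferred.to_dict("records"):
        vol = load_volume(rec["image"])
        msk = load_volume(rec[mask_col], as_mask=True)
        cases.append(
            (rec["patient_id"], vol, msk, rec["left_label"], rec["right_label"])
        )
    table = rad.build_feature_table(cases, bin_width=float(r["bin_width"]))
    table = table.merge(
        inferred[["patient_id", "split"]].drop_duplicates(), on="patient_id"
    )
    table.to_csv(config.workdir / "features.tsv", sep="\t", index=False)
    return table


def stage_classify(config: RunConfig, table: pd.DataFrame) -> Dict[str, dict]:
    r = config["radiomics"]
    seed = config.seed_for("classify")
    results: Dict[str, dict] = {}
    for side in ("left", "right"):
        sub = table[table["side"] == side]
        train = sub[sub["split"] == "train"]
        valid = sub[sub["split"] == "valid"]
        selection = rad.select_features(
            train, side, rad.SelectionConfig(cap=int(r["cap"]), seed=seed)
        )
        Xtr = train[selection.selected].to_numpy(float)
        Xva = valid[selection.selected].to_numpy(float)
        comparison = clf.fit_classifiers(
            Xtr, train["label"], Xva, valid["label"],
            model_set=tuple(config["classify"]["model_set"]), seed=seed,
        )
        best = comparison.best
        threshold, j = clf.youden_threshold(best.roc)
        cm = clf.confusion_at_threshold(best.valid_scores, valid["label"], threshold)
        results[side] = {
            "selection": selection,
            "comparison": comparison,
            "selected_model": comparison.selected,
            "threshold": threshold,
            "youden_j": j,
            "valid_labels": valid["label"].to_numpy(int),
            "confusion": cm,
            "summary": {
                "valid_scores": [float(x) for x in best.valid_scores],
                "valid_labels": [int(x) for x in valid["label"]],
                "acc_pct": cm.accuracy * 100,
                "auc_pct": best.roc.auc * 100,
                "auc_ci_pct": [c * 100 for c in best.roc.ci95],
                "sens_pct": cm.sensitivity * 100,
                "spec_pct": cm.specificity * 100,
                "threshold": threshold,
                "n_features": len(selection.selected),
                "model": comparison.selected,
            },
        }
    return results


def run_cascade(config: RunConfig) -> dict:
    """Execute the full stage graph; returns the consolidated report dict
    (also written to ``<workdir>/report.json``)."""
    workdir = config.workdir
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "config_snapshot.yaml")
    report: dict = {"seed": config.seed}
    state: dict = {}
    try:
        stage = "phantom"
        _stage_logger(workdir, stage).info("generating cohort")
        state["manifest"] = stage_phantoms(config)
        stage = "preprocess"
        _stage_logger(workdir, stage).info("preprocessing")
        state["pre"] = stage_preprocess(config, state["manifest"])
        stage = "train_seg"
        _stage_logger(workdir, stage).info("training segmentation model")
        model, history = stage_train_seg(config, state["pre"])
        report["train_final_loss"] = history.train_loss[-1]
        stage = "infer_seg"
        _stage_logger(workdir, stage).info("running inference")
        state["inferred"] = stage_infer_seg(config, state["pre"], model)
        stage = "eval_seg"
        seg_table = stage_eval_seg(config, state["inferred"])
        report["seg_metrics"] = seg_table.to_dict("records")
        stage = "features"
        _stage_logger(workdir, stage).info("extracting features")
        state["features"] = stage_features(config, state["inferred"])
        stage = "classify"
        _stage_logger(workdir, stage).info("fitting classifiers")
        clf_results = stage_classify(config, state["features"])
        report["classification"] = {
            side: res["summary"] for side, res in clf_results.items()
        }
        report["selected_classifier"] = {
            side: res["selected_model"] for side, res in clf_results.items()
        }
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise CascadeError(stage, str(exc)) from exc
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def compare_manual_vs_auto(cases_manual, cases_auto, split_by_patient: dict,
                           seed: int = 0, model_name: str = "random_forest",
                           bin_width: float = rad.DEFAULT_BIN_WIDTH,
                           cap: int = 24) -> Dict[str, clf.DelongResult]:
    """Paired AUC comparison of classifiers built from manual vs automatic
    masks.

    ``cases_*``: iterables of (patient_id, volume, mask, left_label,
    right_label) covering the same patients; ``split_by_patient`` maps
    patient_id -> 'train' / 'valid'.  Returns a DelongResult per side.
    """
    cases_manual = list(cases_manual)
    cases_auto = list(cases_auto)
    ids_m = [c[0] for c in cases_manual]
    ids_a = [c[0] for c in cases_auto]
    if set(ids_m) != set(ids_a):
        missing = sorted(set(ids_m) ^ set(ids_a))
        raise ValueError(f"patient mismatch between manifests: {missing}")

    def side_scores(cases):
        table = rad.build_feature_table(cases, bin_width=bin_width)
        table["split"] = table["patient_id"].map(split_by_patient)
        out = {}
        for side in ("left", "right"):
            sub = table[table["side"] == side]
            train = sub[sub["split"] == "train"]
            valid = sub[sub["split"] == "valid"].sort_values("patient_id")
            selection = rad.select_features(
                train, side, rad.SelectionConfig(cap=cap, seed=seed)
            )
            comparison = clf.fit_classifiers(
                train[selection.selected].to_numpy(float), train["label"],
                valid[selection.selected].to_numpy(float), valid["label"],
                model_set=(model_name,), seed=seed,
            )
            out[side] = (
                comparison.best.valid_scores,
                valid["label"].to_numpy(int),
                valid["patient_id"].tolist(),
            )
        return out

    manual = side_scores(cases_manual)
    auto = side_scores(cases_auto)
    results = {}
    for side in ("left", "right"):
        sc_m, y_m, pid_m = manual[side]
        sc_a, y_a, pid_a = auto[side]
        if pid_m != pid_a:
            raise ValueError(f"validation patients differ for side {side}")
        results[side] = clf.delong_test(sc_m, sc_a, y_m, paired=True)
    return results
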