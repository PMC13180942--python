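"""End-to-end orchestration: simulate -> detect -> label -> train with
mining -> fuse/calibrate -> evaluate -> explain, plus the ablation ladder.

The ladder isolates each component cumulatively on the same cohort and
seeds:

1. ``baseline``      — detector-only: decide s >= tau_s.
2. ``+hnm``          — a plain ROI classifier trained *with* hard-negative
                       mining (no confidence conditioning); decide on y_hat.
3. ``+adjudicator``  — the confidence-conditioned adjudicator (z = [psi; s]),
                       still with mining; decide on y_hat.
4. ``+fusion``       — convex score fusion S = alpha*y_hat + (1-alpha)*s
                       with alpha tuned on validation; decide on S.

All thresholds (alpha, tau, tau_mine) are selected on the validation split
only; the test split is touched exactly once per configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .adjnet import AdjudicatorModel, TrainConfig, TrainHistory, predict_proba, train
from .boxes import Box, Detection
from .fuse import (
    DEFAULT_ALPHA,
    brier,
    bootstrap_ci,
    calibration_report,
    ece,
    fuse_scores,
    select_alpha,
    select_threshold,
)
from .metrics import (
    average_precision,
    classification_metrics,
    confusion_from_predictions,
    map_at_iou,
    roc_auc,
)
from .mining import MiningConfig, MiningPool, make_mining_hook
from .roidata import (
    AugmentConfig,
    RoiRecord,
    SplitSpec,
    assert_patient_disjoint,
    box_to_patch_coords,
    build_roi_records,
    split_by_patient,
    write_roi_manifest,
)
from .synthgen import DetectorConfig, SceneConfig, SyntheticScene, mock_detect, generate_cohort
from .xai import gradcam, heatmap_to_mask, localization_scores

PATCH_MEAN = 0.45
PATCH_SD = 0.25
CONFOUNDER_SITE_IOU = 0.3
MATCHED_RECALL = 0.9

LADDER = ("baseline", "+hnm", "+adjudicator", "+fusion")


@dataclass(frozen=True)
class AblationFlags:
    """Which components are active.  ``adjudicator`` here means the
    confidence conditioning of the classifier head; with it off the model
    sees a constant 0.5 in place of s."""

    classifier: bool = True
    mining: bool = True
    adjudicator: bool = True
    fusion: bool = True

    @classmethod
    def for_row(cls, row: str) -> "AblationFlags":
        return {
            "baseline": cls(classifier=False, mining=False, adjudicator=False, fusion=False),
            "+hnm": cls(classifier=True, mining=True, adjudicator=False, fusion=False),
            "+adjudicator": cls(classifier=True, mining=True, adjudicator=True, fusion=False),
            "+fusion": cls(classifier=True, mining=True, adjudicator=True, fusion=True),
        }[row]


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale defaults: 256x256 scenes, 64x64 patches, 4-block CNN,
    12 epochs at lr 7e-4 — minutes on one CPU.  One global seed derives the
    scene, detector, split, training and bootstrap streams."""

    seed: int = 0
    n_patients: int = 100
    scenes_per_patient: int = 2
    scene: SceneConfig = field(default_factory=SceneConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    split_ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    patch_size: int = 64
    context_pad: float = 0.5
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            max_epochs=12,
            learning_rate=7e-4,
            augment_config=AugmentConfig(
                rotation_deg=8.0, brightness=0.08, translate_frac=0.04,
                scale_frac=0.04, hflip=True,
            ),
        )
    )
    mining: MiningConfig = field(default_factory=MiningConfig)
    flags: AblationFlags = field(default_factory=AblationFlags)
    alpha_grid_step: float = 0.05
    n_calib_bins: int = 10
    n_boot: int = 200
    out_dir: Optional[str] = None


@dataclass
class BenchmarkData:
    """A fully prepared patient-disjoint benchmark: scenes, detections,
    labeled ROI records and their split assignment."""

    scenes: list[SyntheticScene]
    detections: list[list[Detection]]
    train: list[RoiRecord]
    val: list[RoiRecord]
    test: list[RoiRecord]
    scene_index: dict[str, int]  # image_id -> scene position
    config: ExperimentConfig

    def scene_of(self, record: RoiRecord) -> SyntheticScene:
        return self.scenes[self.scene_index[record.image_id]]


def _derive_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def build_benchmark(config: ExperimentConfig) -> BenchmarkData:
    """Generate the cohort, run the mock detector, label and crop ROIs and
    make the patient-disjoint split."""
    scene_seed, det_seed, split_seed, *_ = _derive_seeds(config.seed)
    scene_cfg = replace(config.scene, seed=scene_seed)
    det_cfg = replace(config.detector, seed=det_seed)
    scenes = generate_cohort(scene_cfg, config.n_patients, config.scenes_per_patient)
    detections = [mock_detect(s, det_cfg) for s in scenes]
    records: list[RoiRecord] = []
    scene_index: dict[str, int] = {}
    for i, (scene, dets) in enumerate(zip(scenes, detections)):
        image_id = f"scene_{i:05d}"
        scene_index[image_id] = i
        records.extend(
            build_roi_records(
                scene,
                dets,
                patch_size=config.patch_size,
                mean=PATCH_MEAN,
                sd=PATCH_SD,
                context_pad=config.context_pad,
                image_id=image_id,
            )
        )
    spec = SplitSpec(ratios=config.split_ratios, seed=split_seed)
    train_r, val_r, test_r = split_by_patient(records, spec)
    return BenchmarkData(
        scenes=scenes,
        detections=detections,
        train=train_r,
        val=val_r,
        test=test_r,
        scene_index=scene_index,
        config=config,
    )


def is_confounder_sited(record: RoiRecord, scene: SyntheticScene) -> bool:
    """A negative ROI 'sits on' a confounder if it overlaps one at IoU >=
    0.3 (growth plate, overlapping edges, implant)."""
    from .metrics import iou

    return any(
        iou(record.box, cb.box) >= CONFOUNDER_SITE_IOU for cb in scene.confounder_boxes
    )


def _with_model_confidence(records: Sequence[RoiRecord], use_s: bool) -> list[RoiRecord]:
    if use_s:
        return list(records)
    return [replace(r, s=0.5) for r in records]


def _build_pool(
    data: BenchmarkData, mining_on: bool, use_s: bool, mining_cfg: MiningConfig
) -> MiningPool:
    """Initial pool: positives + easy negatives; confounder-sited training
    negatives form the mining reservoir (ignored entirely when mining is
    off)."""
    pos, easy_neg, hard_candidates = [], [], []
    for r in data.train:
        if r.y == 1:
            pos.append(r)
        elif is_confounder_sited(r, data.scene_of(r)):
            hard_candidates.append(r)
        else:
            easy_neg.append(r)
    pos = _with_model_confidence(pos, use_s)
    easy_neg = _with_model_confidence(easy_neg, use_s)
    reservoir = _with_model_confidence(hard_candidates, use_s) if mining_on else []
    return MiningPool(
        P=pos,
        N0=easy_neg,
        reservoir=reservoir,
        allow_duplicates=mining_cfg.allow_duplicates,
        max_pool_growth=mining_cfg.max_pool_growth,
    )


def threshold_for_recall(
    scores: np.ndarray, labels: np.ndarray, target_recall: float
) -> float:
    """Largest threshold of the rule (S >= tau) reaching the target recall
    (0.0 if even accepting everything falls short)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.sort(s[y == 1])[::-1]
    if len(pos) == 0:
        raise ValueError("no positives")
    k = int(np.ceil(target_recall * len(pos)))
    k = max(1, min(k, len(pos)))
    return float(pos[k - 1])


def confounder_fp_count_at_recall(
    data: BenchmarkData,
    test_scores: np.ndarray,
    target_recall: float = MATCHED_RECALL,
) -> int:
    """False positives sited on confounders when the test threshold is set
    to the matched-recall operating point."""
    y = np.array([r.y for r in data.test])
    tau = threshold_for_recall(test_scores, y, target_recall)
    count = 0
    for r, s_val in zip(data.test, test_scores):
        if r.y == 0 and s_val >= tau and is_confounder_sited(r, data.scene_of(r)):
            count += 1
    return count


def _map50(
    data: BenchmarkData,
    test_scene_ids: set[int],
    roi_scores: dict[tuple, float],
    tau: Optional[float],
) -> float:
    """Detection-level mAP@0.5 on the test scenes.

    Each surviving proposal is re-scored with its final (adjudicated or
    fused) score; proposals below tau are removed when tau is given.
    """
    dets_per_image, gts_per_image = [], []
    for i in sorted(test_scene_ids):
        scene = data.scenes[i]
        kept = []
        for d in data.detections[i]:
            key = (i, round(d.box.x_min), round(d.box.y_min), round(d.box.x_max), round(d.box.y_max))
            score = roi_scores.get(key, d.score)
            if tau is None or score >= tau:
                kept.append(Detection(d.box, min(max(score, 0.0), 1.0)))
        dets_per_image.append(kept)
        gts_per_image.append(list(scene.fracture_boxes))
    if sum(len(g) for g in gts_per_image) == 0:
        return float("nan")
    return map_at_iou(dets_per_image, gts_per_image, 0.5)


def evaluate_localization(
    model: AdjudicatorModel,
    data: BenchmarkData,
    records: Sequence[RoiRecord],
    use_s: bool,
    rel_threshold: float = 0.5,
) -> dict:
    """Grad-CAM localization on true-fracture ROIs of the given split:
    mask IoU, Dice, pointing-game accuracy and the area-chance rate."""
    from .metrics import iou

    ious, dices, hits, chances = [], [], [], []
    for r in records:
        if r.y != 1:
            continue
        scene = data.scene_of(r)
        gt = max(scene.fracture_boxes, key=lambda fb: iou(r.box, fb))
        h, w = scene.image.shape
        crop_box = r.box.pad(data.config.context_pad).clamp(w, h)
        expert = box_to_patch_coords(gt, crop_box, data.config.patch_size)
        sal = gradcam(model, r.patch, r.s if use_s else 0.5)
        mask = heatmap_to_mask(sal.heatmap, rel_threshold)
        iou_v, dice_v, hit = localization_scores(sal.heatmap, mask, expert)
        ious.append(iou_v)
        dices.append(dice_v)
        hits.append(hit)
        chances.append(expert.area / (data.config.patch_size**2))
    if not hits:
        return {"mask_iou": float("nan"), "dice": float("nan"),
                "pointing_accuracy": float("nan"), "chance_rate": float("nan"), "n": 0}
    return {
        "mask_iou": float(np.mean(ious)),
        "dice": float(np.mean(dices)),
        "pointing_accuracy": float(np.mean(hits)),
        "chance_rate": float(np.mean(chances)),
        "n": len(hits),
    }


@dataclass
class EvalReport:
    configuration: str
    alpha: float
    tau: float
    metrics: dict
    calibration: dict
    pool_sizes: tuple[int, int, int]
    history: Optional[TrainHistory] = None
    localization: Optional[dict] = None
    model: Optional[AdjudicatorModel] = None

    def to_dict(self) -> dict:
        out = {
            "configuration": self.configuration,
            "alpha": self.alpha,
            "tau": self.tau,
            "metrics": self.metrics,
            "calibration": self.calibration,
            "pool_sizes": list(self.pool_sizes),
        }
        if self.localization is not None:
            out["localization"] = self.localization
        return out


def evaluate_config(
    data: BenchmarkData,
    flags: AblationFlags,
    name: str = "",
    with_localization: bool = False,
) -> EvalReport:
    """Train (if the configuration has a classifier) and evaluate one
    ablation configuration on the shared benchmark."""
    config = data.config
    _, _, _, train_seed, boot_seed, _ = _derive_seeds(config.seed)
    y_val = np.array([r.y for r in data.val])
    y_test = np.array([r.y for r in data.test])
    s_val = np.array([r.s for r in data.val])
    s_test = np.array([r.s for r in data.test])

    model = None
    history = None
    pool_sizes = (0, 0, 0)
    if flags.classifier:
        pool = _build_pool(data, flags.mining, flags.adjudicator, config.mining)
        model = AdjudicatorModel(
            patch_size=config.patch_size,
            seed=_derive_seeds(train_seed)[0],
            dtype=np.float32,
        )
        hook = None
        if flags.mining:
            hook = make_mining_hook(
                fuse_fn=lambda y_hat, s: fuse_scores(y_hat, s, DEFAULT_ALPHA),
                tau_mine=config.mining.tau_mine,
                cadence_epochs=config.mining.cadence_epochs,
            )
        val_for_train = _with_model_confidence(data.val, flags.adjudicator)
        tcfg = replace(config.train, seed=train_seed)
        model, history = train(model, pool, val_for_train, tcfg, mining_hook=hook)
        pool_sizes = history.n_pos[-1], history.n_neg0[-1], history.n_hard[-1]
        y_hat_val = predict_proba(model, val_for_train)
        y_hat_test = predict_proba(
            model, _with_model_confidence(data.test, flags.adjudicator)
        )
    else:
        y_hat_val = y_hat_test = None

    if not flags.classifier:
        alpha = 0.0
        tau, _ = select_threshold(s_val, y_val)
        scores_val, scores_test = s_val, s_test
    elif flags.fusion:
        alpha, tau, _ = select_alpha(y_hat_val, s_val, y_val, config.alpha_grid_step)
        scores_val = fuse_scores(y_hat_val, s_val, alpha)
        scores_test = fuse_scores(y_hat_test, s_test, alpha)
    else:
        alpha = 1.0
        tau, _ = select_threshold(y_hat_val, y_val)
        scores_val, scores_test = y_hat_val, y_hat_test

    pred_test = scores_test >= tau
    cm = confusion_from_predictions(y_test, pred_test)
    mets = classification_metrics(cm)
    mets["roc_auc"] = roc_auc(scores_test, y_test)
    mets["average_precision"] = average_precision(scores_test, y_test)

    test_scene_ids = {data.scene_index[r.image_id] for r in data.test}
    roi_scores = {
        (data.scene_index[r.image_id], round(r.box.x_min), round(r.box.y_min),
         round(r.box.x_max), round(r.box.y_max)): float(sc)
        for r, sc in zip(data.test, scores_test)
    }
    mets["map50"] = _map50(
        data, test_scene_ids, roi_scores, tau if flags.classifier else None
    )
    mets["confounder_fp_at_matched_recall"] = confounder_fp_count_at_recall(
        data, scores_test
    )

    def _f1_fixed_tau(s_arr, y_arr):
        c = confusion_from_predictions(y_arr, s_arr >= tau)
        return classification_metrics(c)["f1"]

    ci = bootstrap_ci(
        _f1_fixed_tau, scores_test, y_test, n_boot=config.n_boot, seed=boot_seed
    )
    mets["f1_ci_low"], mets["f1_ci_high"] = ci

    rep = calibration_report(scores_test, y_test, config.n_calib_bins)
    calib = {
        "ece": rep.ece,
        "brier": rep.brier,
        "ece_detector_raw": ece(s_test, y_test, config.n_calib_bins),
        "brier_detector_raw": brier(s_test, y_test),
    }

    localization = None
    if with_localization and model is not None:
        localization = evaluate_localization(
            model, data, data.test, use_s=flags.adjudicator
        )

    return EvalReport(
        configuration=name or "custom",
        alpha=float(alpha),
        tau=float(tau),
        metrics={k: float(v) for k, v in mets.items()},
        calibration=calib,
        pool_sizes=pool_sizes,
        history=history,
        localization=localization,
        model=model,
    )


def run_pipeline(config: ExperimentConfig) -> EvalReport:
    """The full workflow under one configuration; persists artifacts when
    ``config.out_dir`` is set."""
    data = build_benchmark(config)
    assert_patient_disjoint(data.train, data.val, data.test)
    name = "full" if config.flags.classifier else "baseline"
    report = evaluate_config(
        data, config.flags, name=name, with_localization=config.flags.classifier
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for split, recs in (("train", data.train), ("val", data.val), ("test", data.test)):
            write_roi_manifest(recs, out / f"rois_{split}.csv")
        if report.history is not None:
            report.history.to_csv(out / "train_history.csv")
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        import pandas as pd

        pd.DataFrame(
            [{"metric": k, "value": v} for k, v in
             {**report.metrics, **report.calibration}.items()]
        ).to_csv(out / "metrics.csv", index=False)
    return report


def run_ablation(
    config: ExperimentConfig, seeds: Sequence[int] = (0,)
) -> list[dict]:
    """The four-row ablation ladder, per seed, on a shared cohort per seed.

    Returns one row dict per (seed, configuration) with mAP@0.5, F1 and ECE
    (plus the full metric set)."""
    rows = []
    for seed in seeds:
        cfg = replace(config, seed=int(seed))
        data = build_benchmark(cfg)
        for row_name in LADDER:
            rep = evaluate_config(data, AblationFlags.for_row(row_name), name=row_name)
            rows.append(
                {
                    "seed": int(seed),
                    "configuration": row_name,
                    "map50": rep.metrics["map50"],
                    "f1": rep.metrics["f1"],
                    "ece": rep.calibration["ece"],
                    "report": rep.to_dict(),
                }
            )
    return rows
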