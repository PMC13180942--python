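"""From scenes + detections to labeled ROI records.

Covers label assignment by IoU overlap against expert fracture boxes,
crop/resize/normalize of ROI patches, seeded augmentation, patient-disjoint
splitting, and annotation I/O (YOLO-txt, a COCO-like JSON dialect, PNG
scenes and CSV manifests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .boxes import Box, Detection
from .metrics import iou
from .synthgen import ConfounderBox, SyntheticScene

PROVENANCES = ("orig_pos", "orig_neg", "mined_neg")

DEFAULT_LABEL_IOU = 0.5  # matches the NMS/evaluation IoU used throughout


@dataclass(frozen=True)
class RoiRecord:
    """One labeled ROI: patch, box, detector confidence, label, provenance."""

    patch: np.ndarray  # patch_size x patch_size, normalized intensities
    box: Box  # in source-image coordinates
    s: float  # detector confidence in [0, 1]
    y: int  # 1 = fracture, 0 = non-fracture
    patient_id: str
    provenance: str = "orig_neg"
    image_id: str = ""  # source scene identifier (for de-duplication keys)

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must be in [0, 1]")
        if self.y not in (0, 1):
            raise ValueError("y must be binary")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    def key(self) -> tuple[str, int, int, int, int]:
        """De-duplication key: source image + integer-rounded box."""
        return (
            self.image_id,
            int(round(self.box.x_min)),
            int(round(self.box.y_min)),
            int(round(self.box.x_max)),
            int(round(self.box.y_max)),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (defaults 0.8/0.1/0.1) and a shuffle seed."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3:
            raise ValueError("exactly three ratios required")
        if any(not 0.0 < r < 1.0 for r in self.ratios):
            raise ValueError("each ratio must lie in (0, 1)")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


def assign_label(
    detection: Detection,
    fracture_boxes: Sequence[Box],
    iou_threshold: float = DEFAULT_LABEL_IOU,
) -> int:
    """1 iff the detection overlaps some expert fracture box at
    IoU >= ``iou_threshold``, else 0 (0 when there are no fracture boxes)."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    if not fracture_boxes:
        return 0
    best = max(iou(detection.box, fb) for fb in fracture_boxes)
    return int(best >= iou_threshold)


def crop_roi(
    image: np.ndarray,
    box: Box,
    patch_size: int,
    mean: float = 0.0,
    sd: float = 1.0,
    context_pad: float = 0.0,
) -> np.ndarray:
    """Crop a (clamped, optionally context-padded) box and bilinearly resize
    to ``patch_size`` square, then normalize as ``(patch - mean) / sd``.

    The defaults are identity normalization; training profiles pass the
    dataset statistics.  Raises on a zero-area intersection with the image.
    """
    h, w = image.shape[:2]
    if context_pad > 0.0:
        box = box.pad(context_pad)
    box = box.clamp(w, h)  # raises if the intersection is empty
    x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    crop = image[y0:y1, x0:x1].astype(float)
    if crop.shape != (patch_size, patch_size):
        crop = _sk_resize(
            crop, (patch_size, patch_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return (crop - mean) / sd


def box_to_patch_coords(
    box: Box, crop_box: Box, patch_size: int
) -> Box:
    """Map an image-coordinate box into the coordinate frame of a patch that
    was cropped from ``crop_box`` and resized to ``patch_size`` square."""
    sx = patch_size / crop_box.width
    sy = patch_size / crop_box.height
    x0 = np.clip((box.x_min - crop_box.x_min) * sx, 0, patch_size - 1)
    y0 = np.clip((box.y_min - crop_box.y_min) * sy, 0, patch_size - 1)
    x1 = np.clip((box.x_max - crop_box.x_min) * sx, x0 + 1, patch_size)
    y1 = np.clip((box.y_max - crop_box.y_min) * sy, y0 + 1, patch_size)
    return Box(float(x0), float(y0), float(x1), float(y1))


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the training-time augmentations (evaluation never augments).

    ``rotation_deg`` — max |rotation| in degrees; ``brightness`` — max
    additive intensity shift; ``translate_frac`` / ``scale_frac`` — affine
    translation (fraction of side) and isotropic rescale range; ``hflip`` —
    allow horizontal flips.  All-zero ranges give the identity transform.
    """

    rotation_deg: float = 10.0
    brightness: float = 0.10
    translate_frac: float = 0.05
    scale_frac: float = 0.05
    hflip: bool = True


def augment(patch: np.ndarray, config: AugmentConfig, seed: int) -> np.ndarray:
    """Seeded random rotation + brightness + affine jitter of one patch.

    Output shape equals input shape; identical seeds give identical output.
    Intensities are shifted before any clipping so a constant patch moves by
    exactly the drawn brightness delta.
    """
    rng = np.random.default_rng(seed)
    out = patch.astype(float)
    n = out.shape[0]

    if config.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    scale = 1.0 + rng.uniform(-config.scale_frac, config.scale_frac)
    tx, ty = rng.uniform(-config.translate_frac, config.translate_frac, size=2) * n
    if scale != 1.0 or tx != 0.0 or ty != 0.0:
        center = (n - 1) / 2.0
        matrix = np.array([[1.0 / scale, 0.0], [0.0, 1.0 / scale]])
        offset = center - matrix @ np.array([center + ty, center + tx])
        out = ndimage.affine_transform(out, matrix, offset=offset, order=1, mode="nearest")
    out = out + rng.uniform(-config.brightness, config.brightness)
    return out


def build_roi_records(
    scene: SyntheticScene,
    detections: Sequence[Detection],
    patch_size: int,
    iou_threshold: float = DEFAULT_LABEL_IOU,
    mean: float = 0.0,
    sd: float = 1.0,
    context_pad: float = 0.0,
    image_id: str = "",
) -> list[RoiRecord]:
    """Label every detection against the scene's fracture boxes and crop its
    patch.  Provenance is ``orig_pos``/``orig_neg`` by label."""
    records = []
    for det in detections:
        y = assign_label(det, scene.fracture_boxes, iou_threshold)
        patch = crop_roi(
            scene.image, det.box, patch_size, mean=mean, sd=sd, context_pad=context_pad
        )
        records.append(
            RoiRecord(
                patch=patch,
                box=det.box,
                s=det.score,
                y=y,
                patient_id=scene.patient_id,
                provenance="orig_pos" if y == 1 else "orig_neg",
                image_id=image_id or scene.patient_id,
            )
        )
    return records


def split_by_patient(
    records: Sequence[RoiRecord], spec: SplitSpec
) -> tuple[list[RoiRecord], list[RoiRecord], list[RoiRecord]]:
    """Patient-disjoint train/val/test partition.

    Patients are shuffled with the spec seed, then assigned greedily: each
    patient goes to the not-yet-full split whose ROI shortfall (target
    fraction x N minus current size) is largest.  With uniform ROIs per
    patient and compatible counts this hits the target ratios exactly; it
    can never place one patient in two splits.
    """
    if not records:
        raise ValueError("no records to split")
    by_patient: dict[str, list[RoiRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    patients = sorted(by_patient)
    if len(patients) < 3:
        raise ValueError("patient-disjoint split requires at least 3 patients")
    rng = np.random.default_rng(spec.seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_total = len(records)
    targets = [r * n_total for r in spec.ratios]
    splits: tuple[list[RoiRecord], ...] = ([], [], [])
    for pid in order:
        shortfalls = [targets[k] - len(splits[k]) for k in range(3)]
        k = int(np.argmax(shortfalls))
        splits[k].extend(by_patient[pid])
    train, val, test = splits
    assert_patient_disjoint(train, val, test)
    return train, val, test


def assert_patient_disjoint(*splits: Sequence[RoiRecord]) -> None:
    """Raise if any patient identifier appears in more than one split."""
    seen: dict[str, int] = {}
    for k, part in enumerate(splits):
        for pid in {r.patient_id for r in part}:
            if pid in seen and seen[pid] != k:
                raise ValueError(f"patient {pid} leaks across splits")
            seen[pid] = k


# ---------------------------------------------------------------------------
# annotation and manifest I/O

_CATEGORIES = ("fracture", "growth_plate", "overlap", "implant")


def write_scene_png(scene: SyntheticScene, path: str | Path) -> None:
    """Scene image as 8-bit grayscale PNG."""
    arr = np.clip(scene.image * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def read_scene_png(path: str | Path) -> np.ndarray:
    """Grayscale PNG back to float intensities in [0, 1]."""
    return np.asarray(Image.open(str(path)).convert("L"), dtype=float) / 255.0


def write_yolo_txt(boxes: Sequence[Box], width: int, height: int, path: str | Path) -> None:
    """Fracture boxes in YOLO-txt: ``class cx cy w h`` normalized, class 0.

    Values are written with ``repr`` so the reader recovers the exact
    floats; with integer box coordinates and power-of-two image dimensions
    the box -> normalized -> box round trip is itself exact.
    """
    lines = []
    for b in boxes:
        cx = (b.x_min + b.x_max) / (2.0 * width)
        cy = (b.y_min + b.y_max) / (2.0 * height)
        bw = b.width / width
        bh = b.height / height
        lines.append(f"0 {cx!r} {cy!r} {bw!r} {bh!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: str | Path, width: int, height: int) -> list[Box]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _cls, cx, cy, bw, bh = line.split()
        cxf, cyf, bwf, bhf = float(cx), float(cy), float(bw), float(bh)
        boxes.append(
            Box(
                (cxf - bwf / 2) * width,
                (cyf - bhf / 2) * height,
                (cxf + bwf / 2) * width,
                (cyf + bhf / 2) * height,
            )
        )
    return boxes


def write_coco_json(scenes: Sequence[SyntheticScene], path: str | Path) -> None:
    """COCO-like dialect: images carry patient ids; annotations carry
    ``bbox=[x_min, y_min, width, height]`` and a category name."""
    images, annotations = [], []
    for i, scene in enumerate(scenes):
        h, w = scene.image.shape
        images.append(
            {"id": i, "file": f"scene_{i:05d}.png", "patient_id": scene.patient_id,
             "height": h, "width": w}
        )
        for b in scene.fracture_boxes:
            annotations.append(
                {"image_id": i, "bbox": [b.x_min, b.y_min, b.width, b.height],
                 "category": "fracture"}
            )
        for cb in scene.confounder_boxes:
            annotations.append(
                {"image_id": i,
                 "bbox": [cb.box.x_min, cb.box.y_min, cb.box.width, cb.box.height],
                 "category": cb.kind}
            )
    Path(path).write_text(json.dumps({"images": images, "annotations": annotations}))


def read_coco_json(path: str | Path) -> dict:
    """Parse the COCO-like dialect into images + per-image Box lists."""
    data = json.loads(Path(path).read_text())
    per_image: dict[int, dict[str, list]] = {
        img["id"]: {"meta": img, "fracture": [], "confounders": []}
        for img in data["images"]
    }
    for ann in data["annotations"]:
        x, y, w, h = ann["bbox"]
        box = Box(x, y, x + w, y + h)
        cat = ann["category"]
        if cat not in _CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        entry = per_image[ann["image_id"]]
        if cat == "fracture":
            entry["fracture"].append(box)
        else:
            entry["confounders"].append(ConfounderBox(box, cat))
    return per_image


MANIFEST_COLUMNS = (
    "image_file", "x_min", "y_min", "x_max", "y_max", "s", "y",
    "patient_id", "provenance",
)


def write_roi_manifest(records: Sequence[RoiRecord], path: str | Path) -> None:
    rows = [
        {
            "image_file": r.image_id, "x_min": r.box.x_min, "y_min": r.box.y_min,
            "x_max": r.box.x_max, "y_max": r.box.y_max, "s": r.s, "y": r.y,
            "patient_id": r.patient_id, "provenance": r.provenance,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_roi_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"image_file": str, "patient_id": str})
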