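"""Synthetic radiograph-like benchmark scenes and a mock high-recall detector.

The generator emulates the ROI-level structure of pediatric wrist
radiographs at desk scale: bright elongated "bone" bands on a noisy
background, thin sharp dark discontinuities crossing a band (fracture
positives), smooth wide transverse lucent bands (growth-plate confounders),
bright crossing edges from superimposed bones (overlap confounders) and,
optionally, small saturated implant-like blobs.  Every structure carries a
tight ground-truth box, and every scene a patient identifier so splits can
be made patient-disjoint.

The mock detector stands in for a fine-tuned single-class detector run in a
high-recall configuration: one jittered proposal per true fracture, false
alarms sited on confounders and at random locations, type-specific
Beta-distributed confidences (informative but imperfect and, by default,
overconfident on false alarms), a low confidence threshold and greedy NMS.
A real detector can be plugged in through the same ``Detection`` contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .boxes import Box, Detection
from .metrics import nms

_MIN_DIM = 64
_STRUCT_MARGIN = 6  # keep structure boxes this far from the image border
_MIN_BOX_SIDE = 24  # expand tight boxes to at least this side length


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    ``confounder_rates`` are per-bone probabilities for (growth-plate,
    overlap, implant) structures; the implant entry may be omitted.
    """

    image_height: int = 256
    image_width: int = 256
    n_bones: int = 3
    fracture_rate: float = 0.5
    confounder_rates: tuple[float, ...] = (0.6, 0.4)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < _MIN_DIM or self.image_width < _MIN_DIM:
            raise ValueError(f"image dimensions must be >= {_MIN_DIM}")
        rates = (self.fracture_rate, *self.confounder_rates)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_bones < 0:
            raise ValueError("n_bones must be non-negative")


@dataclass(frozen=True)
class ConfounderBox:
    box: Box
    kind: str  # growth_plate | overlap | implant


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # H x W grayscale in [0, 1]
    fracture_boxes: tuple[Box, ...]
    confounder_boxes: tuple[ConfounderBox, ...]
    patient_id: str


@dataclass(frozen=True)
class DetectorConfig:
    """Mock-detector behaviour.

    ``fp_rate_confounder`` is the probability that each confounder box emits
    a false-positive proposal (so the expected count per scene is that
    probability times the number of confounders); ``fp_rate_random`` is the
    Poisson mean of off-structure false positives per scene.
    ``conf_distributions`` maps proposal type (``tp``, ``confounder``,
    ``random``) to Beta(a, b) parameters on [0, 1]; the defaults make the
    confidence informative but overconfident on confounder false alarms,
    which is the regime a second-stage adjudicator exists to fix.
    """

    conf_threshold: float = 0.25
    nms_iou: float = 0.5
    jitter_sd: float = 2.0
    fp_rate_confounder: float = 0.8
    fp_rate_random: float = 1.0
    conf_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tp": (9.0, 1.8),
            "confounder": (7.5, 2.4),
            "random": (2.5, 3.5),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conf_threshold < 1.0:
            raise ValueError("conf_threshold must be in (0, 1)")
        if not 0.0 < self.nms_iou < 1.0:
            raise ValueError("nms_iou must be in (0, 1)")


# ---------------------------------------------------------------------------
# scene rendering helpers


def _segment_distance(
    yy: np.ndarray, xx: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Per-pixel distance to the segment p0-p1 (points are (x, y))."""
    d = p1 - p0
    len2 = float(d @ d)
    t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / max(len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    px = p0[0] + t * d[0]
    py = p0[1] + t * d[1]
    return np.hypot(xx - px, yy - py)


def _soft_band(dist: np.ndarray, half_width: float, softness: float) -> np.ndarray:
    """Smooth indicator of |dist| < half_width with a sigmoid edge."""
    return 1.0 / (1.0 + np.exp((dist - half_width) / max(softness, 1e-6)))


def _tight_box(
    cx: float, cy: float, ext_x: float, ext_y: float, width: int, height: int
) -> Box:
    side_x = max(2.0 * ext_x, float(_MIN_BOX_SIDE))
    side_y = max(2.0 * ext_y, float(_MIN_BOX_SIDE))
    x0 = int(round(cx - side_x / 2))
    y0 = int(round(cy - side_y / 2))
    x1 = int(round(cx + side_x / 2))
    y1 = int(round(cy + side_y / 2))
    x0 = max(0, min(x0, width - _MIN_BOX_SIDE))
    y0 = max(0, min(y0, height - _MIN_BOX_SIDE))
    x1 = min(width, max(x1, x0 + _MIN_BOX_SIDE))
    y1 = min(height, max(y1, y0 + _MIN_BOX_SIDE))
    return Box(float(x0), float(y0), float(x1), float(y1))


def generate_scene(config: SceneConfig, patient_id: str) -> SyntheticScene:
    """Render one seeded scene.  (config, patient_id) fully determine the
    output, bit-exactly: the RNG stream is derived from ``config.seed`` and
    a CRC of the patient identifier."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(patient_id.encode())])
    )
    h, w = config.image_height, config.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # background: low base intensity with a gentle illumination gradient
    gx, gy = rng.uniform(-0.04, 0.04, size=2)
    image = 0.12 + gx * (xx / w - 0.5) + gy * (yy / h - 0.5)

    fracture_boxes: list[Box] = []
    confounder_boxes: list[ConfounderBox] = []

    rates = tuple(config.confounder_rates) + (0.0, 0.0)
    gp_rate, ov_rate, implant_rate = rates[0], rates[1], rates[2]

    for b in range(max(config.n_bones, 0)):
        # one near-vertical band per image column slot
        slot_w = w / max(config.n_bones, 1)
        cx_top = (b + 0.5) * slot_w + rng.uniform(-0.12, 0.12) * slot_w
        angle = rng.uniform(-0.35, 0.35)  # radians off vertical
        p0 = np.array([cx_top - np.tan(angle) * h / 2, -4.0])
        p1 = np.array([cx_top + np.tan(angle) * h / 2, h + 4.0])
        half_width = rng.uniform(10.0, 15.0)
        dist = _segment_distance(yy, xx, p0, p1)
        image += 0.42 * _soft_band(dist, half_width, 1.8)
        # brighter cortical margins
        image += 0.10 * np.exp(-0.5 * ((dist - half_width) / 1.6) ** 2)

        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        normal = np.array([-axis[1], axis[0]])

        # non-overlapping positions along the shaft for the structures
        slots = rng.permutation([0.22, 0.42, 0.62, 0.82])
        slot_iter = iter(slots)

        def _center(t: float) -> np.ndarray:
            c = p0 + t * (p1 - p0)
            c[0] = np.clip(c[0], _STRUCT_MARGIN + 12, w - _STRUCT_MARGIN - 12)
            c[1] = np.clip(c[1], _STRUCT_MARGIN + 12, h - _STRUCT_MARGIN - 12)
            return c

        if rng.random() < config.fracture_rate:
            t = next(slot_iter) + rng.uniform(-0.04, 0.04)
            c = _center(t)
            tilt = rng.uniform(-0.5, 0.5)
            fdir = np.cos(tilt) * normal + np.sin(tilt) * axis
            half_len = rng.uniform(0.9, 1.2) * half_width
            # jagged two-piece dark line: thin and sharp
            kink = rng.uniform(-0.35, 0.35)
            kdir = np.cos(tilt + kink) * normal + np.sin(tilt + kink) * axis
            mid = c + 0.15 * half_len * axis * rng.choice([-1.0, 1.0])
            thick = rng.uniform(1.1, 1.8)
            # variable depth: some fractures are faint and visually ambiguous
            depth = rng.uniform(0.16, 0.42)
            for q0, q1 in ((c - half_len * fdir, mid), (mid, c + half_len * kdir)):
                fd = _segment_distance(yy, xx, q0, q1)
                image -= depth * _soft_band(fd, thick, 0.7)
            fracture_boxes.append(
                _tight_box(c[0], c[1], half_len + 3, half_len + 3, w, h)
            )

        if rng.random() < gp_rate:
            t = next(slot_iter) + rng.uniform(-0.04, 0.04)
            c = _center(t)
            band_half = rng.uniform(3.0, 6.0)
            gd = _segment_distance(
                yy, xx, c - 1.6 * half_width * normal, c + 1.6 * half_width * normal
            )
            # smooth, wide lucent band (Gaussian profile, no sharp edge);
            # depth varies so the deepest plates approach faint fractures
            image -= rng.uniform(0.14, 0.30) * np.exp(-0.5 * (gd / band_half) ** 2)
            fracture_like = 1.4 * half_width
            confounder_boxes.append(
                ConfounderBox(
                    _tight_box(c[0], c[1], fracture_like, fracture_like, w, h),
                    "growth_plate",
                )
            )

        if rng.random() < ov_rate:
            t = next(slot_iter) + rng.uniform(-0.04, 0.04)
            c = _center(t)
            cross_angle = rng.uniform(0.5, 1.1) * rng.choice([-1.0, 1.0])
            cdir = np.cos(cross_angle) * axis + np.sin(cross_angle) * normal
            half_len = rng.uniform(1.6, 2.2) * half_width
            cd = _segment_distance(yy, xx, c - half_len * cdir, c + half_len * cdir)
            cw = rng.uniform(4.0, 6.0)
            image += 0.22 * _soft_band(cd, cw, 1.5)
            image += 0.08 * np.exp(-0.5 * ((cd - cw) / 1.5) ** 2)
            confounder_boxes.append(
                ConfounderBox(
                    _tight_box(c[0], c[1], 1.3 * half_width, 1.3 * half_width, w, h),
                    "overlap",
                )
            )

        if rng.random() < implant_rate:
            t = next(slot_iter) + rng.uniform(-0.04, 0.04)
            c = _center(t)
            r = rng.uniform(5.0, 9.0)
            dd = np.hypot(xx - c[0], yy - c[1])
            image += 0.9 * _soft_band(dd, r, 1.0)
            confounder_boxes.append(
                ConfounderBox(_tight_box(c[0], c[1], r + 3, r + 3, w, h), "implant")
            )

    image += rng.normal(0.0, config.noise_sd, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    return SyntheticScene(
        image=image,
        fracture_boxes=tuple(fracture_boxes),
        confounder_boxes=tuple(confounder_boxes),
        patient_id=patient_id,
    )


def generate_cohort(
    config: SceneConfig, n_patients: int, scenes_per_patient: int = 1
) -> list[SyntheticScene]:
    """A seeded cohort of ``n_patients * scenes_per_patient`` scenes with
    unique per-patient identifiers (``P0000``, ``P0001``, ...)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if scenes_per_patient < 1:
        raise ValueError("scenes_per_patient must be >= 1")
    master = np.random.default_rng(config.seed)
    scenes: list[SyntheticScene] = []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        for _ in range(scenes_per_patient):
            # distinct scenes (even of one patient) differ through the
            # spawned per-scene seed
            scene_seed = int(master.integers(0, 2**31 - 1))
            scenes.append(generate_scene(replace(config, seed=scene_seed), pid))
    return scenes


# ---------------------------------------------------------------------------
# mock detector


def _jitter_box(box: Box, rng: np.random.Generator, sd: float, w: int, h: int) -> Box:
    if sd <= 0.0:
        return box
    dx, dy = rng.normal(0.0, sd, size=2)
    dw, dh = rng.normal(0.0, sd / 2.0, size=2)
    x0 = box.x_min + dx - dw / 2
    x1 = box.x_max + dx + dw / 2
    y0 = box.y_min + dy - dh / 2
    y1 = box.y_max + dy + dh / 2
    if x1 - x0 < 4:
        x1 = x0 + 4
    if y1 - y0 < 4:
        y1 = y0 + 4
    return Box(x0, y0, x1, y1).clamp(w, h)


def mock_detect(scene: SyntheticScene, config: DetectorConfig) -> list[Detection]:
    """High-recall proposal generation on a synthetic scene.

    One jittered proposal per fracture box with a high-range confidence;
    false positives on confounder boxes and at random locations with
    lower-range confidences; sub-threshold proposals dropped; greedy NMS at
    ``config.nms_iou``.  Deterministic given (scene, config): the RNG is
    keyed on the detector seed and a CRC of the scene pixels.
    """
    h, w = scene.image.shape
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(scene.image.tobytes())])
    )
    a_tp, b_tp = config.conf_distributions["tp"]
    a_cf, b_cf = config.conf_distributions["confounder"]
    a_rd, b_rd = config.conf_distributions["random"]

    proposals: list[Detection] = []
    for fb in scene.fracture_boxes:
        box = _jitter_box(fb, rng, config.jitter_sd, w, h)
        proposals.append(Detection(box, float(rng.beta(a_tp, b_tp))))
    for cb in scene.confounder_boxes:
        if rng.random() < config.fp_rate_confounder:
            box = _jitter_box(cb.box, rng, max(config.jitter_sd, 1.0), w, h)
            proposals.append(Detection(box, float(rng.beta(a_cf, b_cf))))
    for _ in range(rng.poisson(config.fp_rate_random)):
        side = rng.uniform(20.0, 44.0)
        cx = rng.uniform(side / 2, w - side / 2)
        cy = rng.uniform(side / 2, h - side / 2)
        box = Box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        proposals.append(Detection(box, float(rng.beta(a_rd, b_rd))))

    proposals = [d for d in proposals if d.score >= config.conf_threshold]
    return nms(proposals, config.nms_iou)


def detect_cohort(
    scenes: Sequence[SyntheticScene], config: DetectorConfig
) -> list[list[Detection]]:
    """Run the mock detector over a cohort (one proposal list per scene)."""
    return [mock_detect(s, config) for s in scenes]
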