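"""Generate a synthetic radiograph-like scene and write its annotations.

The scene has bright bone bands, thin dark fracture lines (positives) and
growth-plate / overlapping-edge confounders (hard negatives), each with a
tight ground-truth box and a patient identifier.
"""

from pathlib import Path

from roiadj import SceneConfig, generate_scene
from roiadj.roidata import write_coco_json, write_scene_png, write_yolo_txt

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

config = SceneConfig(fracture_rate=1.0, confounder_rates=(0.8, 0.6), seed=7)
scene = generate_scene(config, patient_id="P0001")

write_scene_png(scene, out / "scene.png")
h, w = scene.image.shape
write_yolo_txt(scene.fracture_boxes, w, h, out / "scene.txt")
write_coco_json([scene], out / "annotations.json")

print(f"scene {w}x{h}, patient {scene.patient_id}")
print(f"fracture boxes:   {len(scene.fracture_boxes)}")
for kind in ("growth_plate", "overlap"):
    n = sum(1 for c in scene.confounder_boxes if c.kind == kind)
    print(f"{kind:15s}   {n}")
print(f"wrote PNG + YOLO-txt + COCO-like JSON to {out}/")
# One fracture per bone (rate 1.0); the confounder counts are the
# fracture-mimicking structures a detector will false-alarm on.
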