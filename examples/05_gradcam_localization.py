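"""Grad-CAM saliency for adjudication decisions, scored against expert boxes.

For each true-fracture test ROI the heatmap is thresholded to a mask and
compared with the ground-truth fracture box (IoU/Dice); the pointing game
checks whether the heatmap maximum falls inside the box.
"""

from roiadj import ExperimentConfig
from roiadj import pipeline as pl

config = ExperimentConfig(seed=0)
data = pl.build_benchmark(config)
report = pl.evaluate_config(
    data, pl.AblationFlags(), name="+fusion", with_localization=True
)

loc = report.localization
print(f"true-fracture test ROIs evaluated: {loc['n']}")
print(f"mean mask IoU:  {loc['mask_iou']:.3f}")
print(f"mean Dice:      {loc['dice']:.3f}")
print(f"pointing game:  {loc['pointing_accuracy']:.3f} "
      f"(chance = box area / patch area = {loc['chance_rate']:.3f})")
# Pointing accuracy above the area-chance rate means the adjudicator's
# attention concentrates on the fracture, not arbitrary patch locations.
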