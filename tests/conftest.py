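"""Shared fixtures.

``benchmark_results`` runs the full synthetic study once per test session
(five seeds, the four-row ablation ladder plus a mining-disabled control
and Grad-CAM localization) and is shared by all the stochastic directional
tests, keeping the suite within desk-scale runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from roiadj import pipeline as pl
from roiadj.boxes import Box
from roiadj.roidata import RoiRecord

BENCHMARK_SEEDS = (0, 1, 2, 3, 4)


def make_record(
    patient_id: str = "P0000",
    y: int = 0,
    s: float = 0.5,
    box: Box | None = None,
    image_id: str = "img0",
    provenance: str | None = None,
    patch_size: int = 4,
) -> RoiRecord:
    """A minimal ROI record for bookkeeping-level tests."""
    return RoiRecord(
        patch=np.zeros((patch_size, patch_size)),
        box=box or Box(0, 0, 16, 16),
        s=s,
        y=y,
        patient_id=patient_id,
        provenance=provenance or ("orig_pos" if y else "orig_neg"),
        image_id=image_id,
    )


def make_cohort_records(n_patients: int, rois_per_patient: int) -> list[RoiRecord]:
    """Uniform ROIs-per-patient records (unique boxes per record)."""
    records = []
    for p in range(n_patients):
        for k in range(rois_per_patient):
            records.append(
                make_record(
                    patient_id=f"P{p:04d}",
                    y=k % 2,
                    s=0.5,
                    box=Box(k * 20, p % 7, k * 20 + 16, p % 7 + 16),
                    image_id=f"img{p:04d}",
                )
            )
    return records


@pytest.fixture(scope="session")
def benchmark_results():
    """Per-seed ladder reports on the synthetic benchmark.

    Returns {seed: {row_name: EvalReport}} with rows 'baseline', '+hnm',
    '+adjudicator', '+fusion' and the control 'full_nomine'; the '+fusion'
    row carries Grad-CAM localization results.
    """
    results = {}
    for seed in BENCHMARK_SEEDS:
        cfg = pl.ExperimentConfig(seed=seed)
        data = pl.build_benchmark(cfg)
        per_row = {}
        for row in pl.LADDER:
            per_row[row] = pl.evaluate_config(
                data,
                pl.AblationFlags.for_row(row),
                name=row,
                with_localization=(row == "+fusion"),
            )
        per_row["full_nomine"] = pl.evaluate_config(
            data, pl.AblationFlags(mining=False), name="full_nomine"
        )
        per_row["_patient_sets"] = tuple(
            frozenset(r.patient_id for r in split)
            for split in (data.train, data.val, data.test)
        )
        results[seed] = per_row
    return results
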