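"""Imaging arm on a rendered sub-cohort: quantify, segment, extract features.

Renders PET/ldCT phantoms for a 24-case sub-cohort and measures SUV metrics
for every case against the simulated truth. Mirroring the study design, only
visually FDG-positive nodules enter the radiomic stage: those are segmented
with the background-corrected 50%-of-SUVpeak isocontour, flagged when under
the 64-voxel minimum, and the 107-feature set per modality (plus PET TLG) is
extracted.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from thyropet import phantom, pipeline, segment, suv

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

config = phantom.CohortConfig(n_total=24, seed=20240916)
records = phantom.generate_cohort(config, imaging=True, grid_shape=(48, 48, 48))

rows, feature_rows = [], []
for rec in records:
    pet, ct, truth = rec.images
    report = suv.quantify_nodule(pet, truth)
    row = {
        "case_id": rec.case_id,
        "visual_positive": rec.visual_positive,
        "suv_max_true": rec.suv_max,
        "suv_max_measured": report.suv_max,
        "suv_peak_measured": report.suv_peak,
        "background_measured": report.background_suv_max,
        "voi_voxels": None,
        "meets_64_voxel_minimum": None,
    }
    if rec.visual_positive:
        centre = truth.origin + np.argwhere(truth.data).mean(axis=0) * truth.spacing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, voi = pipeline.quantify_and_segment_case(
                    pet, truth, centre, rec.nodule_diameter_mm
                )
            except ValueError as err:
                print(f"{rec.case_id}: segmentation failed ({err})")
                voi = None
        if voi is not None:
            row["voi_voxels"] = voi.voxel_count
            row["meets_64_voxel_minimum"] = segment.check_min_voxels(voi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                feats = pipeline.extract_case_features(pet, ct, voi)
            feats.name = rec.case_id
            feature_rows.append(feats)
    rows.append(row)

measured = pd.DataFrame(rows)
measured.to_csv(OUT / "imaging_quantification.csv", index=False)
features = pd.DataFrame(feature_rows)
features.to_csv(OUT / "imaging_features.csv")

segmented = measured.dropna(subset=["voi_voxels"])
n_small = int((segmented["meets_64_voxel_minimum"] == False).sum())  # noqa: E712
corr = measured[["suv_max_true", "suv_max_measured"]].corr().iloc[0, 1]
print(f"quantified {len(measured)} cases; segmented {len(segmented)} FDG-positive nodules; "
      f"{n_small} VOI(s) under 64 voxels")
print(f"true vs measured SUVmax correlation: {corr:.3f} "
      "(partial-volume blur pulls small hot nodules down)")
print(f"feature table: {features.shape[0]} cases x {features.shape[1]} features "
      "(107 PET + TLG + 107 CT)")
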