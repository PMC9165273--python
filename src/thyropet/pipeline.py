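"""End-to-end orchestration: simulate -> quantify -> segment -> features ->
reduce -> train/evaluate -> report.

Two entry modes mirror the two result arms:

* ``tabular`` — per-case SUV metrics only; runs the rule-out threshold
  analysis, and the radiomic classifier on a synthetic tabular feature set;
* ``imaging`` — renders PET/ldCT phantoms per case, measures SUVs, segments
  the VOI, extracts the radiomic features, then runs both arms.

Every stage seeds from the single run seed; the run manifest records the
config hash, stage timings and warnings (e.g. sub-64-voxel VOIs).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, dimred, phantom, radiomics, rocstats, segment, suv
from .volumes import ImageVolume, VoiMask


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "tabular"  # "tabular" | "imaging"
    n_total: int = 123
    seed: int = 0
    output_dir: str = "results/run"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    redundancy_threshold: float = 0.9
    l1_ratio: float = 0.5
    penalty_strength: float | None = 0.1
    n_splits: int = 20
    train_frac: float = 0.8
    min_sensitivity: float = 0.95
    threshold_mode: str = "relative"
    calibration: str = "by_group"
    run_classifier: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def quantify_and_segment_case(
    pet: ImageVolume,
    truth: VoiMask,
    locator_centre_mm,
    locator_extent_mm,
    threshold_mode: str = "relative",
):
    """Measure SUVs and segment the VOI for one imaging case.

    Returns (SuvReport, VoiMask). The background comes from the mirrored
    contralateral box; segmentation uses the background-corrected isocontour
    within the locator box.
    """
    background_region = suv.mirrored_background_box(truth)
    box = segment.apply_boxing(pet, locator_centre_mm, locator_extent_mm)
    box_mask = VoiMask(segment._box_mask(pet.shape, *box), pet.spacing, pet.origin)
    report = suv.SuvReport(
        suv_max=suv.compute_suvmax(pet, box_mask),
        suv_peak=min(suv.compute_suvpeak(pet, box_mask), suv.compute_suvmax(pet, box_mask)),
        background_suv_max=suv.compute_background(pet, background_region),
    )
    voi = segment.segment_nodule(pet, box, report.background_suv_max, mode=threshold_mode)
    return report, voi


def extract_case_features(
    pet: ImageVolume, ct: ImageVolume, voi: VoiMask
) -> pd.Series:
    """PET (4 mm) + CT (2 mm) feature vector with the PET TLG appended."""
    pet_i = radiomics.interpolate_volume(pet, radiomics.PET_TARGET_SPACING_MM)
    ct_i = radiomics.interpolate_volume(ct, radiomics.CT_TARGET_SPACING_MM)
    pet_mask = segment.resample_mask(
        voi, pet_i.spacing, target_shape=pet_i.shape, target_origin=pet_i.origin
    )
    ct_mask = segment.resample_mask(
        voi, ct_i.spacing, target_shape=ct_i.shape, target_origin=ct_i.origin
    )
    pet_fv = radiomics.extract_features(pet_i, pet_mask, modality="PET")
    pet_fv.extras["TLG"] = radiomics.compute_tlg(pet_i, pet_mask)
    ct_fv = radiomics.extract_features(ct_i, ct_mask, modality="CT")
    return pd.concat([pet_fv.as_series("PET_"), ct_fv.as_series("CT_")])


def synthetic_feature_table(records, seed: int = 0, n_noise_blocks: int = 8, block_size: int = 10) -> pd.DataFrame:
    """Synthetic stand-in radiomic feature table for tabular-mode runs.

    Builds a case-by-feature matrix with the correlation structure the
    dimensionality reduction expects: latent factors (PET intensity tied to
    log SUVmax, nodule size tied to log diameter, plus independent texture
    factors) each drive a redundant block of features. It carries no real
    image texture — it exists so the classifier arm is runnable and testable
    without rendering volumes.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    latents = {
        "intensity": np.log([r.suv_max for r in records]),
        "size": np.log([r.nodule_diameter_mm for r in records]),
    }
    for extra in range(n_noise_blocks - len(latents)):
        latents[f"texture_{extra}"] = rng.standard_normal(n)
    cols = {}
    for li, (lname, latent) in enumerate(latents.items()):
        z = (latent - np.mean(latent)) / (np.std(latent) + 1e-12)
        for j in range(block_size):
            loading = rng.uniform(0.6, 0.95)
            noise = rng.standard_normal(n) * np.sqrt(1 - loading**2)
            cols[f"F{li:02d}_{lname}_{j:02d}"] = loading * z + noise
    return pd.DataFrame(cols, index=[r.case_id for r in records])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time() - t0}

        def done(**extra):
            manifest["stages"][name].update(
                {"t_end": time.time() - t0, **extra}
            )

        return done

    # --- simulate ---------------------------------------------------------
    done = stage("simulate")
    cohort_cfg = phantom.CohortConfig(
        n_total=config.n_total,
        seed=config.seed,
        suv_distributions=phantom.calibrated_suv_distributions(config.calibration),
    )
    records = phantom.generate_cohort(cohort_cfg, imaging=(config.mode == "imaging"),
                                      grid_shape=config.grid_shape)
    frame = phantom.cohort_to_frame(records)
    done(n_cases=len(records))

    # --- quantify / segment / features (imaging mode) ---------------------
    features = None
    if config.mode == "imaging":
        done = stage("quantify_segment_features")
        rows = []
        feature_rows = []
        small_vois = 0
        for rec in records:
            pet, ct, truth = rec.images
            centre = truth.origin + (np.argwhere(truth.data).mean(axis=0)) * truth.spacing
            try:
                report, voi = quantify_and_segment_case(
                    pet, truth, centre, rec.nodule_diameter_mm, config.threshold_mode
                )
            except ValueError as err:
                manifest["warnings"].append(f"{rec.case_id}: {err}")
                continue
            if not segment.check_min_voxels(voi):
                small_vois += 1
            rows.append({"case_id": rec.case_id, **report.rounded(6)})
            if rec.visual_positive:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    feats = extract_case_features(pet, ct, voi)
                feats.name = rec.case_id
                feature_rows.append(feats)
        measured = pd.DataFrame(rows).set_index("case_id")
        frame = frame.set_index("case_id").join(measured, rsuffix="_measured").reset_index()
        features = pd.DataFrame(feature_rows) if feature_rows else None
        manifest["warnings"].append(f"{small_vois} VOI(s) below 64 voxels")
        done(n_quantified=len(rows), n_small_vois=small_vois)

    frame.to_csv(out / "cohort.csv", index=False)

    # --- threshold analysis (rule-out arm) --------------------------------
    done = stage("threshold_analysis")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = rocstats.stratified_analysis(frame, min_sensitivity=config.min_sensitivity)
    table = rocstats.tables_to_frame(results)
    table.to_csv(out / "threshold_tables.csv", index=False)
    done(n_rows=len(table))

    # --- radiomic classifier arm ------------------------------------------
    if config.run_classifier:
        done = stage("classifier")
        positive = [r for r in records if r.visual_positive]
        labels = np.array([r.is_malignant for r in positive], dtype=int)
        if features is None:
            feats = synthetic_feature_table(positive, seed=config.seed + 1)
        else:
            feats = features.loc[[r.case_id for r in positive if r.case_id in features.index]]
            labels = np.array(
                [r.is_malignant for r in positive if r.case_id in features.index], dtype=int
            )
        evaluation = None
        if len(feats) >= 20 and np.bincount(labels, minlength=2).min() >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evaluation = classify.repeated_split_eval(
                    feats,
                    labels,
                    pipeline_factory=lambda: classify.FactorElasticNetPipeline(
                        redundancy_threshold=config.redundancy_threshold,
                        l1_ratio=config.l1_ratio,
                        penalty_strength=config.penalty_strength,
                        seed=config.seed,
                    ),
                    k=config.n_splits,
                    train_frac=config.train_frac,
                    seed=config.seed,
                )
            (out / "split_evaluation.json").write_text(
                json.dumps(evaluation.to_dict(), indent=2)
            )
            done(mean_auc=evaluation.mean_auc, n_radiomics=len(feats))
        else:
            manifest["warnings"].append("classifier skipped: too few eligible cases")
            done(skipped=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
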