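"""End-to-end demo pipeline: phantoms -> degradation -> features -> robustness.

Stages run in order with cached intermediates: a stage whose output files
exist and whose recorded input hashes match is skipped on re-run.  Every
stage directory receives a manifest (config echo, derived seed, input
hashes); all randomness flows from the single global seed via per-stage
derived seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ioutils, robustness
from .phantom import CohortSpec, PhantomSpec, make_cohort, make_phantom
from .preprocess import DegradeConfig, clip_and_normalize, degrade
from .radiomics.table import build_table

__all__ = ["pipeline_run", "DEFAULT_PIPELINE_CONFIG"]

log = logging.getLogger("lesionsr.pipeline")

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "n_subjects": 6,
    "bins": [8, 16, 32, 64],
    "phantom": {"shape": [16, 48, 48], "lesion_radius_vox": 6.0},
    "degrade": {"noise_sd": 0.25, "scale": 2},
}


def _stage_seed(global_seed: int, stage: str) -> int:
    return int(np.random.default_rng([global_seed, hash(stage) % 2**31]).integers(2**31))


def _stage_done(stage_dir: Path, expected: list[str]) -> bool:
    if not (stage_dir / "manifest.json").exists():
        return False
    manifest = ioutils.read_manifest(stage_dir)
    for name in expected:
        f = stage_dir / name
        if not f.exists():
            return False
        recorded = manifest.get("output_hashes", {}).get(name)
        if recorded is not None and ioutils.file_sha256(f) != recorded:
            log.info("stage %s: hash mismatch on %s, recomputing", stage_dir.name, name)
            return False
    return True


def _finish_stage(stage_dir: Path, config: dict, seed: int, outputs: list[str]) -> None:
    manifest = {
        "config": config,
        "seeds": {"stage": seed},
        "output_hashes": {n: ioutils.file_sha256(stage_dir / n) for n in outputs},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def pipeline_run(config: dict, out_dir: str | Path) -> Path:
    """Run phantom -> degrade -> features -> robustness, caching by hash."""
    unknown = set(config) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))

    # -- stage 1: phantom cohort --------------------------------------------
    ph_dir = out / "phantom"
    ph_dir.mkdir(exist_ok=True)
    ph_seed = _stage_seed(cfg["seed"], "phantom")
    template = PhantomSpec(
        shape=tuple(cfg["phantom"]["shape"]),
        lesion_radius_vox=cfg["phantom"]["lesion_radius_vox"],
    )
    names = [f"subject{j:02d}" for j in range(cfg["n_subjects"])]
    vol_files = [f"{n}_vol.nii.gz" for n in names] + [f"{n}_mask.nii.gz" for n in names]
    if _stage_done(ph_dir, vol_files):
        log.info("stage phantom: cache hit")
    else:
        spec = CohortSpec(n_subjects=cfg["n_subjects"], template=template, seed=ph_seed)
        subjects, meta = make_cohort(spec)
        for name, reps in zip(names, subjects):
            vol, mask = reps[0]
            ioutils.write_volume(vol, ph_dir / f"{name}_vol.nii.gz",
                                 spacing_mm=template.spacing_mm)
            ioutils.write_mask(mask, ph_dir / f"{name}_mask.nii.gz",
                               spacing_mm=template.spacing_mm)
        (ph_dir / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
        _finish_stage(ph_dir, cfg["phantom"], ph_seed, vol_files)

    # -- stage 2: degraded (LR) volumes -------------------------------------
    de_dir = out / "degraded"
    de_dir.mkdir(exist_ok=True)
    de_seed = _stage_seed(cfg["seed"], "degrade")
    lr_files = [f"{n}_lr.nii.gz" for n in names]
    if _stage_done(de_dir, lr_files):
        log.info("stage degrade: cache hit")
    else:
        dcfg = DegradeConfig(**cfg["degrade"], seed=de_seed)
        for name in names:
            vol = ioutils.read_volume(ph_dir / f"{name}_vol.nii.gz")
            norm = clip_and_normalize(vol.data, dcfg.hu_window)
            lr = np.stack(
                [degrade(sl, replace(dcfg, seed=(de_seed + k) % 2**31))
                 for k, sl in enumerate(norm)]
            )
            ioutils.write_volume(lr, de_dir / f"{name}_lr.nii.gz",
                                 spacing_mm=template.spacing_mm)
        _finish_stage(de_dir, cfg["degrade"], de_seed, lr_files)

    # -- stage 3: radiomic feature tables ------------------------------------
    ft_dir = out / "features"
    ft_dir.mkdir(exist_ok=True)
    ft_seed = _stage_seed(cfg["seed"], "features")
    if _stage_done(ft_dir, ["table.csv"]):
        log.info("stage features: cache hit")
    else:
        cohort = []
        for name in names:
            vol = ioutils.read_volume(ph_dir / f"{name}_vol.nii.gz").data
            mask = ioutils.read_mask(ph_dir / f"{name}_mask.nii.gz")
            cohort.append((vol, mask))
        versions = robustness.perturb_roi(cohort[0][1])
        table = build_table(
            cohort,
            bins=cfg["bins"],
            roi_versions={
                name: (lambda m, _n=name: robustness.perturb_roi(m)[_n])
                for name in versions
            },
            subject_ids=names,
        )
        table.to_csv(ft_dir / "table.csv")
        _finish_stage(ft_dir, {"bins": cfg["bins"]}, ft_seed, ["table.csv"])

    # -- stage 4: robustness report ------------------------------------------
    rb_dir = out / "robustness"
    rb_dir.mkdir(exist_ok=True)
    if _stage_done(rb_dir, ["icc_bins.csv", "summary.json"]):
        log.info("stage robustness: cache hit")
    else:
        from .radiomics.table import FeatureTable

        table = FeatureTable.from_csv(ft_dir / "table.csv")
        best_bins, bin_summary = robustness.select_optimal_bins(table)
        icc_bins = robustness.icc_table(table, mode="bins")
        icc_bins.to_csv(rb_dir / "icc_bins.csv", index=False)

        wide = _wide_matrix(table, best_bins)
        ranking = robustness.pca_importance(wide)
        ranking.as_frame().to_csv(rb_dir / "importance.csv", index=False)
        summary = {
            "optimal_bins": best_bins,
            "excellent_by_bins": bin_summary.to_dict(orient="records"),
            "top3_variance_fraction": ranking.top3_variance_fraction,
            "n_excellent_bins_mode": int((icc_bins["robustness"] == "Excellent").sum()),
        }
        (rb_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        _finish_stage(rb_dir, {}, 0, ["icc_bins.csv", "summary.json"])

    return out


def _wide_matrix(table, n_bins: int) -> pd.DataFrame:
    """Subjects x features matrix at one bin setting, original ROIs."""
    sub = table.frame
    sub = sub[(sub["n_bins"] == n_bins) & (sub["roi_version"] == "original")]
    return sub.pivot_table(index="subject", columns="feature", values="value")
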