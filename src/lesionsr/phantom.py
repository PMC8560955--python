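"""Synthetic CT-like lesion phantoms.

Generates HU-valued 3D volumes containing a single spherical lesion with
controllable internal texture, the matching binary ROI mask, and a 2D-style
axis-aligned bounding box.  Cohorts of such phantoms with a known
between-subject / within-measurement variance split make downstream
intraclass-correlation behaviour predictable, so the whole robustness
pipeline can be exercised without any external CT data.

Conventions: voxel indices are 0-based, bounding boxes are half-open
``[lo, hi)``, and all randomness flows from explicit integer seeds
(equal seeds give bit-identical volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "CohortSpec", "BBox", "make_phantom", "make_cohort"]

TextureModel = Literal["gaussian_field", "blobs", "checker"]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open box ``[lo, hi)`` in voxel coordinates (z, y, x)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def contains_mask(self, mask: np.ndarray) -> bool:
        idx = np.argwhere(mask)
        if idx.size == 0:
            return True
        return bool(
            np.all(idx.min(axis=0) >= self.lo) and np.all(idx.max(axis=0) < self.hi)
        )

    def as_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi)}


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a single lesion phantom.

    HU levels default so that the diagnostic window [-100, 400] HU used for
    preprocessing is informative: soft-tissue-like background around -50 HU
    and a lesion sitting at ~100 HU with tens of HU of internal texture.
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 0.98, 0.98)
    background_hu: float = -50.0
    lesion_center: tuple[int, int, int] | None = None  # None -> volume centre
    lesion_radius_vox: float = 10.0
    lesion_offset_hu: float = 150.0
    texture_model: TextureModel = "gaussian_field"
    texture_corr_vox: float = 2.0
    texture_amplitude_hu: float = 40.0
    noise_hu: float = 5.0
    bbox_margin_vox: int = 2
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive voxel triplet, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.lesion_radius_vox <= 0:
            raise ValueError(
                f"lesion_radius_vox must be > 0 (got {self.lesion_radius_vox}): empty ROI"
            )
        if self.texture_amplitude_hu < 0:
            raise ValueError("texture_amplitude_hu must be >= 0")
        if self.noise_hu < 0:
            raise ValueError("noise_hu must be >= 0")
        c = self.center()
        for axis, (ci, si) in enumerate(zip(c, self.shape)):
            if ci - self.lesion_radius_vox < 0 or ci + self.lesion_radius_vox > si - 1:
                raise ValueError(
                    "lesion does not fit inside the volume: centre coordinate "
                    f"{ci} with radius {self.lesion_radius_vox} exceeds axis {axis} "
                    f"of extent {si}"
                )

    def center(self) -> tuple[int, int, int]:
        if self.lesion_center is not None:
            return tuple(int(v) for v in self.lesion_center)
        return tuple(int(s // 2) for s in self.shape)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of phantoms sharing a template, with a known variance split.

    ``between_subject_sd`` is the SD (HU) of a per-subject additive lesion
    intensity offset a_j; ``within_noise_sd`` is the SD (HU) of a scalar
    per-replicate intensity offset eps_jk (think calibration drift between
    repeated measurements).  A mean-intensity statistic over the ROI is then
    exactly mu + a_j + eps_jk, so the consistency ICC of that statistic has
    the closed form sigma_a^2 / (sigma_a^2 + sigma_e^2).
    """

    n_subjects: int = 20
    between_subject_sd: float = 30.0
    within_noise_sd: float = 10.0
    template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.between_subject_sd < 0 or self.within_noise_sd < 0:
            raise ValueError("cohort SDs must be >= 0")
        self.template.validate()


def _lesion_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean texture field over the full grid, ~unit SD, then scaled."""
    if spec.texture_amplitude_hu == 0:
        return np.zeros(spec.shape)
    if spec.texture_model == "gaussian_field":
        white = rng.standard_normal(spec.shape)
        smooth = ndimage.gaussian_filter(white, sigma=spec.texture_corr_vox, mode="wrap")
        sd = smooth.std()
        field_ = smooth / sd if sd > 0 else smooth
    elif spec.texture_model == "blobs":
        white = rng.standard_normal(spec.shape)
        smooth = ndimage.gaussian_filter(white, sigma=spec.texture_corr_vox, mode="wrap")
        thr = np.quantile(smooth, 0.7)
        field_ = (smooth > thr).astype(float) * 2.0 - 1.0
    elif spec.texture_model == "checker":
        period = max(int(round(spec.texture_corr_vox)), 1)
        zz, yy, xx = np.indices(spec.shape)
        field_ = (((zz // period) + (yy // period) + (xx // period)) % 2) * 2.0 - 1.0
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown texture model {spec.texture_model!r}")
    return spec.texture_amplitude_hu * field_


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, BBox]:
    """Build one phantom: (volume HU float64, binary mask, bbox).

    The mask is the spherical lesion support (in voxel units, isotropic in
    index space); the bbox is the tight box of the mask grown by
    ``bbox_margin_vox`` and clamped to the volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    zz, yy, xx = np.indices(spec.shape)
    cz, cy, cx = spec.center()
    dist2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    mask = dist2 <= spec.lesion_radius_vox**2
    if not mask.any():
        raise ValueError("lesion mask is empty")

    vol = np.full(spec.shape, float(spec.background_hu))
    vol[mask] += spec.lesion_offset_hu
    vol += mask * _lesion_texture(spec, rng)
    if spec.noise_hu > 0:
        vol += spec.noise_hu * rng.standard_normal(spec.shape)

    idx = np.argwhere(mask)
    lo = idx.min(axis=0) - spec.bbox_margin_vox
    hi = idx.max(axis=0) + 1 + spec.bbox_margin_vox
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, spec.shape)
    bbox = BBox(lo=tuple(int(v) for v in lo), hi=tuple(int(v) for v in hi))
    return vol, mask, bbox


def make_cohort(
    spec: CohortSpec, n_repeats: int = 1
) -> tuple[list[list[tuple[np.ndarray, np.ndarray]]], dict]:
    """Generate a cohort of phantoms with recorded generation parameters.

    Returns ``(subjects, meta)`` where ``subjects[j][r]`` is the ``(volume,
    mask)`` pair for subject ``j``, replicate ``r``.  Subject j's lesion
    intensity is shifted by a_j ~ N(0, between_subject_sd^2); each replicate
    additionally by eps_jr ~ N(0, within_noise_sd^2).  ``meta`` echoes the
    drawn offsets so parameter-recovery tests can compare against truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(0.0, spec.between_subject_sd, size=spec.n_subjects)
    eps = rng.normal(0.0, spec.within_noise_sd, size=(spec.n_subjects, n_repeats))
    # independent sub-seeds for the per-volume texture/noise draws
    sub_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)

    subjects: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for j in range(spec.n_subjects):
        reps = []
        sub_spec = replace(
            spec.template,
            lesion_offset_hu=spec.template.lesion_offset_hu + a[j],
            seed=int(sub_seeds[j]),
        )
        vol, mask, _ = make_phantom(sub_spec)
        for r in range(n_repeats):
            v = vol.copy()
            v[mask] += eps[j, r]
            reps.append((v, mask))
        subjects.append(reps)

    meta = {
        "n_subjects": spec.n_subjects,
        "n_repeats": n_repeats,
        "between_subject_sd": spec.between_subject_sd,
        "within_noise_sd": spec.within_noise_sd,
        "subject_offsets_hu": a.tolist(),
        "replicate_offsets_hu": eps.tolist(),
        "seed": spec.seed,
    }
    return subjects, meta
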