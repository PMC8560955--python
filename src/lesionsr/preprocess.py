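"""HRCT -> LRCT degradation pipeline for paired patch generation.

High-resolution lesion patches are windowed to a diagnostic HU range,
normalised to [0, 1], then degraded into their low-resolution counterparts
by additive Gaussian white noise, Gaussian blurring, integer downsampling
and nearest-neighbour upsampling back onto the original grid, so the LR
and HR member of every pair share one pixel grid.

Fixed conventions (all deterministic):

* pipeline order: noise -> blur -> downsample -> nearest upsample;
* the even blur kernel is anchored at the top-left pixel of its central
  2x2 block, normalised to sum one, applied with reflect padding;
* downsampling keeps the top-left pixel of every ``scale x scale`` block
  (the blur is the anti-alias filter); sides not divisible by ``scale``
  are reflect-padded up and the result cropped back;
* noise is added on the normalised [0, 1] scale and the image re-clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "DegradeConfig",
    "PatchPair",
    "clip_and_normalize",
    "degrade",
    "crop_to_bbox",
    "make_pairs",
]

HU_WINDOW_DEFAULT = (-100.0, 400.0)


@dataclass(frozen=True)
class DegradeConfig:
    hu_window: tuple[float, float] = HU_WINDOW_DEFAULT
    noise_sd: float = 0.25
    blur_kernel_px: int = 8
    blur_sigma: float = 1.6
    scale: int = 2
    upsample: str = "nearest"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"HU window must satisfy lo < hi, got {self.hu_window}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blur_kernel_px < 1:
            raise ValueError("blur_kernel_px must be >= 1")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.upsample != "nearest":
            raise ValueError(f"unsupported upsample mode {self.upsample!r}")


@dataclass(frozen=True)
class PatchPair:
    """Co-registered LR/HR lesion patch pair on a common grid, values in [0,1]."""

    lr: np.ndarray
    hr: np.ndarray
    bbox: tuple[int, int, int, int]  # (y_lo, x_lo, y_hi, x_hi), half-open
    volume_id: str = ""
    slice_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr.shape != self.hr.shape:
            raise ValueError(
                f"lr and hr shapes differ: {self.lr.shape} vs {self.hr.shape}"
            )


def clip_and_normalize(
    volume: np.ndarray, window: tuple[float, float] = HU_WINDOW_DEFAULT
) -> np.ndarray:
    """Clip HU values to ``window`` and map affinely onto [0, 1]."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"HU window must satisfy lo < hi, got {window}")
    arr = np.asarray(volume, dtype=float)
    n_bad = int(np.size(arr) - np.isfinite(arr).sum())
    if n_bad:
        raise ValueError(f"volume contains {n_bad} non-finite voxels")
    return (np.clip(arr, lo, hi) - lo) / (hi - lo)


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Separable Gaussian kernel of given (possibly even) size, sum one.

    For even sizes there is no centre pixel; the anchor is the top-left
    element of the central 2x2 block (index ``size//2 - 1``), so offsets run
    from ``-(size//2 - 1)`` to ``size//2``.
    """
    anchor = (size - 1) // 2 if size % 2 else size // 2 - 1
    off = np.arange(size) - anchor
    if sigma <= 0:
        k1 = (off == 0).astype(float)
    else:
        k1 = np.exp(-(off.astype(float) ** 2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    return np.outer(k1, k1)


def _anchored_correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlate with reflect padding, kernel anchored per gaussian_kernel_2d."""
    kh, kw = kernel.shape
    ah = (kh - 1) // 2 if kh % 2 else kh // 2 - 1
    aw = (kw - 1) // 2 if kw % 2 else kw // 2 - 1
    padded = np.pad(img, ((ah, kh - 1 - ah), (aw, kw - 1 - aw)), mode="reflect")
    windows = sliding_window_view(padded, kernel.shape)
    return np.einsum("ijkl,kl->ij", windows, kernel)


def degrade(hr: np.ndarray, cfg: DegradeConfig) -> np.ndarray:
    """Degrade a normalised HR image into its LR counterpart (same shape)."""
    cfg.validate()
    img = np.asarray(hr, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={img.ndim}")
    if cfg.scale > min(img.shape):
        raise ValueError(
            f"scale {cfg.scale} exceeds smallest image side {min(img.shape)}"
        )
    h, w = img.shape

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img = np.clip(img + rng.normal(0.0, cfg.noise_sd, img.shape), 0.0, 1.0)

    if cfg.blur_kernel_px > 1:
        img = _anchored_correlate(img, gaussian_kernel_2d(cfg.blur_kernel_px, cfg.blur_sigma))

    if cfg.scale > 1:
        pad_h = (-h) % cfg.scale
        pad_w = (-w) % cfg.scale
        if pad_h or pad_w:
            img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect")
        img = img[:: cfg.scale, :: cfg.scale]
        img = np.repeat(np.repeat(img, cfg.scale, axis=0), cfg.scale, axis=1)
        img = img[:h, :w]

    return np.clip(img, 0.0, 1.0)


def crop_to_bbox(
    image: np.ndarray, bbox: tuple[int, int, int, int], margin_px: int = 0
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop ``image`` to a half-open (y_lo, x_lo, y_hi, x_hi) box + margin.

    The expanded box is clamped to the image bounds (no padding), so corner
    lesions yield smaller patches.  Returns the patch and the actual box used.
    """
    y_lo, x_lo, y_hi, x_hi = bbox
    h, w = image.shape
    y0 = max(y_lo - margin_px, 0)
    x0 = max(x_lo - margin_px, 0)
    y1 = min(y_hi + margin_px, h)
    x1 = min(x_hi + margin_px, w)
    if y1 <= y0 or x1 <= x0 or y_hi <= 0 or x_hi <= 0 or y_lo >= h or x_lo >= w:
        raise ValueError(f"bbox {bbox} does not intersect image of shape {image.shape}")
    return image[y0:y1, x0:x1], (y0, x0, y1, x1)


def make_pairs(
    volumes: Sequence[tuple[str, np.ndarray]],
    bboxes: Sequence[tuple[str, int, int, int, int, int]],
    cfg: DegradeConfig,
    margin_px: int = 0,
) -> list[PatchPair]:
    """Build LR/HR patch pairs from volumes and per-slice lesion boxes.

    ``volumes``: iterable of ``(volume_id, 3D HU array)``.
    ``bboxes``: rows ``(volume_id, slice, y_lo, x_lo, y_hi, x_hi)``, 0-based
    half-open.  One pair is produced per lesion slice; patch sizes follow the
    individual boxes (multi-size patches are preserved, never resized).
    """
    if not bboxes:
        raise ValueError("no lesion bounding boxes given")
    vols = dict(volumes)
    pairs: list[PatchPair] = []
    for i, (vid, sl, y_lo, x_lo, y_hi, x_hi) in enumerate(bboxes):
        norm = clip_and_normalize(vols[vid][sl], cfg.hu_window)
        hr, used = crop_to_bbox(norm, (y_lo, x_lo, y_hi, x_hi), margin_px)
        pair_seed = (cfg.seed + i) % (2**31 - 1)
        lr = degrade(hr, replace(cfg, seed=pair_seed))
        pairs.append(
            PatchPair(lr=lr, hr=hr, bbox=used, volume_id=vid, slice_index=sl, seed=pair_seed)
        )
    return pairs
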