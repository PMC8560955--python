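"""Gray-level quantization (fixed bin count) of ROI voxels.

Texture matrices operate on discrete gray levels 1..N_g obtained by
equal-width binning of the ROI's own intensity range — the "number of
bins" rebinning whose effect on feature stability the robustness analysis
quantifies.  Bins are half-open with the top edge closed, so the ROI
maximum maps to level ``n_bins``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizedROI", "quantize"]


@dataclass(frozen=True)
class QuantizedROI:
    """Discretised ROI: integer levels on the full grid, 0 outside the mask."""

    levels: np.ndarray  # int32, 0 outside mask, 1..n_bins inside
    mask: np.ndarray  # bool
    n_bins: int
    value_range: tuple[float, float]
    degenerate: bool  # constant ROI (single gray level)

    @property
    def max_level(self) -> int:
        """Highest occupied gray level (equals n_bins unless degenerate)."""
        return int(self.levels.max())


def quantize(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> QuantizedROI:
    """Map ROI voxel values onto levels 1..n_bins by equal-width binning.

    Bin width is ``(max - min) / n_bins`` over the ROI voxels; value v maps
    to ``floor((v - min)/width) + 1`` with the maximum closed into bin
    ``n_bins``.  A constant ROI maps entirely to level 1 and sets the
    ``degenerate`` flag.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError(f"volume/mask shape mismatch: {volume.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")

    vals = volume[mask]
    if not np.isfinite(vals).all():
        raise ValueError("ROI contains non-finite voxels")
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        return QuantizedROI(levels, mask, n_bins, (vmin, vmax), degenerate=True)
    width = (vmax - vmin) / n_bins
    lv = np.floor((vals - vmin) / width).astype(np.int32) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[mask] = lv
    return QuantizedROI(levels, mask, n_bins, (vmin, vmax), degenerate=False)
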