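"""Quantitative surface-fluorescence analysis.

Raw 5-ALA/PPIX fluorescence intensities are summarized per sample and then
normalized linearly to [0, 1] across the *whole dataset*: the lower and
upper bounds are the global minimum and maximum over all samples.  This
makes values comparable across samples at the cost of sensitivity to a
single extreme sample — the bounds are therefore recorded so any value can
be re-normalized reproducibly.  Transverse profiles (a thin band of rows
averaged per column) co-register the fluorescence with a B-scan location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fioct.errors import DegenerateRangeError, EmptyROIError, InvalidParameterError

__all__ = [
    "FluorescenceImage",
    "NormalizedFluorescence",
    "summarize_fluorescence",
    "normalize_dataset",
    "transverse_profile",
]


@dataclass
class FluorescenceImage:
    """2D non-negative fluorescence intensity image."""

    intensity: np.ndarray
    lateral_pixel_um: float = 0.4
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise InvalidParameterError("fluorescence image must be 2D")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("fluorescence intensities must be >= 0")


@dataclass
class NormalizedFluorescence:
    """Dataset-normalized values in [0, 1] plus the bounds that produced them."""

    values: np.ndarray
    global_min: float
    global_max: float

    def renormalize(self, raw: np.ndarray | float) -> np.ndarray:
        """Map further raw values with the recorded bounds (clipped to [0,1])."""
        x = (np.asarray(raw, dtype=float) - self.global_min) / (
            self.global_max - self.global_min
        )
        return np.clip(x, 0.0, 1.0)


def summarize_fluorescence(
    image: FluorescenceImage, roi: tuple[slice, slice] | None = None
) -> dict:
    """Mean and median raw intensity over an ROI (default: whole image).

    Mean is the headline statistic; the median is reported alongside.
    """
    data = image.intensity[roi] if roi is not None else image.intensity
    if data.size == 0:
        raise EmptyROIError("fluorescence ROI is empty")
    return {
        "mean": float(np.mean(data)),
        "median": float(np.median(data)),
        "n_pixels": int(data.size),
        "sample_id": image.sample_id,
    }


def normalize_dataset(
    values, per_image: bool = False
) -> NormalizedFluorescence:
    """Min-max normalize raw per-sample summaries across the dataset.

    ``v -> (v - min) / (max - min)`` with global dataset bounds, so the
    dataset minimum maps to 0 and the maximum to 1.  ``per_image=True``
    instead normalizes each value against itself, which is only meaningful
    for array-valued entries; it is off by default.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidParameterError("need at least two values to normalize")
    if per_image:
        raise NotImplementedError("per-image normalization applies to full images")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateRangeError("all fluorescence values are identical")
    return NormalizedFluorescence(values=(arr - lo) / (hi - lo), global_min=lo, global_max=hi)


def transverse_profile(
    image: FluorescenceImage, row: int, band: int = 3
) -> np.ndarray:
    """Per-column mean over ``band`` rows centered on ``row``.

    The default 3-pixel band matches the thin transverse strip displayed
    above co-registered B-scans.  The band must lie fully inside the image.
    """
    if band < 1:
        raise InvalidParameterError("band must be >= 1")
    h = image.intensity.shape[0]
    lo = row - (band - 1) // 2
    hi = lo + band
    if lo < 0 or hi > h:
        raise InvalidParameterError(f"band rows [{lo}, {hi}) outside image height {h}")
    return image.intensity[lo:hi].mean(axis=0)
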