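"""Depth-resolved attenuation mapping from OCM intensity volumes.

Pipeline: detect the tissue surface, flatten the volume so the surface sits
at depth 0, estimate a per-voxel attenuation coefficient, then summarize by
ROI statistics or en-face projection.

The estimator is the depth-resolved single-scatter form

    mu[i] = I[i] / (2 * delta * sum_{j > i} I[j])

with ``delta`` the axial pixel pitch in mm, applied per A-line on
linear-scale intensity.  On a noiseless single-exponential A-line with a
complete tail this converges to ``(exp(2 mu delta) - 1) / (2 delta)``, i.e.
``mu`` up to O(mu delta) discretization.  The deepest ``tail_guard`` fraction
of each column is masked because the truncated tail sum inflates the
estimate near the bottom of the imaging range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from fioct.errors import EmptyROIError, InvalidParameterError, SurfaceNotFoundError

__all__ = [
    "OCMVolume",
    "SurfaceMap",
    "AttenuationMap",
    "ROISelection",
    "detect_surface",
    "flatten_volume",
    "estimate_attenuation",
    "attenuation_profile_from_roi",
    "mean_attenuation_roi",
    "enface_projection",
]


@dataclass
class OCMVolume:
    """Linear-intensity OCM volume, axes (x, y, z) with z increasing into tissue."""

    intensity: np.ndarray  # (nx, ny, nz), non-negative, linear scale
    axial_pixel_mm: float = 0.001
    lateral_pixel_um: float = 0.4
    valid: np.ndarray | None = None  # optional (nx, ny, nz) bool mask

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise InvalidParameterError("intensity must be a 3D (x, y, z) array")
        if self.axial_pixel_mm <= 0 or self.lateral_pixel_um <= 0:
            raise InvalidParameterError("pixel spacings must be positive")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("linear intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @staticmethod
    def from_db(db: np.ndarray, **kwargs) -> "OCMVolume":
        """Construct from dB-scale data (imported volumes are often logged)."""
        return OCMVolume(intensity=np.power(10.0, np.asarray(db, float) / 10.0), **kwargs)


@dataclass
class SurfaceMap:
    """Per-(x, y) tissue-surface depth index, pixels."""

    depth: np.ndarray  # (nx, ny) int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=int)


@dataclass
class AttenuationMap:
    """Per-voxel attenuation coefficients (mm^-1) with a validity mask."""

    mu: np.ndarray  # (nx, ny, nz), mm^-1 where valid
    valid: np.ndarray  # (nx, ny, nz) bool
    axial_pixel_mm: float = 0.001

    def masked(self) -> np.ndarray:
        """mu with invalid voxels as NaN."""
        return np.where(self.valid, self.mu, np.nan)


@dataclass
class ROISelection:
    """Axis-aligned sub-volume: B-scan (x), lateral (y) and depth (z) ranges.

    Ranges are half-open [start, stop) pixel index pairs; ``None`` means the
    full extent.  A 100-B-scan ROI mirrors the manual sub-volume convention
    of the emulated workflow.
    """

    bscan_range: tuple[int, int] | None = None
    lateral_range: tuple[int, int] | None = None
    depth_range: tuple[int, int] | None = None

    def slices(self, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        out = []
        for rng, n in zip((self.bscan_range, self.lateral_range, self.depth_range), shape):
            if rng is None:
                out.append(slice(0, n))
            else:
                lo, hi = rng
                if not (0 <= lo < hi <= n):
                    raise InvalidParameterError(f"ROI range {rng} outside extent {n}")
                out.append(slice(lo, hi))
        return tuple(out)


def _trailing_mean(a: np.ndarray, window: int, axis: int = -1) -> np.ndarray:
    """Mean over the trailing window [i - window + 1, i] along ``axis``.

    A trailing (causal) window avoids smearing signal upward, which would
    bias surface detection toward shallower depths.
    """
    c = np.cumsum(a, axis=axis, dtype=float)
    c = np.concatenate([np.zeros_like(np.take(c, [0], axis=axis)), c], axis=axis)
    n = a.shape[axis]
    idx_hi = np.arange(1, n + 1)
    idx_lo = np.maximum(idx_hi - window, 0)
    total = np.take(c, idx_hi, axis=axis) - np.take(c, idx_lo, axis=axis)
    counts = (idx_hi - idx_lo).astype(float)
    shape = [1] * a.ndim
    shape[axis] = n
    return total / counts.reshape(shape)


def noise_threshold(
    volume: OCMVolume,
    threshold_percentile: float = 99.0,
    noise_depth: int = 5,
    noise_factor: float = 2.0,
) -> float:
    """Surface-detection threshold from the above-surface noise floor.

    Estimated as ``noise_factor`` times the ``threshold_percentile``-th
    percentile of the top ``noise_depth`` axial pixels, which are assumed to
    lie above the tissue surface everywhere.
    """
    nz = volume.intensity.shape[2]
    if nz <= noise_depth:
        raise InvalidParameterError("volume too shallow for noise estimation")
    noise = volume.intensity[:, :, :noise_depth]
    return float(noise_factor * np.percentile(noise, threshold_percentile))


def detect_surface(
    volume: OCMVolume,
    threshold_percentile: float = 99.0,
    smooth_window: int = 5,
    noise_depth: int = 5,
    noise_factor: float = 2.0,
    median_size: int = 5,
    threshold: float | None = None,
) -> SurfaceMap:
    """Locate the tissue surface in every A-line.

    The detection threshold comes from :func:`noise_threshold` unless given
    explicitly (pass the original volume's threshold when re-detecting on a
    flattened volume, whose top rows no longer contain pure noise).  Per
    column, the first depth whose trailing-window smoothed intensity exceeds
    the threshold is found and then refined to the first raw crossing inside
    that window.  The resulting map is lateral-median filtered
    (``median_size`` x ``median_size``).
    """
    intensity = volume.intensity
    nx, ny, nz = intensity.shape
    if threshold is None:
        threshold = noise_threshold(volume, threshold_percentile, noise_depth,
                                    noise_factor)

    smoothed = _trailing_mean(intensity, smooth_window, axis=2)
    above = smoothed > threshold
    any_above = above.any(axis=2)
    if not any_above.any():
        raise SurfaceNotFoundError("no column crosses the surface threshold")

    first_smooth = np.argmax(above, axis=2)  # 0 where never above; masked below

    # refine: earliest raw crossing within the trailing window
    raw_above = intensity > threshold
    depth = np.full((nx, ny), -1, dtype=int)
    lo = np.maximum(first_smooth - (smooth_window - 1), 0)
    for dx in range(nx):  # nx is modest; inner work vectorized over y, z
        for dy in range(ny):
            if not any_above[dx, dy]:
                continue
            a, b = lo[dx, dy], first_smooth[dx, dy] + 1
            window = raw_above[dx, dy, a:b]
            hits = np.flatnonzero(window)
            depth[dx, dy] = a + hits[0] if hits.size else first_smooth[dx, dy]

    # fill columns without a crossing from the overall median, then smooth
    fill = int(np.median(depth[depth >= 0]))
    depth[depth < 0] = fill
    if median_size > 1:
        depth = ndimage.median_filter(depth, size=median_size, mode="nearest")
    return SurfaceMap(depth=depth)


def flatten_volume(volume: OCMVolume, surface: SurfaceMap) -> OCMVolume:
    """Shift each A-line so the detected surface sits at depth 0.

    Columns are circularly shifted by their surface depth; voxels wrapped in
    from the bottom are marked invalid in the output's ``valid`` mask.
    Flattening an already-flat volume (surface all zero) is the identity.
    """
    intensity = volume.intensity
    nx, ny, nz = intensity.shape
    depth = surface.depth
    if depth.shape != (nx, ny):
        raise InvalidParameterError("surface map shape mismatch")

    z = np.arange(nz)
    src = (z[None, None, :] + depth[:, :, None]) % nz
    flat = np.take_along_axis(intensity, src, axis=2)
    valid = z[None, None, :] < (nz - depth[:, :, None])
    if volume.valid is not None:
        valid &= np.take_along_axis(volume.valid, src, axis=2)
    return OCMVolume(
        intensity=flat,
        axial_pixel_mm=volume.axial_pixel_mm,
        lateral_pixel_um=volume.lateral_pixel_um,
        valid=valid,
    )


def estimate_attenuation(volume: OCMVolume, tail_guard: float = 0.1) -> AttenuationMap:
    """Per-voxel depth-resolved attenuation map, mm^-1.

    ``mu[i] = I[i] / (2 * delta * sum_{j>i} I[j])`` per column.  The deepest
    ``tail_guard`` fraction of samples is masked (truncation bias), as are
    voxels with a non-positive tail sum and voxels invalid in the input.
    """
    if not 0 <= tail_guard < 1:
        raise InvalidParameterError("tail_guard must be in [0, 1)")
    intensity = volume.intensity
    nz = intensity.shape[2]
    delta = volume.axial_pixel_mm

    csum = np.cumsum(intensity[:, :, ::-1], axis=2)[:, :, ::-1]
    tail = csum - intensity  # sum over j > i
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = intensity / (2.0 * delta * tail)

    valid = tail > 0
    n_guard = int(np.ceil(tail_guard * nz))
    if n_guard > 0:
        valid[:, :, nz - n_guard:] = False
    if volume.valid is not None:
        valid &= volume.valid
    mu = np.where(valid, mu, 0.0)
    return AttenuationMap(mu=mu, valid=valid, axial_pixel_mm=delta)


def attenuation_profile_from_roi(
    volume: OCMVolume,
    roi: ROISelection | None = None,
    tail_guard: float = 0.1,
    max_truncation: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth profile of mu from the ROI's ensemble-averaged A-line.

    Speckle is unit-mean multiplicative, so averaging the ROI's A-lines
    before estimation recovers the deterministic envelope; estimating first
    and averaging after would be biased by the skewed speckle statistics.

    The estimator's tail sum is truncated by the finite imaging depth,
    which inflates mu near the bottom by a factor ~1/(1 - exp(-2 mu delta
    (nz - i))).  A second, adaptive guard therefore masks all depths whose
    predicted truncation exceeds ``max_truncation``, using a first-pass mu
    estimate from the shallowest valid depths.  Returns ``(mu_profile,
    valid)`` over the ROI's depth axis.
    """
    roi = roi or ROISelection()
    sx, sy, sz = roi.slices(volume.shape)
    # average over the ROI's lateral extent but keep the FULL depth axis:
    # slicing depth before estimation would truncate the tail sum and
    # inflate mu throughout the window
    full_z = slice(0, volume.shape[2])
    sub = volume.intensity[sx, sy, full_z]
    if volume.valid is not None:
        w = volume.valid[sx, sy, full_z]
        denom = np.maximum(w.sum(axis=(0, 1)), 1)
        aline = (sub * w).sum(axis=(0, 1)) / denom
    else:
        aline = sub.mean(axis=(0, 1))
    one_col = OCMVolume(
        intensity=aline[None, None, :], axial_pixel_mm=volume.axial_pixel_mm,
        lateral_pixel_um=volume.lateral_pixel_um,
    )
    amap = estimate_attenuation(one_col, tail_guard=tail_guard)
    mu, valid = amap.mu[0, 0], amap.valid[0, 0].copy()

    idx = np.flatnonzero(valid)
    if idx.size:
        shallow = idx[: max(idx.size // 2, 1)]
        mu0 = float(np.median(mu[shallow]))
        if mu0 > 0 and 0 < max_truncation < 1:
            n = len(aline)
            guard = int(np.ceil(np.log(1.0 / max_truncation)
                                / (2.0 * mu0 * volume.axial_pixel_mm)))
            adaptive = valid.copy()
            adaptive[max(n - guard, 0):] = False
            # keep the shallow quartile if the guard would swallow everything
            valid = adaptive if adaptive.any() else _keep_shallow(valid, idx)
    # restrict reporting (not the tail sum) to the requested depth window
    report = np.zeros_like(valid)
    report[sz] = True
    return mu, valid & report


def _keep_shallow(valid: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.zeros_like(valid)
    out[idx[: max(idx.size // 4, 1)]] = True
    return out


def mean_attenuation_roi(amap: AttenuationMap, roi: ROISelection) -> dict:
    """ROI summary of a per-voxel map: median (headline), mean, std, n_valid.

    The median is reported as the primary statistic; the mean is also
    returned since both conventions appear in the literature.
    """
    sx, sy, sz = roi.slices(amap.mu.shape)
    mu = amap.mu[sx, sy, sz]
    valid = amap.valid[sx, sy, sz]
    values = mu[valid]
    if values.size == 0:
        raise EmptyROIError("ROI contains no valid attenuation voxels")
    return {
        "median_mm1": float(np.median(values)),
        "mean_mm1": float(np.mean(values)),
        "std_mm1": float(np.std(values)),
        "n_valid": int(values.size),
        "n_bscans": sx.stop - sx.start,
    }


def enface_projection(
    amap: AttenuationMap,
    depth_range: tuple[int, int] | None = None,
    reducer: str = "mean",
) -> np.ndarray:
    """Reduce valid mu over a depth window to a 2D en-face map (mm^-1).

    Lateral positions with no valid voxel in the window are NaN.
    """
    if reducer not in ("mean", "median"):
        raise InvalidParameterError(f"unknown reducer {reducer!r}")
    nz = amap.mu.shape[2]
    lo, hi = depth_range if depth_range is not None else (0, nz)
    if not (0 <= lo < hi <= nz):
        raise InvalidParameterError("empty or out-of-range depth window")
    mu = np.where(amap.valid, amap.mu, np.nan)[:, :, lo:hi]
    with np.errstate(invalid="ignore"):
        if reducer == "mean":
            out = np.nanmean(mu, axis=2)
        else:
            out = np.nanmedian(mu, axis=2)
    return out


def save_enface_png(enface: np.ndarray, path, vmin: float | None = None, vmax: float | None = None) -> None:
    """Write a color-mapped en-face image (darker red = lower attenuation,
    orange/yellow = higher, matching the field's display convention)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(enface.T, cmap="hot", vmin=vmin, vmax=vmax, origin="lower")
    ax.set_xlabel("x (B-scan)")
    ax.set_ylabel("y")
    fig.colorbar(im, ax=ax, label="attenuation (mm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
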