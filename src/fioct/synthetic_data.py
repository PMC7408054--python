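"""Synthetic phantom generators with known ground truth.

Every downstream stage of the pipeline (attenuation mapping, fluorescence
quantification, cell-density mapping, B-scan classification) is exercised on
data produced here, so parameter recovery can be checked against the truth
channel instead of unavailable patient material.

The optical model is deliberately minimal: a single-scattering Beer-Lambert
A-scan, ``I(z) = I0 * exp(-2 * mu * z)``, with fully developed speckle
modelled as multiplicative unit-mean exponential intensity noise (the
standard statistics for coherent intensity imaging). Attenuation presets for
the tissue classes follow the median coefficients reported for lower-grade
glioma, glioblastoma and metastasis cohorts (tumor core ~2.9-3.2 mm^-1,
non-neoplastic parenchyma ~4.1-4.5 mm^-1), so "tumor" phantom regions
attenuate *less* than parenchyma, as observed in tissue.

All generators are pure functions of (spec, seed): identical inputs yield
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from fioct.errors import InvalidParameterError, PlacementError

# Median attenuation coefficients (mm^-1) by cohort and tissue class:
# TU = tumor core, INF = infiltration zone, BP = non-neoplastic parenchyma.
ATTENUATION_PRESETS_MM1 = {
    "lgg": {"BP": 4.35, "INF": 2.95, "TU": 2.90},
    "gb": {"BP": 4.45, "INF": 4.00, "TU": 3.20},
    "met": {"BP": 4.13, "INF": 3.90, "TU": 3.03},
}

#: Matching normalized 5-ALA fluorescence medians (dimensionless, [0, 1]).
FLUORESCENCE_PRESETS = {
    "lgg": {"BP": 0.16, "INF": 0.25, "TU": 0.26},
    "gb": {"BP": 0.28, "INF": 0.49, "TU": 0.60},
    "met": {"BP": 0.35, "INF": 0.50, "TU": 0.69},
}

#: Spread (std. dev.) of the attenuation presets, mm^-1, same keys.
ATTENUATION_SPREAD_MM1 = {
    "lgg": {"BP": 1.20, "INF": 0.86, "TU": 0.38},
    "gb": {"BP": 0.99, "INF": 0.71, "TU": 0.76},
    "met": {"BP": 0.64, "INF": 1.61, "TU": 1.15},
}

#: Default axial sampling, mm per pixel (order of the ~1 um OCM axial
#: resolution of the visible-light system being emulated).
DEFAULT_AXIAL_PIXEL_MM = 0.001

#: Conventional published H&E optical-density stain vectors (rows are unit
#: vectors for hematoxylin, eosin and a residual channel).  The renderer and
#: the color-deconvolution stage share this single matrix.
HE_STAIN_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)


def _unit_rows(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def he_stain_matrix() -> np.ndarray:
    """3x3 unit-row stain matrix (H, E, residual = normalized cross product)."""
    he = _unit_rows(HE_STAIN_VECTORS)
    residual = np.cross(he[0], he[1])
    residual /= np.linalg.norm(residual)
    return np.vstack([he, residual])


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class PhantomRegion:
    """A laterally delimited tissue region of an OCM phantom."""

    mask: np.ndarray  # (nx, ny) bool, lateral footprint
    mu_mm1: float  # attenuation coefficient, mm^-1
    reflectivity: float = 1.0  # dimensionless backscatter scale


@dataclass
class PhantomSpec:
    """Specification of a speckled Beer-Lambert OCM phantom volume.

    ``surface`` gives the per-column tissue-surface depth z0(x, y) in pixels;
    voxels above it contain only background noise.  Region masks must
    partition the lateral field.
    """

    shape: tuple[int, int, int]  # (nx, ny, nz), z = depth
    regions: list[PhantomRegion]
    surface: np.ndarray | int = 10
    axial_pixel_mm: float = DEFAULT_AXIAL_PIXEL_MM
    speckle: bool = True
    noise_floor: float = 0.02  # background intensity scale
    seed: int = 0

    def surface_map(self) -> np.ndarray:
        nx, ny, _ = self.shape
        surf = np.broadcast_to(np.asarray(self.surface, dtype=int), (nx, ny))
        return np.array(surf)

    def validate(self) -> None:
        nx, ny, nz = self.shape
        if self.axial_pixel_mm <= 0:
            raise InvalidParameterError("axial_pixel_mm must be positive")
        if not self.regions:
            raise InvalidParameterError("phantom needs at least one region")
        cover = np.zeros((nx, ny), dtype=int)
        for region in self.regions:
            if region.mu_mm1 < 0:
                raise InvalidParameterError("region attenuation mu must be >= 0")
            if region.mask.shape != (nx, ny):
                raise InvalidParameterError("region mask shape mismatch")
            cover += region.mask.astype(int)
        if not np.all(cover == 1):
            raise InvalidParameterError("region masks must partition the lateral field")
        surf = self.surface_map()
        if surf.min() < 0 or surf.max() >= nz:
            raise InvalidParameterError("surface must lie within the axial range")


@dataclass
class GroundTruth:
    """Truth channel attached to a synthetic volume/image.

    Lateral dimensions match the data it annotates.  Unused fields are None.
    """

    mu_map: np.ndarray | None = None  # (nx, ny) attenuation, mm^-1
    surface_map: np.ndarray | None = None  # (nx, ny) surface depth, pixels
    cell_centroids: np.ndarray | None = None  # (n, 2) as (x, y) pixels
    class_labels: np.ndarray | None = None  # per-B-scan class index


@dataclass
class HESlideSpec:
    """Specification of a synthetic H&E-stained slide image.

    Nuclei are hematoxylin-dominant ellipses rendered on a uniform eosin
    background via optical-density mixing, RGB = 255 * 10^(-OD . stains).
    """

    shape: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_um: float = 0.5
    n_nuclei: int = 100
    radius_range: tuple[float, float] = (4.0, 7.0)  # semi-axis range, px
    allow_overlap: bool = False
    hematoxylin_od: float = 0.9  # OD amplitude inside nuclei
    nucleus_eosin_od: float = 0.05
    background_eosin_od: float = 0.15
    retry_factor: int = 100  # retry budget = retry_factor * n_nuclei
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0:
            raise InvalidParameterError("n_nuclei must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise InvalidParameterError("invalid nucleus radius range")
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be positive")


@dataclass
class FluorescenceCoupling:
    """Affine negative coupling of surface fluorescence to attenuation.

    fl = intercept - slope * mu + N(0, noise_sigma); the defaults place the
    preset attenuation range (2.9-4.5 mm^-1) on a fluorescence scale where
    tumor-like (low-mu) regions fluoresce more, as in 5-ALA-labelled tissue.
    """

    intercept: float = 1.35
    slope: float = 0.22  # fluorescence units per mm^-1
    noise_sigma: float = 0.05


@dataclass
class LabeledBScanSet:
    """Grayscale B-scans with class, sample and patient identity.

    Label convention: 0 = non-neoplastic brain parenchyma, 1 = tumor core
    (infiltration-zone scans carry class name "infiltration" and are pooled
    with tumor only when the caller chooses to).
    """

    images: np.ndarray  # (n, h, w) float32
    labels: np.ndarray  # (n,) int
    class_names: tuple[str, ...]
    sample_ids: np.ndarray  # (n,) str
    patient_ids: np.ndarray  # (n,) str
    split: np.ndarray  # (n,) str, "train" | "test"
    mu_mm1: np.ndarray  # (n,) embedded true attenuation

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray) -> "LabeledBScanSet":
        mask = np.asarray(mask)
        return LabeledBScanSet(
            images=self.images[mask],
            labels=self.labels[mask],
            class_names=self.class_names,
            sample_ids=self.sample_ids[mask],
            patient_ids=self.patient_ids[mask],
            split=self.split[mask],
            mu_mm1=self.mu_mm1[mask],
        )

    def train_test(self) -> tuple["LabeledBScanSet", "LabeledBScanSet"]:
        return self.subset(self.split == "train"), self.subset(self.split == "test")


# --------------------------------------------------------------------------
# OCM phantom simulation
# --------------------------------------------------------------------------


def simulate_ascan(
    mu_mm1: float,
    n_depth: int,
    axial_pixel_mm: float = DEFAULT_AXIAL_PIXEL_MM,
    speckle: bool = True,
    seed: int | None = 0,
    i0: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-scattering Beer-Lambert A-line.

    The deterministic envelope is ``I[i] = i0 * exp(-2 * mu * delta * i)``
    (round-trip attenuation).  With ``speckle=True`` every sample is
    multiplied by an independent unit-mean exponential variate, the intensity
    statistics of fully developed speckle.
    """
    if mu_mm1 < 0:
        raise InvalidParameterError(f"attenuation mu must be >= 0, got {mu_mm1}")
    if axial_pixel_mm <= 0:
        raise InvalidParameterError("axial_pixel_mm must be positive")
    if n_depth < 2:
        raise InvalidParameterError("n_depth must be >= 2")
    z = np.arange(n_depth, dtype=float)
    envelope = i0 * np.exp(-2.0 * mu_mm1 * axial_pixel_mm * z)
    if not speckle:
        return envelope
    if rng is None:
        rng = np.random.default_rng(seed)
    return envelope * rng.exponential(1.0, size=n_depth)


def simulate_volume(spec: PhantomSpec):
    """Render a phantom volume and its ground truth.

    Returns ``(volume, truth)`` where ``volume`` is an
    :class:`fioct.oct_attenuation.OCMVolume` (imported lazily to keep module
    dependencies one-way) and ``truth`` carries the per-column attenuation
    and surface maps.
    """
    from fioct.oct_attenuation import OCMVolume

    spec.validate()
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)
    surf = spec.surface_map()

    mu_map = np.zeros((nx, ny))
    refl_map = np.zeros((nx, ny))
    for region in spec.regions:
        mu_map[region.mask] = region.mu_mm1
        refl_map[region.mask] = region.reflectivity

    z = np.arange(nz, dtype=float)
    rel_depth = z[None, None, :] - surf[:, :, None]  # depth below surface
    below = rel_depth >= 0
    envelope = refl_map[:, :, None] * np.exp(
        -2.0 * mu_map[:, :, None] * spec.axial_pixel_mm * np.maximum(rel_depth, 0.0)
    )
    if spec.speckle:
        noise = rng.exponential(1.0, size=(nx, ny, nz))
        intensity = np.where(below, envelope * noise, spec.noise_floor * noise)
    else:
        intensity = np.where(below, envelope, 0.0)

    truth = GroundTruth(mu_map=mu_map, surface_map=surf)
    volume = OCMVolume(intensity=intensity, axial_pixel_mm=spec.axial_pixel_mm)
    return volume, truth


def two_region_spec(
    shape: tuple[int, int, int] = (64, 64, 512),
    mu_left: float = ATTENUATION_PRESETS_MM1["lgg"]["BP"],
    mu_right: float = ATTENUATION_PRESETS_MM1["lgg"]["TU"],
    surface: np.ndarray | int = 10,
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """Convenience two-region phantom split down the lateral x axis."""
    nx, ny, _ = shape
    left = np.zeros((nx, ny), dtype=bool)
    left[: nx // 2] = True
    regions = [
        PhantomRegion(mask=left, mu_mm1=mu_left),
        PhantomRegion(mask=~left, mu_mm1=mu_right),
    ]
    return PhantomSpec(shape=shape, regions=regions, surface=surface, seed=seed, **kwargs)


def uniform_spec(
    mu_mm1: float,
    shape: tuple[int, int, int] = (64, 64, 512),
    surface: np.ndarray | int = 10,
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """Single-region phantom with one attenuation coefficient everywhere."""
    nx, ny, _ = shape
    region = PhantomRegion(mask=np.ones((nx, ny), dtype=bool), mu_mm1=mu_mm1)
    return PhantomSpec(shape=shape, regions=[region], surface=surface, seed=seed, **kwargs)


def tilted_surface(shape: tuple[int, int, int], z0: float = 10.0, slope: float = 0.02) -> np.ndarray:
    """Planar surface z(x) = z0 + slope * x, broadcast over y, rounded to px."""
    nx, ny, _ = shape
    surf = z0 + slope * np.arange(nx, dtype=float)
    return np.round(surf).astype(int)[:, None] * np.ones((1, ny), dtype=int)


# --------------------------------------------------------------------------
# H&E slide simulation
# --------------------------------------------------------------------------


def render_od_to_rgb(od_h: np.ndarray, od_e: np.ndarray, od_r: np.ndarray | None = None) -> np.ndarray:
    """Beer-Lambert rendering of per-stain OD fields to an 8-bit RGB image."""
    stains = he_stain_matrix()
    od = np.stack([od_h, od_e, od_r if od_r is not None else np.zeros_like(od_h)], axis=-1)
    transmission = np.power(10.0, -(od @ stains))
    return np.clip(np.round(255.0 * transmission), 0, 255).astype(np.uint8)


def sample_ingamut_stain_mixes(
    n: int,
    rng: np.random.Generator,
    od_h_range: tuple[float, float] = (0.05, 0.8),
    od_e_range: tuple[float, float] = (0.02, 0.4),
    max_channel_od: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Random H/E stain mixtures that stay within the 8-bit render gamut.

    A mix is in-gamut when every RGB channel's total OD stays below
    ``max_channel_od`` (transmission >= ~8 quantization steps of a uint8
    image); beyond that, the half-count rounding of the rendered pixel, not
    the unmixing math, dominates the recovered OD.
    """
    stains = he_stain_matrix()[:2]
    out_h, out_e = [], []
    while len(out_h) < n:
        h = rng.uniform(*od_h_range, size=n)
        e = rng.uniform(*od_e_range, size=n)
        channel_od = np.outer(h, stains[0]) + np.outer(e, stains[1])
        ok = channel_od.max(axis=1) <= max_channel_od
        out_h.extend(h[ok])
        out_e.extend(e[ok])
    return np.array(out_h[:n]), np.array(out_e[:n])


def simulate_he_image(spec: HESlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic H&E slide of stained nuclei with known centroids.

    Nuclei are ellipses of hematoxylin OD ``spec.hematoxylin_od`` on a uniform
    eosin background; with overlap forbidden, centers are rejection-sampled so
    that the pairwise distance exceeds the sum of the two major semi-axes.
    Returns the uint8 RGB image and the ground truth with (x, y) centroids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    rmin, rmax = spec.radius_range

    centers = np.empty((0, 2))  # (row, col)
    majors = np.empty(0)
    placed_axes: list[tuple[float, float, float]] = []  # (a, b, angle)
    budget = spec.retry_factor * max(spec.n_nuclei, 1)
    attempts = 0
    margin = rmax + 1
    while len(placed_axes) < spec.n_nuclei:
        if attempts >= budget:
            raise PlacementError(
                f"placed {len(placed_axes)}/{spec.n_nuclei} nuclei within "
                f"{budget} attempts; image too crowded"
            )
        attempts += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        a = rng.uniform(rmin, rmax)  # major semi-axis
        b = rng.uniform(rmin, a)  # minor semi-axis
        angle = rng.uniform(0, np.pi)
        if not spec.allow_overlap and len(placed_axes):
            d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
            if np.any(d <= majors + a):
                continue
        centers = np.vstack([centers, [r, c]])
        majors = np.append(majors, a)
        placed_axes.append((a, b, angle))

    od_h = np.zeros((h, w))
    od_e = np.full((h, w), spec.background_eosin_od)
    for (r, c), (a, b, angle) in zip(centers, placed_axes):
        r0, r1 = max(int(r - a) - 1, 0), min(int(r + a) + 2, h)
        c0, c1 = max(int(c - a) - 1, 0), min(int(c + a) + 2, w)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        ca, sa = np.cos(angle), np.sin(angle)
        dr, dc = rows - r, cols - c
        u = (dr * ca + dc * sa) / a
        v = (-dr * sa + dc * ca) / b
        inside = u * u + v * v <= 1.0
        od_h[r0:r1, c0:c1][inside] = spec.hematoxylin_od
        od_e[r0:r1, c0:c1][inside] = spec.nucleus_eosin_od

    rgb = render_od_to_rgb(od_h, od_e)
    centroids = np.array([(c, r) for (r, c) in centers], dtype=float).reshape(-1, 2)
    return rgb, GroundTruth(cell_centroids=centroids)


# --------------------------------------------------------------------------
# Fluorescence simulation
# --------------------------------------------------------------------------


def simulate_fluorescence(
    truth: GroundTruth,
    coupling: FluorescenceCoupling | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Surface fluorescence image negatively coupled to local attenuation.

    Each lateral pixel's fluorescence is an affine-decreasing function of the
    true attenuation at that column plus Gaussian noise, clipped at zero —
    emulating the observation that tumor-like low-attenuation tissue shows
    higher 5-ALA fluorescence.
    """
    if truth.mu_map is None:
        raise InvalidParameterError("ground truth must carry a mu map")
    coupling = coupling or FluorescenceCoupling()
    rng = np.random.default_rng(seed)
    fl = coupling.intercept - coupling.slope * truth.mu_map
    if coupling.noise_sigma > 0:
        fl = fl + rng.normal(0.0, coupling.noise_sigma, size=fl.shape)
    return np.clip(fl, 0.0, None)


# --------------------------------------------------------------------------
# Labeled B-scan dataset simulation
# --------------------------------------------------------------------------

#: Attenuation presets used by the B-scan texture renderer, mm^-1 (GB-like).
BSCAN_CLASS_MU = {"non_tumor": 4.45, "tumor": 3.20, "infiltration": 4.00}

#: Axial pixel pitch of rendered B-scans, mm — chosen so the exponential
#: decay is clearly visible across a 128-pixel depth at tissue-like mu.
BSCAN_AXIAL_PIXEL_MM = 0.004


def _render_bscan(
    mu_mm1: float,
    kind: str,
    shape: tuple[int, int],
    rng: np.random.Generator,
    surface_row: int,
    layer_period: float,
    layer_phase: float,
) -> np.ndarray:
    """One grayscale B-scan: rows = depth, cols = lateral position.

    "tumor" renders as fine-grained high-cellularity speckle; "non_tumor" as
    a layered, coarser-grained texture.  Both share the Beer-Lambert depth
    envelope with their class attenuation.
    """
    h, w = shape
    z = np.arange(h, dtype=float)[:, None]
    rel = np.maximum(z - surface_row, 0.0)
    envelope = np.exp(-2.0 * mu_mm1 * BSCAN_AXIAL_PIXEL_MM * rel) * (z >= surface_row)

    speckle = rng.exponential(1.0, size=shape)
    if kind == "tumor":
        texture = speckle  # fine grain, no layering
    else:
        # axonal/laminar structure: depth-periodic banding + coarse speckle
        bands = 1.0 + 0.6 * np.sin(2.0 * np.pi * z / layer_period + layer_phase)
        coarse = ndimage.gaussian_filter(speckle, sigma=(1.0, 2.5))
        texture = bands * coarse
    img = envelope * texture + 0.01 * rng.exponential(1.0, size=shape)
    return img.astype(np.float32)


def simulate_bscan_dataset(
    n_patients: int = 36,
    bscans_per_sample: int = 6,
    classes: tuple[str, ...] = ("non_tumor", "tumor"),
    seed: int = 0,
    image_shape: tuple[int, int] = (128, 128),
    test_patients_per_class: int = 3,
    mu_jitter: float = 0.25,
) -> LabeledBScanSet:
    """Two- or three-class labeled B-scan dataset with patient grouping.

    Patients are split evenly across classes (``n_patients`` must allow at
    least 2 per class); each patient contributes one sample of
    ``bscans_per_sample`` B-scans, mirroring the five-to-six-scans-per-patient
    structure of the cohort being emulated.  ``test_patients_per_class``
    patients per class are tagged split="test" for patient-disjoint
    evaluation.  Class "infiltration" renders as a lateral patchwork of tumor
    and parenchyma columns (a mixture tissue), with label 1 (tumor side).
    """
    n_classes = len(classes)
    if n_patients < 2 * n_classes:
        raise InvalidParameterError("need at least 2 patients per class")
    per_class = n_patients // n_classes
    rng = np.random.default_rng(seed)

    images, labels, sample_ids, patient_ids, split, mus = [], [], [], [], [], []
    pid = 0
    for ci, cname in enumerate(classes):
        label = 0 if cname == "non_tumor" else 1
        test_ids = set(range(per_class - test_patients_per_class, per_class))
        for k in range(per_class):
            patient = f"P{pid:03d}"
            sample = f"S{pid:03d}"
            tag = "test" if k in test_ids else "train"
            mu_sample = BSCAN_CLASS_MU.get(cname, 4.0) + rng.normal(0.0, mu_jitter)
            mu_sample = max(mu_sample, 0.5)
            layer_period = rng.uniform(10.0, 16.0)
            for _ in range(bscans_per_sample):
                surface_row = int(rng.integers(4, 12))
                phase = rng.uniform(0, 2 * np.pi)
                if cname == "infiltration":
                    # scant tumor in parenchyma: 0..5 small tumor-texture
                    # patches; zero-patch scans are indistinguishable from
                    # parenchyma, which is what degrades pooled accuracy
                    tum = _render_bscan(
                        BSCAN_CLASS_MU["tumor"] + rng.normal(0, mu_jitter),
                        "tumor", image_shape, rng, surface_row, layer_period, phase,
                    )
                    img = _render_bscan(
                        BSCAN_CLASS_MU["non_tumor"] + rng.normal(0, mu_jitter),
                        "non_tumor", image_shape, rng, surface_row, layer_period, phase,
                    )
                    patch = 16
                    for _ in range(int(rng.integers(0, 6))):
                        pr = int(rng.integers(surface_row, image_shape[0] - patch))
                        pc = int(rng.integers(0, image_shape[1] - patch))
                        img[pr:pr + patch, pc:pc + patch] = \
                            tum[pr:pr + patch, pc:pc + patch]
                else:
                    img = _render_bscan(
                        mu_sample, cname, image_shape, rng, surface_row,
                        layer_period, phase,
                    )
                images.append(img)
                labels.append(label)
                sample_ids.append(sample)
                patient_ids.append(patient)
                split.append(tag)
                mus.append(mu_sample)
            pid += 1

    return LabeledBScanSet(
        images=np.stack(images),
        labels=np.array(labels, dtype=int),
        class_names=classes,
        sample_ids=np.array(sample_ids),
        patient_ids=np.array(patient_ids),
        split=np.array(split),
        mu_mm1=np.array(mus),
    )


def simulate_cohort_table(
    entities: tuple[str, ...] = ("lgg", "gb", "met"),
    n_per_class: int = 10,
    seed: int = 0,
    spread_scale: float = 1.0,
):
    """Tidy per-sample cohort table for the statistics/report layer.

    Draws per-sample attenuation and normalized fluorescence from Gaussian
    distributions centered on the cohort presets with the printed spreads
    (``spread_scale`` rescales them), plus a cell density negatively coupled
    to attenuation.  Columns: sample_id, patient_id, entity, tissue,
    mu_mm1, fl_norm, density_mm2.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for entity in entities:
        for tissue in ("BP", "INF", "TU"):
            mu0 = ATTENUATION_PRESETS_MM1[entity][tissue]
            sd_mu = ATTENUATION_SPREAD_MM1[entity][tissue] * spread_scale
            fl0 = FLUORESCENCE_PRESETS[entity][tissue]
            for _ in range(n_per_class):
                mu = max(rng.normal(mu0, sd_mu), 0.2)
                fl = float(np.clip(rng.normal(fl0, 0.1 * spread_scale), 0, 1))
                # density rises as attenuation falls (tumor = hypercellular)
                density = max(rng.normal(6000 - 900 * mu, 400), 100.0)
                rows.append({
                    "sample_id": f"S{sid:03d}", "patient_id": f"P{sid:03d}",
                    "entity": entity.upper(), "tissue": tissue,
                    "mu_mm1": mu, "fl_norm": fl, "density_mm2": density,
                })
                sid += 1
    return pd.DataFrame(rows)


def simulate_nonsense_images(
    n: int = 20,
    image_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Structureless out-of-distribution images with balanced arbitrary labels.

    Returns ``(images, labels)`` where labels alternate 0/1 (balanced) and
    carry no relation to image content — the chance-level sanity test input.
    """
    rng = np.random.default_rng(seed)
    images = rng.uniform(0.0, 1.0, size=(n, *image_shape)).astype(np.float32)
    labels = np.arange(n) % 2
    return images, rng.permutation(labels)
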