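"""Single-scan quantification: blood-pool reference, threshold segmentation,
SUVpeak/SUVmax, lesion volumes, PSMA-TV and TL-PSMA.

The measurement chain mirrors PERCIST-style PET quantification: a cylindrical
blood-pool VOI in the aorta provides reference statistics, the segmentation
threshold is ``1.5 x aorta SUVpeak + 2 x aorta SD``, lesions are
26-connected components above threshold (minus physiological regions),
components smaller than 0.3 mL are discarded, and each surviving component
must itself show ``SUVpeak > threshold``.  Patient burden is summarized as
PSMA-TV (total segmented volume, mL) and TL-PSMA (sum of per-lesion
SUVpeak x volume, SUV*cm^3, the PSMA analogue of total lesion glycolysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import CylinderVoi, voxel_centers

#: Diameter (mm) of the SUVpeak sphere, ~1 cm^3 per the PERCIST convention.
PEAK_SPHERE_DIAMETER_MM = 12.0


@dataclass
class SuvVolume:
    """A 3-D grid of (lean-body-mass normalized) SUV values.

    ``values`` is indexed (z, y, x); ``spacing`` is mm per axis.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUV volume must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if self.values.min() < 0:
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class AortaStats:
    suv_peak: float
    suv_mean: float
    suv_sd: float
    voi_voxel_count: int


@dataclass(frozen=True)
class LesionQuant:
    lesion_id: int
    site: str
    volume_ml: float
    suv_peak: float
    suv_max: float
    centroid: tuple[float, float, float]
    voxel_count: int


@dataclass
class ScanQuant:
    threshold: float
    aorta: AortaStats | None
    lesions: list[LesionQuant]
    psma_tv_ml: float
    tl_psma: float


@dataclass
class SegmentationResult:
    """Relabeled component volume (1..K by decreasing size) and sizes."""

    labels: np.ndarray
    voxel_counts: list[int]
    volumes_ml: list[float]
    n_dropped_small: int = 0
    n_dropped_peak: int = 0

    @property
    def n_lesions(self) -> int:
        return len(self.voxel_counts)


@dataclass(frozen=True)
class QuantConfig:
    """Tunable quantification conventions (all defaults stated explicitly)."""

    peak_diameter_mm: float = PEAK_SPHERE_DIAMETER_MM
    min_volume_ml: float = 0.3
    connectivity: int = 26
    aorta_diameter_mm: float = 10.0
    aorta_length_mm: float = 30.0
    #: "per_lesion": TL-PSMA = sum of per-lesion SUVpeak x volume;
    #: "global": global SUVpeak x total PSMA-TV.
    tl_mode: str = "per_lesion"
    exclude_aorta: bool = True


def lean_body_mass(weight_kg: float, height_cm: float, sex: str = "male") -> float:
    """Lean body mass (kg) by the Janmahasatian formula (male form).

    LBM = 9270 * W / (6680 + 216 * BMI), BMI = W / height_m^2.  The study
    population is male; other values of ``sex`` are rejected rather than
    silently computed with the wrong coefficients.
    """
    if sex != "male":
        raise ValueError("only the male formula is supported")
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)


# ---------------------------------------------------------------------------
# SUVpeak
# ---------------------------------------------------------------------------


def sphere_offsets(
    spacing: tuple[float, float, float], diameter_mm: float = PEAK_SPHERE_DIAMETER_MM
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Integer voxel offsets whose centers lie within the peak sphere.

    Returns (offsets, extents) where extents are the per-axis half-widths of
    the bounding box (so a sphere centered at index i is fully in-grid iff
    ``ext <= i < n - ext`` on every axis).
    """
    r = diameter_mm / 2.0
    ext = tuple(int(np.floor(r / s + 1e-9)) for s in spacing)
    grids = np.mgrid[tuple(slice(-e, e + 1) for e in ext)]
    d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    keep = d2 <= r * r + 1e-9
    offsets = np.stack([g[keep] for g in grids], axis=1)
    return offsets, ext


def sphere_mean_map(
    volume: SuvVolume, diameter_mm: float = PEAK_SPHERE_DIAMETER_MM
) -> tuple[np.ndarray, np.ndarray]:
    """(mean-in-sphere map, admissible-center mask) for the whole grid.

    The map value at a voxel is the mean SUV over the digitized sphere
    centered there; it is valid only where the sphere lies fully inside the
    grid (the returned boolean mask).
    """
    offsets, ext = sphere_offsets(volume.spacing, diameter_mm)
    kernel = np.zeros(tuple(2 * e + 1 for e in ext))
    kernel[tuple((offsets + np.asarray(ext)).T)] = 1.0
    kernel /= kernel.sum()
    conv = ndimage.correlate(volume.values, kernel, mode="constant", cval=0.0)
    valid = np.zeros(volume.shape, dtype=bool)
    inner = tuple(
        slice(e, n - e) if n > 2 * e else slice(0, 0)
        for e, n in zip(ext, volume.shape)
    )
    valid[inner] = True
    return conv, valid


def suv_peak(
    volume: SuvVolume,
    mask: np.ndarray,
    diameter_mm: float = PEAK_SPHERE_DIAMETER_MM,
    _mean_map: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Peak SUV: the largest sphere-mean over sphere centers inside ``mask``.

    The sphere (default 1.2 cm diameter) may extend beyond the mask but not
    beyond the grid; ties go to the lowest (z, y, x) center.  If no center in
    the mask admits a fully in-grid sphere (component hugging the boundary),
    spheres clipped at the grid edge are used instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match the volume")
    if not mask.any():
        raise ValueError("suv_peak requires a non-empty mask")
    conv, valid = _mean_map if _mean_map is not None else sphere_mean_map(volume, diameter_mm)
    centers = mask & valid
    if centers.any():
        cand = np.where(centers, conv, -np.inf)
        return float(cand.flat[np.argmax(cand)])
    # fallback: clipped spheres for masks confined to the boundary margin
    offsets, _ = sphere_offsets(volume.spacing, diameter_mm)
    best = -np.inf
    shape = np.asarray(volume.shape)
    for center in np.argwhere(mask):
        pos = center + offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        m = float(volume.values[tuple(pos[ok].T)].mean())
        if m > best:
            best = m
    return best


# ---------------------------------------------------------------------------
# Blood-pool reference and threshold
# ---------------------------------------------------------------------------


def aorta_stats(
    volume: SuvVolume,
    cylinder: CylinderVoi,
    peak_diameter_mm: float = PEAK_SPHERE_DIAMETER_MM,
) -> AortaStats:
    """Mean/SD (n-1 denominator) and SUVpeak over the blood-pool cylinder."""
    mask = cylinder.mask(volume.shape, volume.spacing)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("aorta VOI contains no voxel centers")
    if n < 2:
        raise ValueError("aorta VOI of a single voxel: SD is undefined")
    vals = volume.values[mask]
    peak = suv_peak(volume, mask, peak_diameter_mm)
    return AortaStats(
        suv_peak=peak,
        suv_mean=float(vals.mean()),
        suv_sd=float(vals.std(ddof=1)),
        voi_voxel_count=n,
    )


def compute_threshold(stats: AortaStats) -> float:
    """Segmentation threshold T = 1.5 x blood-pool SUVpeak + 2 x blood-pool SD."""
    if stats.suv_sd < 0:
        raise ValueError("negative SD")
    return 1.5 * stats.suv_peak + 2.0 * stats.suv_sd


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def segment_lesions(
    volume: SuvVolume,
    threshold: float,
    min_volume_ml: float = 0.3,
    exclusion_mask: np.ndarray | None = None,
    connectivity: int = 26,
    peak_diameter_mm: float = PEAK_SPHERE_DIAMETER_MM,
    _mean_map: tuple[np.ndarray, np.ndarray] | None = None,
) -> SegmentationResult:
    """Threshold segmentation with the small-volume and SUVpeak filters.

    Components are voxels with SUV strictly greater than ``threshold``
    (26-connectivity by default), minus ``exclusion_mask`` (physiological
    uptake such as the blood-pool region).  Components below ``min_volume_ml``
    are discarded, as are components whose own SUVpeak does not exceed the
    threshold.  Surviving components are relabeled 1..K by decreasing volume
    (ties by first voxel in scan order).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    above = volume.values > threshold
    if exclusion_mask is not None:
        above &= ~np.asarray(exclusion_mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw_labels, n_raw = ndimage.label(above, structure=structure)
    voxel_ml = volume.voxel_volume_ml

    if n_raw and _mean_map is None:
        _mean_map = sphere_mean_map(volume, peak_diameter_mm)

    kept: list[tuple[int, int, int]] = []  # (voxel_count, first_index, raw_label)
    flat = raw_labels.ravel()
    counts = np.bincount(flat, minlength=n_raw + 1)
    n_dropped_small = n_dropped_peak = 0
    for lab in range(1, n_raw + 1):
        n_vox = int(counts[lab])
        if n_vox * voxel_ml < min_volume_ml:
            n_dropped_small += 1
            continue
        comp_mask = raw_labels == lab
        if suv_peak(volume, comp_mask, peak_diameter_mm, _mean_map=_mean_map) <= threshold:
            n_dropped_peak += 1
            continue
        first = int(np.flatnonzero(flat == lab)[0])
        kept.append((n_vox, first, lab))

    kept.sort(key=lambda t: (-t[0], t[1]))
    labels = np.zeros(volume.shape, dtype=np.int32)
    voxel_counts, volumes_ml = [], []
    for new_id, (n_vox, _first, lab) in enumerate(kept, start=1):
        labels[raw_labels == lab] = new_id
        voxel_counts.append(n_vox)
        volumes_ml.append(n_vox * voxel_ml)
    return SegmentationResult(
        labels, voxel_counts, volumes_ml, n_dropped_small, n_dropped_peak
    )


# ---------------------------------------------------------------------------
# Whole-scan quantification
# ---------------------------------------------------------------------------


def _majority_site(
    comp_mask: np.ndarray,
    site_labels: np.ndarray | None,
    site_names: dict[int, str] | None,
) -> str:
    if site_labels is None:
        return "unknown"
    codes = site_labels[comp_mask]
    codes = codes[codes != 0]
    if codes.size == 0:
        return "unknown"
    values, counts = np.unique(codes, return_counts=True)
    code = int(values[np.argmax(counts)])
    if site_names is None:
        return str(code)
    return site_names.get(code, "unknown")


def quantify_scan(
    volume: SuvVolume,
    aorta_voi: CylinderVoi | None = None,
    threshold: float | None = None,
    site_labels: np.ndarray | None = None,
    site_names: dict[int, str] | None = None,
    exclusion_mask: np.ndarray | None = None,
    config: QuantConfig = QuantConfig(),
) -> ScanQuant:
    """Full single-scan quantification.

    Either an aorta VOI (from which the threshold is derived) or an explicit
    ``threshold`` must be given.  When the VOI is given it is also excluded
    from segmentation (physiological blood-pool uptake) unless
    ``config.exclude_aorta`` is False.
    """
    stats = None
    if aorta_voi is not None:
        stats = aorta_stats(volume, aorta_voi, config.peak_diameter_mm)
        if threshold is None:
            threshold = compute_threshold(stats)
        if config.exclude_aorta:
            voi_mask = aorta_voi.mask(volume.shape, volume.spacing)
            exclusion_mask = (
                voi_mask if exclusion_mask is None else (exclusion_mask | voi_mask)
            )
    if threshold is None:
        raise ValueError("either aorta_voi or threshold must be provided")

    mean_map = sphere_mean_map(volume, config.peak_diameter_mm)
    seg = segment_lesions(
        volume,
        threshold,
        min_volume_ml=config.min_volume_ml,
        exclusion_mask=exclusion_mask,
        connectivity=config.connectivity,
        peak_diameter_mm=config.peak_diameter_mm,
        _mean_map=mean_map,
    )

    zc, yc, xc = voxel_centers(volume.shape, volume.spacing)
    lesions: list[LesionQuant] = []
    for lesion_id in range(1, seg.n_lesions + 1):
        comp = seg.labels == lesion_id
        peak = suv_peak(volume, comp, config.peak_diameter_mm, _mean_map=mean_map)
        idx = np.argwhere(comp)
        centroid = (
            float(((idx[:, 0] + 0.5) * volume.spacing[0]).mean()),
            float(((idx[:, 1] + 0.5) * volume.spacing[1]).mean()),
            float(((idx[:, 2] + 0.5) * volume.spacing[2]).mean()),
        )
        lesions.append(
            LesionQuant(
                lesion_id=lesion_id,
                site=_majority_site(comp, site_labels, site_names),
                volume_ml=seg.volumes_ml[lesion_id - 1],
                suv_peak=peak,
                suv_max=float(volume.values[comp].max()),
                centroid=centroid,
                voxel_count=seg.voxel_counts[lesion_id - 1],
            )
        )

    psma_tv = float(sum(l.volume_ml for l in lesions))
    if config.tl_mode == "per_lesion":
        tl = float(sum(l.suv_peak * l.volume_ml for l in lesions))
    elif config.tl_mode == "global":
        tl = (max(l.suv_peak for l in lesions) * psma_tv) if lesions else 0.0
    else:
        raise ValueError("tl_mode must be 'per_lesion' or 'global'")
    return ScanQuant(
        threshold=float(threshold),
        aorta=stats,
        lesions=lesions,
        psma_tv_ml=psma_tv,
        tl_psma=tl,
    )


def select_extreme_lesions(scan: ScanQuant, k: int = 2) -> list[LesionQuant]:
    """The k most- and k least-avid lesions per metastasis site, plus the
    primary prostate lesion(s).

    Sites with at most 2k lesions contribute all of them; ties are broken by
    lesion_id.  This mirrors the lesion-sampling scheme used to cover a wide
    range of avidity in the lesion-level analysis.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: dict[int, LesionQuant] = {}
    by_site: dict[str, list[LesionQuant]] = {}
    for lesion in scan.lesions:
        by_site.setdefault(lesion.site, []).append(lesion)
    for site, lesions in by_site.items():
        if site == "prostate":
            chosen = lesions
        elif len(lesions) <= 2 * k:
            chosen = lesions
        else:
            ordered = sorted(lesions, key=lambda l: (l.suv_peak, l.lesion_id))
            chosen = ordered[:k] + ordered[-k:]
        for lesion in chosen:
            selected[lesion.lesion_id] = lesion
    return [selected[i] for i in sorted(selected)]
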