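"""Ventilation quantification from magnitude MR lung images.

Given a 3-D magnitude image ``S[i, j, k]`` (``i``, ``j`` in-slice pixel
indices, ``k`` slice index), the pipeline is

1. denoising (configurable standard filter),
2. intensity clustering into ordered ventilation classes,
3. removal of the trachea / major airways,
4. noise-bias correction of the remaining in-mask intensities,
5. normalization to a ventilated volume fraction (VVF) map, and
6. its coefficient of variation CV = sigma_VVF / mu_VVF,

the scalar index of ventilation heterogeneity.  The bias correction uses
the Rayleigh statistics of the magnitude background:

    S_hat = sqrt(S^2 - (2/pi) * Sbar_BG^2)

with ``Sbar_BG`` the mean intensity of a sampled noise-only region, and a
negative radicand clamped to zero (magnitudes cannot be negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateClusteringError, EmptySignalError

logger = logging.getLogger(__name__)

__all__ = [
    "VentilationImage",
    "BackgroundEstimate",
    "SegmentationResult",
    "VVFMap",
    "QuantifyResult",
    "denoise",
    "classify_ventilation",
    "remove_major_airways",
    "estimate_background",
    "correct_bias",
    "compute_vvf",
    "compute_cv",
    "quantify_image",
]


@dataclass(frozen=True)
class VentilationImage:
    """3-D magnitude intensity grid with voxel spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.8, 1.8, 13.0)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("magnitude intensities must be nonnegative")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean intensity of a sampled noise-only region."""

    mean_intensity: float
    region: np.ndarray  # boolean mask of the sampled voxels

    def __post_init__(self):
        if self.mean_intensity < 0:
            raise ValueError("background mean must be nonnegative")
        if not np.any(self.region):
            raise ValueError("background region is empty")


@dataclass(frozen=True)
class SegmentationResult:
    """Class labels plus the derived ventilated and airway masks.

    ``class_labels`` holds 0 for background and 1..C for ventilation
    classes of increasing mean intensity; ``ventilated_mask`` is the
    nonzero-label set minus the removed airway voxels.
    """

    class_labels: np.ndarray
    ventilated_mask: np.ndarray
    airway_mask: np.ndarray

    def __post_init__(self):
        if np.any(self.ventilated_mask & self.airway_mask):
            raise ValueError("ventilated and airway masks must be disjoint")


@dataclass(frozen=True)
class VVFMap:
    """Per-voxel ventilated volume fraction and its summary statistics."""

    vvf: np.ndarray  # full grid, zero outside the ventilated mask
    mask: np.ndarray
    mean_vvf: float
    sd_vvf: float
    cv: float

    def __post_init__(self):
        total = float(self.vvf[self.mask].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"VVF must sum to 1 (got {total!r})")


@dataclass
class QuantifyResult:
    """Every intermediate of the quantification pipeline, for audit."""

    denoised: VentilationImage
    segmentation: SegmentationResult
    background: Optional[BackgroundEstimate]
    corrected: np.ndarray
    vvf: VVFMap
    cv: float = field(init=False)

    def __post_init__(self):
        self.cv = self.vvf.cv


def denoise(image: VentilationImage, method: str = "median", **params) -> VentilationImage:
    """Apply a standard denoising filter; shape and nonnegativity preserved.

    ``method`` is one of ``median`` (radius ``radius``, default 1, applied
    in-plane per slice — slices are far thicker than the in-plane
    resolution, so a cubic window would mix nearly uncorrelated tissue
    and erode the lung boundary; ``median3d`` gives the cubic window),
    ``nonlocal_means`` (scikit-image, ``h`` relative to the intensity
    range) or ``none``.
    """
    arr = image.intensities
    if method == "none":
        return image
    if method in ("median", "median3d"):
        radius = int(params.get("radius", 1))
        if radius < 1:
            raise ValueError("median radius must be >= 1")
        size = 2 * radius + 1
        footprint = (size, size, 1) if method == "median" else (size, size, size)
        out = ndimage.median_filter(arr, size=footprint, mode="nearest")
    elif method == "nonlocal_means":
        from skimage.restoration import denoise_nl_means

        scale = float(arr.max()) or 1.0
        h = float(params.get("h", 0.05)) * scale
        out = denoise_nl_means(arr, h=h, fast_mode=True, preserve_range=True)
        out = np.clip(out, 0.0, None)
    else:
        raise ValueError(f"unknown denoising method {method!r}")
    return VentilationImage(out, image.spacing)


def classify_ventilation(
    image: VentilationImage, n_classes: int = 4, seed: int = 0
) -> np.ndarray:
    """Cluster voxel intensities into ``n_classes`` ordered ventilation classes.

    One-dimensional k-means with seeded k-means++ initialization; the
    returned labels are re-indexed by ascending cluster mean so label 0 is
    always the lowest-intensity (background) class.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    values = image.intensities.reshape(-1, 1)
    if np.unique(values).size < n_classes:
        raise DegenerateClusteringError(
            f"image has fewer than {n_classes} distinct intensity values"
        )
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_classes, n_init=4, random_state=seed)
    # fit on a subsample for large volumes; predict every voxel
    if values.shape[0] > 200_000:
        rng = np.random.default_rng(seed)
        fit_idx = rng.choice(values.shape[0], size=200_000, replace=False)
        km.fit(values[fit_idx])
        raw = km.predict(values)
    else:
        raw = km.fit_predict(values)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(n_classes, dtype=np.int32)
    relabel[order] = np.arange(n_classes, dtype=np.int32)
    return relabel[raw].reshape(image.shape)


def fill_ventilation_holes(labels: np.ndarray) -> np.ndarray:
    """Reassign background-class voxels fully enclosed (in-slice) by
    ventilated tissue to the lowest ventilation class.

    Low-signal pockets inside the lung field are poorly ventilated
    airspace, not air outside the body; leaving them out of the
    ventilated mask would censor exactly the voxels that carry the
    heterogeneity signal.
    """
    labels = np.asarray(labels).copy()
    nonzero = labels > 0
    for k in range(labels.shape[2]):
        filled = ndimage.binary_fill_holes(nonzero[:, :, k])
        hole = filled & ~nonzero[:, :, k]
        labels[:, :, k][hole] = 1
    return labels


def remove_major_airways(
    labels: np.ndarray,
    image: VentilationImage,
    superior_fraction: float = 0.12,
    midline_fraction: float = 0.14,
    dilate: int = 1,
    max_volume_fraction: float = 0.10,
    bright_quantile: float = 0.75,
) -> SegmentationResult:
    """Remove the trachea and major airways from a class-label grid.

    The gas-filled trachea is among the brightest structures in the
    image; the heuristic takes the connected components of the bright
    voxels (labeled voxels above the ``bright_quantile`` intensity
    quantile) that touch a superior midline corridor (top
    ``superior_fraction`` of rows, central ``midline_fraction`` of
    columns), dilates them by ``dilate`` voxels and removes them, capped
    at ``max_volume_fraction`` of the labeled voxels.  Finding no
    candidate is not an error: the airway mask comes back empty with a
    logged warning.
    """
    labels = np.asarray(labels)
    ni, nj, _ = labels.shape
    nonzero = labels > 0
    airway = np.zeros(labels.shape, dtype=bool)
    if not nonzero.any():
        logger.warning("all-zero label grid: no airway candidate found")
        return SegmentationResult(labels, nonzero, airway)

    thresh = np.quantile(image.intensities[nonzero], bright_quantile)
    top = nonzero & (image.intensities >= thresh)
    comp, n_comp = ndimage.label(top)
    half_band = max(1, int(round(midline_fraction * nj / 2)))
    seed = np.zeros(labels.shape, dtype=bool)
    seed[: max(1, int(round(superior_fraction * ni))),
         nj // 2 - half_band : nj // 2 + half_band + 1, :] = True
    hit = np.unique(comp[seed & top])
    hit = hit[hit > 0]
    if hit.size == 0:
        logger.warning("no airway candidate found in the superior midline corridor")
        return SegmentationResult(labels, nonzero, airway)

    cap = max_volume_fraction * int(nonzero.sum())
    # brightest candidates first, stop at the volume cap
    means = ndimage.mean(image.intensities, comp, hit)
    total = 0
    for lab in hit[np.argsort(means)[::-1]]:
        size = int((comp == lab).sum())
        if total and total + size > cap:
            break
        airway |= comp == lab
        total += size
    if dilate > 0:
        grown = ndimage.binary_dilation(airway, iterations=dilate)
        if grown.sum() <= cap or grown.sum() <= airway.sum():
            airway = grown
    ventilated = nonzero & ~airway
    return SegmentationResult(labels, ventilated, airway)


def estimate_background(
    image: VentilationImage,
    region: str | np.ndarray = "corners",
    corner_size: int = 4,
    ventilated_mask: Optional[np.ndarray] = None,
) -> BackgroundEstimate:
    """Mean intensity of a noise-only region.

    ``region='corners'`` samples cubes of ``corner_size`` voxels at the
    eight grid corners (assumed outside the body); an explicit boolean
    mask overrides, and must not overlap the ventilated mask.
    """
    if isinstance(region, str):
        if region != "corners":
            raise ValueError(f"unknown background region {region!r}")
        mask = np.zeros(image.shape, dtype=bool)
        c = max(1, corner_size)
        for sl in _corner_slices(image.shape, c):
            mask[sl] = True
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("background mask shape mismatch")
    if not mask.any():
        raise ValueError("background region is empty")
    if ventilated_mask is not None and np.any(mask & ventilated_mask):
        raise ValueError("background region overlaps the ventilated mask")
    return BackgroundEstimate(float(image.intensities[mask].mean()), mask)


def _corner_slices(shape, c):
    for si in (slice(0, c), slice(-c, None)):
        for sj in (slice(0, c), slice(-c, None)):
            for sk in (slice(0, min(c, shape[2])), slice(-min(c, shape[2]), None)):
                yield (si, sj, sk)


def correct_bias(
    image: VentilationImage,
    background: BackgroundEstimate | float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Noise-bias-corrected intensities ``sqrt(S^2 - (2/pi) Sbar_BG^2)``.

    Applied to in-mask voxels only (the remaining non-background pixels);
    a negative radicand is clamped to zero.  Returns a full grid that is
    zero outside ``mask``.
    """
    sbar = background.mean_intensity if isinstance(background, BackgroundEstimate) else float(background)
    if sbar < 0:
        raise ValueError("background mean must be nonnegative")
    s = image.intensities
    out = np.sqrt(np.clip(s * s - (2.0 / np.pi) * sbar * sbar, 0.0, None))
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


def compute_vvf(corrected: np.ndarray, ventilated_mask: np.ndarray, ddof: int = 0) -> VVFMap:
    """Normalize corrected intensities to ventilated volume fractions.

    ``VVF = S_hat / sum(S_hat)`` over the ventilated mask; fractions sum
    to one by construction.  ``ddof`` selects the SD convention of the CV
    (0 = population, 1 = sample).
    """
    corrected = np.asarray(corrected, dtype=float)
    mask = np.asarray(ventilated_mask, dtype=bool)
    vals = corrected[mask]
    total = vals.sum()
    if vals.size == 0 or total <= 0:
        raise EmptySignalError("corrected in-mask signal sums to zero")
    vvf_grid = np.where(mask, corrected / total, 0.0)
    frac = vals / total
    mean = float(frac.mean())
    sd = float(frac.std(ddof=ddof)) if frac.size > ddof else 0.0
    return VVFMap(vvf_grid, mask, mean, sd, sd / mean)


def compute_cv(vvf: VVFMap, ddof: int = 0) -> float:
    """Coefficient of variation sigma_VVF / mu_VVF of the in-mask fractions."""
    vals = vvf.vvf[vvf.mask]
    if vals.size == 0:
        raise ValueError("empty ventilated mask")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean VVF must be positive")
    return float(vals.std(ddof=ddof) / mean)


def quantify_image(
    image: VentilationImage,
    config=None,
    airway_mask: Optional[np.ndarray] = None,
    ventilated_mask: Optional[np.ndarray] = None,
) -> QuantifyResult:
    """Full pipeline: denoise -> classify -> remove airways -> bias-correct
    -> VVF -> CV.

    ``config`` is an :class:`~ventmech.config.ImagingConfig` (defaults used
    when omitted).  An explicit ``ventilated_mask`` bypasses segmentation
    (pre-segmented input); an explicit ``airway_mask`` overrides the
    heuristic airway removal.
    """
    from .config import ImagingConfig

    cfg = config if config is not None else ImagingConfig()

    den = denoise(image, cfg.denoise_method, radius=cfg.denoise_radius)
    if ventilated_mask is not None:
        mask = np.asarray(ventilated_mask, dtype=bool)
        labels = mask.astype(np.int32)
        seg = SegmentationResult(labels, mask, np.zeros(image.shape, dtype=bool))
    else:
        labels = classify_ventilation(den, cfg.n_classes, cfg.kmeans_seed)
        if cfg.fill_holes:
            labels = fill_ventilation_holes(labels)
        if airway_mask is not None:
            aw = np.asarray(airway_mask, dtype=bool)
            seg = SegmentationResult(labels, (labels > 0) & ~aw, aw)
        else:
            seg = remove_major_airways(
                labels,
                den,
                superior_fraction=cfg.superior_fraction,
                midline_fraction=cfg.midline_fraction,
                dilate=cfg.airway_dilate,
                max_volume_fraction=cfg.airway_max_volume_fraction,
            )

    if cfg.background_region == "none":
        bg = None
        corrected = np.where(seg.ventilated_mask, den.intensities, 0.0)
    else:
        bg = estimate_background(
            den, cfg.background_region, cfg.corner_size, seg.ventilated_mask
        )
        corrected = correct_bias(den, bg, seg.ventilated_mask)
    vvf = compute_vvf(corrected, seg.ventilated_mask, ddof=cfg.sd_ddof)
    return QuantifyResult(den, seg, bg, corrected, vvf)
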