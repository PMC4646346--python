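"""Synthetic lung phantoms, ventilation truth maps and Rician noise.

The phantom emulates a coronal multi-slice magnitude acquisition: two
laterally separated lung fields, a midline superior airway (trachea and
main bronchi, gas-filled and therefore bright), patchy low-ventilation
defects with smooth edges riding on a multiplicative lognormal texture,
and Rician noise — the magnitude statistics of complex MR data, which
turn signal-free background into a Rayleigh distribution with mean
``sigma * sqrt(pi/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .errors import ConvergenceError
from .imaging import VentilationImage

__all__ = [
    "LungPhantom",
    "TrueVentilationMap",
    "make_lung_phantom",
    "make_ventilation_truth",
    "add_rician_noise",
    "render_image",
    "PRESET_TARGET_CV",
]

# named target-CV presets for the study conditions
PRESET_TARGET_CV = {
    "healthy_premch": 0.38,
    "healthy_postmch": 0.48,
    "healthy_postdi": 0.42,
    "asthmatic_premch": 0.42,
    "asthmatic_postmch": 0.51,
    "asthmatic_postdi": 0.46,
}


@dataclass(frozen=True)
class LungPhantom:
    """Boolean lung and airway masks on a common grid (spacing in mm)."""

    lung_mask: np.ndarray
    airway_mask: np.ndarray
    spacing: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        if self.lung_mask.shape != self.airway_mask.shape:
            raise ValueError("mask shapes differ")
        if not self.lung_mask.any():
            raise ValueError("lung mask is empty")
        if np.any(self.lung_mask & self.airway_mask):
            raise ValueError("lung and airway masks must be disjoint")


@dataclass(frozen=True)
class TrueVentilationMap:
    """Noiseless ventilation signal (zero outside the lung mask)."""

    signal: np.ndarray
    lung_mask: np.ndarray
    target_cv: float
    realized_cv: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")
        if np.any(self.signal[~self.lung_mask] != 0):
            raise ValueError("signal must be zero outside the lung mask")
        if self.realized_cv < 0:
            raise ValueError("realized CV must be nonnegative")


def make_lung_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (3.6, 3.6, 13.0),
    seed: int = 0,
) -> LungPhantom:
    """Two ellipsoidal lung fields plus a midline superior airway.

    Axis 0 runs superior -> inferior, axis 1 left -> right, axis 2 is the
    slice (anterior -> posterior) direction, so coarse slice counts are
    allowed; the in-plane dimensions must be at least 16 and the slice
    count at least 4.  Deterministic for a fixed seed (mild seeded jitter
    of the lung geometry).
    """
    ni, nj, nk = (int(v) for v in shape)
    if ni < 16 or nj < 16 or nk < 4:
        raise ValueError(f"degenerate shape {shape}: need in-plane >= 16, slices >= 4")
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.meshgrid(
        np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij"
    )
    lung = np.zeros((ni, nj, nk), dtype=bool)
    for side in (-1.0, 1.0):
        jit = rng.uniform(0.97, 1.03, size=3)
        ci, cj, ck = 0.58 * ni, (0.5 + side * 0.24) * nj, 0.5 * nk
        ai, aj, ak = 0.33 * ni * jit[0], 0.155 * nj * jit[1], 0.46 * nk * jit[2]
        lung |= (
            ((ii - ci) / ai) ** 2 + ((jj - cj) / aj) ** 2 + ((kk - ck) / ak) ** 2
        ) <= 1.0
    # trachea: vertical tube on the midline, from the top down
    r_aw = max(1.2, 0.04 * nj)
    tube = ((jj - 0.5 * nj) ** 2 + ((kk - 0.5 * nk) * 1.5) ** 2) <= r_aw**2
    airway = tube & (ii <= 0.45 * ni)
    lung &= ~airway
    return LungPhantom(lung, airway, tuple(float(s) for s in spacing), seed)


def _defect_field(
    phantom: LungPhantom, defect_count: int, defect_radius_mm: float, rng
) -> np.ndarray:
    """Sum of Gaussian-profile spherical inclusions centered in the lung."""
    field = np.zeros(phantom.lung_mask.shape)
    if defect_count <= 0:
        return field
    # center defects in the lung interior so their smooth profiles stay
    # surrounded by ventilated tissue rather than bleeding off the edge
    interior = ndimage.binary_erosion(
        phantom.lung_mask, structure=np.ones((3, 3, 1), dtype=bool), iterations=2
    )
    idx = np.argwhere(interior if interior.sum() >= defect_count else phantom.lung_mask)
    centers = idx[rng.choice(idx.shape[0], size=defect_count, replace=False)]
    sp = np.asarray(phantom.spacing)
    grids = np.meshgrid(*[np.arange(n) for n in field.shape], indexing="ij")
    coords = np.stack(grids, axis=-1) * sp  # mm coordinates
    sigma = defect_radius_mm / 2.0  # radius ~ 2 sigma of the profile
    for c in centers:
        d2 = ((coords - c * sp) ** 2).sum(axis=-1)
        field += np.exp(-d2 / (2 * sigma**2))
    return field


def make_ventilation_truth(
    phantom: LungPhantom,
    target_cv: float,
    defect_count: int = 6,
    defect_radius_mm: float = 12.0,
    seed: int = 0,
    baseline: float = 100.0,
    texture_sigma_vox: float = 2.5,
    defect_floor: float = 0.3,
) -> TrueVentilationMap:
    """Noiseless ventilation map whose in-mask CV matches ``target_cv``.

    The signal is ``baseline * exp(t * s0 * G) * max(1 - t * D, floor)``
    where ``G`` is a smoothed, in-mask-standardized Gaussian texture and
    ``D`` the summed Gaussian defect profiles; the single scale ``t`` is
    solved by bracketing so the realized population CV lands within
    +-0.02 of the target (in practice much closer).  An unattainable
    target raises :class:`ConvergenceError` naming the achieved CV.
    """
    if target_cv < 0:
        raise ValueError("target_cv must be nonnegative")
    mask = phantom.lung_mask
    rng = np.random.default_rng(seed)
    g = ndimage.gaussian_filter(rng.standard_normal(mask.shape), texture_sigma_vox)
    gm = g[mask]
    g = (g - gm.mean()) / gm.std()
    d = _defect_field(phantom, defect_count, defect_radius_mm, rng)

    s0 = 0.30  # texture log-SD per unit scale

    def signal_at(t: float) -> np.ndarray:
        tex = np.exp(t * s0 * g)
        vent = np.maximum(1.0 - t * d, defect_floor)
        return np.where(mask, baseline * tex * vent, 0.0)

    def cv_at(t: float) -> float:
        v = signal_at(t)[mask]
        return float(v.std() / v.mean())

    if target_cv == 0:
        sig = np.where(mask, baseline, 0.0)
        return TrueVentilationMap(sig, mask, 0.0, 0.0)

    t_max = 3.0
    achieved = cv_at(t_max)
    if achieved + 0.02 < target_cv:
        raise ConvergenceError(
            f"target CV {target_cv:g} unattainable; achieved {achieved:.4f}",
            achieved=achieved,
        )
    if achieved <= target_cv:
        t = t_max  # just-attainable edge; realized CV still within tolerance
    else:
        t = optimize.brentq(lambda t: cv_at(t) - target_cv, 0.0, t_max, xtol=1e-6)
    sig = signal_at(t)
    realized = float(sig[mask].std() / sig[mask].mean())
    if abs(realized - target_cv) > 0.02:
        raise ConvergenceError(
            f"calibration stopped at CV {realized:.4f} for target {target_cv:g}",
            achieved=realized,
        )
    return TrueVentilationMap(sig, mask, float(target_cv), realized)


def add_rician_noise(
    truth: TrueVentilationMap | np.ndarray,
    sigma: float,
    seed: int = 0,
    spacing: tuple[float, float, float] = (3.6, 3.6, 13.0),
) -> VentilationImage:
    """Magnitude image ``sqrt((A + n1)^2 + n2^2)`` with iid Gaussian
    ``n1, n2`` of SD ``sigma`` — Rician around the true amplitude ``A``,
    Rayleigh where ``A = 0``."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if isinstance(truth, TrueVentilationMap):
        amplitude = truth.signal
    else:
        amplitude = np.asarray(truth, dtype=float)
    if sigma == 0:
        return VentilationImage(amplitude.copy(), spacing)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=amplitude.shape)
    n2 = rng.normal(0.0, sigma, size=amplitude.shape)
    return VentilationImage(np.hypot(amplitude + n1, n2), spacing)


def render_image(
    phantom: LungPhantom,
    truth: TrueVentilationMap,
    sigma: float,
    seed: int = 0,
    airway_intensity: Optional[float] = None,
) -> VentilationImage:
    """Compose the full magnitude image: parenchymal signal plus the
    bright gas-filled trachea (default 1.8x the mean lung signal), then
    Rician noise."""
    mean_sig = float(truth.signal[phantom.lung_mask].mean())
    bright = 1.8 * mean_sig if airway_intensity is None else float(airway_intensity)
    amplitude = truth.signal + bright * phantom.airway_mask
    return add_rician_noise(amplitude, sigma, seed, phantom.spacing)
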