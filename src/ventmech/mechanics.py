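"""Multisine forced-oscillation waveform design and lung impedance estimation.

A broadband ventilation waveform delivers flow at several non-sum,
non-difference (NSND) frequencies between 0.1 and 8 Hz, with tone phases
chosen to minimize the crest factor of the delivered *volume* so that the
signal also ventilates the subject with a normal tidal volume.  From a
synchronized recording of airway-opening pressure ``P_ao``, esophageal
pressure ``P_es`` and flow ``Q_ao``, lung impedance is

    Z_L(w) = P_tp(w) / Q_ao(w),      P_tp = P_ao - P_es,

with resistance ``R_L = Re[Z_L]`` and elastance ``E_L = -w Im[Z_L]``.
Four scalar features summarize the spectrum: resistance at the lowest
tone (``r_low``, dominated by tissue and heterogeneous constriction),
resistance at the highest tone (``r_high``, conductive airway
resistance), their difference (``r_het``, the frequency dependence that
signals parallel heterogeneity), and elastance at the lowest tone
(``e_low``).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import IllConditionedBinError, InfeasibleDesignError

__all__ = [
    "ForcingWaveform",
    "PressureFlowRecording",
    "ImpedanceSpectrum",
    "MechanicsFeatures",
    "is_nsnd",
    "select_nsnd_frequencies",
    "crest_factor",
    "optimize_phases",
    "synthesize_flow",
    "estimate_impedance",
    "to_resistance_elastance",
    "extract_features",
    "default_waveform",
]


@dataclass(frozen=True)
class ForcingWaveform:
    """Multisine flow forcing: tone m has frequency ``multiples[m] *
    fundamental_hz``, flow amplitude ``amplitudes[m]`` (L/s, before the
    tidal-volume rescaling applied at synthesis) and phase ``phases[m]``."""

    fundamental_hz: float
    multiples: tuple[int, ...]
    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    tidal_volume_l: float = 0.5
    duration_s: float = 40.0
    fs_hz: float = 40.0

    def __post_init__(self):
        m = tuple(int(v) for v in self.multiples)
        if len(m) == 0:
            raise ValueError("waveform needs at least one tone")
        if any(v < 1 for v in m) or any(b >= c for b, c in zip(m, m[1:])):
            raise ValueError("multiples must be strictly increasing integers >= 1")
        if len(self.amplitudes) != len(m) or len(self.phases) != len(m):
            raise ValueError("amplitudes/phases must match multiples")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("tone amplitudes must be positive")
        object.__setattr__(self, "multiples", m)
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.fundamental_hz * np.asarray(self.multiples, dtype=float)


@dataclass(frozen=True)
class PressureFlowRecording:
    """Synchronized pressure-flow traces sampled at ``fs_hz``."""

    time_s: np.ndarray
    pao: np.ndarray
    pes: np.ndarray
    qao: np.ndarray
    fs_hz: float

    def __post_init__(self):
        n = len(self.time_s)
        if not (len(self.pao) == len(self.pes) == len(self.qao) == n):
            raise ValueError("all traces must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs must be positive")

    @property
    def ptp(self) -> np.ndarray:
        """Transpulmonary pressure P_ao - P_es (cm H2O)."""
        return np.asarray(self.pao) - np.asarray(self.pes)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex lung impedance at the forcing frequencies, with the
    resistance/elastance decomposition filled on demand."""

    frequencies_hz: np.ndarray
    z: np.ndarray
    r: Optional[np.ndarray] = None
    e: Optional[np.ndarray] = None


@dataclass(frozen=True)
class MechanicsFeatures:
    r_low: float
    r_high: float
    r_het: float
    e_low: float

    def __post_init__(self):
        if abs(self.r_het - (self.r_low - self.r_high)) > 1e-12 * max(
            1.0, abs(self.r_low), abs(self.r_high)
        ):
            raise ValueError("r_het must equal r_low - r_high")


def is_nsnd(multiples: Sequence[int]) -> bool:
    """True iff no element equals the sum or absolute difference of any
    pair of elements, pairs with repetition included (so harmonics, which
    are self-sums k + k, are excluded)."""
    ms = [int(m) for m in multiples]
    if len(ms) == 0:
        raise ValueError("empty frequency-multiple list")
    if any(m < 1 for m in ms) or len(set(ms)) != len(ms):
        raise ValueError("multiples must be distinct positive integers")
    s = set(ms)
    for b in ms:
        for c in ms:
            if b + c in s or abs(b - c) in s:
                return False
    return True


def select_nsnd_frequencies(
    fundamental_hz: float,
    f_min: float = 0.1,
    f_max: float = 8.0,
    count: int = 7,
    growth_factor: float = 1.8,
) -> tuple[int, ...]:
    """Greedy approximately log-spaced NSND tone selection.

    Walks the admissible integer multiples of the fundamental upward,
    accepting a multiple iff the set so far stays NSND and the candidate
    is at least ``growth_factor`` times the previous acceptance.  With the
    defaults (fundamental 0.1 Hz, 7 tones in [0.1, 8] Hz) this yields
    multiples (1, 3, 7, 13, 24, 44, 80), i.e. 0.1 to 8.0 Hz.
    """
    if not (f_min < f_max):
        raise ValueError("f_min must be below f_max")
    if count < 1:
        raise ValueError("count must be >= 1")
    if fundamental_hz <= 0 or fundamental_hz > f_min + 1e-12:
        raise ValueError("fundamental must be positive and <= f_min")
    m_lo = int(np.ceil(f_min / fundamental_hz - 1e-9))
    m_hi = int(np.floor(f_max / fundamental_hz + 1e-9))
    chosen: list[int] = []
    for m in range(max(1, m_lo), m_hi + 1):
        if chosen and m < growth_factor * chosen[-1]:
            continue
        if is_nsnd(chosen + [m]):
            chosen.append(m)
            if len(chosen) == count:
                return tuple(chosen)
    raise InfeasibleDesignError(
        f"could only place {len(chosen)} NSND tones of {count} requested "
        f"in [{f_min}, {f_max}] Hz",
        achieved=len(chosen),
    )


def _volume_crest(multiples, amplitudes, phases) -> float:
    """Crest factor (peak/RMS) of the integrated multisine over one
    fundamental period, on a grid of >= 64 samples per period of the
    highest tone."""
    m = np.asarray(multiples, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    p = np.asarray(phases, dtype=float)
    n = max(256, int(64 * m.max()))
    # work in fundamental-normalized time; crest is invariant to f0
    t = np.arange(n) / n
    vol = (a / m) @ np.sin(2 * np.pi * np.outer(m, t) + p[:, None])
    return float(np.abs(vol).max() / np.sqrt(np.mean(vol * vol)))


def crest_factor(waveform: ForcingWaveform, domain: str = "volume") -> float:
    """Peak-to-RMS ratio of the synthesized waveform over one fundamental
    period; ``domain`` selects the volume (default: tidal-volume delivery
    is the design goal) or flow signal."""
    if not any(a > 0 for a in waveform.amplitudes):
        raise ValueError("zero-amplitude waveform")
    if domain == "volume":
        return _volume_crest(waveform.multiples, waveform.amplitudes, waveform.phases)
    if domain == "flow":
        m = np.asarray(waveform.multiples, dtype=float)
        a = np.asarray(waveform.amplitudes, dtype=float)
        p = np.asarray(waveform.phases, dtype=float)
        n = max(256, int(64 * m.max()))
        t = np.arange(n) / n
        flow = a @ np.cos(2 * np.pi * np.outer(m, t) + p[:, None])
        return float(np.abs(flow).max() / np.sqrt(np.mean(flow * flow)))
    raise ValueError(f"unknown crest-factor domain {domain!r}")


def optimize_phases(
    multiples: Sequence[int],
    amplitudes: Sequence[float],
    restarts: int = 8,
    seed: int = 0,
) -> tuple[float, ...]:
    """Seeded multi-start local search minimizing the volume crest factor.

    Starts from zero phases, Schroeder-style quadratic phases, and
    ``restarts`` random draws; each start is refined by Nelder-Mead.  The
    returned phase set never exceeds the zero-phase crest.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    m = np.asarray(multiples, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0 or np.any(a <= 0):
        raise ValueError("amplitudes must be positive")
    k = m.size
    if k == 1:
        return (0.0,)

    def cost(p):
        return _volume_crest(m, a, p)

    rng = np.random.default_rng(seed)
    power = (a / m) ** 2
    schroeder = -np.pi * np.cumsum(np.concatenate([[0.0], power[:-1]])) / power.sum()
    starts = [np.zeros(k), schroeder]
    starts += [rng.uniform(0, 2 * np.pi, size=k) for _ in range(restarts)]
    best_p, best_c = np.zeros(k), cost(np.zeros(k))
    for p0 in starts:
        res = optimize.minimize(
            cost, p0, method="Nelder-Mead",
            options={"maxiter": 400 * k, "xatol": 1e-4, "fatol": 1e-6},
        )
        if res.fun < best_c:
            best_p, best_c = res.x, res.fun
    return tuple(float(p) for p in np.mod(best_p, 2 * np.pi))


def scaled_tones(waveform: ForcingWaveform) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tone frequencies (Hz), flow amplitudes (L/s) and phases after the
    single rescaling that makes the peak-to-peak volume excursion equal the
    requested tidal volume."""
    if not any(a > 0 for a in waveform.amplitudes):
        raise ValueError("zero-amplitude waveform")
    m = np.asarray(waveform.multiples, dtype=float)
    a = np.asarray(waveform.amplitudes, dtype=float)
    p = np.asarray(waveform.phases, dtype=float)
    n = max(256, int(64 * m.max()))
    t = np.arange(n) / n
    f0 = waveform.fundamental_hz
    vol = (a / (2 * np.pi * m * f0)) @ np.sin(2 * np.pi * np.outer(m, t) + p[:, None])
    p2p = vol.max() - vol.min()
    scale = waveform.tidal_volume_l / p2p
    return m * f0, a * scale, p


def synthesize_flow(waveform: ForcingWaveform) -> np.ndarray:
    """Sampled multisine flow (L/s) over ``duration_s`` at ``fs_hz``.

    The duration must span an integer number of fundamental periods so
    that every tone falls exactly on a discrete spectral bin.
    """
    cycles = waveform.duration_s * waveform.fundamental_hz
    if abs(cycles - round(cycles)) > 1e-9 or round(cycles) < 1:
        raise ValueError(
            "duration must be a positive integer number of fundamental periods"
        )
    freqs, amps, phases = scaled_tones(waveform)
    n = int(round(waveform.fs_hz * waveform.duration_s))
    t = np.arange(n) / waveform.fs_hz
    return amps @ np.cos(2 * np.pi * np.outer(freqs, t) + phases[:, None])


def _bin_coefficients(x: np.ndarray, n_per: int, bins: np.ndarray) -> np.ndarray:
    """Complex single-sided Fourier coefficients at ``bins``, averaged over
    the M consecutive single-period segments of ``x``."""
    m_seg = x.size // n_per
    seg = x[: m_seg * n_per].reshape(m_seg, n_per)
    spec = np.fft.rfft(seg, axis=1)[:, bins] * (2.0 / n_per)
    return spec.mean(axis=0)


def estimate_impedance(
    recording: PressureFlowRecording,
    waveform: ForcingWaveform,
    min_flow_amp: float = 1e-9,
) -> ImpedanceSpectrum:
    """Lung impedance Z_L = P_tp / Q_ao at each forcing bin.

    The recording is cut into single-fundamental-period segments; the
    discrete Fourier coefficients of P_tp and Q_ao at each forcing bin are
    averaged across segments (rectangular window — exact on integer
    periods) and divided.  A flow coefficient below ``min_flow_amp`` (L/s)
    at any bin raises :class:`IllConditionedBinError`.
    """
    n_per_f = recording.fs_hz / waveform.fundamental_hz
    n_per = int(round(n_per_f))
    if abs(n_per_f - n_per) > 1e-6:
        raise ValueError("sampling rate is not an integer multiple of the fundamental")
    if len(recording.qao) < n_per:
        raise ValueError("recording shorter than one fundamental period")
    bins = np.asarray(waveform.multiples, dtype=int)
    if bins.max() >= n_per // 2 + 1:
        raise ValueError("forcing frequency above the Nyquist bin")
    q = _bin_coefficients(np.asarray(recording.qao, dtype=float), n_per, bins)
    p = _bin_coefficients(np.asarray(recording.ptp, dtype=float), n_per, bins)
    small = np.abs(q) < min_flow_amp
    if small.any():
        f_bad = waveform.frequencies_hz[small][0]
        raise IllConditionedBinError(
            f"flow coefficient below {min_flow_amp} L/s at {f_bad:g} Hz"
        )
    return to_resistance_elastance(
        ImpedanceSpectrum(waveform.frequencies_hz, p / q)
    )


def to_resistance_elastance(spectrum: ImpedanceSpectrum) -> ImpedanceSpectrum:
    """Fill ``r = Re[Z]`` and ``e = -w Im[Z]`` (w = 2 pi f)."""
    f = np.asarray(spectrum.frequencies_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    z = np.asarray(spectrum.z)
    return dataclasses.replace(
        spectrum, r=z.real.copy(), e=-2 * np.pi * f * z.imag
    )


def extract_features(
    spectrum: ImpedanceSpectrum, f_low: float = 0.1, f_high: float = 8.0
) -> MechanicsFeatures:
    """R_low, R_high, R_het = R_low - R_high, and E_low.

    Read at the tones nearest to ``f_low`` and ``f_high``; a warning is
    issued when the nearest tone deviates from the nominal frequency by
    more than 5%.
    """
    f = np.asarray(spectrum.frequencies_hz, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two tones to extract features")
    if spectrum.r is None or spectrum.e is None:
        spectrum = to_resistance_elastance(spectrum)
    i_lo = int(np.argmin(np.abs(f - f_low)))
    i_hi = int(np.argmin(np.abs(f - f_high)))
    if i_lo == i_hi:
        raise ValueError("low and high feature tones coincide")
    for nominal, actual in ((f_low, f[i_lo]), (f_high, f[i_hi])):
        if abs(actual - nominal) > 0.05 * nominal:
            warnings.warn(
                f"nearest tone {actual:g} Hz deviates >5% from nominal {nominal:g} Hz",
                stacklevel=2,
            )
    r_low = float(spectrum.r[i_lo])
    r_high = float(spectrum.r[i_hi])
    return MechanicsFeatures(r_low, r_high, r_low - r_high, float(spectrum.e[i_lo]))


def default_waveform(
    fundamental_hz: float = 0.1,
    f_min: float = 0.1,
    f_max: float = 8.0,
    count: int = 7,
    growth_factor: float = 1.8,
    tidal_volume_l: float = 0.5,
    duration_s: float = 40.0,
    fs_hz: float = 40.0,
    amplitude_profile: str = "equal_volume",
    optimizer_restarts: int = 6,
    seed: int = 0,
    optimize: bool = True,
) -> ForcingWaveform:
    """The default 7-tone NSND design with crest-optimized phases.

    ``equal_volume`` gives every tone the same volume amplitude (flow
    amplitude proportional to frequency); ``equal_flow`` gives equal flow
    amplitudes.
    """
    multiples = select_nsnd_frequencies(
        fundamental_hz, f_min, f_max, count, growth_factor
    )
    m = np.asarray(multiples, dtype=float)
    if amplitude_profile == "equal_volume":
        amplitudes = m / m[0]
    elif amplitude_profile == "equal_flow":
        amplitudes = np.ones_like(m)
    else:
        raise ValueError(f"unknown amplitude profile {amplitude_profile!r}")
    if optimize and count > 1:
        phases = optimize_phases(multiples, amplitudes, optimizer_restarts, seed)
    else:
        phases = tuple(0.0 for _ in multiples)
    return ForcingWaveform(
        fundamental_hz, multiples, tuple(amplitudes), phases,
        tidal_volume_l, duration_s, fs_hz,
    )
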