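"""Parallel-compartment lung model and forward simulation of recordings.

The lung is abstracted as a central airway (resistance + inertance) in
series with parallel branches, each a resistance-elastance-inertance
unit:

    Z_b(w) = R_b + j (w I_b - E_b / w)
    Z_L(w) = R_c + j w I_c + ( sum_b 1 / Z_b(w) )^-1

Branches with unequal time constants (R_b E_b products) produce the
classic Otis frequency dependence: apparent resistance falls and
apparent elastance rises toward low frequency, the mechanical signature
of heterogeneous constriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mechanics import (
    ForcingWaveform,
    ImpedanceSpectrum,
    PressureFlowRecording,
    scaled_tones,
    to_resistance_elastance,
)

__all__ = ["LungModel", "model_impedance", "simulate_recording"]


@dataclass(frozen=True)
class LungModel:
    """Central airway plus parallel (R_b, E_b, I_b) branches.

    Units: resistance cm H2O/L/s, elastance cm H2O/L, inertance
    cm H2O/L/s^2.
    """

    branches: tuple[tuple[float, float, float], ...]
    central_resistance: float = 0.0
    central_inertance: float = 0.0

    def __post_init__(self):
        br = tuple(tuple(float(v) for v in b) for b in self.branches)
        if len(br) == 0:
            raise ValueError("model needs at least one branch")
        for r, e, i in br:
            if r <= 0 or e <= 0 or i < 0:
                raise ValueError("branch must have R > 0, E > 0, I >= 0")
        if self.central_resistance < 0 or self.central_inertance < 0:
            raise ValueError("central elements must be nonnegative")
        object.__setattr__(self, "branches", br)


def model_impedance(model: LungModel, frequencies: Sequence[float]) -> ImpedanceSpectrum:
    """Closed-form input impedance of the parallel-compartment model."""
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("frequencies must be a nonempty 1-D sequence")
    if np.any(f <= 0):
        raise ValueError("all frequencies must be positive")
    w = 2 * np.pi * f
    admittance = np.zeros_like(w, dtype=complex)
    for r, e, i in model.branches:
        zb = r + 1j * (w * i - e / w)
        admittance += 1.0 / zb
    z = model.central_resistance + 1j * w * model.central_inertance + 1.0 / admittance
    return to_resistance_elastance(ImpedanceSpectrum(f, z))


def simulate_recording(
    model: LungModel,
    waveform: ForcingWaveform,
    fs: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PressureFlowRecording:
    """Forward-simulate a pressure-flow recording of the model under the
    multisine forcing.

    The flow trace is the synthesized multisine; transpulmonary pressure
    is built tone by tone as ``P_tp(w) = Z_L(w) Q_ao(w)``.  All pressure
    signal is routed through the esophageal channel (``P_es = -P_tp``
    plus Gaussian noise of SD ``noise_sd``; ``P_ao`` is independent noise
    around zero), so only the difference ``P_ao - P_es = P_tp + noise``
    carries meaning — the convention under which impedance is estimated.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    cycles = duration * waveform.fundamental_hz
    if abs(cycles - round(cycles)) > 1e-9 or round(cycles) < 1:
        raise ValueError("duration must be an integer number of fundamental periods")
    f_max = waveform.fundamental_hz * max(waveform.multiples)
    if fs <= 2 * f_max:
        raise ValueError("fs must exceed twice the highest forcing frequency")
    freqs, amps, phases = scaled_tones(waveform)
    z = model_impedance(model, freqs).z
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    arg = 2 * np.pi * np.outer(freqs, t) + phases[:, None]
    qao = amps @ np.cos(arg)
    ptp = (amps * np.abs(z)) @ np.cos(arg + np.angle(z)[:, None])
    rng = np.random.default_rng(seed)
    pes = -ptp + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else -ptp
    pao = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    return PressureFlowRecording(t, pao, pes, qao, float(fs))
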