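"""Virtual cohort generation: images, recordings and the study table.

Each virtual subject carries a latent constriction-heterogeneity
variable per condition.  The latent value drives, scaled by a single
``coupling`` knob, (i) the target CV and defect load of the subject's
ventilation image and (ii) the dispersion of branch resistances of the
subject's parallel-compartment lung model — the mechanism by which a
patchy constriction pattern produces both image heterogeneity and the
Otis-type frequency dependence R_het.  Airway reactivity is tied to the
baseline latent value: asthmatic log10(PC20) decreases linearly in it
(with scatter), healthy subjects sit censored above the 25 mg/mL
maximum dose.

The generator's defaults emulate the study conditions: a methacholine
challenge raises the latent value (PostMch), after which five deep
inspirations relax it fully in healthy subjects but only partially in
asthmatics (PostDI).  Target CVs land near 0.38/0.48/0.42 (healthy) and
0.44/0.51/0.47 (asthmatic) across the three conditions.

Every measured quantity in the returned study table is produced by
running the actual measurement pipeline on the synthetic raw data
(image quantification and impedance estimation), not copied from the
generator's internals; the ground-truth latent value is carried in a
separate column for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .imaging import quantify_image
from .lungmodel import LungModel, simulate_recording
from .mechanics import ForcingWaveform, default_waveform, estimate_impedance, extract_features
from .phantom import make_lung_phantom, make_ventilation_truth, render_image

__all__ = ["CohortSpec", "CohortResult", "simulate_cohort"]

CONDITIONS = ("PreMch", "PostMch", "PostDI")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design parameters.

    ``coupling`` scales how strongly the latent heterogeneity variable
    feeds the image defect load and the branch-resistance dispersion;
    0 severs the link entirely (the null generator), 1 is the default
    calibrated strength.
    """

    n_healthy: int = 4
    n_asthmatic: int = 9
    coupling: float = 1.0
    pc20_range: tuple[float, float] = (0.05, 25.0)
    noise_sigma: float = 4.0
    seed: int = 0
    # image geometry and acquisition
    image_shape: tuple[int, int, int] = (48, 32, 8)
    spacing: tuple[float, float, float] = (3.6, 3.6, 13.0)
    baseline_signal: float = 100.0
    # latent-variable model
    cv_floor: float = 0.35
    cv_gain: float = 0.25
    di_recovery_healthy: float = 0.9
    di_recovery_asthmatic: float = 0.5
    # lung-model calibration
    n_branches: int = 8
    branch_r_base: float = 14.0
    branch_e_base: float = 56.0
    constriction_gain: float = 3.0
    dispersion_gain: float = 1.8
    elastance_gain: float = 0.8
    # recording
    recording_fs_hz: float = 40.0
    recording_duration_s: float = 40.0
    recording_noise_sd: float = 0.15
    # PC20 link: log10(PC20) = a - b * latent_baseline + N(0, sd)
    pc20_intercept: float = 1.6
    pc20_slope: float = 4.0
    pc20_scatter: float = 0.3

    def __post_init__(self):
        if self.n_healthy < 0 or self.n_asthmatic < 0:
            raise ValueError("subject counts must be nonnegative")
        if self.n_healthy + self.n_asthmatic < 2:
            raise ValueError("need at least 2 subjects in total")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")
        lo, hi = self.pc20_range
        if not (0 < lo < hi):
            raise ValueError("pc20_range must be a positive interval")


@dataclass
class CohortResult:
    table: pd.DataFrame
    waveform: ForcingWaveform
    raw: Optional[dict] = None  # (subject_id, condition) -> (image, recording, truth)


def _latents(spec: CohortSpec, group: str, rng) -> tuple[float, float, float]:
    """Latent heterogeneity at PreMch, PostMch and PostDI for one subject."""
    if group == "healthy":
        base = max(0.01, rng.normal(0.10, 0.04))
        boost = max(0.0, rng.normal(0.42, 0.08))
        rec = spec.di_recovery_healthy
    else:
        base = max(0.05, rng.normal(0.35, 0.10))
        boost = max(0.0, rng.normal(0.30, 0.08))
        rec = spec.di_recovery_asthmatic
    post = base + boost
    di = max(0.01, post - rec * (post - base) + rng.normal(0.0, 0.02))
    return base, post, di


def _subject_model(spec: CohortSpec, latent: float, rng) -> LungModel:
    """Parallel-compartment model whose branch-R dispersion grows with
    coupling * latent.

    The lognormal resistance multipliers are normalized to unit harmonic
    mean, so dispersion widens the time-constant spread (raising the
    low-frequency resistance and elastance, the Otis effect) without
    collapsing the parallel (high-frequency) resistance.
    """
    b = spec.n_branches
    r_mean = spec.branch_r_base * (1.0 + spec.constriction_gain * latent)
    s = spec.dispersion_gain * spec.coupling * latent
    mult = np.exp(s * rng.standard_normal(b) + 0.5 * s * s)
    e_b = spec.branch_e_base * (1.0 + spec.elastance_gain * latent)
    branches = tuple((float(r_mean * m), float(e_b), 0.01) for m in mult)
    return LungModel(branches, central_resistance=1.0, central_inertance=0.01)


def simulate_cohort(
    spec: CohortSpec,
    keep_raw: bool = False,
    sink: Optional[Callable] = None,
    imaging_config=None,
    waveform: Optional[ForcingWaveform] = None,
) -> CohortResult:
    """Generate and *measure* a whole virtual cohort.

    For every subject and condition, a noisy magnitude image and a
    pressure-flow recording are generated and pushed through the imaging
    and mechanics pipelines; the resulting study table holds one row per
    subject-condition with the measured CV and mechanics features, PC20,
    FEV1 %predicted, and the ground-truth latent heterogeneity.

    ``sink(subject_id, condition, image, recording, truth)`` is called
    for every generated artifact (for streaming to disk); ``keep_raw``
    retains them in memory on the result object.
    """
    rng = np.random.default_rng(spec.seed)
    wf = waveform if waveform is not None else default_waveform(
        fs_hz=spec.recording_fs_hz, duration_s=spec.recording_duration_s,
        seed=int(rng.integers(2**31)),
    )
    rows = []
    raw = {} if keep_raw else None
    subjects = [("healthy", i) for i in range(spec.n_healthy)] + [
        ("asthmatic", i) for i in range(spec.n_asthmatic)
    ]
    for group, idx in subjects:
        sid = f"{'H' if group == 'healthy' else 'A'}{idx + 1}"
        latents = _latents(spec, group, rng)
        phantom = make_lung_phantom(
            spec.image_shape, spec.spacing, seed=int(rng.integers(2**31))
        )
        # AHR from the baseline latent value
        if group == "healthy":
            pc20, censored = spec.pc20_range[1], True
        else:
            log_pc20 = (
                spec.pc20_intercept - spec.pc20_slope * latents[0]
                + rng.normal(0.0, spec.pc20_scatter)
            )
            pc20 = 10.0 ** log_pc20
            censored = pc20 > spec.pc20_range[1]
            pc20 = float(np.clip(pc20, *spec.pc20_range))
        if group == "healthy":
            fev1 = float(rng.normal(110.0, 7.0))
        else:
            fev1 = float(np.clip(95.0 - 50.0 * latents[0] + rng.normal(0.0, 6.0),
                                 55.0, 125.0))

        for cond, latent in zip(CONDITIONS, latents):
            target_cv = spec.cv_floor + spec.cv_gain * spec.coupling * latent
            defects = 2 + int(round(10 * spec.coupling * latent))
            truth = make_ventilation_truth(
                phantom, target_cv, defect_count=defects,
                seed=int(rng.integers(2**31)), baseline=spec.baseline_signal,
            )
            image = render_image(phantom, truth, spec.noise_sigma,
                                 seed=int(rng.integers(2**31)))
            model = _subject_model(spec, latent, rng)
            recording = simulate_recording(
                model, wf, spec.recording_fs_hz, spec.recording_duration_s,
                noise_sd=spec.recording_noise_sd, seed=int(rng.integers(2**31)),
            )
            quant = quantify_image(image, imaging_config)
            feats = extract_features(estimate_impedance(recording, wf))
            rows.append({
                "subject_id": sid, "group": group, "condition": cond,
                "cv": quant.cv, "r_low": feats.r_low, "r_high": feats.r_high,
                "r_het": feats.r_het, "e_low": feats.e_low,
                "pc20_mg_ml": pc20, "pc20_censored": censored,
                "fev1_pct_pred": fev1, "latent_heterogeneity": latent,
            })
            if sink is not None:
                sink(sid, cond, image, recording, truth)
            if raw is not None:
                raw[(sid, cond)] = (image, recording, truth)
    return CohortResult(pd.DataFrame(rows), wf, raw)
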