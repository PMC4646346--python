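# Methods

This note documents the models, numerical choices and limitations of
`ventmech` in the spirit of a methods appendix. It states nothing the
test suite or `scripts/acceptance.py` do not themselves compute.

## Image quantification

The ventilated-airspace pipeline is: denoise → cluster intensities into
ordered classes → remove the trachea/major airways → estimate the
background noise level → bias-correct the remaining intensities →
normalize to ventilated volume fractions (VVF) → coefficient of
variation (CV). Every intermediate is retained on the result object.

**Coordinates.** Voxel indices are 0-based; axis 0 runs
superior→inferior within a coronal slice, axis 1 left→right, axis 2 is
the slice index. All computation is in index space; the NIfTI affine
only carries voxel spacing.

**Denoising.** Default: median filter of radius 1 applied *in-plane*
(3×3×1). Slices are an order of magnitude thicker (13 mm) than the
in-plane resolution, so a cubic 3×3×3 window mixes nearly uncorrelated
tissue; on phantoms it erodes the lung boundary (≈9 % of lung voxels
lost) and depresses the recovered CV by ≈0.06. The cubic window remains
available as `median3d`, and non-local means and `none` are options.

**Clustering.** One-dimensional k-means (scikit-learn) with k = 4
classes by default, seeded k-means++ initialization (seed 0), labels
re-indexed by ascending cluster mean so label 0 is always the
lowest-intensity (background) class. Images with fewer distinct values
than classes raise a degenerate-clustering error. Volumes above 2×10⁵
voxels are fit on a seeded subsample and predicted in full.

**Hole filling.** Background-class voxels fully enclosed in-slice by
labeled tissue are reassigned to the lowest ventilation class
(`fill_holes`, default on). Enclosed low-signal pockets are poorly
ventilated airspace, not air outside the body; excluding them would
censor exactly the voxels that carry the heterogeneity signal.

**Airway removal.** The gas-filled trachea is bright. Candidates are
labeled voxels above the 0.75 intensity quantile; connected components
touching a superior midline corridor (top 12 % of rows, central 14 % of
columns) are removed, dilated by one voxel, capped at 10 % of the
labeled volume. With lognormal parenchymal texture the single top
k-means class is the extreme texture tail rather than the airway, which
is why a quantile threshold rather than the top class defines the
candidate set. No candidate found is a warning, not an error; a manual
airway mask overrides the heuristic. On phantoms the heuristic removes
≥97 % of true airway voxels with no lung leakage.

**Background and bias correction.** The noise level S̄_BG is the mean
intensity over the eight grid-corner cubes (4 voxels a side by default),
assumed outside the body; an explicit mask overrides and must not touch
the ventilated mask. In-mask intensities are corrected as
Ŝ = √(S² − (2/π) S̄²_BG); this subtracts the Rayleigh-background power
(a Rayleigh field of scale σ has mean σ√(π/2), so (2/π) S̄²_BG
estimates σ²). A negative radicand is clamped to zero: intensities are
magnitudes, and rare sub-noise voxels should not abort a run. The
correction is applied only after segmentation, to the remaining
non-background voxels.

**VVF and CV.** VVF = Ŝ/ΣŜ over the ventilated mask (sums to 1 within
10⁻⁹ by construction); CV = σ_VVF/μ_VVF with the *population* SD over
all in-mask voxels of the volume, slices pooled. The sample-SD
convention is available via `sd_ddof=1`; the pooled-population choice is
ours — equivalently CV is the relative spread of corrected intensities,
which makes it invariant to any positive rescaling of the raw image
(the background estimate scales identically), a property the tests
verify.

## Waveform design and impedance estimation

**NSND selection.** Tones are integer multiples of a fundamental
(default 0.1 Hz). A set is NSND iff no member equals the sum or absolute
difference of any pair of members, pairs with repetition included (so
harmonics k+k are excluded). Selection is greedy from the smallest
admissible multiple upward, accepting a candidate iff the set stays
NSND and the candidate is ≥1.8× the previous acceptance (approximately
log-spaced). The default design lands on multiples (1, 3, 7, 13, 24,
44, 80): seven tones spanning exactly 0.1–8 Hz. Published tone sets can
be supplied directly to `ForcingWaveform`.

**Amplitudes and phases.** The default amplitude profile gives each
tone the same *volume* amplitude (flow amplitude ∝ frequency); an
equal-flow profile is available. Phases minimize the crest factor
(peak/RMS) of the integrated *volume* waveform — tidal-volume delivery
is the design goal — via a seeded multi-start Nelder–Mead search started
from zero phases, Schroeder quadratic phases and random draws; the
result never exceeds the zero-phase crest, and a flow-domain criterion
is available. Crest factors are evaluated over one fundamental period
on a grid of ≥64 samples per period of the highest tone. At synthesis
a single scale factor sets the peak-to-peak volume excursion to the
requested tidal volume (0.5 L default).

**Estimation.** Recordings must span an integer number of fundamental
periods with the sampling rate an integer multiple of the fundamental,
so every tone falls exactly on a discrete bin — a rectangular window is
then exact and no leakage correction is needed. The recording is cut
into single-period segments, complex Fourier coefficients of
P_tp = P_ao − P_es and Q_ao at each forcing bin are averaged across
segments (reducing broadband noise), and Z_L is their ratio. A flow
coefficient below a configurable floor (10⁻⁹ L/s) raises an
ill-conditioned-bin error naming the frequency. Features are read at
the tones nearest 0.1 and 8 Hz, warning when the match deviates by more
than 5 %; R_het = R_low − R_high exactly.

On noiseless simulated recordings the estimator recovers the
closed-form model impedance at all seven tones to ~10⁻¹³ relative
error; the contractual bound in the tests is 10⁻³.

## Parallel-compartment lung model

Z_b(ω) = R_b + j(ωI_b − E_b/ω) per branch;
Z_L = R_c + jωI_c + (Σ_b Z_b⁻¹)⁻¹. Branches with unequal time constants
R_b·C_b produce the Otis effect: resistance falls and apparent elastance
rises toward low frequency, the mechanical footprint of heterogeneous
constriction. Forward simulation builds P_tp tone-by-tone from the
closed form, routes all pressure signal through the esophageal channel
(P_es = −P_tp + noise, P_ao = independent noise) — only the difference
P_ao − P_es is contractual — and adds white Gaussian pressure noise,
the simplest measurement-noise model.

## Synthetic cohort

Each virtual subject carries a latent constriction-heterogeneity value
λ per condition:

* healthy baseline λ ~ N(0.10, 0.04), asthmatic N(0.35, 0.10) (clipped
  positive);
* the challenge adds N(0.42, 0.08) (healthy) or N(0.30, 0.08)
  (asthmatic) — the smaller asthmatic increment on a higher baseline
  reproduces the observed ordering of post-challenge CVs;
* five deep inspirations relax the increment by 90 % in healthy and
  50 % in asthmatic subjects (configurable), matching the qualitative
  observation that recovery is partial in asthma.

λ drives, scaled by the single `coupling` knob (default 1; 0 severs the
link): (i) the image target CV = 0.35 + 0.25·coupling·λ and the defect
count 2 + round(10·coupling·λ); and (ii) the dispersion of branch
resistances, lognormal with log-SD 1.8·coupling·λ. The resistance
multipliers are normalized to unit *harmonic* mean: dispersion then
widens the time-constant spread (raising R_low and E_low) without
collapsing the parallel high-frequency resistance — with unit
arithmetic mean, dispersion lowers both, which we measured and
rejected. Overall constriction scales mean branch resistance by
(1 + 3λ) and elastance by (1 + 0.8λ). With 8 branches, base branch
R = 14 cmH₂O/L/s and E = 56 cmH₂O/L, central R = 1, I = 0.01, the
healthy-baseline means land near R_low 3.3, R_high 3.2, E_low 7.6 —
a realistic adult operating point.

AHR: asthmatic log₁₀(PC20) = 1.6 − 4.0·λ_baseline + N(0, 0.3), clipped
to (0.05, 25] mg/mL, censored above the 25 mg/mL maximum dose; healthy
subjects are censored at 25 by definition. This yields PC20 values
spanning ~0.3–15 mg/mL and occasionally reproduces the
"one censored asthmatic" pattern.

**Phantom.** Two ellipsoidal lung fields (seeded 3 % geometric jitter)
plus a midline superior airway tube rendered at 1.8× the mean lung
signal; 48×32×8 grid at 3.6×3.6×13 mm by default. Ventilation truth is
baseline × lognormal texture (Gaussian field smoothed at 2.5 voxels,
standardized in-mask) × smooth spherical defects (Gaussian profile,
12 mm radius ≈ 2σ, intensity floor 0.3× baseline, centers in the eroded
lung interior). A single scale jointly deepens texture and defects and
is solved by bracketing so the realized in-lung population CV lands
within ±0.02 of the target (in practice ~10⁻⁶); unattainable targets
raise a convergence error naming the achieved CV. Rician noise is exact:
M = √((A+n₁)² + n₂²) with iid Gaussian n₁, n₂ (σ = 4 default against a
baseline of 100, i.e. SNR 25), giving a Rayleigh background whose mean
σ√(π/2) the corner-based background estimator recovers.

**What the generator does and does not emulate.** It reproduces the
magnitude-noise statistics, cm-scale patchy defects, the bright trachea,
the three-condition protocol structure and a controllable
image-mechanics coupling. It does not model k-space acquisition, coil
sensitivity, partial-volume boundaries, registration error between
conditions, breathing effort during forcing, or airway-tree anatomy
beyond parallel compartments. Passing recovery tests therefore show the
pipeline is correct and well-conditioned under these idealizations, not
that clinical CV values would be recovered with the same fidelity.

**Measurement bias.** The measured CV slightly underestimates the
generator truth (≈−0.02 at a true CV of 0.38, growing to ≈−0.05 at
0.6): segmentation censors the darkest defect cores and the median
filter attenuates fine texture. The bias is monotone — recovered CV
rises strictly with the target across presets — so ordering and
correlation analyses are unaffected; the acceptance suite bounds the
healthy-preset recovery error at ±0.05.

## Statistics

Pearson r with the two-tailed p from t = r√((n−2)/(1−r²)); paired and
unpaired (equal-variance) two-tailed Student's t-tests; post-hoc power
from the noncentral-t distribution at the observed standardized effect
(statsmodels), with the paired test treated as one-sample on the
differences. Zero-variance inputs raise degenerate-test /
undefined-correlation errors; in the condition summary a degenerate
contrast is surfaced as a per-variable note rather than aborting the
grid. No multiple-testing correction is applied, matching the
single-test α = 0.05, power ≥ 0.8 convention. Pooling for the
CV–mechanics correlations treats every subject-condition row as an
independent point (a repeated-measures caveat: rows within a subject
are correlated, so pooled p-values are anticonservative). The PC20
correlation uses the linear mg/mL scale by default with a log₁₀ option;
subjects censored at the maximum dose are excluded before correlating.

## Problem sizes and determinism

Default test/acceptance problem sizes — 48×32×8 phantoms, 40-subject
cohorts (120 subject-condition rows), 40-s recordings at 40 Hz
(4 fundamental periods), 10⁴–10⁵ Monte-Carlo replicates — were chosen
so the whole suite runs in about a minute on one CPU while leaving
Monte-Carlo error well inside every asserted tolerance. All randomness
flows through seeded `numpy` generators; cohorts, phantoms, recordings
and the full protocol are byte-reproducible for a fixed seed, and the
protocol manifest records the config hash and seed needed to re-run.

## Known limitations

* The exact published tone sets, amplitude profiles and
  phase-optimization criteria of the original ventilation-waveform
  hardware are not restated here; the defaults are declared design
  choices, and overrides are accepted via configuration.
* The airway-removal heuristic is tuned to the phantom geometry class
  (superior midline trachea); real data may need the manual-mask path.
* Esophageal-balloon artifacts, breathing-effort rejection beyond
  segment averaging, and constant-phase tissue models are out of scope.
* CV conventions (population vs sample SD, pooled vs per-slice) change
  the third decimal on realistic volumes; both are exposed because the
  convention used for the published values is not stated.
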