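# Methods

This note documents the models, defaults and numerical choices behind
`tiltnirs`, and what the synthetic-data results do and do not demonstrate
about real recordings.

## Protocol and task model

A session is four consecutive tilt segments — 0°, −10°, −20°, back to 0°
("pre0", "m10", "m20", "post0") — of 20 min each (80 min total). The task
window begins 900 s into each segment and lasts 280 s: four blocks, each a
10 s countdown plus 20 trials at a 3 s pitch (2 s stimulus, 1 s
inter-stimulus interval), i.e. 60 s of trials per block.

Stimuli are two-operand sums/differences of multiples of 10 with operands
in 10..90; by default results are also restricted to 10..90 so that every
result can recur as an n-back target and no stimulus has an implausible
negative answer (configurable). Correct answers: control — any press;
0-back — yes iff the result equals 50, read as an equality match to keep
the four conditions on one match/non-match logic; 1-/2-back — yes iff the
result equals the result 1/2 trials back. The first n trials of an n-back
block are unscoreable, leaving 20/20/19/18 scoreable trials.

Target prevalence is not left to chance: the generator first draws
match/non-match (p = 0.5) for each scoreable trial, then samples operands
realising it. This keeps yes-rates at 50% for every level, so accuracy is
comparable across levels and a guessing responder scores 0.5.

Counterbalancing uses a cyclic Latin square: participant p at tilt t runs
block order rotation (p + t) mod 4 of (control, 0back, 1back, 2back). All
four conditions are counterbalanced together rather than pinning the
control block to a fixed slot; across any four consecutive participants
every order occupies every tilt position exactly once.

Scoring: accuracy is n_correct / n_scoreable; missing responses are
incorrect and contribute no latency; mean RT averages correct responses
only.

## Forward signal model

Activation: each block contributes a boxcar over its 60 s trial window
(countdown excluded), convolved with a canonical double-gamma HRF (gamma
shapes 6 and 16, scale 1 s, undershoot ratio 1:6; peak ≈ 5 s). The kernel
is normalised to unit integral, so a sustained block at programmed
amplitude a plateaus at a µmol/L — amplitudes are steady-state
concentration changes, which makes them a well-defined recovery target.

Default amplitudes (µmol/L): ΔHbO 0.05/0.20/0.35/0.50 and ΔHbR
−0.02/−0.07/−0.12/−0.17 for control/0/1/2-back. The monotone ordering
encodes the expected load gradient (prefrontal HbO rises, HbR falls with
working-memory load); the magnitudes are plausible values for prefrontal
block designs, chosen once — the source study reports its concentration
figures in uncalibrated relative units, so no literal magnitudes exist to
copy.

Tilt drift: per-segment plateau offsets (default 0 / 1.5 / 3.0 / 0.5
µmol/L on HbO; HbR follows at ratio 0.5, both signs positive as a
volume-shift proxy). Transitions are causal cosine smoothsteps starting at
each tilt boundary and completing in 120 s: the hemodynamic consequence of
a posture change follows the change, and a transition centred on the
boundary would leak into the preceding tilt's final task block. Drift
magnitudes are scenario parameters, not literature values; the headline
invariance result is independent of their choice, which the tests verify
by varying them arbitrarily.

Nuisance: sinusoidal physiological components (cardiac 1.1 Hz at 0.10 µM,
respiratory 0.25 Hz at 0.10 µM, Mayer 0.10 Hz at 0.15 µM; session-random
phases shared across channels, HbR carries −0.4 of the HbO oscillation),
white noise of SD 0.20 µM (HbR 0.10 µM) correlated ρ = 0.3 between the two
channels, and a lognormal per-subject amplitude gain (σ = 0.2, mean exactly
1) for inter-individual variability. Config validation warns when an
oscillation is programmed at or above Nyquist (5 Hz at the default
10 Hz sampling). Optional artifacts: one-sample spikes and sustained
baseline jumps, off by default.

Optics: intensities follow the exact MBLL forward model
I(λ,t) = I_ref·10^(−[ε(λ,HbO)ΔHbO + ε(λ,HbR)ΔHbR]·d·DPF) at 660/860 nm,
d = 2 cm, DPF = 6.06 at both wavelengths. Extinction coefficients are the
standard compiled hemoglobin values (Prahl, OMLC): ε(660) = 319.6 (HbO) /
3226.56 (HbR), ε(860) = 1058.0 / 694.32, in 1/(M·cm); the µM/cm unit
bridge lives in exactly one place (`OpticalGeometry.mbll_matrix`).

## Processing chain

OD uses log base 10 (the optical-density convention; forward and inverse
share the base, so results are base-consistent regardless). I₀ is the mean
of the whole recording per channel × wavelength — tilt correction is
carried by baseline subtraction, deliberately not by I₀ choice.
Non-positive samples are imputed from the nearest positive neighbour before
the log and logged as QC events.

The moving average (50 samples = 5 s at 10 Hz) is centred with shrinking
edge windows; a trailing window would delay the HRF by 2.5 s and bias block
means toward the transient. For the even default width the centre sits half
a sample late (24 before, 25 after), the closest centred placement.

Baseline: within each tilt, the mean over the 10 s (100 samples)
immediately preceding the first countdown of that tilt's task is subtracted
from the whole segment, per channel and chromophore. One window per tilt
(not per block): later blocks inherit the same reference, so the correction
removes segment-constant shifts without touching between-block dynamics.

Block averages are means over each block's 60 s trial window (countdown
excluded), then averaged over QC-surviving channels. QC excludes a channel
when any criterion fires — saturation (>10% of raw samples at the channel
maximum, emulating A/D clipping), high-frequency residual (SD of raw minus
smoothed ΔHbO > 1.0 µM), or motion jumps (>3 sample-to-sample steps above
5 µM); a participant is excluded when both channels fail. "Excessively
noisy" has no standard definition, so all thresholds are explicit config
and every exclusion is logged. On perfectly noise-free synthetic data the
saturation rule can misfire (a flat signal sits at its own maximum); such
scenarios should disable it, as the tests do.

Because every stage from concentration to block average is linear,
(i) scaling programmed amplitudes scales block averages identically,
(ii) any per-tilt constant shift cancels exactly in baseline subtraction.
Point (ii) is the computational form of the claim that short-term tilt does
not bias task-evoked measures; it holds analytically, and numerically to
~1e−12 µM (IEEE arithmetic prevents literal bit-identity).

## Amplitude recovery

Block averages are linear in the programmed amplitudes, but not equal to
them: the HRF plateau is incomplete early in a block, undershoot tails
leak into following blocks, and smoothing redistributes signal. Recovery
therefore inverts the chain's linear response: for each distinct block
order, the unit-amplitude response of each level is pushed through the
identical noise-free chain, giving a per-tilt 4×4 gain matrix M with
M[i, j] = measured average at block i from unit amplitude on level j;
solving M a = b for the measured averages b returns estimates on the
programmed scale. Gain matrices are cached per block-order signature (the
Latin square produces only four). Recovery is exact in the noise-free limit
and unbiased at the default noise (worst per-level bias ≈ 1% over 200
simulated participants); in small cohorts the recovered amplitudes share
the cohort's mean subject gain, a sampling effect rather than bias.

## Statistics

The rm-ANOVA is the classical univariate within-subject decomposition
(subject, A, A×S, B, B×S, A×B, A×B×S), each effect tested against its own
subject-interaction error; partial η² = SS_effect/(SS_effect+SS_error).
Greenhouse–Geisser ε is Box's estimate from the covariance of the effect's
orthonormalised contrast scores (Kronecker contrasts for the interaction,
matching R `car`/SPSS/JASP), clamped to [1/df, 1]; ε = 1 exactly for
two-level factors. Correction is applied whenever ε < 1 — "when necessary"
is read as ε-based rather than gated on a preliminary sphericity test,
and both corrected and uncorrected p-values are reported. Degenerate
inputs: all-equal data gives F = 0; a zero error term gives F = ∞;
rank-deficient contrast covariance pins ε at its lower bound.

Post hocs are paired t-tests on subject-level marginal means with Holm
correction (uniformly more powerful than Bonferroni, no sphericity
assumption; method selectable). Identical columns return p = 1 rather than
NaN. Subjects with missing cells are dropped listwise and reported.

The study driver analyses the four dependent variables of the design —
accuracy (n-back levels only), mean correct RT with and without the
control condition, and ΔHbO/ΔHbR block averages (all four conditions) —
each as condition × tilt.

## Problem sizes and reproducibility

All randomness flows from integer seeds through `numpy` SeedSequence
spawning; fixed seeds give bit-identical sessions, reports and JSON.
Monte-Carlo suites use sizes chosen for single-core desk runs: type-I
calibration uses 1000 null 18-subject tables; recovery validation uses 200
simulated participants (10 cohorts × 20 for ordering checks plus pooled
bias); detection-rate checks use replicate cohorts of 18, where the default
effect sizes put power near 1 so small replicate counts already bind.

## What the synthetic results do not show

The generator emulates the measurement geometry, timing and noise structure
of a tilt-table session, not its biophysics: no layered-tissue photon
transport or partial pathlength effects, no systemic blood-pressure
response to tilt, no motion/sweat/grimace artifact morphology beyond
idealised spikes and jumps, sinusoidal (not bandpass-stochastic)
physiological rhythms, and drift that is constant per tilt after a smooth
transition. Passing tests therefore demonstrate the correctness and
invariances of the *pipeline* under controlled conditions — they do not
certify that real tilt sessions contain no nonlinear interaction between
fluid shift and task-evoked hemodynamics, which is an empirical question
for real data. Real concentration estimates also carry unknown absolute
scale (fixed DPF, unknown partial volume), which is why analyses here, as
in practice, rest on within-subject changes rather than absolute values.
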