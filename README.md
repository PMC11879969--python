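# tiltnirs

A tested Python pipeline for studying whether head-down tilt (HDT) — the
standard ground-based analog of microgravity fluid shift — biases fNIRS
measures of cognitive load. It is aimed at researchers who run (or plan)
tilt-table or spaceflight-analog experiments with simple continuous-wave
NIRS hardware and want a fully controllable, ground-truth-driven testbed for
their task, signal-processing, and statistics chain.

The package covers four layers:

1. **Task engine** — the Toulouse N-back Task: n-back match judgements on
   the results of two-operand arithmetic over multiples of 10 (`10 + 40`,
   `90 − 30`). Four conditions (control reaction task, 0-, 1-, 2-back),
   20 trials of 2 s + 1 s ISI per block, 10 s countdowns, four-block task
   windows placed at the end of each of four 20-min tilt segments
   (0°, −10°, −20°, 0°), counterbalanced by a Latin square across tilts and
   participants. Scoring uses only the scoreable trials (20/20/19/18 for
   control/0/1/2-back).

2. **Synthetic-data generator** — a forward model of a full 80-min session
   with known ground truth: block-design activation (boxcar ⊗ double-gamma
   HRF) whose ΔHbO rises and ΔHbR falls with n-back level, tilt-dependent
   slow baseline shifts, physiological oscillations (cardiac ≈1.1 Hz,
   respiratory ≈0.25 Hz, Mayer ≈0.1 Hz), white sensor noise, optional
   motion artifacts, and behavioural responses that degrade with difficulty.
   Raw two-channel, dual-wavelength (660/860 nm) intensities are produced by
   the exact modified Beer–Lambert forward model.

3. **Processing chain** — optical density `OD = −log₁₀(I/I₀)` with `I₀` the
   whole-recording mean; MBLL inversion
   `[ΔHbO; ΔHbR] = (E·d·DPF)⁻¹ [OD₆₆₀; OD₈₆₀]` with a 20 mm separation and
   DPF 6.06; a centred 50-sample moving average; per-tilt baseline
   subtraction over the 10 s preceding each task window; 60-s block averages
   per condition; channel QC and averaging.

4. **Statistics** — two-way repeated-measures ANOVA (condition × tilt) with
   Greenhouse–Geisser correction, partial η², and Holm-corrected paired
   post hocs, in a statsmodels-style Model/Results interface.

Because every stage of the chain is linear, a constant per-tilt baseline
shift — the fluid-shift confound — cancels exactly in the baseline
subtraction. The package states this claim computationally and verifies it
end to end against programmed ground truth.

## Worked example

```python
from tiltnirs import StudyConfig
from tiltnirs.study import simulate_cohort, recover_amplitudes, recovery_summary
from tiltnirs.anova import rm_anova

cfg = StudyConfig(n_participants=12, seed=7)
blocks, behavior, designs, truths, qc = simulate_cohort(cfg)

print(behavior.groupby("level")[["accuracy", "mean_correct_rt"]].mean().round(3))
```

```
         accuracy  mean_correct_rt
level
0back       0.976            0.857
1back       0.921            1.091
2back       0.782            1.219
control     0.989            0.453
```

Accuracy falls and reaction time rises with n-back level, as programmed.
The fNIRS block averages show the same gradient, and the tilt factor shows
nothing:

```python
res = rm_anova(blocks.rename(columns={"hbo_uM": "value"}),
               dv="value", within=("level", "tilt"), subject="participant")
print(res.summary())
```

```
Two-way repeated-measures ANOVA
  n subjects: 12;  level: 4 levels;  tilt: 4 levels
  Greenhouse-Geisser correction applied whenever epsilon < 1

effect                   F          df     eps     p(GG)   pEta2
level              207.346      (3,33)   0.335    0.0000   0.950
tilt                 0.295      (3,33)   0.903    0.8093   0.026
level:tilt           1.262      (9,99)   0.545    0.2940   0.103
```

The task-condition main effect is large (partial η² = 0.95) while the HDT
angle has no effect (p = 0.81) — the signal the pipeline is built to
detect, and the invariance it is built to guarantee. Amplitude recovery
against ground truth:

```python
print(recovery_summary(recover_amplitudes(blocks, designs, cfg), cfg).round(3))
```

```
  level chromophore  programmed_uM  recovered_uM  bias_uM  bias_pct
control         hbo           0.05         0.041   -0.009   -17.736
  0back         hbo           0.20         0.174   -0.026   -12.910
  1back         hbo           0.35         0.310   -0.040   -11.311
  2back         hbo           0.50         0.444   -0.056   -11.207
  ...
```

The common ≈ −11% offset across levels is this 12-person cohort's mean
per-subject amplitude gain (subjects vary lognormally around 1), not a
pipeline bias: over 200 simulated participants the worst per-level bias is
about 1%, and in noise-free runs recovery is exact to numerical precision.

A command-line interface wraps the same functionality
(`tiltnirs generate/score/simulate/process/analyze/study`); see
`tiltnirs --help`.

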