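# alphashutter

Analysis pipeline for testing whether the phase of the posterior EEG alpha
rhythm, read at each individual's retina-to-V1 conduction delay, predicts the
observation of near-threshold visual flashes — together with a synthetic-EEG
generator that embeds a known gating effect so every stage can be validated
by parameter recovery.

## The scientific problem

The ~10 Hz occipital alpha rhythm is hypothesized to reflect cycling
excitability of the visual thalamus: during the inhibitory half of each
cycle, weak stimuli are less likely to be relayed to primary visual cortex
(a "shutter"). Testing this cleanly requires referencing the phase
measurement not to stimulus onset `t0` but to the moment the afferent volley
reaches V1, `t2 = t0 + conduction delay`, which differs between individuals.

The pipeline implements that design end to end:

1. **Conduction delay (t2).** Upper- and lower-visual-field checkerboards
   evoke C1 visual-evoked potentials of opposite polarity at POz. After
   mastoid re-referencing, a zero-phase 0.01–50 Hz Butterworth band-pass,
   epoching (−50 to 200 ms) and blink rejection (150 ms windows, 75 ms
   steps, ≥100 µV peak-to-peak on the vertical EOG), the difference wave
   (upper − lower) is averaged and the latency of its most negative sample
   in 0–110 ms is the individual's `t2`.
2. **Phase/amplitude at t2.** Flash-task EEG is down-sampled to 512 Hz,
   re-referenced, band-passed identically, pooled into left (O1, PO3, PO7)
   and right (O2, PO4, PO8) occipital signals, and convolved with a 10 Hz
   complex Morlet wavelet (2⅔ cycles, σ_t = n_c/(2πf₀) = 42.44 ms). Phase is
   reported with 90° = alpha peak and 270° = trough; peak-to-peak amplitude
   is `2√power`. Each flash trial is read at `t0 + t2`; trials whose
   hemispheric phases differ by more than 90° are rejected, the rest get a
   combined (circular-mean) phase and (arithmetic-mean) amplitude.
3. **ΔOR statistic.** Retained trials are median-split by amplitude and
   grouped into 90° phase bins centered on 0°, 90°, 180°, 270°. Each bin's
   observation rate (OR, % of flashes reported seen) minus the overall OR is
   ΔOR. Rotating the bin in 1° steps gives a 360-point ΔOR profile whose
   center-of-mass direction is the *preferred phase*; the ΔOR difference
   between preferred and opposite (pessimal) directions is the preferred
   phase effect (PPE). For a cosine-shaped profile, PPE = 4 × the
   center-of-mass magnitude.
4. **Statistics.** A 2 (amplitude) × 4 (phase) within-subjects ANOVA with
   Mauchly sphericity tests, partial η² = F·df₁/(F·df₁+df₂), observed power
   from a noncentral F with λ = F·df₁, Tukey HSD over phase bins within each
   amplitude level, Bonferroni-corrected one-sample t tests of each cell
   against zero, and t-based cartesian confidence intervals on the group
   preferred-phase vector.

## Worked example

```python
import numpy as np
import alphashutter as ash

# one synthetic participant: gating embedded at the alpha trough (270 deg)
cfg = ash.ShutterConfig(seed=1, n_trials=160, true_t2=75.0,
                        true_preferred_phase=270.0, gating_depth=0.15)
rec, events, truth = ash.gen_shutter_recording(cfg)

lo, ro = ash.compute_analytic(rec, ash.AnalysisParams())
analysis = ash.analyze_trials(lo, ro, events, t_measure_ms=75.0)

for level in ("high", "low"):
    p = analysis.preferred[level]
    print(f"{level}: preferred {p.angle_deg:.1f} deg, PPE {p.ppe:.1f}%")
print(f"overall OR {analysis.grid.overall_or:.1f}%")
```

Output:

```
high: preferred 282.1 deg, PPE 25.6%
low: preferred 246.3 deg, PPE 29.1%
overall OR 57.5%
```

The high-amplitude preferred phase lands near the embedded trough (282.1°
vs the true 270°); the PPE says flashes at the preferred phase were
observed ~26 percentage points more often than at the opposite phase. A
single participant is noisy — at the 20-participant cohort scale the group
preferred phase recovers 270° within a few degrees, the high-amplitude
group PPE clearly exceeds the low-amplitude one, and the phase × amplitude
interaction becomes significant (see `tests/test_acceptance.py`).

The same analysis runs from the shell:

```bash
alphashutter run --seed 1 --outdir out/       # simulate -> c1 -> analyze -> stats
alphashutter analyze --outdir out/ --measure-time -100   # prestimulus control
```

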