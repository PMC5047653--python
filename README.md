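# shoalresp

Intermittent-flow respirometry analysis of the **calming effect** — the
reduction in an individual's metabolic rate when conspecific (shoal-mate)
cues are present — in small gregarious fishes, plus body-condition
tracking over a social-isolation holding period.

The package takes time-stamped dissolved-oxygen traces from a
dual-chamber respirometer (a sealed inner chamber holding the focal fish,
an outer chamber holding shoal-mates that provide visual and olfactory
cues) through the full analysis chain:

1. **Slope extraction** — each 9-min sealed measurement period yields one
   OLS slope of [O2] vs time (first/last minute excluded), converted to
   whole-animal uptake *Ṁ*O₂ = −s·V_eff (mg O₂ h⁻¹), with an r² > 0.97
   quality gate.
2. **Background correction** — bacterial respiration fitted from
   empty-chamber runs before and after the trial, interpolated linearly
   in time and subtracted.
3. **Metabolic summaries** — MR_min (mean of the lowest decile of
   per-period *Ṁ*O₂, the standard-metabolic-rate proxy), RMR (mean after
   a 5 h settling exclusion), ISR (first post-transfer rate minus MR_min)
   and a stabilization-time detector.
4. **Body condition & allometry** — Fulton's K = 100·M/L³ trajectories,
   and mass correction of metabolic rates via log-log residuals carried
   to a reference mass.
5. **Inference** — a self-contained paired sign-flip permutation test
   (exact for n ≤ 12) reporting the mean per-fish percent reduction, and
   a conventional linear mixed model (random intercept per individual,
   mass covariate) via statsmodels.

Because raw trials of this kind are rarely archived, the package ships a
fully seeded **simulator** of the whole measurement chain (closed-form
oxygen mass balance, optode noise, handling-stress decay, background
drift, per-fish treatment effects) with ground-truth records, so every
pipeline stage is testable by parameter recovery. See `docs/methods.md`
for the model and all defaults.

## Worked example

```python
import shoalresp as sr

chamber = sr.ChamberSpec()                      # 0.100 L, 9 min / 3 min cycle
config  = sr.SimulationConfig(seed=1)
fish    = sr.FishRecord("f1", mass_g=1.84, length_cm=3.69)

trace, truth = sr.simulate_trial(chamber, fish, "solitary", config)
pre  = sr.simulate_background_trial(chamber, config, "pre")
post = sr.simulate_background_trial(chamber, config, "post")
slopes  = sr.process_trial(trace, pre, post, chamber, fish.mass_g)
summary = sr.summarize_trial(slopes, "f1", "solitary")
```

which prints, via `examples/03_metabolic_summary.py`:

```
solitary testing: MR_min = 0.341, RMR = 0.359, ISR = 0.253 mg O2/h; stabilised at 4.7 h (true floor 0.350 mg O2/h)
   shoal testing: MR_min = 0.210, RMR = 0.228, ISR = 0.246 mg O2/h; stabilised at 4.7 h (true floor 0.217 mg O2/h)
```

MR_min is the low-decile minimum-metabolism estimate: this fish's
minimum rate drops from 0.341 to 0.210 mg O₂ h⁻¹ when shoal-mates are
visible and smellable — the calming effect. RMR sits just above MR_min
(routine activity), ISR ≈ 0.25 mg O₂ h⁻¹ is the handling-stress
elevation on arrival, and both trials settle in under 5 h. At cohort
scale (`examples/04_treatment_comparison.py`, 16 fish, seed 1):

```
MR_min: solitary 0.347 +- 0.005 vs shoal 0.266 +- 0.011 mg O2/h (n = 16 pairs)
mean per-fish reduction: 23.3% (truth: 23.1%)
paired sign-flip permutation p = 0.00010 (Monte-Carlo)
```

The `examples/` scripts cover each capability: cohort simulation, trial
processing, metabolic summaries, and treatment comparison with condition
trajectories.

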