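"""Per-trial metabolic phenotype: MR_min, RMR, ISR and stabilization time.

MR_min (mean of the lowest decile of per-period MO2) proxies standard
metabolic rate; RMR is the mean after the first 5 h of settling; ISR is
the first post-transfer rate minus MR_min, indexing the handling-stress
response.
"""

import shoalresp as sr

chamber = sr.ChamberSpec()
config = sr.SimulationConfig(seed=1)
fish = sr.FishRecord("f1", mass_g=1.84, length_cm=3.69)

for condition in ("solitary", "shoal"):
    trace, truth = sr.simulate_trial(chamber, fish, condition, config)
    pre = sr.simulate_background_trial(chamber, config, "pre")
    post = sr.simulate_background_trial(chamber, config, "post")
    slopes = sr.process_trial(trace, pre, post, chamber, fish.mass_g)
    s = sr.summarize_trial(slopes, fish.fish_id, condition)
    print(f"{condition:>8} testing: MR_min = {s.mr_min:.3f}, "
          f"RMR = {s.rmr:.3f}, ISR = {s.isr:.3f} mg O2/h; "
          f"stabilised at {s.stabilization_time_h:.1f} h "
          f"(true floor {truth.floor(condition):.3f} mg O2/h)")

print("\nThe shoal-testing MR_min sits below the solitary one: the calming "
      "effect of shoal-mate visual and olfactory cues on minimum metabolism.")
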