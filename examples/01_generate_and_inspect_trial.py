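"""Generate one synthetic stepping trial and inspect its ground truth.

A trial is a pair of synchronized streams - dual force plates at
1,000 Hz and 14 lower-body markers at 100 Hz - plus metadata. The
generator embeds the event times a perfect detector should find.
"""

import numpy as np

import apastep as ap

cfg = ap.GeneratorConfig(seed=7)
participant = ap.gen_participants(cfg, np.random.default_rng(7))[0]
print(f"participant {participant.participant}: theta = {participant.theta_k:.3f}, "
      f"single means {participant.mu_sl_mm:.1f} / {participant.mu_sm_mm:.1f} mm")

trial = ap.gen_timeseries_trial(participant, "dual-medial", seed=42, config=cfg)
print(f"plate stream: {len(trial.plate)} samples at 1 kHz, "
      f"markers: {len(trial.markers)} samples at 100 Hz")
print(f"go cue at {trial.meta.go_time_s:.3f} s, body weight {trial.meta.body_weight_n:.0f} N")

truth = trial.meta.sim["truth"]
print("\nground-truth events (s):")
for key in ("onset_time_s", "lateral_peak_time_s", "posterior_peak_time_s",
            "foot_off_time_s", "foot_contact_time_s"):
    print(f"  {key:24s} {truth[key]:.3f}")
print(f"ground-truth lateral displacement: {truth['lateral_disp_mm']:.1f} mm "
      f"(template amplitude {truth['amp_lateral_mm']:.1f} mm)")
# The small deficit vs the amplitude is the sub-millimeter tail the
# 0.05 m/s onset threshold cuts off before the rule can fire.
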