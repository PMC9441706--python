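"""Run the detection pipeline on one trial and compare with truth.

The detectors work on filtered signals only: 20 Hz zero-phase
Butterworth for plates, 4 Hz for markers, then the global COP, its
velocity, and the textual event rules.
"""

import numpy as np

import apastep as ap

cfg = ap.GeneratorConfig(seed=7)
participant = ap.gen_participants(cfg, np.random.default_rng(7))[0]
trial = ap.gen_timeseries_trial(participant, "single-medial", seed=11, config=cfg)

events = ap.detect_events(trial)
margins = ap.stability_margins(trial, events.foot_contact_time_s)
truth = trial.meta.sim["truth"]

print(f"{'event':24s} {'detected':>9s} {'truth':>9s}")
for key, det in [
    ("onset_time_s", events.onset_time_s),
    ("lateral_peak_time_s", events.lateral_peak_time_s),
    ("posterior_peak_time_s", events.posterior_peak_time_s),
    ("foot_off_time_s", events.foot_off_time_s),
    ("foot_contact_time_s", events.foot_contact_time_s),
]:
    print(f"{key:24s} {det:9.3f} {truth[key]:9.3f}")
print(f"\nlateral displacement  {events.lateral_disp_mm:6.1f} mm "
      f"(truth {truth['lateral_disp_mm']:.1f})")
print(f"posterior displacement {events.posterior_disp_mm:5.1f} mm "
      f"(truth {truth['posterior_disp_mm']:.1f})")
print(f"movement time          {events.movement_time_s:5.3f} s")
print(f"MOS_ML {margins.mos_ml_mm:6.1f} mm, MOS_AP {margins.mos_ap_mm:6.1f} mm "
      f"(positive = XCOM inside the base of support)")
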