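"""Inject each trial-failure mode and watch its exclusion rule fire.

Five failure modes mirror the exclusion criteria: uneven baseline
stance, COP onset before the go cue, an initial shift toward the
stance side, target reveal before the initial COP peaks, and multiple
steps to stop.
"""

import numpy as np

import apastep as ap
from apastep.pipeline import PipelineConfig, process_trial

cfg = ap.GeneratorConfig(seed=7)
participant = ap.gen_participants(cfg, np.random.default_rng(7))[1]
pc = PipelineConfig(generator=cfg)

pairs = [
    ("uneven_stance", "single-center"),
    ("early_onset", "dual-medial"),
    ("abnormal_initial_direction", "dual-lateral"),
    ("late_peak_reveal", "dual-medial"),
    ("multiple_steps", "single-lateral"),
]
clean = ap.gen_timeseries_trial(participant, "dual-medial", seed=3, config=cfg)
_, verdict, _ = process_trial(clean, pc)
print(f"{'injected mode':30s} {'rules fired'}")
print(f"{'(none - clean trial)':30s} {verdict.failed_rules or 'valid'}")
for mode, condition in pairs:
    trial = ap.gen_timeseries_trial(participant, condition, seed=3, config=cfg)
    bad = ap.inject_failure(trial, mode)
    _, verdict, _ = process_trial(bad, pc)
    print(f"{mode:30s} {verdict.failed_rules}")
# Each mode trips exactly the rule built to catch it - the confusion
# matrix of injected mode vs fired rule is diagonal.
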