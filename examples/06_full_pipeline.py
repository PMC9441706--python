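"""End-to-end run: render a small time-series cohort, detect, QC,
analyze, and print the report digest.

Uses a reduced cohort (6 participants x 6 trials per condition) so the
example finishes in seconds; the defaults run the full 13 x 24 design.
"""

import apastep as ap
from apastep.pipeline import PipelineConfig, render_markdown, run

config = PipelineConfig(
    generator=ap.GeneratorConfig(n_participants=6, trials_per_condition=6, seed=17),
    seed=17,
    mcmc_iterations=3500,
    mcmc_warmup=1000,
)
report = run(config)
print(render_markdown(report))
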