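"""Recover a known interviewer effect end to end.

Simulates replicate cohorts with a 5-point telephone shift and no
selection bias, runs score -> match -> compare on each, and summarises
how well the matched estimate recovers the injected shift.
"""

import warnings

from sf36mode import SimulationConfig, recovery_experiment
from sf36mode.scoring import SCALE_ORDER

cfg = SimulationConfig.default().with_(
    response_coefficients={},
    response_targets={"internet": 0.292, "telephone": 0.75},
    latent_loadings={},
    latent_means={s: 55.0 for s in SCALE_ORDER},
    latent_sds={s: 18.0 for s in SCALE_ORDER},
    interviewer_effect={s: 5.0 for s in SCALE_ORDER},
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = recovery_experiment(cfg, n_replicates=10, seed=5)

summary = table.groupby("scale")[["unmatched_estimate", "matched_estimate"]].mean()
print("injected telephone shift: 5.0 points on every scale (10 replicates)")
print(summary.round(2))
print("both estimates should hover around 5; with no selection bias the")
print("matched and unmatched estimates agree, the study's key diagnostic.")
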