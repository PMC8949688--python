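"""Score SF-36 questionnaires: 8 scales plus the two component summaries.

Builds a tiny simulated cohort, scores every responder, and prints one
respondent's profile.  Scale scores live on 0-100 (higher = better
health); PCS/MCS are norm-based (general-population mean 50, SD 10).
"""

from sf36mode import ScoringSpec, SimulationConfig, score_cohort, simulate_cohort

cohort = simulate_cohort(SimulationConfig.default().with_(n_per_arm=50), seed=1)
responders = cohort[cohort["responder"] == 1].set_index("id")
scored = score_cohort(responders, ScoringSpec.default())

first = scored.iloc[0]
print(f"scored {len(scored)} responders; respondent {scored.index[0]}:")
for s in ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH"):
    print(f"  {s}: {first[s]:6.2f}  ({int(first[f'n_answered_{s}'])} items answered)")
print(f"  PCS: {first['PCS']:.2f}   MCS: {first['MCS']:.2f}")
print("scale scores are 0-100 sums of calibrated answers; a scale is only")
print("valid when at least half of its items were answered (missing items")
print("are imputed with the respondent's mean over the answered ones).")
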