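"""Internal-consistency gate: Cronbach's alpha per scale and per arm.

A scale is conventionally acceptable when alpha > .7; the report flags
anything at or below that threshold.
"""

from sf36mode import SimulationConfig, reliability_report, simulate_cohort

cohort = simulate_cohort(SimulationConfig.default(), seed=2)
responders = cohort[cohort["responder"] == 1]
report = reliability_report(responders, group_col="arm")

for _, row in report[report["group"] == "pooled"].iterrows():
    flag = "" if row["acceptable"] else "   <-- below the .7 gate"
    print(f"{row['scale']}: alpha = {row['alpha']:.3f} "
          f"(k={row['k']} items, n={row['n']} complete cases){flag}")
print("alpha near 1 means the items of a scale move together across")
print("respondents; coarse two-level items (role scales) sit lower.")
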