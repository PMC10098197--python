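"""Classify dosing adequacy per substance against the 0.8-1.2 band.

The used daily dose (UDD, what farms actually gave per kg per day)
divided by the defined daily dose (DDD_kg, the labelled reference) says
whether a substance was under-, correctly, or over-dosed. Ratios within
[0.8, 1.2] count as correct.
"""

from amuquant import dosing_classification
from amuquant.reference import reference_dataset

ref = reference_dataset()

print(f"{'substance':28s} {'UDD/DDD':>8s}  verdict")
for _, row in ref.dose_table.iterrows():
    ratio, verdict = dosing_classification(row["dose_ratio"], 1.0)
    print(f"{row['substance']:28s} {ratio:8.2f}  {verdict.value}")

verdicts = [
    dosing_classification(r, 1.0)[1].value
    for r in ref.dose_table["dose_ratio"]
]
print("\nSummary:",
      {v: verdicts.count(v) for v in ("UNDER", "CORRECT", "OVER")})
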