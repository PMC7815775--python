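"""Convert survey-meter exposure rates to annual dose and stratify subjects.

Occupancy-weighted rates are converted with the 0.0767 uR/h -> mGy/y
factor; group I is < 1.5 mGy/y (NLNRA), groups II-IV are HLNRA strata.
"""

from common import CONFIG, RUN_DIR
from radprot import pipeline

dose = pipeline.stage_dosimetry(CONFIG, RUN_DIR)
counts = dose["group"].value_counts().sort_index()
print(f"{len(dose)} subjects; dose range "
      f"{dose['annual_dose'].min():.2f}-{dose['annual_dose'].max():.2f} mGy/y")
for group, n in counts.items():
    print(f"  group {group}: {n} subjects")
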