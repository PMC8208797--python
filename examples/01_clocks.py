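"""Score a small cohort with both biological-age clocks.

Builds a three-person cohort with typical mid-life blood chemistry,
computes the Gompertz-mortality PhenoAge (via the 10-year mortality
risk) and the Klemera-Doubal BioAge, and prints the per-person results.
"""

import pandas as pd

import bioage as ba

people = pd.DataFrame(
    {
        "age": [45.0, 60.0, 60.0],
        "sex": ["female", "female", "male"],
        "albumin": [47.0, 45.2, 43.0],          # g/L
        "creatinine": [70.0, 72.0, 95.0],       # umol/L
        "glucose": [4.8, 5.2, 6.1],             # mmol/L
        "crp": [0.15, 0.42, 0.80],              # mg/dL
        "lymphocyte_pct": [33.0, 31.0, 28.0],
        "mcv": [89.0, 90.4, 92.0],              # fL
        "rdw": [12.9, 13.3, 14.1],              # %
        "alkaline_phosphatase": [62.0, 71.0, 88.0],  # U/L
        "wbc": [5.9, 6.8, 7.9],                 # 10^3 cells/uL
    },
    index=pd.Index(["anna", "beth", "carl"], name="id"),
)
cohort = ba.CohortTable(data=people, biomarkers=list(people.columns[2:]))

params = ba.GompertzClockParams.nhanes3()
result = ba.phenoage(cohort, params)
result["phenoage_accel"] = ba.residual_acceleration(
    result["phenoage"], people["age"])

print(result.round(3))
print()
print("Each row: the log-hazard linear predictor xb, the implied 10-year")
print("mortality risk, PhenoAge in years, and the age-adjusted acceleration")
print("(positive = biologically older than the cohort's age trend predicts).")
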