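# PhenoAge Gompertz clock, NHANES III training.
# gamma is per month; horizon 120 months = 10-year mortality risk.
# CRP enters on the natural-log scale (see log_biomarkers).

intercept = -19.907
age_coefficient = 0.0804
gamma = 0.0076927
horizon_months = 120.0
log_biomarkers = ["crp"]

[coefficients]
albumin = -0.0336
creatinine = 0.0095
glucose = 0.1953
crp = 0.0954
lymphocyte_pct = -0.0120
mcv = 0.0268
rdw = 0.3306
alkaline_phosphatase = 0.00188
wbc = 0.0554

# risk -> years transform: a + ln(-b * ln(1 - risk)) / c
[outer]
a = 141.50
b = 0.00553
c = 0.09165

[units]
albumin = "g/L"
creatinine = "umol/L"
glucose = "mmol/L"
crp = "mg/dL"
lymphocyte_pct = "%"
mcv = "fL"
rdw = "%"
alkaline_phosphatase = "U/L"
wbc = "10^3 cells/uL"
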