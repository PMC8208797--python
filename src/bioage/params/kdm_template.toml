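# Klemera-Doubal (BioAge) parameter template — SYNTHETIC PLACEHOLDERS.
#
# q = intercept and k = slope of the biomarker-on-age regression in the
# training data, s = its residual SD. The published training values live in
# restricted supplementary material; the numbers below are plausible
# placeholders on common clinical scales and MUST be replaced with values
# estimated on your own training cohort (see bioage.simulate.kdm_params_from_sim
# for the synthetic-cohort route).

s_ba = 31.63

[biomarkers.albumin]
q = 50.0
k = -0.08
s = 2.5
unit = "g/L"

[biomarkers.alkaline_phosphatase]
q = 60.0
k = 0.25
s = 20.0
unit = "U/L"

[biomarkers.creatinine]
q = 65.0
k = 0.15
s = 13.0
unit = "umol/L"

[biomarkers.crp]
q = 0.05
k = 0.002
s = 0.25
unit = "mg/dL"

[biomarkers.total_cholesterol]
q = 4.5
k = 0.02
s = 1.0
unit = "mmol/L"

[biomarkers.sbp]
q = 110.0
k = 0.5
s = 15.0
unit = "mmHg"

[biomarkers.hba1c]
q = 30.0
k = 0.12
s = 5.0
unit = "mmol/mol"
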