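"""Published summary statistics of the two-wave adolescent smoking cohort.

These are the printed margins and coefficients of the 181-subject cohort
the synthetic generator is calibrated to: contingency tables of smoking
status against gender, school type and wave, covariate means, the ordinal
smoking-level distributions, and the prediction-model coefficients. They
serve two purposes: as calibration targets for
:mod:`igtev.cohort` defaults, and as frozen inputs for validating the
statistical machinery (the chi-square values computable from these counts
are exact checks).

All 2x2 tables are ``[[a, b], [c, d]]`` lists with the row/column meaning
documented per table.
"""

from __future__ import annotations

N_SUBJECTS = 181

# Rows: current smoker at wave 2 (no, yes); columns: current smoker at
# wave 1 (no, yes). 153 of 181 subjects (84.5%) smoked at neither wave.
SMOKER_WAVE1_BY_WAVE2 = [[153, 6], [11, 11]]

# Rows: gender (male, female); columns: wave-1 smoking (non-current, current).
GENDER_BY_SMOKER_T1 = [[76, 15], [88, 2]]
# Rows: school type (academic, vocational); columns as above.
SCHOOL_BY_SMOKER_T1 = [[95, 4], [69, 13]]
# Same compositions against wave-2 smoking status.
GENDER_BY_SMOKER_T2 = [[73, 18], [86, 4]]
SCHOOL_BY_SMOKER_T2 = [[92, 7], [67, 15]]

# Wave-1 covariate summaries (mean, SD) pooled toward the non-smoker column
# (which dominates at 164/181).
AGE_MEAN, AGE_SD = 16.2, 0.55
WM_MEAN, WM_SD = 61.8, 6.8
SAP_MEAN, SAP_SD = 3.56, 1.07

# rEV parameter summaries by wave-1 smoking group (mean, SD).
W_NONSMOKER = (0.40, 0.36)
W_SMOKER_T1 = (0.37, 0.38)
PHI_OVERALL = (0.23, 0.33)
C_OVERALL = (4.0, 4.0)

# Smoking-level distribution (ordinal 1..6) among current smokers,
# per wave: counts over levels <1/day, 1/day, 2-5, 6-10, 11-20, >20.
LEVEL_COUNTS_T1 = [7, 3, 5, 2, 0, 0]
LEVEL_COUNTS_T2 = [6, 3, 10, 1, 1, 1]

# Marginal current-smoker prevalences.
PREVALENCE_T1 = 17 / 181
PREVALENCE_T2 = 22 / 181

# Logistic model for wave-2 smoking status (reported B coefficients):
# baseline smoking and the attention weight w are the structural effects
# the generator injects.
B_SMOKER_T1 = 3.075
B_WEIGHT_W = -2.673

# Linear model for wave-2 smoking level: standardized betas.
BETA_LEVEL_T1 = 0.643
BETA_WEIGHT_W = -0.122
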