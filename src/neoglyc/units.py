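"""Unit conversion constants.

All model mathematics run in a single consistent unit system:
time in minutes, glucose concentration in mmol/L, insulin concentration
in mU/L, infusion rates in the clinical charting units noted below with
explicit conversion at the model boundary.
"""

#: Molar mass of glucose (g/mol == mg/mmol), used to convert glucose
#: appearance rates from mg/kg/min to mmol/kg/min.
GLUCOSE_MOLAR_MASS = 180.16

#: Dextrose concentration: 1 % w/v == 1 g/100 mL == 10 mg/mL.
MG_PER_ML_PER_PCT = 10.0

#: Glucose-equivalent carbohydrate content of expressed breast milk
#: (mg glucose per mL of milk, ~7.2 g/dL). EBM intakes are charted in
#: mL/kg/day; this named constant converts them to mg/kg/min. The value
#: is configurable wherever EBM is converted.
EBM_CARB_MG_PER_ML = 72.0

MINUTES_PER_DAY = 1440.0
MINUTES_PER_HOUR = 60.0

#: Insulin infusion charted in U/kg/hr; the model works in mU/kg/min.
MU_PER_MIN_PER_U_HR = 1000.0 / 60.0

#: Standard neonatal insulin dilution: [5 x weight (kg)] U made up to
#: 20 mL, i.e. 0.25 U/kg/mL regardless of weight.
INSULIN_DILUTION_U_PER_KG_PER_ML = 0.25

#: Hard safety cap on the insulin infusion rate (U/kg/hr).
MAX_INSULIN_RATE = 0.5
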