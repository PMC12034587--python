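"""Shared column schema for the per-patient clinical feature table.

The 18 clinical variables collected for carotid-endarterectomy patients:
demographics and presentation (age, sex, stenosis rate, NIHSS stroke scale,
MPRAGE plaque grade, smoking), comorbidities, and antithrombotic / statin
medication, plus the image-derived pathological risk score and the binary
outcome (cardiovascular event within one year of surgery).
"""

ID_COLUMN = "patient_id"
LABEL_COLUMN = "event"
RISK_COLUMN = "risk_score"

CONTINUOUS_COLUMNS = [
    "Age",
    "Vessel stenosis rate",
    "NIHSS",
    "MPRAGE",
]

BINARY_COLUMNS = [
    "Male sex",
    "Smoking history",
    "Hypertension",
    "Diabetes mellitus",
    "Dyslipidemia",
    "Arteriosclerosis obliterans",
    "Coronary artery disease",
    "Aspirin",
    "Ticlopidine",
    "Clopidogrel",
    "Cilostazol",
    "Warfarin",
    "Heparin/argatroban",
    "Statins",
]

CLINICAL_COLUMNS = CONTINUOUS_COLUMNS + BINARY_COLUMNS

assert len(CLINICAL_COLUMNS) == 18
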