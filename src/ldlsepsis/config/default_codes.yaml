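# Default code and medication lists for the LDL-sepsis pipeline.
#
# These are deliberately small, editable, illustrative lists: every filter in
# the pipeline reads from this file (or a user-supplied replacement) and never
# hard-codes a clinical code.  Codes match by prefix after normalisation
# (upper-case, whitespace stripped), so "038" covers "038.9" etc.

# Billing codes that qualify an admission as an infection admission
# (bacterial infections; viral/mycobacterial/fungal deliberately absent).
infection_codes:
  ICD9CM: ["481", "482", "486", "590.10", "599.0", "680", "681", "682", "567.9", "510.9"]
  ICD10: ["J15", "J18", "N10", "N39.0", "L03", "K65.9"]

# Evidence of severe chronic illness that excludes a patient from the
# measured-LDL cohort when coded in the year before the index admission:
# HIV, end-stage kidney disease, liver disease, chemotherapy for cancer.
exclusion_condition_codes:
  ICD9CM: ["042", "585.5", "585.6", "571", "572", "V58.11"]
  ICD10: ["B20", "N18.5", "N18.6", "K70", "K72", "K74", "Z51.11"]

# Explicit severe-sepsis / septic-shock codes (highly specific surveillance set).
severe_sepsis_shock_codes:
  ICD9CM: ["995.92", "785.52"]
  ICD10: ["R65.20", "R65.21"]

# Mechanical-ventilation procedure codes.
ventilation_codes:
  PROC: ["96.70", "96.71", "96.72"]
  ICD10: ["5A1935Z", "5A1945Z", "5A1955Z"]

# Billing code for administration of a vasopressor agent.
vasopressor_admin_codes:
  PROC: ["00.17"]

# Critical-care service codes usable as ICU evidence in addition to the
# admission-level ICU flag.
icu_codes:
  PROC: ["99291", "99292"]

# Medication name lists (normalised to lower case at lookup).
antibiotic_names:
  - vancomycin
  - piperacillin-tazobactam
  - cefepime
  - ceftriaxone
  - cefazolin
  - levofloxacin
  - ciprofloxacin
  - meropenem
  - azithromycin
  - ampicillin-sulbactam
  - metronidazole
  - doxycycline

statin_names:
  - atorvastatin
  - simvastatin
  - rosuvastatin
  - pravastatin
  - lovastatin
  - fluvastatin
  - pitavastatin

norepinephrine_names:
  - norepinephrine
  - norepinephrine bitartrate
  - levophed

dopamine_names:
  - dopamine
  - dopamine hydrochloride

dobutamine_names:
  - dobutamine
  - dobutamine hydrochloride

# Diagnosis-code -> phecode mapping (longest-prefix match), reduced
# illustrative subset of a phenome-wide grouping.
icd_phecode_map:
  ICD9CM:
    "410": "411.2"
    "428": "428.2"
    "443": "443.9"
    "433": "433.1"
    "434": "433.1"
    "290": "290.1"
    "491": "496.2"
    "492": "496.2"
    "496": "496.2"
    "714": "714.1"
    "531": "531.1"
    "532": "531.1"
    "533": "531.1"
    "571.2": "571.5"
    "571.5": "571.5"
    "571.8": "571.5"
    "250.0": "250.1"
    "250.4": "250.7"
    "250.5": "250.7"
    "250.6": "250.7"
    "342": "344.1"
    "585": "585.3"
    "153": "153.2"
    "162": "165.1"
    "174": "174.1"
    "204": "204.1"
    "572": "571.8"
    "196": "198.1"
    "197": "198.1"
    "198": "198.1"
    "042": "071.1"
  ICD10:
    "I21": "411.2"
    "I50": "428.2"
    "I73": "443.9"
    "I63": "433.1"
    "F03": "290.1"
    "J44": "496.2"
    "M05": "714.1"
    "K27": "531.1"
    "K70.3": "571.5"
    "E11.9": "250.1"
    "E11.2": "250.7"
    "G81": "344.1"
    "N18": "585.3"
    "C18": "153.2"
    "C34": "165.1"
    "C50": "174.1"
    "C91": "204.1"
    "K72.9": "571.8"
    "C78": "198.1"
    "C79": "198.1"
    "B20": "071.1"

# Phecode -> modified Charlson/Deyo comorbidity category.  The diabetes and
# diabetes-with-complications categories are merged downstream into a single
# diabetes indicator.
phecode_charlson_map:
  "411.2": myocardial_infarction
  "428.2": congestive_heart_failure
  "443.9": peripheral_vascular_disease
  "433.1": cerebrovascular_disease
  "290.1": dementia
  "496.2": chronic_pulmonary_disease
  "714.1": rheumatic_disease
  "531.1": peptic_ulcer_disease
  "571.5": mild_liver_disease
  "250.1": diabetes
  "250.7": diabetes_with_complications
  "344.1": hemiplegia_paraplegia
  "585.3": renal_disease
  "153.2": malignancy
  "165.1": malignancy
  "174.1": malignancy
  "204.1": malignancy
  "571.8": moderate_severe_liver_disease
  "198.1": metastatic_solid_tumor
  "071.1": aids_hiv

# Multiple-testing significance threshold for three correlated outcomes.
alpha: 0.0167
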