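"""Synthetic longitudinal EHR generator with a controlled confounding structure.

The generator emulates the data-generating process the downstream analysis
assumes: a latent per-patient comorbidity burden (count of active
Charlson/Deyo categories) that simultaneously *lowers* baseline LDL
cholesterol and *raises* the odds of sepsis, ICU admission and in-hospital
death, plus an additive polygenic component of LDL calibrated to explain a
chosen fraction of LDL variance.  The direct effect of LDL on sepsis is a
free parameter (``direct_ldl_logor_per_sd``, default 0): with it at zero and
confounding active, the crude LDL–sepsis association is negative while the
burden-adjusted association is null — the structure a confounder-adjusted
analysis must recover.

Outcome model per patient (z = standardised true LDL, B = burden):

    logit P(sepsis) = logit(base rate) + beta_C * B + beta_L * z

and analogously for ICU admission and death with their own base rates.
Every patient receives an index admission carrying an infection code and an
antibiotic within a day of admission, so the infection filter is exercised
but not informative; sepsis cases additionally receive the minimal event
evidence for exactly one detection pathway (explicit code or one of five
organ-dysfunction criteria), chosen uniformly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ehr import CodeConfig, EhrBundle, validate_bundle
from .errors import ParameterError

#: the six detection pathways of the sepsis phenotyping algorithm
SEPSIS_CRITERIA = (
    "explicit_code",
    "cardiovascular",
    "respiratory",
    "renal",
    "hepatic",
    "hematologic",
)

#: raw (un-merged) modified Charlson/Deyo comorbidity categories
RAW_CATEGORIES = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes",
    "diabetes_with_complications",
    "hemiplegia_paraplegia",
    "renal_disease",
    "malignancy",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
    "aids_hiv",
)

# one representative ICD-9-CM diagnosis code per category, consistent with the
# shipped default phecode/Charlson mapping
CATEGORY_PLANT_CODES: dict[str, str] = {
    "myocardial_infarction": "410.1",
    "congestive_heart_failure": "428.0",
    "peripheral_vascular_disease": "443.9",
    "cerebrovascular_disease": "434.91",
    "dementia": "290.0",
    "chronic_pulmonary_disease": "496",
    "rheumatic_disease": "714.0",
    "peptic_ulcer_disease": "533.9",
    "mild_liver_disease": "571.5",
    "diabetes": "250.00",
    "diabetes_with_complications": "250.60",
    "hemiplegia_paraplegia": "342.9",
    "renal_disease": "585.9",
    "malignancy": "153.9",
    "moderate_severe_liver_disease": "572.2",
    "metastatic_solid_tumor": "197.7",
    "aids_hiv": "042",
}

# hospitalisation-burden prevalences in an infection cohort; the four
# categories excluded from the measured-LDL subcohort get small rates
DEFAULT_PREVALENCES: dict[str, float] = {
    "myocardial_infarction": 0.13,
    "congestive_heart_failure": 0.22,
    "peripheral_vascular_disease": 0.09,
    "cerebrovascular_disease": 0.19,
    "dementia": 0.08,
    "chronic_pulmonary_disease": 0.27,
    "rheumatic_disease": 0.06,
    "peptic_ulcer_disease": 0.03,
    "mild_liver_disease": 0.03,
    "diabetes": 0.25,
    "diabetes_with_complications": 0.08,
    "hemiplegia_paraplegia": 0.02,
    "renal_disease": 0.04,
    "malignancy": 0.12,
    "moderate_severe_liver_disease": 0.02,
    "metastatic_solid_tumor": 0.03,
    "aids_hiv": 0.01,
}


def default_snp_weights() -> pd.DataFrame:
    """Load the shipped synthetic 81-SNP weight table.

    The table is a synthetic stand-in (rsid, effect_allele, beta in mg/dL per
    allele, minor-allele frequency) drawn once and frozen; any user table
    with the same columns can replace it.
    """
    ref = importlib.resources.files("ldlsepsis.config") / "snp_weights_synthetic_81.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def calibrate_grs_noise(betas, mafs, target_r2: float) -> float:
    """Residual SD sigma such that Var(GRS) / (Var(GRS) + sigma^2) = target_r2.

    Var(GRS) is the Hardy-Weinberg variance  sum_i beta_i^2 * 2 maf_i (1-maf_i).
    """
    if not (0 < target_r2 < 1):
        raise ParameterError(f"target_r2 must lie in (0, 1), got {target_r2}")
    betas = np.asarray(betas, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ParameterError("minor-allele frequencies must lie in (0, 0.5]")
    var_grs = float(np.sum(betas**2 * 2.0 * mafs * (1.0 - mafs)))
    return float(np.sqrt(var_grs * (1.0 - target_r2) / target_r2))


def hardy_weinberg_grs_variance(weights: pd.DataFrame) -> float:
    b = weights["beta"].to_numpy(float)
    m = weights["maf"].to_numpy(float)
    return float(np.sum(b**2 * 2.0 * m * (1.0 - m)))


@dataclass
class SimParams:
    """Tunable study conditions for the synthetic cohort.

    Defaults encode the cohort this pipeline analyses: mean (SD) baseline LDL
    103.4 (32.6) mg/dL, a polygenic score explaining 5.8% of LDL variance,
    roughly 15% marginal sepsis risk, and a comorbidity burden that shifts
    LDL by ``ldl_comorbidity_shift`` mg/dL per active category while raising
    the log-odds of each outcome by ``comorbidity_logor`` per category.
    """

    n_patients: int = 4000
    seed: int = 0
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    ldl_mean: float = 103.4
    ldl_sd: float = 32.6
    ldl_comorbidity_shift: float = -5.5
    direct_ldl_logor_per_sd: float = 0.0
    comorbidity_logor: float = 0.65
    sepsis_base_rate: float = 0.05
    icu_base_rate: float = 0.025
    death_base_rate: float = 0.006
    grs_target_r2: float = 0.058
    n_snps: int = 81
    snp_weights: pd.DataFrame | None = None
    ldl_measurement_sd: float = 5.0
    statin_prob: float = 0.25
    albumin_low_prob: float = 0.02
    multi_episode_prob: float = 0.0
    noise_code_rate: float = 1.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ParameterError("n_patients must be non-negative")
        if not (0 < self.grs_target_r2 < 1):
            raise ParameterError("grs_target_r2 must lie in (0, 1)")
        if self.ldl_sd <= 0:
            raise ParameterError("ldl_sd must be positive")
        for k, p in self.comorbidity_prevalences.items():
            if k not in RAW_CATEGORIES:
                raise ParameterError(f"unknown comorbidity category {k!r}")
            if not (0 <= p < 1):
                raise ParameterError(f"prevalence for {k!r} outside [0, 1)")
        for name in ("sepsis_base_rate", "icu_base_rate", "death_base_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ParameterError(f"{name} must lie in (0, 1)")
        for name in ("statin_prob", "albumin_low_prob", "multi_episode_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1]")

    def weights(self) -> pd.DataFrame:
        w = self.snp_weights if self.snp_weights is not None else default_snp_weights()
        if self.n_snps > len(w):
            raise ParameterError(
                f"n_snps={self.n_snps} exceeds weight table ({len(w)} rows)"
            )
        return w.iloc[: self.n_snps].reset_index(drop=True)


@dataclass
class SimTruth:
    """Latent per-patient ground truth, for parameter-recovery tests only.

    Never consumed by the analysis pipeline.
    """

    per_patient: pd.DataFrame  # burden, ldl_true, grs_raw, p_*, outcome draws
    params: SimParams

    def write(self, path: str | Path) -> None:
        self.per_patient.to_csv(path, index=False)


_EPOCH = np.datetime64("1970-01-01")


def _dates(days: np.ndarray) -> pd.Series:
    return pd.Series(_EPOCH + days.astype("timedelta64[D]")).dt.normalize()


def generate_bundle(
    params: SimParams, config: CodeConfig | None = None
) -> tuple[EhrBundle, SimTruth]:
    """Generate a validated synthetic EhrBundle and its latent truth.

    Deterministic for a fixed ``params.seed``.  Planted codes follow the
    shipped default code configuration; pass a custom ``config`` only if its
    lists contain the default planted codes.
    """
    params.validate()
    config = config or CodeConfig.default()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    weights = params.weights()

    cats = list(RAW_CATEGORIES)
    prev = np.array(
        [params.comorbidity_prevalences.get(c, 0.0) for c in cats], dtype=float
    )

    if n == 0:
        empty = _empty_bundle(config)
        truth = SimTruth(
            per_patient=pd.DataFrame(
                columns=["patient_id", "burden", "ldl_true", "grs_raw",
                         "p_sepsis", "sepsis", "criterion", "p_icu", "icu",
                         "p_death", "death"]
            ),
            params=params,
        )
        return empty, truth

    pid = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.578, "female", "male")
    admit_day = rng.integers(9131, 16800, n)  # 1995..2015
    age_years = np.clip(rng.normal(64.1, 15.9, n), 18.5, 95.0)
    birth_day = admit_day - np.round(age_years * 365.25).astype(int)
    los = rng.integers(3, 15, n)
    discharge_day = admit_day + los

    comorb = rng.random((n, len(cats))) < prev
    # burden counts *merged* categories (diabetes with and without
    # complications are one category), matching the covariate model
    merged = comorb.copy()
    i_dm = cats.index("diabetes")
    i_dmc = cats.index("diabetes_with_complications")
    merged[:, i_dm] |= merged[:, i_dmc]
    merged = np.delete(merged, i_dmc, axis=1)
    burden = merged.sum(axis=1)

    # genotypes under Hardy-Weinberg, no linkage disequilibrium
    maf = weights["maf"].to_numpy(float)
    beta = weights["beta"].to_numpy(float)
    geno = rng.binomial(2, maf, size=(n, len(maf))).astype(float)
    grs_raw = geno @ beta

    # variance budget: total Var(LDL) = ldl_sd^2, split into genetic part
    # (grs_target_r2 of the total), burden part and residual noise
    var_hw = hardy_weinberg_grs_variance(weights)
    s = np.sqrt(params.grs_target_r2) * params.ldl_sd / np.sqrt(var_hw)
    p_dm_merged = 1.0 - (1.0 - prev[i_dm]) * (1.0 - prev[i_dmc])
    prev_merged = np.delete(prev, i_dmc)
    prev_merged[i_dm] = p_dm_merged  # i_dm precedes i_dmc in category order
    var_burden = float(np.sum(prev_merged * (1 - prev_merged)))
    eps_var = (
        params.ldl_sd**2 * (1 - params.grs_target_r2)
        - params.ldl_comorbidity_shift**2 * var_burden
    )
    if eps_var <= 0:
        raise ParameterError(
            "ldl_comorbidity_shift too large for the requested ldl_sd/grs_target_r2"
        )
    grs_centered = grs_raw - 2.0 * float(beta @ maf)
    ldl_true = (
        params.ldl_mean
        + s * grs_centered
        + params.ldl_comorbidity_shift * (burden - float(prev_merged.sum()))
        + rng.normal(0.0, np.sqrt(eps_var), n)
    )
    ldl_true = np.clip(ldl_true, 10.0, None)
    z = (ldl_true - params.ldl_mean) / params.ldl_sd

    def _outcome(base_rate: float) -> tuple[np.ndarray, np.ndarray]:
        lp = (
            logit(base_rate)
            + params.comorbidity_logor * burden
            + params.direct_ldl_logor_per_sd * z
        )
        p = expit(lp)
        return p, rng.random(n) < p

    p_sepsis, sepsis = _outcome(params.sepsis_base_rate)
    p_icu, icu_draw = _outcome(params.icu_base_rate)
    p_death, death = _outcome(params.death_base_rate)
    criterion_idx = rng.integers(0, len(SEPSIS_CRITERIA), n)
    criterion = np.where(
        sepsis, np.array(SEPSIS_CRITERIA, dtype=object)[criterion_idx], ""
    )
    icu_flag = icu_draw | (sepsis & (criterion == "respiratory"))

    # ---- event streams ------------------------------------------------
    c_pid: list[np.ndarray] = []
    c_day: list[np.ndarray] = []
    c_sys: list[np.ndarray] = []
    c_code: list[np.ndarray] = []

    def add_codes(idx: np.ndarray, day: np.ndarray, code: str, system: str = "ICD9CM"):
        if len(idx) == 0:
            return
        c_pid.append(pid[idx])
        c_day.append(day)
        c_sys.append(np.full(len(idx), system, dtype=object))
        c_code.append(np.full(len(idx), code, dtype=object))

    # comorbidity diagnoses in the lookback year
    for j, cat in enumerate(cats):
        idx = np.where(comorb[:, j])[0]
        day = admit_day[idx] - rng.integers(30, 366, len(idx))
        add_codes(idx, day, CATEGORY_PLANT_CODES[cat])
    # chemotherapy encounter for metastatic disease (drives the chronic
    # exclusion the same way HIV/liver codes do)
    meta_idx = np.where(comorb[:, cats.index("metastatic_solid_tumor")])[0]
    add_codes(
        meta_idx, admit_day[meta_idx] - rng.integers(30, 366, len(meta_idx)), "V58.11"
    )

    # the index infection code, dated within the admission
    inf_codes = np.asarray(config.infection_codes["ICD9CM"], dtype=object)
    all_idx = np.arange(n)
    inf_choice = inf_codes[rng.integers(0, len(inf_codes), n)]
    inf_day = admit_day + rng.integers(0, 3, n)
    c_pid.append(pid)
    c_day.append(inf_day)
    c_sys.append(np.full(n, "ICD9CM", dtype=object))
    c_code.append(inf_choice)

    # benign background codes (unmapped by every filter)
    n_noise = rng.poisson(params.noise_code_rate, n)
    noise_idx = np.repeat(all_idx, n_noise)
    add_codes(
        noise_idx,
        admit_day[noise_idx] - rng.integers(1, 1826, len(noise_idx)),
        "V70.0",
    )

    # ---- medications ---------------------------------------------------
    m_pid: list[np.ndarray] = []
    m_day: list[np.ndarray] = []
    m_drug: list[np.ndarray] = []

    abx = np.asarray(config.antibiotic_names, dtype=object)
    m_pid.append(pid)
    m_day.append(admit_day + rng.integers(-1, 2, n))
    m_drug.append(abx[rng.integers(0, len(abx), n)])

    # ---- laboratory streams -------------------------------------------
    l_pid: list[np.ndarray] = []
    l_day: list[np.ndarray] = []
    l_analyte: list[np.ndarray] = []
    l_value: list[np.ndarray] = []
    l_inpt: list[np.ndarray] = []

    def add_labs(idx, day, analyte, value, inpatient=False):
        if len(idx) == 0:
            return
        l_pid.append(pid[idx])
        l_day.append(day)
        l_analyte.append(np.full(len(idx), analyte, dtype=object))
        # day-resolution values at lab-report precision; keeps CSVs stable
        l_value.append(np.round(np.asarray(value, dtype=float), 4))
        l_inpt.append(np.full(len(idx), inpatient, dtype=bool))

    # outpatient LDL panel, all strictly more than one year pre-index
    n_ldl = np.clip(1 + rng.poisson(1.0, n), 1, 4)
    ldl_idx = np.repeat(all_idx, n_ldl)
    ldl_day = admit_day[ldl_idx] - rng.integers(370, 1826, len(ldl_idx))
    ldl_val = np.clip(
        ldl_true[ldl_idx] + rng.normal(0, params.ldl_measurement_sd, len(ldl_idx)),
        10.0,
        None,
    )
    add_labs(ldl_idx, ldl_day, "ldl", ldl_val)
    first_ldl_day = np.full(n, 10**9)
    np.minimum.at(first_ldl_day, ldl_idx, ldl_day)

    # HDL / triglycerides / BMI for the extended-adjustment covariates
    for analyte, draw in (
        ("hdl", lambda k: np.clip(rng.normal(50.84, 17.1, k), 10, None)),
        ("triglycerides", lambda k: rng.lognormal(4.897, 0.610, k)),
        ("bmi", lambda k: np.clip(rng.normal(30.3, 7.7, k), 14, 65)),
    ):
        day = admit_day - rng.integers(30, 2001, n)
        add_labs(all_idx, day, analyte, draw(n))

    # low-albumin episodes adjacent to one LDL draw, plus background albumin
    low_alb = np.where(rng.random(n) < params.albumin_low_prob)[0]
    if len(low_alb):
        # attach to each selected patient's first LDL date
        alb_day = first_ldl_day[low_alb] + rng.integers(-20, 21, len(low_alb))
        add_labs(low_alb, alb_day, "albumin", np.full(len(low_alb), 2.5))
    bg_alb = np.where(rng.random(n) < 0.3)[0]
    add_labs(
        bg_alb,
        admit_day[bg_alb] - rng.integers(30, 1500, len(bg_alb)),
        "albumin",
        np.clip(rng.normal(4.1, 0.3, len(bg_alb)), 3.3, None),
    )

    # statin initiation strictly after the first LDL measurement
    statins = np.asarray(config.statin_names, dtype=object)
    st_idx = np.where(rng.random(n) < params.statin_prob)[0]
    if len(st_idx):
        gap = np.maximum(admit_day[st_idx] - first_ldl_day[st_idx], 2)
        st_day = first_ldl_day[st_idx] + 1 + (rng.random(len(st_idx)) * (gap - 1)).astype(int)
        m_pid.append(pid[st_idx])
        m_day.append(st_day)
        m_drug.append(statins[rng.integers(0, len(statins), len(st_idx))])

    # pre-admission organ-function baseline panel for every patient
    base_day = admit_day - rng.integers(30, 366, n)
    creat_base = np.clip(rng.normal(0.9, 0.1, n), 0.4, None)
    bili_base = np.clip(rng.normal(0.6, 0.1, n), 0.2, None)
    plate_base = np.clip(rng.normal(250, 40, n), 120, None)
    add_labs(all_idx, base_day, "creatinine", creat_base)
    add_labs(all_idx, base_day, "bilirubin_total", bili_base)
    add_labs(all_idx, base_day, "platelets", plate_base)

    # unremarkable in-window panel for a random half (never triggers criteria)
    inw = np.where(rng.random(n) < 0.5)[0]
    inw_day = admit_day[inw] + rng.integers(-1, 2, len(inw))
    add_labs(inw, inw_day, "creatinine",
             creat_base[inw] * rng.uniform(0.9, 1.3, len(inw)), True)
    add_labs(inw, inw_day, "bilirubin_total",
             bili_base[inw] * rng.uniform(0.8, 1.3, len(inw)), True)
    add_labs(inw, inw_day, "platelets",
             plate_base[inw] * rng.uniform(0.7, 1.2, len(inw)), True)

    # ---- sepsis evidence planting (one pathway per case) ---------------
    def cases(name: str) -> np.ndarray:
        return np.where(sepsis & (criterion == name))[0]

    idx = cases("explicit_code")
    add_codes(idx, admit_day[idx], config.severe_sepsis_shock_codes["ICD9CM"][0])

    idx = cases("cardiovascular")
    if len(idx):
        m_pid.append(pid[idx])
        m_day.append(admit_day[idx])
        m_drug.append(np.full(len(idx), config.norepinephrine_names[0], dtype=object))

    idx = cases("respiratory")  # icu_flag already forced True above
    add_codes(idx, admit_day[idx], config.ventilation_codes["PROC"][0], "PROC")

    idx = cases("renal")
    add_labs(idx, admit_day[idx] + rng.integers(0, 2, len(idx)), "creatinine",
             creat_base[idx] * rng.uniform(2.05, 3.0, len(idx)), True)

    idx = cases("hepatic")
    hep_val = np.maximum(2.0, bili_base[idx] * 2.05) * rng.uniform(1.0, 1.4, len(idx))
    add_labs(idx, admit_day[idx] + rng.integers(0, 2, len(idx)),
             "bilirubin_total", hep_val, True)

    idx = cases("hematologic")
    hem_val = np.minimum(95.0, 0.45 * plate_base[idx])
    add_labs(idx, admit_day[idx] + rng.integers(0, 2, len(idx)),
             "platelets", hem_val, True)

    # ---- optional earlier infection episode -----------------------------
    a_pid = [pid]
    a_admit = [admit_day]
    a_disch = [discharge_day]
    a_icu = [icu_flag]
    a_died = [death]
    if params.multi_episode_prob > 0:
        extra = np.where(rng.random(n) < params.multi_episode_prob)[0]
        if len(extra):
            e_admit = first_ldl_day[extra] - rng.integers(10, 101, len(extra))
            e_admit = np.maximum(e_admit, birth_day[extra] + 20 * 365)
            e_disch = e_admit + rng.integers(2, 8, len(extra))
            a_pid.append(pid[extra])
            a_admit.append(e_admit)
            a_disch.append(e_disch)
            a_icu.append(np.zeros(len(extra), bool))
            a_died.append(np.zeros(len(extra), bool))
            add_codes(extra, e_admit, str(inf_codes[0]))
            m_pid.append(pid[extra])
            m_day.append(e_admit)
            m_drug.append(abx[rng.integers(0, len(abx), len(extra))])

    patients = pd.DataFrame(
        {"patient_id": pid, "sex": sex, "birth_date": _dates(birth_day)}
    )
    admissions = pd.DataFrame(
        {
            "patient_id": np.concatenate(a_pid),
            "admit_date": _dates(np.concatenate(a_admit)),
            "discharge_date": _dates(np.concatenate(a_disch)),
            "icu_flag": np.concatenate(a_icu),
            "died_in_hospital": np.concatenate(a_died),
        }
    )
    coded_events = pd.DataFrame(
        {
            "patient_id": np.concatenate(c_pid),
            "date": _dates(np.concatenate(c_day)),
            "system": np.concatenate(c_sys),
            "code": np.concatenate(c_code),
        }
    )
    med_events = pd.DataFrame(
        {
            "patient_id": np.concatenate(m_pid),
            "date": _dates(np.concatenate(m_day)),
            "drug": np.concatenate(m_drug),
        }
    )
    labs = pd.DataFrame(
        {
            "patient_id": np.concatenate(l_pid),
            "date": _dates(np.concatenate(l_day)),
            "analyte": np.concatenate(l_analyte),
            "value": np.concatenate(l_value),
            "inpatient": np.concatenate(l_inpt),
        }
    )
    genotypes = pd.DataFrame(geno, index=pd.Index(pid, name="patient_id"),
                             columns=weights["rsid"].tolist())

    bundle = validate_bundle(
        EhrBundle(patients, admissions, coded_events, med_events, labs, genotypes),
        config,
    )
    truth = SimTruth(
        per_patient=pd.DataFrame(
            {
                "patient_id": pid,
                "burden": burden,
                "ldl_true": ldl_true,
                "grs_raw": grs_raw,
                "p_sepsis": p_sepsis,
                "sepsis": sepsis,
                "criterion": criterion,
                "p_icu": p_icu,
                "icu": icu_flag,
                "p_death": p_death,
                "death": death,
            }
        ),
        params=params,
    )
    return bundle, truth


def _empty_bundle(config: CodeConfig) -> EhrBundle:
    from .ehr import TABLE_SCHEMAS

    tables = {
        name: pd.DataFrame(columns=cols) for name, cols in TABLE_SCHEMAS.items()
    }
    bundle = EhrBundle(**tables, genotypes=None)
    return validate_bundle(bundle, config)


def plant_sepsis_evidence(
    bundle: EhrBundle,
    patient_id: str,
    criterion: str,
    config: CodeConfig | None = None,
) -> EhrBundle:
    """Insert the minimal event set satisfying exactly one sepsis pathway.

    Events are planted in the window (days -1..+1 around the patient's first
    admission); lab criteria also receive the pre-admission baseline value
    they are judged against.  Returns a new validated bundle.
    """
    if criterion not in SEPSIS_CRITERIA:
        raise ParameterError(f"unknown criterion {criterion!r}")
    config = config or CodeConfig.default()
    adm = bundle.admissions[bundle.admissions["patient_id"] == patient_id]
    if not len(adm):
        raise ParameterError(f"patient {patient_id!r} has no admission")
    adm = adm.sort_values("admit_date").iloc[0]
    day0 = adm["admit_date"]
    out = bundle.copy()

    def add_code(code: str, system: str, date) -> None:
        row = pd.DataFrame(
            [{"patient_id": patient_id, "date": date, "system": system, "code": code}]
        )
        out.coded_events = pd.concat([out.coded_events, row], ignore_index=True)

    def add_lab(analyte: str, value: float, date, inpatient: bool) -> None:
        row = pd.DataFrame(
            [
                {
                    "patient_id": patient_id,
                    "date": date,
                    "analyte": analyte,
                    "value": value,
                    "inpatient": inpatient,
                }
            ]
        )
        out.labs = pd.concat([out.labs, row], ignore_index=True)

    def add_med(drug: str, date) -> None:
        row = pd.DataFrame([{"patient_id": patient_id, "date": date, "drug": drug}])
        out.med_events = pd.concat([out.med_events, row], ignore_index=True)

    pre = day0 - pd.Timedelta(days=200)
    if criterion == "explicit_code":
        add_code(config.severe_sepsis_shock_codes["ICD9CM"][0], "ICD9CM", day0)
    elif criterion == "cardiovascular":
        add_med(config.norepinephrine_names[0], day0)
    elif criterion == "respiratory":
        add_code(config.ventilation_codes["PROC"][0], "PROC", day0)
        mask = (out.admissions["patient_id"] == patient_id) & (
            out.admissions["admit_date"] == day0
        )
        out.admissions.loc[mask, "icu_flag"] = True
    elif criterion == "renal":
        add_lab("creatinine", 0.9, pre, False)
        add_lab("creatinine", 1.9, day0, True)
    elif criterion == "hepatic":
        add_lab("bilirubin_total", 0.6, pre, False)
        add_lab("bilirubin_total", 2.4, day0, True)
    elif criterion == "hematologic":
        add_lab("platelets", 210.0, pre, False)
        add_lab("platelets", 95.0, day0 + pd.Timedelta(days=1), True)
    return validate_bundle(out, config)
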