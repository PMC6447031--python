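"""Comorbidity covariate construction (modified Charlson/Deyo categories).

Diagnosis codes dated in the year before the index admission ([index-365 d,
index-1 d]) are mapped to phecodes by longest-prefix match and then grouped
into the modified Charlson/Deyo categories; the diabetes and
diabetes-with-complications categories are merged into a single diabetes
indicator.  Categories are used as binary covariates — no summed index score
is computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr import CodeConfig, EhrBundle, _normalize_code, completed_years
from .simulate import RAW_CATEGORIES

LOOKBACK_DAYS = 365

#: output category order after merging the two diabetes categories
MERGED_CATEGORIES: tuple[str, ...] = tuple(
    c for c in RAW_CATEGORIES if c != "diabetes_with_complications"
)

#: categories structurally absent from the measured-LDL cohort because the
#: chronic-illness exclusions remove every patient carrying them
MEASURED_COHORT_ABSENT = (
    "mild_liver_disease",
    "moderate_severe_liver_disease",
    "aids_hiv",
    "metastatic_solid_tumor",
)


def map_code_to_categories(code: str, system: str, config: CodeConfig) -> set[str]:
    """Map one diagnosis code to raw Charlson categories via its phecode.

    Longest-prefix match of the normalised code against the configured
    ICD->phecode map; unmapped codes yield the empty set.
    """
    if system not in config.icd_phecode_map:
        return set()
    table = config.icd_phecode_map[system]
    norm = _normalize_code(code)
    candidate = norm
    while candidate:
        if candidate in table:
            phecode = table[candidate]
            cat = config.phecode_charlson_map.get(phecode)
            return {cat} if cat else set()
        candidate = candidate[:-1]
    return set()


def _merge_diabetes(flags: pd.DataFrame) -> pd.DataFrame:
    merged = flags.copy()
    merged["diabetes"] = (
        merged["diabetes"] | merged["diabetes_with_complications"]
    )
    return merged[list(MERGED_CATEGORIES)]


def build_covariates_all(
    bundle: EhrBundle, index_episodes: pd.DataFrame, config: CodeConfig
) -> pd.DataFrame:
    """Covariate vector per index episode: age, sex, merged category flags.

    Flags derive only from codes in the one-year lookback ending the day
    before admission; age is in completed years at admission.
    """
    if not len(index_episodes):
        return pd.DataFrame(
            columns=["patient_id", "age", "sex", *MERGED_CATEGORIES]
        )
    ep = index_episodes[["patient_id", "admit_date"]].copy()
    ep["admit_date"] = pd.to_datetime(ep["admit_date"])

    ce = bundle.coded_events
    ce = ce[ce["system"].isin(list(config.icd_phecode_map))]
    # categorise unique (system, code) pairs once, then broadcast
    pairs = ce[["system", "code"]].drop_duplicates()
    cat_of_pair = {
        (s, c): map_code_to_categories(c, s, config)
        for s, c in pairs.itertuples(index=False)
    }
    cats = [cat_of_pair[k] for k in zip(ce["system"], ce["code"])]
    mapped = ce.assign(categories=pd.Series(cats, index=ce.index, dtype=object))
    mapped = mapped[mapped["categories"].map(bool).astype(bool)]

    joined = ep.merge(
        mapped[["patient_id", "date", "categories"]], on="patient_id", how="inner"
    )
    rel = (joined["admit_date"] - joined["date"]).dt.days
    joined = joined[(rel >= 1) & (rel <= LOOKBACK_DAYS)]
    long = joined.explode("categories")

    flags = pd.DataFrame(
        False, index=ep["patient_id"], columns=list(RAW_CATEGORIES)
    )
    if len(long):
        hit = (
            long.groupby(["patient_id", "categories"]).size().unstack(fill_value=0)
            > 0
        )
        flags.update(hit)
    flags = flags.astype(bool)
    flags = _merge_diabetes(flags)

    pat = bundle.patients.set_index("patient_id")
    age = completed_years(
        ep["patient_id"].map(pat["birth_date"]), ep["admit_date"]
    )
    out = pd.DataFrame(
        {
            "patient_id": ep["patient_id"].to_numpy(),
            "age": age.to_numpy(),
            "sex": ep["patient_id"].map(pat["sex"]).to_numpy(),
        }
    )
    return pd.concat([out, flags.reset_index(drop=True)], axis=1)


def build_covariates(
    bundle: EhrBundle, episode: pd.Series, config: CodeConfig
) -> pd.Series:
    """Covariate vector for a single index episode row."""
    df = build_covariates_all(bundle, episode.to_frame().T, config)
    return df.iloc[0]
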