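"""Baseline LDL qualification, lipid/BMI medians and chronic-illness exclusions.

A patient's baseline LDL is the median of *qualifying* measurements: taken
more than one year before the index admission, outpatient, at age >= 18, not
within 30 days (either direction) of a serum albumin below 3 g/dL, and
strictly before the first mention of statin therapy.  Patients with no
qualifying measurement leave the measured-LDL cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr import CodeConfig, EhrBundle, code_matches, completed_years

#: "more than 1 year before" as a strict day threshold
ONE_YEAR_DAYS = 365
ALBUMIN_CUTOFF_GDL = 3.0
ALBUMIN_WINDOW_DAYS = 30


def first_statin_dates(bundle: EhrBundle) -> pd.Series:
    """Earliest statin medication date per patient (patients without: absent)."""
    med = bundle.med_events
    statin = med[med["drug_class"].map(lambda s: "statin" in s).astype(bool)]
    if not len(statin):
        return pd.Series(dtype="datetime64[ns]")
    return statin.groupby("patient_id")["date"].min()


def _low_albumin(bundle: EhrBundle) -> pd.DataFrame:
    alb = bundle.labs[
        (bundle.labs["analyte"] == "albumin")
        & (bundle.labs["value"] < ALBUMIN_CUTOFF_GDL)
    ]
    return alb[["patient_id", "date"]]


def qualifying_ldl_mask(
    bundle: EhrBundle,
    index_dates: pd.Series,
    config: CodeConfig | None = None,
    apply_one_year_rule: bool = True,
) -> pd.Series:
    """Boolean mask over ``bundle.labs`` rows marking qualifying LDL values.

    ``index_dates`` maps patient_id -> index admission date; LDL rows of
    patients absent from the map are all non-qualifying.
    """
    labs = bundle.labs
    is_ldl = (labs["analyte"] == "ldl").to_numpy()
    mask = is_ldl.copy()

    idx_date = labs["patient_id"].map(index_dates)
    if apply_one_year_rule:
        days_before = (idx_date - labs["date"]).dt.days
        mask &= (days_before > ONE_YEAR_DAYS).fillna(False).to_numpy()
    else:
        mask &= idx_date.notna().to_numpy()

    mask &= ~labs["inpatient"].to_numpy()

    birth = bundle.patients.set_index("patient_id")["birth_date"]
    age = completed_years(labs["patient_id"].map(birth), labs["date"])
    mask &= (age >= 18).to_numpy()

    statin = first_statin_dates(bundle)
    first_statin = labs["patient_id"].map(statin)
    # same-day LDL and first statin counts as exposed (conservative)
    mask &= (first_statin.isna() | (labs["date"] < first_statin)).to_numpy()

    low_alb = _low_albumin(bundle)
    if len(low_alb):
        ldl_rows = labs.loc[mask, ["patient_id", "date"]].reset_index()
        near = ldl_rows.merge(low_alb, on="patient_id", suffixes=("", "_alb"))
        if len(near):
            delta = (near["date"] - near["date_alb"]).dt.days.abs()
            bad_rows = near.loc[delta <= ALBUMIN_WINDOW_DAYS, "index"].unique()
            mask[bad_rows] = False

    return pd.Series(mask, index=labs.index)


def qualifying_ldl(
    bundle: EhrBundle,
    patient_id: str,
    index_admit_date,
    config: CodeConfig | None = None,
) -> pd.DataFrame:
    """Qualifying LDL measurements for one patient (rows of ``bundle.labs``)."""
    index_dates = pd.Series({patient_id: pd.Timestamp(index_admit_date)})
    mask = qualifying_ldl_mask(bundle, index_dates, config)
    out = bundle.labs[mask & (bundle.labs["patient_id"] == patient_id)]
    return out.sort_values("date").reset_index(drop=True)


def baseline_median(values) -> float:
    """Median of qualifying values; even counts average the two middle values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no qualifying measurements: patient has no baseline")
    return float(np.median(arr))


def latest_prestatin_ldl_dates(bundle: EhrBundle) -> pd.Series:
    """Latest LDL date per patient passing the index-independent rules.

    Used to select the index episode (first infection after a qualifying
    LDL measurement) before the one-year rule — which depends on the index
    date itself — can be applied.
    """
    mask = qualifying_ldl_mask(
        bundle,
        index_dates=pd.Series(
            pd.Timestamp.max.normalize(),
            index=bundle.patients["patient_id"],
        ),
        apply_one_year_rule=False,
    )
    ldl = bundle.labs[mask]
    return ldl.groupby("patient_id")["date"].max()


def apply_chronic_exclusions(
    episodes: pd.DataFrame, bundle: EhrBundle, config: CodeConfig
) -> pd.DataFrame:
    """Drop episodes with severe-chronic-illness codes in the prior year.

    A patient is excluded when any exclusion-list code (HIV, end-stage
    kidney disease, liver disease, chemotherapy) is dated within
    [index - 365 d, index - 1 d].
    """
    if not len(episodes):
        return episodes.copy()
    ce = bundle.coded_events
    mask = code_matches(
        ce["code"], ce["system"], config.code_prefixes("exclusion_condition_codes")
    )
    excl = ce.loc[mask, ["patient_id", "date"]]
    if not len(excl):
        return episodes.reset_index(drop=True)
    joined = episodes[["patient_id", "admit_date"]].merge(
        excl, on="patient_id", how="inner"
    )
    rel = (joined["admit_date"] - joined["date"]).dt.days
    hit = joined.loc[(rel >= 1) & (rel <= 365), "patient_id"].unique()
    out = episodes[~episodes["patient_id"].isin(hit)]
    return out.reset_index(drop=True)


def closest_to_admission_ldl(
    bundle: EhrBundle, patient_id: str, index_admit_date
) -> float:
    """LDL value closest in time to the index admission, no exclusions.

    Ties between an earlier and a later measurement go to the earlier one.
    """
    ldl = bundle.labs[
        (bundle.labs["analyte"] == "ldl")
        & (bundle.labs["patient_id"] == patient_id)
    ]
    if not len(ldl):
        raise ValueError(f"patient {patient_id!r} has no LDL measurement")
    delta = (ldl["date"] - pd.Timestamp(index_admit_date)).dt.days
    order = ldl.assign(absdelta=delta.abs(), date_=ldl["date"]).sort_values(
        ["absdelta", "date_"], kind="stable"
    )
    return float(order["value"].iloc[0])


def closest_ldl_all(bundle: EhrBundle, index_dates: pd.Series) -> pd.Series:
    """Vectorised closest-to-admission LDL per patient (ties -> earlier)."""
    ldl = bundle.labs[bundle.labs["analyte"] == "ldl"].copy()
    ldl = ldl[ldl["patient_id"].isin(index_dates.index)]
    if not len(ldl):
        return pd.Series(dtype=float)
    idx_date = ldl["patient_id"].map(index_dates)
    ldl["absdelta"] = (ldl["date"] - idx_date).dt.days.abs()
    ldl = ldl.sort_values(["patient_id", "absdelta", "date"], kind="stable")
    first = ldl.drop_duplicates("patient_id", keep="first")
    return first.set_index("patient_id")["value"].astype(float)


def ehr_length_years(bundle: EhrBundle) -> pd.Series:
    """(last event date - first event date) / 365.25 per patient, in years."""
    frames = [
        bundle.admissions[["patient_id", "admit_date"]].rename(
            columns={"admit_date": "date"}
        ),
        bundle.admissions[["patient_id", "discharge_date"]].rename(
            columns={"discharge_date": "date"}
        ),
        bundle.coded_events[["patient_id", "date"]],
        bundle.med_events[["patient_id", "date"]],
        bundle.labs[["patient_id", "date"]],
    ]
    ev = pd.concat(frames, ignore_index=True)
    if not len(ev):
        return pd.Series(dtype=float)
    g = ev.groupby("patient_id")["date"]
    return (g.max() - g.min()).dt.days / 365.25


def build_baseline_profiles(
    bundle: EhrBundle,
    index_episodes: pd.DataFrame,
    config: CodeConfig | None = None,
) -> pd.DataFrame:
    """Per-patient baseline lipid profile for the index episodes.

    Columns: ldl_baseline (median of qualifying values), n_qualifying,
    hdl_median, tg_median, bmi_median (medians over *all* values in the
    record, mirroring how those covariates are ascertained) and
    ehr_length_years.  Patients without a qualifying LDL are absent.
    """
    if not len(index_episodes):
        return pd.DataFrame(
            columns=[
                "patient_id",
                "ldl_baseline",
                "n_qualifying",
                "hdl_median",
                "tg_median",
                "bmi_median",
                "ehr_length_years",
            ]
        )
    index_dates = index_episodes.set_index("patient_id")["admit_date"]
    mask = qualifying_ldl_mask(bundle, index_dates, config)
    qual = bundle.labs[mask]
    agg = qual.groupby("patient_id")["value"].agg(["median", "size"])
    agg.columns = ["ldl_baseline", "n_qualifying"]

    med = {}
    for analyte, col in (
        ("hdl", "hdl_median"),
        ("triglycerides", "tg_median"),
        ("bmi", "bmi_median"),
    ):
        rows = bundle.labs[bundle.labs["analyte"] == analyte]
        med[col] = rows.groupby("patient_id")["value"].median()

    out = agg.join([s.rename(c) for c, s in med.items()], how="left")
    out = out.join(ehr_length_years(bundle).rename("ehr_length_years"), how="left")
    out = out.loc[out.index.isin(index_dates.index)]
    return out.reset_index()
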