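"""Infection-episode identification and index-episode selection.

An infection episode is an adult (>=18 y) hospital admission carrying at
least one qualifying infection billing code dated within the admission and
at least one antibiotic administration on relative day -1, 0 or +1 (day 0 =
admission date).  Episodes are returned as a DataFrame, one row per
(patient, admission), with evidence columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr import CodeConfig, EhrBundle, code_matches, completed_years

EPISODE_COLUMNS = [
    "patient_id",
    "admit_date",
    "discharge_date",
    "icu_flag",
    "died_in_hospital",
    "infection_code",
    "infection_date",
    "antibiotic_day",
    "age_at_admission",
]


def _empty_episodes() -> pd.DataFrame:
    return pd.DataFrame(columns=EPISODE_COLUMNS)


def find_episodes(bundle: EhrBundle, config: CodeConfig) -> pd.DataFrame:
    """All candidate infection episodes (one row per qualifying admission).

    The infection code attributed to an admission must be dated within
    [admit_date, discharge_date]; the evidence columns report the earliest
    such code (ties broken lexicographically) and the smallest qualifying
    antibiotic day in {-1, 0, +1}.
    """
    adm = bundle.admissions.copy()
    if not len(adm):
        return _empty_episodes()
    adm = adm.reset_index(drop=True)
    adm["admission_idx"] = adm.index

    ce = bundle.coded_events
    inf_mask = code_matches(
        ce["code"], ce["system"], config.code_prefixes("infection_codes")
    )
    inf = ce.loc[inf_mask, ["patient_id", "date", "code"]]
    cand = adm.merge(inf, on="patient_id", how="inner")
    cand = cand[
        (cand["date"] >= cand["admit_date"]) & (cand["date"] <= cand["discharge_date"])
    ]
    if not len(cand):
        return _empty_episodes()
    cand = cand.sort_values(["admission_idx", "date", "code"], kind="stable")
    cand = cand.drop_duplicates("admission_idx", keep="first")

    med = bundle.med_events
    abx = med[med["drug_class"].map(lambda s: "antibiotic" in s).astype(bool)][
        ["patient_id", "date"]
    ]
    with_abx = cand.merge(abx, on="patient_id", how="inner", suffixes=("", "_abx"))
    rel = (with_abx["date_abx"] - with_abx["admit_date"]).dt.days
    with_abx = with_abx.assign(antibiotic_day=rel)[rel.between(-1, 1)]
    if not len(with_abx):
        return _empty_episodes()
    with_abx = with_abx.sort_values(["admission_idx", "antibiotic_day"], kind="stable")
    episodes = with_abx.drop_duplicates("admission_idx", keep="first")

    birth = bundle.patients.set_index("patient_id")["birth_date"]
    age = completed_years(
        episodes["patient_id"].map(birth).reset_index(drop=True),
        episodes["admit_date"].reset_index(drop=True),
    )
    episodes = episodes.reset_index(drop=True).assign(age_at_admission=age.to_numpy())
    episodes = episodes[episodes["age_at_admission"] >= 18]

    episodes = episodes.rename(
        columns={"date": "infection_date", "code": "infection_code"}
    )
    return episodes[EPISODE_COLUMNS].reset_index(drop=True)


def select_index(
    episodes: pd.DataFrame,
    ldl_baseline_dates: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Select at most one index episode per patient.

    Without an LDL map: the earliest episode (ties broken by admit date then
    lexicographic infection code).  With a map of patient_id -> latest
    qualifying LDL measurement date: the earliest episode whose admit date is
    strictly after that date; patients absent from the map get no index
    episode.
    """
    if not len(episodes):
        return episodes.copy()
    ep = episodes.copy()
    if ldl_baseline_dates is not None:
        ldl = pd.Series(ldl_baseline_dates)
        if not len(ldl):
            return _empty_episodes()
        cutoff = pd.to_datetime(ep["patient_id"].map(ldl))
        ep = ep[cutoff.notna() & (ep["admit_date"] > cutoff)]
        if not len(ep):
            return _empty_episodes()
    ep = ep.sort_values(
        ["patient_id", "admit_date", "infection_code"], kind="stable"
    )
    return ep.drop_duplicates("patient_id", keep="first").reset_index(drop=True)
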