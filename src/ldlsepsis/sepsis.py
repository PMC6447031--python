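"""Rule-based sepsis phenotyping of index infection episodes.

An episode is called sepsis when, within days -1..+1 of admission, it has an
explicit severe-sepsis/septic-shock code or meets any of five
organ-dysfunction criteria:

cardiovascular
    norepinephrine use, or dopamine/dobutamine use together with a billing
    code for vasopressor administration;
respiratory
    a ventilation code together with ICU admission;
renal
    creatinine doubling or greater over the baseline (lowest value from one
    year before admission to discharge);
hepatic
    total bilirubin >= 2.0 mg/dL and doubled from baseline (lowest value
    over the same span);
hematologic
    platelets < 100 x 10^3/uL with at least a 50% decline from a baseline
    (highest value over the same span) that was itself >= 100.

All "doubling" / "50% decline" thresholds are inclusive.  Because the
baseline spans include the event window itself, a single in-window lab can
never satisfy a doubling criterion on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr import CodeConfig, EhrBundle, code_matches

WINDOW_DAYS = 1  # days -1..+1 around admission
BASELINE_LOOKBACK_DAYS = 365
HEPATIC_ABSOLUTE_MGDL = 2.0
PLATELET_LOW = 100.0

ORGAN_CRITERIA = ("cardiovascular", "respiratory", "renal", "hepatic", "hematologic")


@dataclass
class LabBaselines:
    """Per-episode organ-function baselines (absent analyte -> None)."""

    creatinine_baseline: float | None = None
    bilirubin_baseline: float | None = None
    platelet_baseline: float | None = None


@dataclass
class SepsisCall:
    patient_id: str
    explicit_code: bool
    cardiovascular: bool
    respiratory: bool
    renal: bool
    hepatic: bool
    hematologic: bool
    sepsis: bool
    icu_admission: bool
    in_hospital_death: bool
    evidence: list[str] = field(default_factory=list)


def renal_failure(window_creatinine, baseline: float | None) -> bool:
    """Doubling or greater of baseline creatinine within the window."""
    vals = list(window_creatinine)
    if baseline is None or baseline <= 0 or not vals:
        return False
    return max(vals) >= 2.0 * baseline


def hepatic_failure(window_bilirubin, baseline: float | None) -> bool:
    """Total bilirubin >= 2.0 mg/dL and doubled from baseline."""
    vals = list(window_bilirubin)
    if baseline is None or not vals:
        return False
    return any(v >= HEPATIC_ABSOLUTE_MGDL and v >= 2.0 * baseline for v in vals)


def hematologic_failure(window_platelets, baseline: float | None) -> bool:
    """Platelets < 100 with >= 50% decline from a baseline that was >= 100."""
    vals = list(window_platelets)
    if baseline is None or baseline < PLATELET_LOW or not vals:
        return False
    return any(v < PLATELET_LOW and v <= 0.5 * baseline for v in vals)


class SepsisPhenotyper:
    """Vectorised classifier for a table of index episodes.

    ``classify(episodes)`` returns one row per episode with the explicit-code
    flag, the five organ flags, the overall sepsis call and the ICU/death
    outcomes copied from the admission.
    """

    def __init__(self, bundle: EhrBundle, config: CodeConfig):
        self.bundle = bundle
        self.config = config

    # -- helpers ---------------------------------------------------------
    def _window_codes(self, episodes: pd.DataFrame, attr: str) -> pd.Series:
        """Per-episode flag: any config-listed code in days -1..+1."""
        ce = self.bundle.coded_events
        mask = code_matches(ce["code"], ce["system"], self.config.code_prefixes(attr))
        hits = ce.loc[mask, ["patient_id", "date"]]
        joined = episodes[["episode_idx", "patient_id", "admit_date"]].merge(
            hits, on="patient_id", how="inner"
        )
        rel = (joined["date"] - joined["admit_date"]).dt.days
        flagged = joined.loc[rel.abs() <= WINDOW_DAYS, "episode_idx"].unique()
        return pd.Series(
            np.isin(episodes["episode_idx"].to_numpy(), flagged),
            index=episodes.index,
        )

    def _window_drug(self, episodes: pd.DataFrame, drug_class: str) -> pd.Series:
        med = self.bundle.med_events
        rows = med[med["drug_class"].map(lambda s: drug_class in s).astype(bool)][
            ["patient_id", "date"]
        ]
        joined = episodes[["episode_idx", "patient_id", "admit_date"]].merge(
            rows, on="patient_id", how="inner"
        )
        rel = (joined["date"] - joined["admit_date"]).dt.days
        flagged = joined.loc[rel.abs() <= WINDOW_DAYS, "episode_idx"].unique()
        return pd.Series(
            np.isin(episodes["episode_idx"].to_numpy(), flagged),
            index=episodes.index,
        )

    def _lab_frames(self, episodes: pd.DataFrame, analyte: str) -> pd.DataFrame:
        labs = self.bundle.labs
        rows = labs[labs["analyte"] == analyte][["patient_id", "date", "value"]]
        joined = episodes[
            ["episode_idx", "patient_id", "admit_date", "discharge_date"]
        ].merge(rows, on="patient_id", how="inner")
        rel = (joined["date"] - joined["admit_date"]).dt.days
        joined["rel_day"] = rel
        in_span = (rel >= -BASELINE_LOOKBACK_DAYS) & (
            joined["date"] <= joined["discharge_date"]
        )
        return joined[in_span]

    def compute_baselines(self, episodes: pd.DataFrame) -> pd.DataFrame:
        """Baseline extrema per episode over [admit - 365 d, discharge]."""
        episodes = episodes.copy()
        for col in ("admit_date", "discharge_date"):
            episodes[col] = pd.to_datetime(episodes[col])
        out = pd.DataFrame(index=episodes["episode_idx"])
        for analyte, col, how in (
            ("creatinine", "creatinine_baseline", "min"),
            ("bilirubin_total", "bilirubin_baseline", "min"),
            ("platelets", "platelet_baseline", "max"),
        ):
            span = self._lab_frames(episodes, analyte)
            agg = span.groupby("episode_idx")["value"].agg(how)
            out[col] = agg
        return out

    # -- classification ---------------------------------------------------
    def classify(self, episodes: pd.DataFrame) -> pd.DataFrame:
        episodes = episodes.reset_index(drop=True).copy()
        for col in ("admit_date", "discharge_date"):
            episodes[col] = pd.to_datetime(episodes[col])
        episodes["episode_idx"] = episodes.index
        n = len(episodes)
        if n == 0:
            cols = [
                "patient_id", "explicit_code", *ORGAN_CRITERIA, "sepsis",
                "icu_admission", "in_hospital_death", "evidence",
            ]
            return pd.DataFrame(columns=cols)

        explicit = self._window_codes(episodes, "severe_sepsis_shock_codes")

        norepi = self._window_drug(episodes, "norepinephrine")
        dopa = self._window_drug(episodes, "dopamine") | self._window_drug(
            episodes, "dobutamine"
        )
        admin = self._window_codes(episodes, "vasopressor_admin_codes")
        cardiovascular = norepi | (dopa & admin)

        vent = self._window_codes(episodes, "ventilation_codes")
        icu_evidence = episodes["icu_flag"].astype(bool).reset_index(drop=True) | (
            self._window_codes(episodes, "icu_codes")
        )
        respiratory = vent & icu_evidence

        organ = {}
        for analyte, how, fn in (
            ("creatinine", "min", renal_failure),
            ("bilirubin_total", "min", hepatic_failure),
            ("platelets", "max", hematologic_failure),
        ):
            span = self._lab_frames(episodes, analyte)
            base = (
                span.groupby("episode_idx")["value"].agg(how)
                .reindex(episodes.index)
            )
            window = span[span["rel_day"].abs() <= WINDOW_DAYS]
            agg = "max" if fn in (renal_failure, hepatic_failure) else "min"
            w = (
                window.groupby("episode_idx")["value"].agg(agg)
                .reindex(episodes.index)
            )
            if fn is renal_failure:
                flag = (w >= 2.0 * base) & (base > 0)
            elif fn is hepatic_failure:
                flag = (w >= HEPATIC_ABSOLUTE_MGDL) & (w >= 2.0 * base)
            else:
                flag = (base >= PLATELET_LOW) & (w < PLATELET_LOW) & (w <= 0.5 * base)
            organ[analyte] = flag.fillna(False).astype(bool)

        renal = organ["creatinine"]
        hepatic = organ["bilirubin_total"]
        hematologic = organ["platelets"]

        sepsis = (
            explicit | cardiovascular | respiratory | renal | hepatic | hematologic
        )
        flags = {
            "explicit_code": explicit,
            "cardiovascular": cardiovascular,
            "respiratory": respiratory,
            "renal": renal,
            "hepatic": hepatic,
            "hematologic": hematologic,
        }
        evidence = [
            [name for name, f in flags.items() if bool(f.iloc[i])] for i in range(n)
        ]
        return pd.DataFrame(
            {
                "patient_id": episodes["patient_id"].to_numpy(),
                "explicit_code": explicit.to_numpy(),
                "cardiovascular": cardiovascular.to_numpy(),
                "respiratory": respiratory.to_numpy(),
                "renal": renal.to_numpy(),
                "hepatic": hepatic.to_numpy(),
                "hematologic": hematologic.to_numpy(),
                "sepsis": sepsis.to_numpy(),
                "icu_admission": episodes["icu_flag"].astype(bool).to_numpy(),
                "in_hospital_death": episodes["died_in_hospital"]
                .astype(bool)
                .to_numpy(),
                "evidence": evidence,
            }
        )


def compute_baselines(bundle: EhrBundle, episode: pd.Series) -> LabBaselines:
    """Organ-function baselines for a single episode row."""
    config = CodeConfig.default()
    ph = SepsisPhenotyper(bundle, config)
    ep = episode.to_frame().T.reset_index(drop=True)
    ep["episode_idx"] = 0
    df = ph.compute_baselines(ep)
    row = df.iloc[0]
    def _get(col):
        v = row[col]
        return None if pd.isna(v) else float(v)
    return LabBaselines(
        creatinine_baseline=_get("creatinine_baseline"),
        bilirubin_baseline=_get("bilirubin_baseline"),
        platelet_baseline=_get("platelet_baseline"),
    )


def cardiovascular_failure(
    bundle: EhrBundle, episode: pd.Series, config: CodeConfig
) -> bool:
    return bool(_classify_one(bundle, episode, config).cardiovascular)


def respiratory_failure(
    bundle: EhrBundle, episode: pd.Series, config: CodeConfig
) -> bool:
    return bool(_classify_one(bundle, episode, config).respiratory)


def _classify_one(
    bundle: EhrBundle, episode: pd.Series, config: CodeConfig
) -> SepsisCall:
    ph = SepsisPhenotyper(bundle, config)
    ep = episode.to_frame().T.reset_index(drop=True)
    row = ph.classify(ep).iloc[0]
    return SepsisCall(
        patient_id=row["patient_id"],
        explicit_code=bool(row["explicit_code"]),
        cardiovascular=bool(row["cardiovascular"]),
        respiratory=bool(row["respiratory"]),
        renal=bool(row["renal"]),
        hepatic=bool(row["hepatic"]),
        hematologic=bool(row["hematologic"]),
        sepsis=bool(row["sepsis"]),
        icu_admission=bool(row["icu_admission"]),
        in_hospital_death=bool(row["in_hospital_death"]),
        evidence=list(row["evidence"]),
    )


def classify_sepsis(
    bundle: EhrBundle, episode: pd.Series, config: CodeConfig
) -> SepsisCall:
    """Classify one index episode; see module docstring for the rule set."""
    return _classify_one(bundle, episode, config)
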