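"""Independent brute-force reference for the sepsis classification rules.

A direct, per-patient, loop-based transcription of the decision rules —
explicit severe-sepsis/septic-shock code in the -1..+1 day window, or any of
the five organ-dysfunction criteria — written without any vectorisation and
kept deliberately separate from the package implementation so the two can
be compared on randomized episodes.
"""

from __future__ import annotations


def _in_window(event_day: int, admit_day: int) -> bool:
    return abs(event_day - admit_day) <= 1


def _in_baseline_span(event_day: int, admit_day: int, discharge_day: int) -> bool:
    return admit_day - 365 <= event_day <= discharge_day


def _matches(code: str, system: str, prefixes: list[tuple[str, str]]) -> bool:
    c = code.strip().upper()
    return any(system == s and c.startswith(p) for s, p in prefixes)


def oracle_classify(
    episode: dict,
    codes: list[dict],
    meds: list[dict],
    labs: list[dict],
    config,
) -> dict:
    """Classify one episode from raw per-patient event lists.

    ``episode``: admit_day, discharge_day (ints), icu_flag.  ``codes``:
    dicts with day/system/code.  ``meds``: dicts with day/classes (set).
    ``labs``: dicts with day/analyte/value.
    """
    admit = episode["admit_day"]
    discharge = episode["discharge_day"]

    sev = config.code_prefixes("severe_sepsis_shock_codes")
    vent = config.code_prefixes("ventilation_codes")
    admin = config.code_prefixes("vasopressor_admin_codes")
    icu_codes = config.code_prefixes("icu_codes")

    explicit = False
    has_vent = False
    has_admin = False
    has_icu_code = False
    for ev in codes:
        if not _in_window(ev["day"], admit):
            continue
        if _matches(ev["code"], ev["system"], sev):
            explicit = True
        if _matches(ev["code"], ev["system"], vent):
            has_vent = True
        if _matches(ev["code"], ev["system"], admin):
            has_admin = True
        if _matches(ev["code"], ev["system"], icu_codes):
            has_icu_code = True

    norepi = False
    dopa_dobu = False
    for m in meds:
        if not _in_window(m["day"], admit):
            continue
        if "norepinephrine" in m["classes"]:
            norepi = True
        if "dopamine" in m["classes"] or "dobutamine" in m["classes"]:
            dopa_dobu = True
    cardiovascular = norepi or (dopa_dobu and has_admin)

    respiratory = has_vent and (bool(episode["icu_flag"]) or has_icu_code)

    renal = False
    creat_span = [
        l["value"]
        for l in labs
        if l["analyte"] == "creatinine"
        and _in_baseline_span(l["day"], admit, discharge)
    ]
    if creat_span:
        base = min(creat_span)
        for l in labs:
            if (
                l["analyte"] == "creatinine"
                and _in_window(l["day"], admit)
                and base > 0
                and l["value"] >= 2.0 * base
            ):
                renal = True

    hepatic = False
    bili_span = [
        l["value"]
        for l in labs
        if l["analyte"] == "bilirubin_total"
        and _in_baseline_span(l["day"], admit, discharge)
    ]
    if bili_span:
        base = min(bili_span)
        for l in labs:
            if (
                l["analyte"] == "bilirubin_total"
                and _in_window(l["day"], admit)
                and l["value"] >= 2.0
                and l["value"] >= 2.0 * base
            ):
                hepatic = True

    hematologic = False
    plate_span = [
        l["value"]
        for l in labs
        if l["analyte"] == "platelets"
        and _in_baseline_span(l["day"], admit, discharge)
    ]
    if plate_span:
        base = max(plate_span)
        if base >= 100.0:
            for l in labs:
                if (
                    l["analyte"] == "platelets"
                    and _in_window(l["day"], admit)
                    and l["value"] < 100.0
                    and l["value"] <= 0.5 * base
                ):
                    hematologic = True

    flags = {
        "explicit_code": explicit,
        "cardiovascular": cardiovascular,
        "respiratory": respiratory,
        "renal": renal,
        "hepatic": hepatic,
        "hematologic": hematologic,
    }
    flags["sepsis"] = any(flags.values())
    return flags


def random_episodes(n: int, seed: int, config):
    """Randomized episodes stressing windows and thresholds.

    Returns (episodes DataFrame, validated EhrBundle, per-patient event
    lists for the oracle).  Values are drawn to straddle every decision
    boundary: lab ratios span the doubling cut (with an atom exactly at
    2.0x), event days span the -1..+1 window edges, and code/medication
    evidence appears both inside and outside the window.
    """
    import numpy as np
    import pandas as pd

    from ldlsepsis import EhrBundle, validate_bundle

    rng = np.random.default_rng(seed)
    pid = np.array([f"E{i:05d}" for i in range(n)])
    admit = 15000  # fixed reference day; events placed relative to it
    discharge = admit + rng.integers(2, 10, n)
    icu = rng.random(n) < 0.3

    ev_codes = [[] for _ in range(n)]
    ev_meds = [[] for _ in range(n)]
    ev_labs = [[] for _ in range(n)]

    code_pool = [
        ("995.92", "ICD9CM"), ("785.52", "ICD9CM"), ("R65.21", "ICD10"),
        ("96.70", "PROC"), ("96.72", "PROC"), ("00.17", "PROC"),
        ("99291", "PROC"), ("486", "ICD9CM"), ("V70.0", "ICD9CM"),
    ]
    drug_pool = ["norepinephrine", "dopamine", "dobutamine", "levophed",
                 "vancomycin", "atorvastatin"]

    for i in range(n):
        for _ in range(rng.integers(0, 5)):
            code, system = code_pool[rng.integers(0, len(code_pool))]
            day = admit + int(rng.integers(-3, 4))
            ev_codes[i].append({"day": day, "system": system, "code": code})
        for _ in range(rng.integers(0, 3)):
            drug = drug_pool[rng.integers(0, len(drug_pool))]
            day = admit + int(rng.integers(-3, 4))
            ev_meds[i].append({"day": day, "drug": drug})
        for analyte, lo, hi in (
            ("creatinine", 0.4, 1.5),
            ("bilirubin_total", 0.3, 1.5),
            ("platelets", 80.0, 300.0),
        ):
            if rng.random() < 0.8:
                base = float(rng.uniform(lo, hi))
                ev_labs[i].append(
                    {"day": admit - int(rng.integers(2, 400)),
                     "analyte": analyte, "value": round(base, 3)}
                )
                for _ in range(rng.integers(0, 3)):
                    if rng.random() < 0.15:
                        ratio = 2.0 if analyte != "platelets" else 0.5
                    else:
                        ratio = float(rng.uniform(0.2, 3.5))
                    day = admit + int(rng.integers(-2, 3))
                    ev_labs[i].append(
                        {"day": day, "analyte": analyte,
                         "value": round(base * ratio, 3)}
                    )

    def dates(days):
        return pd.to_datetime(np.asarray(days), unit="D", origin="unix")

    patients = pd.DataFrame(
        {"patient_id": pid, "sex": "male",
         "birth_date": dates(np.full(n, 1000))}
    )
    admissions = pd.DataFrame(
        {"patient_id": pid, "admit_date": dates(np.full(n, admit)),
         "discharge_date": dates(discharge), "icu_flag": icu,
         "died_in_hospital": False}
    )
    c_rows = [
        {"patient_id": pid[i], "date": e["day"], "system": e["system"],
         "code": e["code"]}
        for i in range(n) for e in ev_codes[i]
    ]
    m_rows = [
        {"patient_id": pid[i], "date": e["day"], "drug": e["drug"]}
        for i in range(n) for e in ev_meds[i]
    ]
    l_rows = [
        {"patient_id": pid[i], "date": e["day"], "analyte": e["analyte"],
         "value": e["value"], "inpatient": False}
        for i in range(n) for e in ev_labs[i]
    ]
    coded = pd.DataFrame(c_rows, columns=["patient_id", "date", "system", "code"])
    meds = pd.DataFrame(m_rows, columns=["patient_id", "date", "drug"])
    labs = pd.DataFrame(l_rows,
                        columns=["patient_id", "date", "analyte", "value",
                                 "inpatient"])
    for df in (coded, meds, labs):
        df["date"] = dates(df["date"]) if len(df) else pd.to_datetime(df["date"])

    bundle = validate_bundle(
        EhrBundle(patients, admissions, coded, meds, labs), config
    )
    episodes = admissions.copy()
    oracle_events = []
    for i in range(n):
        from ldlsepsis import classify_drug

        meds_i = [
            {"day": m["day"], "classes": classify_drug(m["drug"], config)}
            for m in ev_meds[i]
        ]
        oracle_events.append(
            {
                "episode": {"admit_day": admit,
                            "discharge_day": int(discharge[i]),
                            "icu_flag": bool(icu[i])},
                "codes": ev_codes[i],
                "meds": meds_i,
                "labs": ev_labs[i],
            }
        )
    return episodes, bundle, oracle_events
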