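"""Core EHR domain model: table schemas, code configuration, readers/writers.

The pipeline works on an :class:`EhrBundle` — five linked longitudinal tables
(patients, admissions, coded events, medication events, laboratory
measurements) plus an optional genotype dosage matrix.  All tables are plain
pandas DataFrames with documented columns; dates are held at day resolution
and all downstream windows are expressed as integer days relative to an index
admission date.

Canonical laboratory units are fixed at ingest:

============  =====================
analyte       canonical unit
============  =====================
ldl, hdl,
triglycerides mg/dL
creatinine    mg/dL
bilirubin     mg/dL  (μmol/L ÷ 17.104)
albumin       g/dL   (g/L ÷ 10)
platelets     10^3/μL
bmi           kg/m²
============  =====================

Tables read from CSV may carry a ``unit`` column; the two documented
alternative units are converted, everything else must already be canonical.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError, SchemaError

SEXES = ("female", "male")
CODE_SYSTEMS = ("ICD9CM", "ICD10", "PROC")
ANALYTES = (
    "ldl",
    "hdl",
    "triglycerides",
    "albumin",
    "creatinine",
    "bilirubin_total",
    "platelets",
    "bmi",
)
DRUG_CLASSES = (
    "antibiotic",
    "statin",
    "norepinephrine",
    "dopamine",
    "dobutamine",
    "other",
)

#: factor converting total bilirubin mg/dL -> μmol/L
BILIRUBIN_UMOL_PER_MGDL = 17.104

TABLE_SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_date"],
    "admissions": [
        "patient_id",
        "admit_date",
        "discharge_date",
        "icu_flag",
        "died_in_hospital",
    ],
    "coded_events": ["patient_id", "date", "system", "code"],
    "med_events": ["patient_id", "date", "drug"],
    "labs": ["patient_id", "date", "analyte", "value", "inpatient"],
}

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "admissions": ["admit_date", "discharge_date"],
    "coded_events": ["date"],
    "med_events": ["date"],
    "labs": ["date"],
}


def _normalize_code(code: str) -> str:
    return str(code).strip().upper()


def _normalize_drug(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class CodeConfig:
    """Clinical code lists and medication name lists driving every filter.

    All lists are editable; the shipped defaults are small illustrative sets.
    Code matching is by prefix on normalised (upper-case) codes within the
    stated code system.
    """

    infection_codes: dict[str, list[str]]
    exclusion_condition_codes: dict[str, list[str]]
    severe_sepsis_shock_codes: dict[str, list[str]]
    ventilation_codes: dict[str, list[str]]
    vasopressor_admin_codes: dict[str, list[str]]
    icu_codes: dict[str, list[str]]
    icd_phecode_map: dict[str, dict[str, str]]
    phecode_charlson_map: dict[str, str]
    antibiotic_names: list[str]
    statin_names: list[str]
    norepinephrine_names: list[str]
    dopamine_names: list[str]
    dobutamine_names: list[str]
    alpha: float = 0.0167
    _drug_lookup: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for attr in (
            "infection_codes",
            "exclusion_condition_codes",
            "severe_sepsis_shock_codes",
            "ventilation_codes",
            "vasopressor_admin_codes",
            "icu_codes",
        ):
            codes = getattr(self, attr)
            if not codes or not any(v for v in codes.values()):
                raise ConfigError(f"code list {attr!r} must be non-empty")
        for attr in (
            "antibiotic_names",
            "statin_names",
            "norepinephrine_names",
            "dopamine_names",
            "dobutamine_names",
        ):
            if not getattr(self, attr):
                raise ConfigError(f"name list {attr!r} must be non-empty")
        if not self.phecode_charlson_map:
            raise ConfigError("phecode_charlson_map must be non-empty")
        lookup: dict[str, str] = {}
        for cls, names in (
            ("antibiotic", self.antibiotic_names),
            ("statin", self.statin_names),
            ("norepinephrine", self.norepinephrine_names),
            ("dopamine", self.dopamine_names),
            ("dobutamine", self.dobutamine_names),
        ):
            for name in names:
                lookup[_normalize_drug(name)] = cls
        object.__setattr__(self, "_drug_lookup", lookup)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CodeConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = known - set(raw) - {"alpha"}
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**{k: raw[k] for k in raw})

    @classmethod
    def default(cls) -> "CodeConfig":
        ref = importlib.resources.files("ldlsepsis.config") / "default_codes.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def to_dict(self) -> dict:
        return {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
            if not f.startswith("_")
        }

    def code_prefixes(self, attr: str) -> list[tuple[str, str]]:
        """Flatten a code-list attribute to (system, normalised prefix) pairs."""
        out = []
        for system, codes in getattr(self, attr).items():
            for code in codes:
                out.append((system, _normalize_code(code)))
        return out


def classify_drug(name: str, config: CodeConfig) -> frozenset[str]:
    """Classify a medication name into drug classes.

    Lookup is insensitive to case and surrounding/internal extra whitespace;
    unknown names map to ``{"other"}``.  Total function: never raises for a
    non-empty name.
    """
    cls = config._drug_lookup.get(_normalize_drug(name))
    return frozenset({cls}) if cls is not None else frozenset({"other"})


def code_matches(codes: pd.Series, systems: pd.Series, prefixes: list[tuple[str, str]]) -> np.ndarray:
    """Vectorised prefix match of (system, code) pairs against a config list."""
    mask = np.zeros(len(codes), dtype=bool)
    if not len(codes):
        return mask
    norm = codes.astype(str).str.strip().str.upper()
    sys_arr = systems.astype(str)
    for system, prefix in prefixes:
        mask |= (sys_arr == system).to_numpy() & norm.str.startswith(prefix).to_numpy()
    return mask


@dataclass
class EhrBundle:
    """The five linked longitudinal tables plus optional genotype dosages.

    ``genotypes`` is a patient × SNP dosage matrix (index ``patient_id``,
    one float column per rsid, values in [0, 2] or NaN for missing).
    """

    patients: pd.DataFrame
    admissions: pd.DataFrame
    coded_events: pd.DataFrame
    med_events: pd.DataFrame
    labs: pd.DataFrame
    genotypes: pd.DataFrame | None = None

    def copy(self) -> "EhrBundle":
        return EhrBundle(
            patients=self.patients.copy(),
            admissions=self.admissions.copy(),
            coded_events=self.coded_events.copy(),
            med_events=self.med_events.copy(),
            labs=self.labs.copy(),
            genotypes=None if self.genotypes is None else self.genotypes.copy(),
        )

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "admissions": self.admissions,
            "coded_events": self.coded_events,
            "med_events": self.med_events,
            "labs": self.labs,
        }


def canonicalize_labs(labs: pd.DataFrame) -> pd.DataFrame:
    """Convert lab values carrying a ``unit`` column to canonical units.

    Only the two documented alternative units are accepted:
    bilirubin μmol/L (÷ 17.104 → mg/dL) and albumin g/L (÷ 10 → g/dL).
    Idempotent: canonical rows pass through unchanged and the unit column is
    rewritten to the canonical unit, so a second pass is the identity.
    """
    labs = labs.copy()
    if "unit" not in labs.columns:
        return labs
    unit = labs["unit"].astype(str).str.strip().str.lower()
    value = labs["value"].astype(float).to_numpy()
    analyte = labs["analyte"].astype(str)

    bili = (analyte == "bilirubin_total") & (unit.isin(["umol/l", "µmol/l", "μmol/l"]))
    value = np.where(bili, value / BILIRUBIN_UMOL_PER_MGDL, value)
    alb = (analyte == "albumin") & (unit == "g/l")
    value = np.where(alb, value / 10.0, value)

    recognised = (
        bili
        | alb
        | unit.isin(["mg/dl", "g/dl", "10^3/ul", "kg/m2", "kg/m^2", "", "nan"])
    )
    if not recognised.all():
        bad = sorted(unit[~recognised].unique())
        raise SchemaError(f"unrecognised lab units: {bad}")
    labs["value"] = value
    labs = labs.drop(columns=["unit"])
    return labs


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.copy()
    for col in _DATE_COLUMNS[table]:
        try:
            df[col] = (
                pd.to_datetime(df[col], format="ISO8601")
                .dt.normalize()
                .astype("datetime64[ns]")
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"table {table!r}, column {col!r}: bad date ({exc})")
    return df


def _check_schema(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing columns {missing}")


def validate_bundle(bundle: EhrBundle, config: CodeConfig) -> EhrBundle:
    """Validate and canonicalize a bundle in one pass.

    Enforces schemas, parses dates, canonicalizes lab units, derives
    ``drug_class`` for every medication event, and checks referential
    integrity (every event's patient_id present in patients), admission date
    ordering, positive lab values and that birth precedes all of a patient's
    events.
    """
    tables = {}
    for name, df in bundle.tables().items():
        _check_schema(df, name)
        tables[name] = _parse_dates(df, name)

    patients = tables["patients"]
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"duplicate patient_id {dup!r} in patients table")
    bad_sex = ~patients["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"patients.sex must be one of {SEXES}")

    known = set(patients["patient_id"])
    for name in ("admissions", "coded_events", "med_events", "labs"):
        orphans = set(tables[name]["patient_id"]) - known
        if orphans:
            raise IntegrityError(
                f"table {name!r} references unknown patient_id(s): "
                f"{sorted(orphans)[:5]}"
            )

    adm = tables["admissions"]
    for col in ("icu_flag", "died_in_hospital"):
        adm[col] = adm[col].astype(bool)
    if (adm["discharge_date"] < adm["admit_date"]).any():
        raise SchemaError("admissions: discharge_date precedes admit_date")

    ce = tables["coded_events"]
    if not ce["system"].isin(CODE_SYSTEMS).all():
        raise SchemaError(f"coded_events.system must be one of {CODE_SYSTEMS}")
    if (ce["code"].astype(str).str.strip() == "").any():
        raise SchemaError("coded_events.code must be non-empty")

    labs = canonicalize_labs(tables["labs"])
    if not labs["analyte"].isin(ANALYTES).all():
        bad = sorted(set(labs["analyte"]) - set(ANALYTES))
        raise SchemaError(f"labs.analyte has unknown analytes {bad}")
    labs["value"] = labs["value"].astype(float)
    if (labs["value"] <= 0).any():
        raise SchemaError("labs.value must be strictly positive")
    labs["inpatient"] = labs["inpatient"].astype(bool)

    med = tables["med_events"]
    med["drug"] = med["drug"].astype(str).map(_normalize_drug)
    med["drug_class"] = med["drug"].map(lambda d: classify_drug(d, config))

    birth = patients.set_index("patient_id")["birth_date"]
    for name, date_col in (
        ("admissions", "admit_date"),
        ("coded_events", "date"),
        ("med_events", "date"),
        ("labs", "date"),
    ):
        df = labs if name == "labs" else (med if name == "med_events" else tables[name])
        if not len(df):
            continue
        b = df["patient_id"].map(birth)
        if (df[date_col] < b).any():
            raise IntegrityError(f"table {name!r}: event precedes patient birth_date")

    return EhrBundle(
        patients=patients.reset_index(drop=True),
        admissions=adm.reset_index(drop=True),
        coded_events=ce.reset_index(drop=True),
        med_events=med.reset_index(drop=True),
        labs=labs.reset_index(drop=True),
        genotypes=bundle.genotypes,
    )


def read_bundle(
    paths: Mapping[str, str | Path],
    config: CodeConfig,
    genotypes: str | Path | None = None,
) -> EhrBundle:
    """Read and validate a bundle from CSV files.

    ``paths`` maps table name (patients, admissions, coded_events,
    med_events, labs) to a CSV path.  ``genotypes`` optionally points at a
    patient × SNP dosage CSV (first column ``patient_id``).
    """
    tables = {}
    for name in TABLE_SCHEMAS:
        if name not in paths:
            raise SchemaError(f"missing path for table {name!r}")
        path = Path(paths[name])
        if not path.exists():
            raise SchemaError(f"file for table {name!r} not found: {path}")
        tables[name] = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    geno = None
    if genotypes is not None:
        geno = pd.read_csv(genotypes, dtype={"patient_id": str}).set_index("patient_id")
        geno = geno.astype(float)
    return validate_bundle(EhrBundle(**tables, genotypes=geno), config)


def write_bundle(bundle: EhrBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables (and genotypes, if present) as CSV.

    Dates are written ISO (YYYY-MM-DD); the derived ``drug_class`` column is
    dropped since it is re-derived at read time, making
    ``read_bundle(write_bundle(b))`` the identity on canonicalized bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in bundle.tables().items():
        df = df.copy()
        if name == "med_events" and "drug_class" in df.columns:
            df = df.drop(columns=["drug_class"])
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    if bundle.genotypes is not None:
        path = outdir / "genotypes.csv"
        bundle.genotypes.to_csv(path, index=True, index_label="patient_id")
        written["genotypes"] = path
    return written


def completed_years(birth: pd.Series, at: pd.Series) -> pd.Series:
    """Age in completed years at a reference date (vectorised)."""
    birth = pd.to_datetime(birth)
    at = pd.to_datetime(at)
    years = at.dt.year.to_numpy() - birth.dt.year.to_numpy()
    # subtract 1 where the birthday has not yet occurred in the at-year
    md_at = at.dt.month.to_numpy() * 100 + at.dt.day.to_numpy()
    md_b = birth.dt.month.to_numpy() * 100 + birth.dt.day.to_numpy()
    return pd.Series(years - (md_at < md_b).astype(int), index=at.index)
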