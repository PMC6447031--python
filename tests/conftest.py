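from __future__ import annotations

import pandas as pd
import pytest

from ldlsepsis import CodeConfig, EhrBundle, SimParams, generate_bundle, validate_bundle


@pytest.fixture(scope="session")
def config() -> CodeConfig:
    return CodeConfig.default()


def build_bundle(
    config: CodeConfig,
    patients: list[dict],
    admissions: list[dict] | None = None,
    coded_events: list[dict] | None = None,
    med_events: list[dict] | None = None,
    labs: list[dict] | None = None,
    genotypes: pd.DataFrame | None = None,
) -> EhrBundle:
    """Build a validated bundle from row dicts, filling schema defaults."""

    def df(rows, columns):
        if not rows:
            return pd.DataFrame(columns=columns)
        return pd.DataFrame(rows)

    pat = df(
        [{"sex": "female", "birth_date": "1950-01-01", **p} for p in patients],
        ["patient_id", "sex", "birth_date"],
    )
    adm = df(
        [
            {"icu_flag": False, "died_in_hospital": False, **a}
            for a in (admissions or [])
        ],
        ["patient_id", "admit_date", "discharge_date", "icu_flag", "died_in_hospital"],
    )
    ce = df(
        [{"system": "ICD9CM", **c} for c in (coded_events or [])],
        ["patient_id", "date", "system", "code"],
    )
    med = df(med_events or [], ["patient_id", "date", "drug"])
    lab = df(
        [{"inpatient": False, **l} for l in (labs or [])],
        ["patient_id", "date", "analyte", "value", "inpatient"],
    )
    return validate_bundle(
        EhrBundle(pat, adm, ce, med, lab, genotypes=genotypes), config
    )


@pytest.fixture()
def bundle_factory(config):
    def factory(**kwargs):
        return build_bundle(config, **kwargs)

    return factory


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic cohort shared by read-only tests."""
    params = SimParams(n_patients=400, seed=7)
    bundle, truth = generate_bundle(params)
    return params, bundle, truth
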