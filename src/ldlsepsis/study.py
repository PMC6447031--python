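"""End-to-end study orchestration.

:class:`SepsisLdlStudy` wires the pipeline stages together: infection-episode
identification, index selection, baseline-LDL qualification with
chronic-illness exclusions, sepsis phenotyping, comorbidity covariates, the
genetic risk score, and the logistic model grid.  ``fit()`` returns a
:class:`StudyResults` carrying the results table (one row per fitted
association), a Figure-1-style attrition table, the GRS validation, and the
two analysis tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import baseline as bl
from .association import (
    DEFAULT_ALPHA,
    AssociationResult,
    ModelSpec,
    fit_per_sd,
    fit_quartiles,
)
from .cohort import find_episodes, select_index
from .covariates import MERGED_CATEGORIES, build_covariates_all
from .ehr import CodeConfig, EhrBundle
from .errors import FitError, LdlSepsisError, QuartileError
from .grs import compute_grs, validate_grs
from .sepsis import SepsisPhenotyper
from .simulate import default_snp_weights

log = logging.getLogger(__name__)


def default_model_grid(include_quartiles: bool = True,
                       include_sensitivity: bool = True) -> list[ModelSpec]:
    """The primary grid: 3 outcomes x unadjusted/adjusted for both predictors,
    plus quartile models and the three sensitivity analyses."""
    specs: list[ModelSpec] = []
    for outcome in ("sepsis", "icu_admission", "in_hospital_death"):
        for adj in ("none", "demographics_comorbidity"):
            specs.append(ModelSpec(outcome=outcome, predictor="measured_ldl",
                                   adjustment=adj))
        for adj in ("none", "demographics_only"):
            specs.append(ModelSpec(outcome=outcome, predictor="grs",
                                   adjustment=adj))
        if include_quartiles:
            specs.append(ModelSpec(outcome=outcome, predictor="measured_ldl",
                                   predictor_form="quartiles",
                                   adjustment="demographics_comorbidity"))
            specs.append(ModelSpec(outcome=outcome, predictor="grs",
                                   predictor_form="quartiles",
                                   adjustment="demographics_only"))
        if include_sensitivity:
            specs.append(ModelSpec(outcome=outcome, predictor="measured_ldl",
                                   adjustment="extended"))
            specs.append(ModelSpec(outcome=outcome, predictor="measured_ldl",
                                   adjustment="demographics_comorbidity",
                                   cohort_variant="no_prior_infection"))
            specs.append(ModelSpec(outcome=outcome, predictor="measured_ldl",
                                   adjustment="extended",
                                   cohort_variant="closest_value_no_exclusions"))
    return specs


@dataclass
class StudyResults:
    """Fitted study: results table, attrition, GRS validation, cohorts."""

    results: list[AssociationResult]
    failures: list[dict]
    attrition: pd.DataFrame
    grs_validation: dict | None
    measured_table: pd.DataFrame
    grs_table: pd.DataFrame | None
    variant_tables: dict = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        rows = [r.as_row() for r in self.results]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["LDL-C / sepsis association study", "=" * 48, "", "Attrition:"]
        for _, row in self.attrition.iterrows():
            lines.append(f"  {row['stage']:<44}{row['n']:>8}")
        if self.grs_validation:
            v = self.grs_validation
            lines.append("")
            lines.append(
                f"GRS validation: r = {v['r']:.3f}, r^2 = {v['r2']:.4f} "
                f"(n = {v['n']})"
            )
        lines.append("")
        t = self.table
        if len(t):
            lines.append(t.to_string(index=False,
                                     float_format=lambda x: f"{x:.3f}"))
        else:
            lines.append("(no model could be fitted)")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "results.csv", index=False)
        self.attrition.to_csv(outdir / "attrition.csv", index=False)
        self.measured_table.to_csv(outdir / "measured_table.csv", index=False)
        if self.grs_table is not None:
            self.grs_table.to_csv(outdir / "grs_table.csv", index=False)
        (outdir / "report.md").write_text(
            "# Study report\n\n```\n" + self.summary() + "\n```\n", encoding="utf-8"
        )


class SepsisLdlStudy:
    """The full cohort study as a fittable model object."""

    def __init__(
        self,
        bundle: EhrBundle,
        config: CodeConfig | None = None,
        snp_weights: pd.DataFrame | None = None,
    ):
        self.bundle = bundle
        self.config = config or CodeConfig.default()
        self.snp_weights = snp_weights
        self._attrition: list[tuple[str, int]] = []

    @classmethod
    def from_csv_dir(cls, directory: str | Path,
                     config: CodeConfig | None = None) -> "SepsisLdlStudy":
        from .ehr import read_bundle

        directory = Path(directory)
        config = config or CodeConfig.default()
        paths = {name: directory / f"{name}.csv"
                 for name in ("patients", "admissions", "coded_events",
                              "med_events", "labs")}
        geno = directory / "genotypes.csv"
        bundle = read_bundle(paths, config,
                             genotypes=geno if geno.exists() else None)
        weights = None
        wpath = directory / "snp_weights.csv"
        if wpath.exists():
            from .grs import read_weights

            weights = read_weights(wpath)
        return cls(bundle, config, weights)

    # -- cohort assembly --------------------------------------------------
    def _note(self, stage: str, n: int) -> None:
        self._attrition.append((stage, int(n)))

    def _analysis_table(self, episodes: pd.DataFrame,
                        predictor: pd.Series | None = None,
                        predictor_name: str = "measured_ldl") -> pd.DataFrame:
        """Outcome flags + covariates (+ predictor) for a set of episodes."""
        ph = SepsisPhenotyper(self.bundle, self.config)
        calls = ph.classify(episodes)
        cov = build_covariates_all(self.bundle, episodes, self.config)
        tab = calls.drop(columns=["evidence"]).merge(cov, on="patient_id")
        tab["sex_male"] = (tab["sex"] == "male").astype(float)
        prof_extra = self.bundle.labs  # medians + EHR length
        med = {}
        for analyte, col in (("hdl", "hdl_median"),
                             ("triglycerides", "tg_median"),
                             ("bmi", "bmi_median")):
            rows = prof_extra[prof_extra["analyte"] == analyte]
            med[col] = rows.groupby("patient_id")["value"].median()
        for col, s in med.items():
            tab[col] = tab["patient_id"].map(s)
        tab["ehr_length_years"] = tab["patient_id"].map(
            bl.ehr_length_years(self.bundle)
        )
        if predictor is not None:
            tab[predictor_name] = tab["patient_id"].map(predictor)
            tab = tab[tab[predictor_name].notna()]
        return tab.reset_index(drop=True)

    def build_cohorts(self, which: set[str] | None = None) -> dict[str, pd.DataFrame]:
        """Assemble the measured-LDL cohort (primary + variants) and the GRS
        cohort, recording attrition along the way.

        ``which`` restricts assembly to a subset of
        {"primary", "no_prior_infection", "closest_value_no_exclusions",
        "grs"}; the primary cohort is always built.
        """
        want = which if which is not None else {
            "primary", "no_prior_infection", "closest_value_no_exclusions", "grs"
        }
        self._attrition = []
        bundle, config = self.bundle, self.config
        self._note("patients in bundle", len(bundle.patients))

        episodes = find_episodes(bundle, config)
        self._note("candidate infection episodes (adult)", len(episodes))

        tables: dict[str, pd.DataFrame] = {}

        # --- measured-LDL primary cohort ---
        ldl_dates = bl.latest_prestatin_ldl_dates(bundle)
        idx_meas = select_index(episodes, ldl_dates)
        self._note("index episodes after a qualifying LDL", len(idx_meas))
        idx_meas = bl.apply_chronic_exclusions(idx_meas, bundle, config)
        self._note("after chronic-illness exclusions", len(idx_meas))
        profiles = bl.build_baseline_profiles(bundle, idx_meas, config)
        idx_meas = idx_meas[idx_meas["patient_id"].isin(profiles["patient_id"])]
        self._note("with a qualifying baseline LDL (measured cohort)",
                   len(idx_meas))
        ldl_baseline = profiles.set_index("patient_id")["ldl_baseline"]
        tables["primary"] = self._analysis_table(idx_meas, ldl_baseline)

        # --- sensitivity: exclude prior infection admissions ---
        if "no_prior_infection" in want:
            prior = episodes.merge(ldl_dates.rename("ldl_date"),
                                   left_on="patient_id", right_index=True)
            had_prior = prior.loc[prior["admit_date"] <= prior["ldl_date"],
                                  "patient_id"].unique()
            keep = ~idx_meas["patient_id"].isin(had_prior)
            tables["no_prior_infection"] = tables["primary"][
                tables["primary"]["patient_id"].isin(
                    idx_meas.loc[keep, "patient_id"]
                )
            ].reset_index(drop=True)
            self._note("sensitivity: no infection before qualifying LDL",
                       len(tables["no_prior_infection"]))

        idx_all = None
        if want & {"closest_value_no_exclusions", "grs"}:
            idx_all = select_index(episodes)
            self._note("index episodes, first-episode rule (GRS cohort base)",
                       len(idx_all))

        # --- sensitivity: closest value, no exclusions ---
        if "closest_value_no_exclusions" in want:
            closest = bl.closest_ldl_all(
                bundle, idx_all.set_index("patient_id")["admit_date"]
            )
            tables["closest_value_no_exclusions"] = self._analysis_table(
                idx_all, closest
            )
            self._note("sensitivity: any LDL value, no exclusions",
                       len(tables["closest_value_no_exclusions"]))

        # --- GRS cohort ---
        if "grs" in want and bundle.genotypes is not None:
            weights = (self.snp_weights if self.snp_weights is not None
                       else default_snp_weights())
            scores = compute_grs(bundle.genotypes, weights)
            grs_series = scores.set_index("patient_id")["grs"]
            tables["grs"] = self._analysis_table(idx_all, grs_series, "grs")
            self._note("genotyped index episodes (GRS cohort)",
                       len(tables["grs"]))
        return tables

    # -- fitting ----------------------------------------------------------
    def fit(self, specs: list[ModelSpec] | None = None) -> StudyResults:
        specs = specs if specs is not None else default_model_grid()
        want = {"primary", "grs"}
        for spec in specs:
            if spec.predictor == "measured_ldl":
                want.add(spec.cohort_variant)
        tables = self.build_cohorts(want)
        alpha = self.config.alpha

        grs_validation = None
        if "grs" in tables and len(tables["primary"]):
            ldl = tables["primary"].set_index("patient_id")["measured_ldl"]
            try:
                scores = tables["grs"][["patient_id", "grs"]].rename(
                    columns={"grs": "grs"}
                )
                grs_validation = validate_grs(scores, ldl)
            except LdlSepsisError as exc:
                log.warning("GRS validation skipped: %s", exc)

        results: list[AssociationResult] = []
        failures: list[dict] = []
        for spec in specs:
            if spec.predictor == "grs":
                data = tables.get("grs")
                if data is None:
                    failures.append({"spec": spec, "error": "no genotypes"})
                    continue
            else:
                data = tables[spec.cohort_variant]
            if not len(data):
                failures.append({"spec": spec, "error": "empty cohort"})
                continue
            try:
                if spec.predictor_form == "per_sd":
                    results.append(fit_per_sd(data, spec, alpha))
                else:
                    results.extend(fit_quartiles(data, spec, alpha))
            except (FitError, QuartileError) as exc:
                failures.append({"spec": spec, "error": str(exc)})
                log.warning("model %s failed: %s", spec, exc)

        attrition = pd.DataFrame(self._attrition, columns=["stage", "n"])
        return StudyResults(
            results=results,
            failures=failures,
            attrition=attrition,
            grs_validation=grs_validation,
            measured_table=tables["primary"],
            grs_table=tables.get("grs"),
            variant_tables={k: v for k, v in tables.items()
                            if k not in ("primary", "grs")},
        )


def run_study(
    bundle: EhrBundle,
    config: CodeConfig | None = None,
    specs: list[ModelSpec] | None = None,
    snp_weights: pd.DataFrame | None = None,
) -> StudyResults:
    """Functional wrapper: build a :class:`SepsisLdlStudy` and fit it."""
    return SepsisLdlStudy(bundle, config, snp_weights).fit(specs)
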