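"""Logistic association models: odds ratios per 1-SD and by quartile.

The analysis table has one row per index episode with the binary outcomes
(sepsis, icu_admission, in_hospital_death), the predictor (measured baseline
LDL or the genetic risk score) and the adjustment covariates.  Continuous
predictors are standardised by the analysis cohort's SD so effect sizes are
odds ratios per 1-SD increase; quartile models code indicator variables for
the lower three quartiles against the highest quartile as reference.

The model surface follows the statsmodels convention: an
:class:`OutcomeModel` built from a DataFrame plus a :class:`ModelSpec`,
whose ``fit()`` returns a results object carrying estimates, Wald 95%
confidence intervals and p-values, with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import MERGED_CATEGORIES
from .errors import FitError, ParameterError, QuartileError

log = logging.getLogger(__name__)

OUTCOMES = ("sepsis", "icu_admission", "in_hospital_death")
PREDICTORS = ("measured_ldl", "grs")
ADJUSTMENTS = ("none", "demographics_only", "demographics_comorbidity", "extended")
COHORT_VARIANTS = ("primary", "no_prior_infection", "closest_value_no_exclusions")

#: default significance threshold for three tested outcomes
DEFAULT_ALPHA = 0.0167

EXTENDED_COVARIATES = ("hdl_median", "tg_median", "ehr_length_years", "bmi_median")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    GRS models adjust at most for demographics (age and sex): the score is
    fixed at conception, so comorbidity adjustment is neither needed nor
    part of the design.
    """

    outcome: str = "sepsis"
    predictor: str = "measured_ldl"
    predictor_form: str = "per_sd"
    adjustment: str = "demographics_comorbidity"
    cohort_variant: str = "primary"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ParameterError(f"unknown outcome {self.outcome!r}")
        if self.predictor not in PREDICTORS:
            raise ParameterError(f"unknown predictor {self.predictor!r}")
        if self.predictor_form not in ("per_sd", "quartiles"):
            raise ParameterError(f"unknown predictor_form {self.predictor_form!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise ParameterError(f"unknown adjustment {self.adjustment!r}")
        if self.cohort_variant not in COHORT_VARIANTS:
            raise ParameterError(f"unknown cohort_variant {self.cohort_variant!r}")
        if self.predictor == "grs" and self.adjustment in (
            "demographics_comorbidity",
            "extended",
        ):
            raise ParameterError(
                "GRS models adjust for demographics only (age and sex)"
            )


@dataclass
class AssociationResult:
    """One fitted association: OR, Wald 95% CI, p-value and bookkeeping."""

    spec: ModelSpec
    n: int
    n_events: int
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    term: str = "per_sd"
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def as_row(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "predictor": self.spec.predictor,
            "form": self.spec.predictor_form,
            "adjustment": self.spec.adjustment,
            "cohort_variant": self.spec.cohort_variant,
            "term": self.term,
            "n": self.n,
            "n_events": self.n_events,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def _covariate_columns(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    if spec.adjustment in ("demographics_only", "demographics_comorbidity", "extended"):
        cols += ["age", "sex_male"]
    if spec.adjustment in ("demographics_comorbidity", "extended"):
        cols += [c for c in MERGED_CATEGORIES if c in data.columns]
    if spec.adjustment == "extended":
        cols += [c for c in EXTENDED_COVARIATES if c in data.columns]
    return cols


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    keep, dropped = [], []
    for c in X.columns:
        if X[c].nunique(dropna=False) > 1:
            keep.append(c)
        else:
            dropped.append(c)
    if dropped:
        log.info("dropping constant design columns: %s", dropped)
    return X[keep]


def _fit_logit(y: pd.Series, X: pd.DataFrame) -> sm.Logit:
    model = sm.Logit(y.astype(float), sm.add_constant(X.astype(float), has_constant="add"))
    res = None
    err: Exception | None = None
    # Newton first; quasi-separated sparse-event fits fall back to L-BFGS
    for method, maxiter in (("newton", 100), ("lbfgs", 2000)):
        try:
            with np.errstate(all="ignore"):
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    cand = model.fit(disp=0, method=method, maxiter=maxiter)
        except Exception as exc:  # separation raises PerfectSeparationError etc.
            err = exc
            continue
        if cand.mle_retvals.get("converged", False):
            res = cand
            break
    if res is None:
        detail = f" ({err})" if err else ""
        raise FitError(
            f"logistic fit did not converge{detail}; columns: {list(X.columns)}"
        )
    bad = [c for c in res.bse.index if not np.isfinite(res.bse[c])]
    if bad:
        raise FitError(f"non-finite standard error for column(s) {bad}")
    return res


_Z95 = 1.959963984540054


def _wald_ci(beta: float, se: float) -> tuple[float, float]:
    # sparse-event fits can have huge SEs; an unbounded CI is the honest answer
    with np.errstate(over="ignore"):
        return float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    predictor_col = spec.predictor
    cols = [spec.outcome, predictor_col] + _covariate_columns(spec, data)
    sub = data[cols].dropna()
    y = sub[spec.outcome].astype(bool)
    x = sub[predictor_col].astype(float)
    covars = _drop_constant(sub[_covariate_columns(spec, data)]) if _covariate_columns(spec, data) else sub[[]]
    return y, covars, x


def fit_per_sd(data: pd.DataFrame, spec: ModelSpec, alpha: float = DEFAULT_ALPHA) -> AssociationResult:
    """OR per 1-SD increase of the predictor, Wald CI and two-sided p.

    The predictor is standardised by the analysis cohort's SD (ddof=1)
    after row-wise deletion of missing covariates.
    """
    y, covars, x = _prepare(data, spec)
    n = len(y)
    n_events = int(y.sum())
    if n_events < 10:
        log.warning("only %d events for %s — estimates unstable", n_events, spec)
    sd = float(x.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise FitError(f"predictor {spec.predictor!r} has zero variance")
    X = covars.copy()
    X[spec.predictor] = (x - x.mean()) / sd
    res = _fit_logit(y, X)
    beta = float(res.params[spec.predictor])
    se = float(res.bse[spec.predictor])
    ci_low, ci_high = _wald_ci(beta, se)
    return AssociationResult(
        spec=spec,
        n=n,
        n_events=n_events,
        or_point=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(res.pvalues[spec.predictor]),
        beta=beta,
        se=se,
        term="per_sd",
        alpha=alpha,
    )


def quartile_bins(values: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Quartile labels 1..4 from empirical 25/50/75 percentile cuts.

    Linear-interpolation percentiles; values equal to a cut point fall in
    the lower quartile.  Raises :class:`QuartileError` when ties leave a
    quartile empty.
    """
    v = values.astype(float).to_numpy()
    if len(np.unique(v)) < 4:
        raise QuartileError("fewer than 4 distinct predictor values")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    labels = np.searchsorted(cuts, v, side="left") + 1
    counts = np.bincount(labels, minlength=5)[1:5]
    if (counts == 0).any():
        raise QuartileError(f"empty quartile with cuts {cuts}")
    return pd.Series(labels, index=values.index), cuts


def fit_quartiles(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = DEFAULT_ALPHA
) -> list[AssociationResult]:
    """ORs for quartiles Q1..Q3 against the highest quartile Q4 (reference)."""
    y, covars, x = _prepare(data, spec)
    labels, _ = quartile_bins(x)
    X = covars.copy()
    for q in (1, 2, 3):
        X[f"Q{q}"] = (labels == q).astype(float)
    res = _fit_logit(y, X)
    out = []
    for q in (1, 2, 3):
        term = f"Q{q}"
        beta = float(res.params[term])
        se = float(res.bse[term])
        ci_low, ci_high = _wald_ci(beta, se)
        out.append(
            AssociationResult(
                spec=spec,
                n=len(y),
                n_events=int(y.sum()),
                or_point=float(np.exp(beta)),
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=float(res.pvalues[term]),
                beta=beta,
                se=se,
                term=f"{term}_vs_Q4",
                alpha=alpha,
            )
        )
    return out


class OutcomeModel:
    """Logistic model of one outcome against one predictor form.

    statsmodels-style: construct from the analysis table and a
    :class:`ModelSpec`, then ``fit()`` for an :class:`OutcomeResults`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, alpha: float = DEFAULT_ALPHA):
        self.data = data
        self.spec = spec
        self.alpha = alpha

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str = "sepsis",
        predictor: str = "measured_ldl", **kwargs
    ) -> "OutcomeModel":
        alpha = kwargs.pop("alpha", DEFAULT_ALPHA)
        return cls(data, ModelSpec(outcome=outcome, predictor=predictor, **kwargs), alpha)

    def fit(self) -> "OutcomeResults":
        if self.spec.predictor_form == "per_sd":
            results = [fit_per_sd(self.data, self.spec, self.alpha)]
        else:
            results = fit_quartiles(self.data, self.spec, self.alpha)
        return OutcomeResults(self, results)


class OutcomeResults:
    """Fitted associations for one :class:`OutcomeModel`."""

    def __init__(self, model: OutcomeModel, results: list[AssociationResult]):
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.results])

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Outcome: {spec.outcome}   Predictor: {spec.predictor} "
            f"({spec.predictor_form})   Adjustment: {spec.adjustment}",
            f"n = {self.results[0].n}, events = {self.results[0].n_events}",
            "-" * 64,
            f"{'term':<12}{'OR':>8}{'95% CI':>18}{'P':>10}",
        ]
        for r in self.results:
            ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
            lines.append(f"{r.term:<12}{r.or_point:>8.2f}{ci:>18}{r.p_value:>10.3g}")
        return "\n".join(lines)
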