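"""Missing-data imputation and univariate logistic risk-factor screening.

Missing age and sex are completed by k-nearest-neighbour imputation under
Gower distance (range-scaled numeric differences, 0/1 categorical
mismatch) over sex, age, country, reporter, exposure category and severity
class; numeric values aggregate by donor median, categorical by mode with
alphabetical tie-break.  Observed values are never altered and the
procedure is fully deterministic (donor-distance ties break by case id).

Risk factors are screened with univariate logistic regressions (one factor
at a time against a binary case-level outcome such as "has ≥1 psychiatric
PT"), reporting per-level odds ratios exp(β) with Wald 95% CIs, and one
Benjamini–Hochberg family across all non-reference levels of the screen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from fqvigil.preprocess import classify_exposure, derive_age_group
from fqvigil.report_model import CaseReport, TermDictionary, severity_class
from fqvigil.tto_analysis import bh_adjust

_CAT_FEATURES = ("sex", "country", "reporter", "exposure", "severity")


class ImputationError(ValueError):
    """Raised when too few complete donor records are available."""


@dataclass(frozen=True, slots=True)
class ImputeConfig:
    k: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ImputationError("k must be at least 1")


@dataclass(frozen=True, slots=True)
class OddsRatioResult:
    predictor: str
    level: str
    reference: str
    n_level: int
    n_events: int
    or_estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    p_adjusted: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def is_reference(self) -> bool:
        return self.level == self.reference


def _features(case: CaseReport) -> dict:
    return {
        "sex": case.sex if case.sex != "unspecified" else None,
        "age": case.age_years,
        "country": case.country,
        "reporter": case.reporter,
        "exposure": classify_exposure(case).category,
        "severity": severity_class(case),
    }


def knn_impute(
    cases: list[CaseReport],
    config: ImputeConfig = ImputeConfig(),
    seed: int | None = None,
) -> tuple[list[CaseReport], dict]:
    """Complete missing age/sex from the k nearest complete donors.

    Donors are cases with both age and sex observed.  Returns new case
    records (inputs are not mutated) and a report listing imputed case ids
    per field.  *seed* is accepted for interface uniformity; the procedure
    is deterministic and does not consume randomness.
    """
    feats = [_features(c) for c in cases]
    donor_idx = [
        i for i, f in enumerate(feats)
        if f["sex"] is not None and f["age"] is not None
    ]
    targets = [
        i for i, f in enumerate(feats)
        if f["sex"] is None or f["age"] is None
    ]
    if not targets:
        return list(cases), {"imputed_age": [], "imputed_sex": []}
    if len(donor_idx) < config.k:
        raise ImputationError(
            f"need at least k={config.k} complete donors, "
            f"have {len(donor_idx)}"
        )
    # deterministic tie-break: donors ordered by case_id
    donor_idx.sort(key=lambda i: cases[i].case_id)

    donor_age = np.asarray([feats[i]["age"] for i in donor_idx], dtype=float)
    ages_obs = [f["age"] for f in feats if f["age"] is not None]
    age_range = max(ages_obs) - min(ages_obs) if len(ages_obs) > 1 else 1.0
    if age_range == 0:
        age_range = 1.0
    donor_cat = {
        name: np.asarray([feats[i][name] for i in donor_idx], dtype=object)
        for name in _CAT_FEATURES
    }

    out = list(cases)
    imputed_age: list[str] = []
    imputed_sex: list[str] = []
    for t in targets:
        f = feats[t]
        dist = np.zeros(len(donor_idx))
        used = np.zeros(len(donor_idx))
        if f["age"] is not None:
            dist += np.abs(donor_age - f["age"]) / age_range
            used += 1
        for name in _CAT_FEATURES:
            if f[name] is None:
                continue
            dist += (donor_cat[name] != f[name]).astype(float)
            used += 1
        gower = dist / np.maximum(used, 1)
        nearest = np.argsort(gower, kind="stable")[: config.k]
        case = out[t]
        updates: dict = {}
        if f["age"] is None:
            updates["age_years"] = float(np.median(donor_age[nearest]))
            imputed_age.append(case.case_id)
        if f["sex"] is None:
            neighbours = donor_cat["sex"][nearest]
            values, counts = np.unique(
                neighbours.astype(str), return_counts=True
            )
            # mode with alphabetical tie-break (np.unique sorts values)
            updates["sex"] = str(values[np.argmax(counts)])
            imputed_sex.append(case.case_id)
        out[t] = dataclasses.replace(case, **updates)
    report = {
        "imputed_age": sorted(imputed_age),
        "imputed_sex": sorted(imputed_sex),
        "n_donors": len(donor_idx),
    }
    return out, report


# ---------------------------------------------------------------------------
# univariate logistic regression

DEFAULT_REFERENCES = {
    "exposure": "ciprofloxacin",
    "therapy": "monotherapy",
    "sex": "male",
    "age_group": "0-17",
    "severity": "non_serious",
}


def predictor_value(case: CaseReport, predictor: str) -> str:
    if predictor == "exposure":
        return classify_exposure(case).category
    if predictor == "therapy":
        exp = classify_exposure(case)
        return (
            exp.combination_subtype
            if exp.category == "combination"
            else "monotherapy"
        )
    if predictor == "sex":
        return case.sex
    if predictor == "age_group":
        return derive_age_group(case.age_years)
    if predictor == "severity":
        return severity_class(case)
    raise KeyError(f"unknown predictor {predictor!r}")


def soc_outcome_flag(dictionary: TermDictionary, soc: str):
    """Binary case-level indicator: ≥1 PT with the given primary SOC."""

    def flag(case: CaseReport) -> bool:
        return any(
            pt in dictionary and dictionary.soc(pt) == soc
            for pt in case.pts()
        )

    return flag


def logistic_univariate(
    cases: list[CaseReport],
    predictor: str,
    outcome_flag,
    reference: str | None = None,
) -> list[OddsRatioResult]:
    """Fit one univariate logistic model; per-level OR = exp(β).

    The factor is dummy-coded against *reference* (default per
    ``DEFAULT_REFERENCES``).  Maximum likelihood by Newton iterations
    (iteratively reweighted least squares), convergence tolerance 1e-8,
    at most 50 iterations.  Perfect separation (a level with zero or all
    events) is flagged, never silently fitted.
    """
    values = [predictor_value(c, predictor) for c in cases]
    y = np.asarray(
        [bool(outcome_flag(c)) for c in cases], dtype=float
    )
    if reference is None:
        reference = DEFAULT_REFERENCES.get(predictor, sorted(set(values))[0])
    levels = sorted(set(values))
    if reference not in levels:
        raise ValueError(
            f"reference level {reference!r} absent from data"
        )
    non_ref = [lv for lv in levels if lv != reference]
    values_arr = np.asarray(values, dtype=object)

    counts = {
        lv: (int((values_arr == lv).sum()),
             int(y[values_arr == lv].sum()))
        for lv in levels
    }
    separated = [
        lv for lv in non_ref + [reference]
        if counts[lv][1] == 0 or counts[lv][1] == counts[lv][0]
    ]
    results: list[OddsRatioResult] = [
        OddsRatioResult(
            predictor=predictor,
            level=reference,
            reference=reference,
            n_level=counts[reference][0],
            n_events=counts[reference][1],
            or_estimate=1.0,
            ci_low=None,
            ci_high=None,
            p_value=None,
            flags=("reference",),
        )
    ]
    if separated:
        for lv in non_ref:
            results.append(
                OddsRatioResult(
                    predictor=predictor,
                    level=lv,
                    reference=reference,
                    n_level=counts[lv][0],
                    n_events=counts[lv][1],
                    or_estimate=None,
                    ci_low=None,
                    ci_high=None,
                    p_value=None,
                    flags=("separation",),
                )
            )
        return results

    X = np.column_stack(
        [np.ones(len(cases))]
        + [(values_arr == lv).astype(float) for lv in non_ref]
    )
    model = sm.Logit(y, X)
    fit = model.fit(method="newton", tol=1e-8, maxiter=50, disp=0)
    flags: tuple[str, ...] = ()
    if not fit.mle_retvals.get("converged", True):
        flags = ("non_convergence",)
    z = 1.959963984540054
    for j, lv in enumerate(non_ref, start=1):
        coef = fit.params[j]
        se = fit.bse[j]
        results.append(
            OddsRatioResult(
                predictor=predictor,
                level=lv,
                reference=reference,
                n_level=counts[lv][0],
                n_events=counts[lv][1],
                or_estimate=float(np.exp(coef)),
                ci_low=float(np.exp(coef - z * se)),
                ci_high=float(np.exp(coef + z * se)),
                p_value=float(fit.pvalues[j]),
                flags=flags,
            )
        )
    return results


def risk_factor_screen(
    cases: list[CaseReport],
    outcome_flag,
    predictors: tuple[str, ...] = (
        "exposure",
        "therapy",
        "sex",
        "age_group",
        "severity",
    ),
    references: dict[str, str] | None = None,
    include_background: bool = False,
) -> list[OddsRatioResult]:
    """Screen several one-factor models with one BH family across levels.

    By default only FQ-exposed cases enter the models (the outcome is
    reported within the exposed cohort).  Imputation, if wanted, must be
    applied before calling (pipeline order: impute → regress).
    """
    if not include_background:
        cases = [
            c for c in cases
            if classify_exposure(c).category != "background"
        ]
    references = references or {}
    all_results: list[OddsRatioResult] = []
    for predictor in predictors:
        all_results.extend(
            logistic_univariate(
                cases, predictor, outcome_flag,
                reference=references.get(predictor),
            )
        )
    testable = [
        i for i, r in enumerate(all_results) if r.p_value is not None
    ]
    adjusted = bh_adjust([all_results[i].p_value for i in testable])
    for i, p_adj in zip(testable, adjusted):
        all_results[i] = dataclasses.replace(
            all_results[i], p_adjusted=float(p_adj)
        )
    return all_results


def results_to_rows(results: list[OddsRatioResult]) -> list[dict]:
    return [
        {
            "predictor": r.predictor,
            "level": r.level,
            "reference": r.reference,
            "n_level": r.n_level,
            "n_events": r.n_events,
            "or": r.or_estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p_value,
            "p_bh": r.p_adjusted,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
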