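"""Deduplication, psychotropic exclusion and exposure/demographic strata.

Pipeline order is dedup → exclusion → classification.  Deduplication uses
an exact composite key over demographics, receive date, suspect-drug names,
indications and reaction PTs; within a key group the case with the
lexicographically smallest id is retained.  Exclusion removes any case
carrying a drug coded under ATC N05 (psycholeptics), N06 (psychoanaleptics)
or N07B (drugs used in addictive disorders), whatever the drug's role.
"""

from __future__ import annotations

from dataclasses import dataclass

from fqvigil.report_model import CaseReport

#: the six FDA-approved fluoroquinolones screened by the pipeline
FQ_NAMES = frozenset(
    {
        "ciprofloxacin",
        "levofloxacin",
        "moxifloxacin",
        "ofloxacin",
        "gemifloxacin",
        "delafloxacin",
    }
)

PSYCHOTROPIC_ATC_PREFIXES = frozenset({"N05", "N06", "N07B"})

AGE_GROUPS = ("0-17", "18-34", "35-64", "65+", "unspecified")

COMBINATION_SUBTYPES = (
    "multiple_fqs",
    "fq_plus_antibiotics",
    "fq_plus_other_meds",
    "none",
)

#: mutually exclusive exposure categories (monotherapy per FQ + combination)
EXPOSURE_CATEGORIES = tuple(sorted(FQ_NAMES)) + ("combination",)

_MISSING = "<missing>"


class ClassificationError(ValueError):
    """Raised when a case has no fluoroquinolone to classify."""


@dataclass(frozen=True, slots=True)
class ExposureClass:
    """Mutually exclusive exposure stratum for one case."""

    category: str  # one FQ name, "combination", or "background"
    combination_subtype: str = "none"

    def __post_init__(self):
        if (self.combination_subtype != "none") != (
            self.category == "combination"
        ):
            raise ValueError(
                "combination_subtype set iff category is 'combination'"
            )


def dedup_key(case: CaseReport) -> tuple:
    """Order-insensitive exact matching key for duplicate detection.

    Missing values match each other (duplicates typically share their
    missingness pattern).  Ages are compared after rounding to whole years.
    """
    age = _MISSING if case.age_years is None else round(case.age_years)
    return (
        age,
        case.sex,
        case.country,
        case.receive_date,
        tuple(sorted({d.name for d in case.suspect_drugs()})),
        tuple(sorted(case.indications)),
        tuple(sorted(case.pts())),
    )


def deduplicate(
    cases: list[CaseReport],
) -> tuple[list[CaseReport], dict]:
    """Remove exact-key duplicates, keeping the smallest case_id per group.

    Returns the retained cases (input order preserved) and a report
    ``{"removed": [...], "retained_for": {removed_id: kept_id}}``.
    """
    groups: dict[tuple, list[CaseReport]] = {}
    for case in cases:
        groups.setdefault(dedup_key(case), []).append(case)
    keep: set[str] = set()
    retained_for: dict[str, str] = {}
    for members in groups.values():
        members = sorted(members, key=lambda c: c.case_id)
        keep.add(members[0].case_id)
        for extra in members[1:]:
            retained_for[extra.case_id] = members[0].case_id
    retained = [c for c in cases if c.case_id in keep]
    report = {
        "removed": sorted(retained_for),
        "retained_for": retained_for,
        "n_input": len(cases),
        "n_retained": len(retained),
    }
    return retained, report


def exclude_psychotropics(
    cases: list[CaseReport],
    atc_prefixes: frozenset[str] = PSYCHOTROPIC_ATC_PREFIXES,
) -> tuple[list[CaseReport], dict]:
    """Drop cases with any drug (any role) under the listed ATC prefixes."""

    def flagged(case: CaseReport) -> bool:
        return any(
            code.startswith(prefix)
            for drug in case.drugs
            for code in drug.atc_codes
            for prefix in atc_prefixes
        )

    removed = [c.case_id for c in cases if flagged(c)]
    retained = [c for c in cases if not flagged(c)]
    report = {
        "removed": sorted(removed),
        "n_input": len(cases),
        "n_retained": len(retained),
    }
    return retained, report


def classify_exposure(
    case: CaseReport,
    fq_names: frozenset[str] = FQ_NAMES,
    *,
    allow_background: bool = True,
) -> ExposureClass:
    """Assign one mutually exclusive exposure stratum.

    Monotherapy requires the FQ to be the only drug mention of any role;
    otherwise the case is combination therapy, with subtype precedence
    multiple_fqs > fq_plus_antibiotics (any non-FQ drug under ATC J01) >
    fq_plus_other_meds.  Cases without any FQ are tagged ``background``
    (or raise, when *allow_background* is false).
    """
    names = {d.name for d in case.drugs}
    fqs = names & fq_names
    if not fqs:
        if allow_background:
            return ExposureClass("background")
        raise ClassificationError(
            f"case {case.case_id} has no fluoroquinolone mention"
        )
    if len(fqs) == 1 and len(names) == 1 and len(case.drugs) >= 1:
        only = next(iter(fqs))
        if names == {only}:
            return ExposureClass(only)
    if len(fqs) >= 2:
        return ExposureClass("combination", "multiple_fqs")
    has_antibiotic = any(
        d.name not in fq_names
        and any(code.startswith("J01") for code in d.atc_codes)
        for d in case.drugs
    )
    if has_antibiotic:
        return ExposureClass("combination", "fq_plus_antibiotics")
    return ExposureClass("combination", "fq_plus_other_meds")


def derive_age_group(age_years: float | None) -> str:
    """Bin age into the standard reporting groups; missing → unspecified."""
    if age_years is None:
        return "unspecified"
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    if age_years < 18:
        return "0-17"
    if age_years < 35:
        return "18-34"
    if age_years < 65:
        return "35-64"
    return "65+"


def preprocess(
    cases: list[CaseReport],
    atc_prefixes: frozenset[str] = PSYCHOTROPIC_ATC_PREFIXES,
) -> tuple[list[CaseReport], dict]:
    """Run dedup then exclusion; returns cases plus a stage-count ledger."""
    deduped, dedup_report = deduplicate(cases)
    retained, excl_report = exclude_psychotropics(deduped, atc_prefixes)
    report = {
        "n_raw": len(cases),
        "n_deduplicated": len(deduped),
        "n_retained": len(retained),
        "dedup": dedup_report,
        "exclusion": excl_report,
    }
    return retained, report
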