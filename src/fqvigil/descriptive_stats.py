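"""Descriptive summaries, between-group tests and fatal-case reports.

Stratified count tables carry column percentages rounded half-up to two
decimals, matching the convention of published demographic tables.  The
between-group machinery offers the Pearson chi-square test (no continuity
correction) and the two-sided Fisher exact test under the
probability-ordering definition; an advisory flag recommends Fisher when
any expected cell falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from fqvigil.preprocess import classify_exposure, derive_age_group
from fqvigil.report_model import CaseReport, TermDictionary, severity_class


class DegenerateTableError(ValueError):
    """Raised when a margin of a count table is zero."""


@dataclass(frozen=True, slots=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    fisher_recommended: bool = False


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (printed tables round 0.005 up, not to even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> float:
    """Column percentage, 2 decimals half-up; empty denominator → 0.00."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator)


_DERIVED_FIELDS = {
    "sex": lambda c: c.sex,
    "age_group": lambda c: derive_age_group(c.age_years),
    "country": lambda c: c.country,
    "reporter": lambda c: c.reporter,
    "severity": severity_class,
    "exposure": lambda c: classify_exposure(c).category,
    "outcome": None,  # multi-valued, handled separately
}


def case_field(case: CaseReport, variable: str) -> str:
    try:
        getter = _DERIVED_FIELDS[variable]
    except KeyError:
        raise KeyError(f"unknown variable {variable!r}") from None
    if getter is None:
        raise KeyError(
            "'outcome' is multi-valued; use summarize row_variable='outcome'"
        )
    return getter(case)


def summarize(
    cases: list[CaseReport],
    row_variable: str,
    column_variable: str = "exposure",
) -> pd.DataFrame:
    """Stratified count table with column percentages and a total column.

    Rows are levels of *row_variable*; columns alternate ``<col>`` counts
    and ``<col>_pct`` percentages.  The multi-valued ``outcome`` row
    variable counts a case once per flag it carries (so those rows are not
    a partition and do not sum to the column total).
    """
    if column_variable == "outcome":
        raise KeyError("'outcome' cannot be a column variable")
    col_values = [case_field(c, column_variable) for c in cases]
    if row_variable == "outcome":
        pairs = [
            (flag, cv)
            for c, cv in zip(cases, col_values)
            for flag in sorted(c.outcomes)
        ]
    else:
        pairs = [
            (case_field(c, row_variable), cv)
            for c, cv in zip(cases, col_values)
        ]
    df = pd.DataFrame(pairs, columns=["row", "col"])
    counts = pd.crosstab(df["row"], df["col"])
    counts["total"] = counts.sum(axis=1)
    col_totals = {
        col: sum(1 for v in col_values if v == col)
        for col in counts.columns
        if col != "total"
    }
    col_totals["total"] = len(cases)
    out = pd.DataFrame(index=counts.index)
    for col in counts.columns:
        out[col] = counts[col]
        out[f"{col}_pct"] = [
            percent(int(v), col_totals[col]) for v in counts[col]
        ]
    out.attrs["column_totals"] = col_totals
    return out


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("count table has a zero margin")
    return row * col / total


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test, Σ(O−E)²/E, no continuity correction.

    Carries a ``fisher_recommended`` advisory flag when any expected cell
    is below 5.
    """
    table = np.asarray(table, dtype=float)
    expected = expected_counts(table)  # raises on degenerate margins
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        method="chi_square",
        fisher_recommended=bool((expected < 5).any()),
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    The two-sided p sums the hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed that of
    the observed table (probability-ordering definition).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("fisher_exact requires a non-negative 2x2 table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        statistic=float(stats.fisher_exact(table)[0]),
        df=None,
        p_value=float(p),
        method="fisher_exact",
    )


def choose_test(table) -> TestResult:
    """Chi-square, or Fisher for a 2×2 with any expected cell < 5."""
    table = np.asarray(table)
    expected = expected_counts(table)
    if table.shape == (2, 2) and (expected < 5).any():
        return fisher_exact(table)
    return chi_square_test(table)


def _distribution(cases: list[CaseReport], variable: str) -> dict:
    total = len(cases)
    out: dict[str, dict] = {}
    values = [case_field(c, variable) for c in cases]
    for level in sorted(set(values)):
        n = values.count(level)
        out[level] = {"n": n, "pct": percent(n, total)}
    return out


def characterize_fatal(
    cases: list[CaseReport],
    dictionary: TermDictionary | None = None,
    soc_filter: str | None = None,
    pt_filter: str | None = None,
) -> dict:
    """Characterise fatal reports within an (optionally filtered) subset.

    Restricts *cases* to the event-filtered subset (reports with ≥1 PT
    under *soc_filter*, then optionally with *pt_filter* among their PTs),
    and reports the fatal count and proportion of that subset, the PT
    frequency ranking among fatal cases (ties broken alphabetically), and
    the sex, age-group and exposure distributions of the fatal cases.
    """
    subset = cases
    if soc_filter is not None:
        if dictionary is None:
            raise ValueError("soc_filter requires a dictionary")
        subset = [
            c
            for c in subset
            if any(
                pt in dictionary and dictionary.soc(pt) == soc_filter
                for pt in c.pts()
            )
        ]
    if pt_filter is not None:
        subset = [c for c in subset if pt_filter in c.pts()]
    fatal = [c for c in subset if "died" in c.outcomes]
    pt_counts: dict[str, int] = {}
    for c in fatal:
        for pt in c.pts():
            pt_counts[pt] = pt_counts.get(pt, 0) + 1
    ranking = sorted(pt_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_subset": len(subset),
        "n_fatal": len(fatal),
        "fatal_pct": percent(len(fatal), len(subset)),
        "pt_ranking": [
            {"pt": pt, "n": n, "pct": percent(n, len(fatal))}
            for pt, n in ranking
        ],
        "sex": _distribution(fatal, "sex"),
        "age_group": _distribution(fatal, "age_group"),
        "exposure": _distribution(fatal, "exposure"),
    }
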