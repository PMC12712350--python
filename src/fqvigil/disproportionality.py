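"""Reporting-odds-ratio (ROR) disproportionality screening.

For each (exposure stratum, event term) pair a 2×2 contingency table is
built over case reports:

    a = exposed cases with the event        b = exposed cases without it
    c = non-exposed cases with the event    d = non-exposed cases without it

with ROR = (a·d)/(b·c) and a log-Wald 95% CI,
``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.  When any cell is zero
the Haldane–Anscombe correction adds 0.5 to all four cells (flagged in the
output).  A pair is a signal when ROR > 1, the CI lower bound exceeds 1,
and at least ``min_cases`` exposed event cases were reported (uncorrected
``a``).  Counting is case-level: a report counts once toward the event side
however many of its PTs map to the term at the requested hierarchy level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from fqvigil.preprocess import classify_exposure
from fqvigil.report_model import CaseReport, TermDictionary

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

LEVELS = ("PT", "HLGT", "SOC")


class UndefinedStratumError(ValueError):
    """Raised when an exposure or comparator margin is empty."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    corrected: bool = False

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d


@dataclass(frozen=True, slots=True)
class SignalResult:
    term: str
    level: str
    exposure: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    is_signal: bool


def ror_estimate(table: ContingencyTable) -> tuple[float, float, float]:
    """ROR point estimate with log-Wald 95% CI.

    Zero cells trigger the Haldane–Anscombe 0.5 correction on all four
    cells; callers can detect this from the returned estimate being based
    on corrected cells via :func:`corrected_table`.
    """
    if table.n_exposed == 0 or table.n_comparator == 0:
        raise UndefinedStratumError(
            "both exposure strata must contain at least one case"
        )
    a, b, c, d = corrected_cells(table)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (
        ror,
        math.exp(log_ror - Z_95 * se),
        math.exp(log_ror + Z_95 * se),
    )


def corrected_cells(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Cells after the Haldane–Anscombe rule (0.5 added iff any cell is 0)."""
    cells = (table.a, table.b, table.c, table.d)
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells)  # type: ignore[return-value]
    return tuple(float(x) for x in cells)  # type: ignore[return-value]


def needs_correction(table: ContingencyTable) -> bool:
    return min(table.a, table.b, table.c, table.d) == 0


def evaluate_signal(
    ror: float, ci_low: float, n_cases: int, min_cases: int = 3
) -> bool:
    """Signal rule: ROR > 1, CI lower bound > 1, and ≥ min_cases cases."""
    return ror > 1 and ci_low > 1 and n_cases >= min_cases


def case_strata(
    cases: list[CaseReport],
) -> list[str]:
    """Exposure category per case ('background' for non-FQ reports)."""
    return [classify_exposure(c).category for c in cases]


def case_terms(
    cases: list[CaseReport], dictionary: TermDictionary, level: str
) -> list[set[str]]:
    """Per-case set of event terms at the requested hierarchy level.

    PTs absent from the dictionary are ignored at HLGT/SOC level (they
    cannot be mapped) but pass through at PT level only when present.
    """
    out = []
    for case in cases:
        terms = set()
        for pt in case.pts():
            if pt in dictionary:
                terms.add(dictionary.map_pt(pt, level))
        out.append(terms)
    return out


def build_table(
    cases: list[CaseReport],
    exposure: str,
    term: str,
    level: str,
    dictionary: TermDictionary,
) -> ContingencyTable:
    """2×2 table for one (exposure, term) pair.

    The comparator stratum is every case not in the exposure stratum
    (for ``all_fq``, every non-FQ/background case).
    """
    if term not in dictionary.terms_at(level):
        raise KeyError(f"unknown {level} term {term!r}")
    strata = case_strata(cases)
    terms = case_terms(cases, dictionary, level)
    return _table_from_strata(strata, terms, exposure, term)


def _table_from_strata(
    strata: list[str], terms: list[set[str]], exposure: str, term: str
) -> ContingencyTable:
    a = b = c = d = 0
    for stratum, term_set in zip(strata, terms):
        if exposure == "all_fq":
            exposed = stratum != "background"
        else:
            exposed = stratum == exposure
        has_event = term in term_set
        if exposed:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def screen(
    cases: list[CaseReport],
    dictionary: TermDictionary,
    exposures: list[str] | None = None,
    levels: tuple[str, ...] = LEVELS,
    min_display_cases: int = 3,
    min_signal_cases: int = 3,
) -> list[SignalResult]:
    """Screen every (exposure, term, level) pair with ≥ min_display_cases.

    Also emits pooled ``all_fq`` rows (all FQ-exposed cases vs background).
    Results are sorted by level, then descending ROR, then term.  No
    multiplicity adjustment is applied to the signal rule.
    """
    strata = case_strata(cases)
    observed = sorted({s for s in strata if s != "background"})
    if exposures is None:
        exposures = observed + ["all_fq"]
    results: list[SignalResult] = []
    for level in levels:
        terms = case_terms(cases, dictionary, level)
        level_terms = sorted({t for ts in terms for t in ts})
        for exposure in exposures:
            for term in level_terms:
                table = _table_from_strata(strata, terms, exposure, term)
                if table.a < min_display_cases:
                    continue
                if table.n_exposed == 0 or table.n_comparator == 0:
                    continue
                ror, lo, hi = ror_estimate(table)
                if needs_correction(table):
                    table = ContingencyTable(
                        table.a, table.b, table.c, table.d, corrected=True
                    )
                results.append(
                    SignalResult(
                        term=term,
                        level=level,
                        exposure=exposure,
                        table=table,
                        ror=ror,
                        ci_low=lo,
                        ci_high=hi,
                        n_cases=table.a,
                        is_signal=evaluate_signal(
                            ror, lo, table.a, min_signal_cases
                        ),
                    )
                )
    level_order = {lvl: i for i, lvl in enumerate(LEVELS)}
    results.sort(key=lambda r: (level_order[r.level], -r.ror, r.term, r.exposure))
    return results


def results_to_rows(results: list[SignalResult]) -> list[dict]:
    """Flatten results for TSV export (forest-plot-ready)."""
    return [
        {
            "exposure": r.exposure,
            "level": r.level,
            "term": r.term,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "corrected": r.table.corrected,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "n_cases": r.n_cases,
            "is_signal": r.is_signal,
        }
        for r in results
    ]
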