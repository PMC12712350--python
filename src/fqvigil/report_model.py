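"""Canonical in-memory schema for spontaneous adverse-event case reports.

A :class:`CaseReport` is one report from a FAERS-dashboard-style extract:
demographics, outcome flags, drug mentions (with roles and ATC codes) and
reaction mentions coded as MedDRA-style preferred terms (PTs).  A
:class:`TermDictionary` maps each PT to its single primary high-level group
term (HLGT) and system organ class (SOC).

The CSV dialect is fixed (see ``CASE_COLUMNS``): list-valued fields are
";"-joined, sub-fields within a drug or reaction are "|"-separated, and
ATC codes within a drug are ","-separated.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unspecified")
REPORTERS = ("consumer", "healthcare_professional", "unspecified")
OUTCOME_FLAGS = (
    "died",
    "life_threatening",
    "hospitalized",
    "disabled",
    "other_serious",
    "non_serious",
)
DRUG_ROLES = ("suspect", "concomitant")

#: fixed column contract for cases.csv (dialect version 1)
CASE_COLUMNS = [
    "case_id",
    "receive_date",
    "sex",
    "age_years",
    "country",
    "reporter",
    "outcomes",
    "indications",
    "drugs",
    "reactions",
]

LIST_SEP = ";"
FIELD_SEP = "|"
ATC_SEP = ","

_ATC_RE = re.compile(r"^[A-Z]\d\d")
_WS_RE = re.compile(r"\s+")


class SchemaError(ValueError):
    """Raised when a file does not match the documented column contract."""


class ValidationError(ValueError):
    """Raised when record contents violate the data-model invariants."""


class DictionaryError(ValueError):
    """Raised when the PT hierarchy is inconsistent."""


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim and collapse internal whitespace.

    Brand and generic mentions of the same agent are pooled downstream, so
    names must compare equal after this normalisation.
    """
    return _WS_RE.sub(" ", name.strip().lower())


@dataclass(frozen=True, slots=True)
class DrugMention:
    """One drug listed on a report (suspect or concomitant), with ATC codes."""

    name: str
    role: str = "suspect"
    atc_codes: frozenset[str] = frozenset()
    start_date: dt.date | None = None

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("drug name must be non-empty")
        if self.role not in DRUG_ROLES:
            raise ValidationError(f"unknown drug role {self.role!r}")
        for code in self.atc_codes:
            if not _ATC_RE.match(code):
                raise ValidationError(f"malformed ATC code {code!r}")


@dataclass(frozen=True, slots=True)
class ReactionMention:
    """One adverse reaction on a report, coded as a preferred term."""

    pt: str
    event_date: dt.date | None = None

    def validate(self) -> None:
        if not self.pt:
            raise ValidationError("reaction PT must be non-empty")


@dataclass(slots=True)
class CaseReport:
    """One spontaneous adverse-event report."""

    case_id: str
    receive_date: dt.date
    sex: str = "unspecified"
    age_years: float | None = None
    country: str = "unspecified"
    reporter: str = "unspecified"
    outcomes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[ReactionMention] = field(default_factory=list)

    def validate(self) -> None:
        if not self.case_id:
            raise ValidationError("case_id must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.reporter not in REPORTERS:
            raise ValidationError(f"unknown reporter {self.reporter!r}")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise ValidationError(
                f"age_years {self.age_years} outside [0, 120]"
            )
        if not self.outcomes:
            raise ValidationError("outcomes must be non-empty")
        for o in self.outcomes:
            if o not in OUTCOME_FLAGS:
                raise ValidationError(f"unknown outcome flag {o!r}")
        if not self.drugs:
            raise ValidationError("drugs must be non-empty")
        if not self.reactions:
            raise ValidationError("reactions must be non-empty")
        for d in self.drugs:
            d.validate()
        for r in self.reactions:
            r.validate()

    def suspect_drugs(self) -> list[DrugMention]:
        return [d for d in self.drugs if d.role == "suspect"]

    def pts(self) -> set[str]:
        return {r.pt for r in self.reactions}


class TermDictionary:
    """PT → (primary HLGT, primary SOC) mapping.

    The mapping must be functional at both levels: each PT has exactly one
    primary HLGT and SOC, and no HLGT may sit under two SOCs.
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        hlgt_soc: dict[str, str] = {}
        for pt, (hlgt, soc) in entries.items():
            prev = hlgt_soc.get(hlgt)
            if prev is not None and prev != soc:
                raise DictionaryError(
                    f"HLGT {hlgt!r} listed under two SOCs: {prev!r}, {soc!r}"
                )
            hlgt_soc[hlgt] = soc
        self._entries = dict(entries)
        self._hlgt_soc = hlgt_soc

    @property
    def entries(self) -> dict[str, tuple[str, str]]:
        return dict(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return pt in self._entries

    def hlgt(self, pt: str) -> str:
        return self._entries[pt][0]

    def soc(self, pt: str) -> str:
        return self._entries[pt][1]

    def map_pt(self, pt: str, level: str) -> str:
        """Map a PT to itself, its primary HLGT, or its primary SOC."""
        if level == "PT":
            if pt not in self._entries:
                raise KeyError(pt)
            return pt
        if level == "HLGT":
            return self.hlgt(pt)
        if level == "SOC":
            return self.soc(pt)
        raise ValueError(f"unknown hierarchy level {level!r}")

    def terms_at(self, level: str) -> set[str]:
        if level == "PT":
            return set(self._entries)
        if level == "HLGT":
            return {h for h, _ in self._entries.values()}
        if level == "SOC":
            return {s for _, s in self._entries.values()}
        raise ValueError(f"unknown hierarchy level {level!r}")

    def pts_under(self, term: str, level: str) -> set[str]:
        """All PTs whose primary mapping at *level* is *term*."""
        if level == "PT":
            return {term} if term in self._entries else set()
        idx = 0 if level == "HLGT" else 1
        return {
            pt for pt, parents in self._entries.items() if parents[idx] == term
        }


def severity_class(case: CaseReport) -> str:
    """Collapse outcome flags into one ordered severity class.

    ``critical`` (life-threatening or fatal) takes precedence over
    ``serious`` (hospitalised, disabled or other serious), which takes
    precedence over ``non_serious``; every case gets exactly one class.
    """
    if case.outcomes & {"died", "life_threatening"}:
        return "critical"
    if case.outcomes & {"hospitalized", "disabled", "other_serious"}:
        return "serious"
    return "non_serious"


# ---------------------------------------------------------------------------
# CSV dialect


def _parse_date(text: str) -> dt.date | None:
    if not text:
        return None
    return dt.date.fromisoformat(text)


def _fmt_date(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def _parse_drug(text: str) -> DrugMention:
    parts = text.split(FIELD_SEP)
    if len(parts) < 2:
        raise ValidationError(f"malformed drug sub-field {text!r}")
    name, role = parts[0], parts[1]
    atc = frozenset(
        c for c in (parts[2].split(ATC_SEP) if len(parts) > 2 else []) if c
    )
    start = _parse_date(parts[3]) if len(parts) > 3 else None
    return DrugMention(
        name=normalize_drug_name(name), role=role, atc_codes=atc,
        start_date=start,
    )


def _fmt_drug(d: DrugMention) -> str:
    return FIELD_SEP.join(
        [d.name, d.role, ATC_SEP.join(sorted(d.atc_codes)),
         _fmt_date(d.start_date)]
    )


def _parse_reaction(text: str) -> ReactionMention:
    parts = text.split(FIELD_SEP)
    return ReactionMention(
        pt=parts[0],
        event_date=_parse_date(parts[1]) if len(parts) > 1 else None,
    )


def _fmt_reaction(r: ReactionMention) -> str:
    return FIELD_SEP.join([r.pt, _fmt_date(r.event_date)])


def _parse_row(row: dict[str, str]) -> CaseReport:
    age_text = row["age_years"].strip()
    case = CaseReport(
        case_id=row["case_id"].strip(),
        receive_date=dt.date.fromisoformat(row["receive_date"].strip()),
        sex=row["sex"].strip() or "unspecified",
        age_years=float(age_text) if age_text else None,
        country=row["country"].strip() or "unspecified",
        reporter=row["reporter"].strip() or "unspecified",
        outcomes=frozenset(
            o for o in row["outcomes"].split(LIST_SEP) if o
        ),
        indications=frozenset(
            i for i in row["indications"].split(LIST_SEP) if i
        ),
        drugs=[_parse_drug(t) for t in row["drugs"].split(LIST_SEP) if t],
        reactions=[
            _parse_reaction(t) for t in row["reactions"].split(LIST_SEP) if t
        ],
    )
    case.validate()
    return case


def read_cases(
    path, *, strict_terms: TermDictionary | None = None
) -> tuple[list[CaseReport], list[dict]]:
    """Read a cases.csv file.

    Returns ``(cases, errors)`` where *errors* collects malformed rows as
    ``{"row": 1-based data row number, "case_id": ..., "error": message}``
    rather than silently dropping them.  A missing mandatory column raises
    :class:`SchemaError`; duplicate case ids raise :class:`ValidationError`
    naming the offenders.  When *strict_terms* is given, every reaction PT
    must be present in that dictionary.
    """
    cases: list[CaseReport] = []
    errors: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            line for line in fh if not line.startswith("#")
        )
        if reader.fieldnames is None:
            raise SchemaError("empty file: no header row")
        missing = set(CASE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                case = _parse_row(row)
                if strict_terms is not None:
                    for pt in case.pts():
                        if pt not in strict_terms:
                            raise ValidationError(
                                f"PT {pt!r} not in dictionary"
                            )
                cases.append(case)
            except (ValidationError, ValueError) as exc:
                errors.append(
                    {"row": i, "case_id": row.get("case_id", ""),
                     "error": str(exc)}
                )
    seen: dict[str, int] = {}
    dupes = []
    for c in cases:
        seen[c.case_id] = seen.get(c.case_id, 0) + 1
    dupes = sorted(cid for cid, n in seen.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate case_id values: {dupes}")
    return cases, errors


def write_cases(cases: list[CaseReport], path) -> None:
    """Write cases in the fixed CSV dialect (round-trips with read_cases)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# fqvigil cases.csv dialect v1\n")
        writer = csv.writer(fh)
        writer.writerow(CASE_COLUMNS)
        for c in cases:
            writer.writerow(
                [
                    c.case_id,
                    c.receive_date.isoformat(),
                    c.sex,
                    "" if c.age_years is None else format(c.age_years, "g"),
                    c.country,
                    c.reporter,
                    LIST_SEP.join(sorted(c.outcomes)),
                    LIST_SEP.join(sorted(c.indications)),
                    LIST_SEP.join(_fmt_drug(d) for d in c.drugs),
                    LIST_SEP.join(_fmt_reaction(r) for r in c.reactions),
                ]
            )


def read_dictionary(path) -> TermDictionary:
    """Read a ``pt,hlgt,soc`` CSV into a :class:`TermDictionary`.

    Exact duplicate rows are collapsed with a warning; the same PT under
    two different parents is a consistency error.
    """
    entries: dict[str, tuple[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"pt", "hlgt", "soc"} <= set(
            reader.fieldnames
        ):
            raise SchemaError("dictionary.csv requires columns pt, hlgt, soc")
        for row in reader:
            pt = row["pt"].strip()
            parents = (row["hlgt"].strip(), row["soc"].strip())
            if pt in entries:
                if entries[pt] == parents:
                    logger.warning("duplicate dictionary row for PT %r", pt)
                    continue
                raise DictionaryError(
                    f"PT {pt!r} listed with conflicting parents "
                    f"{entries[pt]} and {parents}"
                )
            entries[pt] = parents
    return TermDictionary(entries)


def write_dictionary(dictionary: TermDictionary, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pt", "hlgt", "soc"])
        for pt, (hlgt, soc) in sorted(dictionary.entries.items()):
            writer.writerow([pt, hlgt, soc])
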