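"""Synthetic reconstruction of the published FQ report cohort margins.

The real 2011–2024 fluoroquinolone extract sits behind the FAERS Public
Dashboard and cannot be shipped; this module builds a synthetic stand-in
cohort whose marginal counts equal the published totals of that extract
(44 895 reports; 8518 psychiatric and 4367 eye cases; the sex, exposure,
combination-subtype and fatality breakdowns of the psychiatric subset).
Only the asserted margins are faithful — joint structure beyond them is
filled in arbitrarily — so the cohort is a fixture for verifying that the
descriptive operations reproduce the published count/proportion
arithmetic, not a substitute for real data.
"""

from __future__ import annotations

import datetime as dt
import itertools

from fqvigil.report_model import CaseReport, DrugMention, ReactionMention

#: published margins of the FQ adverse-event-report cohort (FAERS dashboard,
#: 2011–2024, post-deduplication/exclusion)
TOTAL_CASES = 44895
PSYCHIATRIC_CASES = 8518
EYE_CASES = 4367
FATAL_TOTAL = 1163

PSYCH_SEX = {"male": 3254, "female": 4753, "unspecified": 511}
PSYCH_EXPOSURE = {
    "ciprofloxacin": 2472,
    "levofloxacin": 1614,
    "moxifloxacin": 745,
    "ofloxacin": 56,
    "gemifloxacin": 5,
    "delafloxacin": 9,
    "combination": 3617,
}
PSYCH_COMBINATION_SUBTYPE = {
    "fq_plus_other_meds": 2627,
    "multiple_fqs": 536,
    "fq_plus_antibiotics": 454,
}
PSYCH_FATAL = 143
PSYCH_FATAL_MALE = 89
SUICIDE_FATAL = 54
SUICIDE_SEX = {"male": 42, "female": 6, "unspecified": 6}
EYE_FATAL = 37

_RECEIVE = dt.date(2018, 6, 1)

_COMBO_DRUGS = {
    "multiple_fqs": [
        DrugMention("ciprofloxacin", "suspect", frozenset({"J01MA02"})),
        DrugMention("levofloxacin", "suspect", frozenset({"J01MA12"})),
    ],
    "fq_plus_antibiotics": [
        DrugMention("ciprofloxacin", "suspect", frozenset({"J01MA02"})),
        DrugMention("metronidazole", "concomitant", frozenset({"J01XD01"})),
    ],
    "fq_plus_other_meds": [
        DrugMention("ciprofloxacin", "suspect", frozenset({"J01MA02"})),
        DrugMention("aspirin", "concomitant", frozenset({"N02BA01"})),
    ],
}

_FQ_ATC = {
    "ciprofloxacin": "J01MA02",
    "levofloxacin": "J01MA12",
    "moxifloxacin": "J01MA14",
    "ofloxacin": "J01MA01",
    "gemifloxacin": "J01MA15",
    "delafloxacin": "J01MA21",
}


def _case(case_id, sex, outcomes, drugs, pts, age=50.0) -> CaseReport:
    return CaseReport(
        case_id=case_id,
        receive_date=_RECEIVE,
        sex=sex,
        age_years=age,
        outcomes=frozenset(outcomes),
        drugs=drugs,
        reactions=[ReactionMention(pt) for pt in pts],
    )


def build_reference_cohort() -> list[CaseReport]:
    """Assemble the synthetic margin-faithful cohort (44 895 cases).

    Psychiatric cases carry the PT ``anxiety`` (suicide deaths carry
    ``completed suicide``), eye cases ``vision blurred``, and the
    remainder ``tendonitis``; all PTs are in the bundled mini-dictionary
    so SOC-level filters behave as on real data.
    """
    ids = (f"R{i:06d}" for i in itertools.count())
    cases: list[CaseReport] = []

    # psychiatric subset: sex sequence honouring the fatal/suicide margins
    sex_seq: list[tuple[str, frozenset, list[str]]] = []
    for sex, n in SUICIDE_SEX.items():
        sex_seq += [(sex, frozenset({"died"}), ["completed suicide"])] * n
    other_fatal_male = PSYCH_FATAL_MALE - SUICIDE_SEX["male"]
    other_fatal = PSYCH_FATAL - SUICIDE_FATAL
    # non-suicide fatal cases spread over several psychiatric PTs so the
    # completed-suicide count (54) stays the top-ranked fatal term
    spread = itertools.cycle(
        ["confusional state", "delirium", "depression",
         "insomnia", "hallucination"]
    )
    sex_seq += [
        ("male", frozenset({"died"}), [next(spread)])
    ] * other_fatal_male
    sex_seq += [
        ("female", frozenset({"died"}), [next(spread)])
    ] * (other_fatal - other_fatal_male)
    nonfatal_sex = {
        "male": PSYCH_SEX["male"] - PSYCH_FATAL_MALE,
        "female": PSYCH_SEX["female"]
        - SUICIDE_SEX["female"]
        - (other_fatal - other_fatal_male),
        "unspecified": PSYCH_SEX["unspecified"] - SUICIDE_SEX["unspecified"],
    }
    for sex, n in nonfatal_sex.items():
        sex_seq += [(sex, frozenset({"other_serious"}), ["anxiety"])] * n
    assert len(sex_seq) == PSYCHIATRIC_CASES

    # exposure sequence with the published per-FQ / combination counts
    drug_seq: list[list[DrugMention]] = []
    for fq, n in PSYCH_EXPOSURE.items():
        if fq == "combination":
            for subtype, m in PSYCH_COMBINATION_SUBTYPE.items():
                drug_seq += [_COMBO_DRUGS[subtype]] * m
        else:
            drug_seq += [
                [DrugMention(fq, "suspect", frozenset({_FQ_ATC[fq]}))]
            ] * n
    assert len(drug_seq) == PSYCHIATRIC_CASES

    for (sex, outcomes, pts), drugs in zip(sex_seq, drug_seq):
        cases.append(_case(next(ids), sex, outcomes, drugs, pts))

    cipro = [DrugMention("ciprofloxacin", "suspect", frozenset({"J01MA02"}))]
    for i in range(EYE_CASES):
        outcomes = {"died"} if i < EYE_FATAL else {"other_serious"}
        cases.append(
            _case(next(ids), "female", outcomes, cipro, ["vision blurred"])
        )

    other = TOTAL_CASES - PSYCHIATRIC_CASES - EYE_CASES
    other_fatal_n = FATAL_TOTAL - PSYCH_FATAL - EYE_FATAL
    for i in range(other):
        outcomes = {"died"} if i < other_fatal_n else {"other_serious"}
        cases.append(
            _case(next(ids), "male", outcomes, cipro, ["tendonitis"])
        )
    assert len(cases) == TOTAL_CASES
    return cases
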