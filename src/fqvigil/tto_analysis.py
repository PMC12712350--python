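"""Time-to-onset (TTO) analysis and rank-based group comparisons.

TTO for a case is the whole-day interval from the earliest suspect
fluoroquinolone start date to the earliest event date among reactions
mapping to the analysed system organ class.  Cases missing either date are
dropped (and accounted for); negative intervals are dropped as
inconsistent rather than clamped, since same-day onset (day 0) is already
a valid sample.

Group comparisons use the Wilcoxon rank-sum test — exact permutation
distribution of the midrank sum (tie-safe, computed by dynamic
programming) for groups of at most 20 each, tie-corrected normal
approximation above — and the tie-corrected Kruskal–Wallis omnibus test
with Benjamini–Hochberg-adjusted pairwise rank-sum comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from fqvigil.descriptive_stats import TestResult
from fqvigil.preprocess import classify_exposure, derive_age_group
from fqvigil.report_model import CaseReport, TermDictionary, severity_class

EXACT_MAX_PER_GROUP = 20


@dataclass(frozen=True, slots=True)
class TTOSample:
    case_id: str
    exposure: str
    tto_days: int
    sex: str
    age_group: str
    therapy: str  # "monotherapy" or "combination"


@dataclass(frozen=True, slots=True)
class Dropped:
    case_id: str
    reason: str  # "missing" or "inconsistent" or "no_qualifying_event"


def compute_tto(
    case: CaseReport,
    soc_filter: str,
    dictionary: TermDictionary,
) -> TTOSample | Dropped:
    """TTO sample for one case, or the drop reason (drops are data)."""
    exposure = classify_exposure(case)
    fq_starts = [
        d.start_date
        for d in case.suspect_drugs()
        if d.name in dictionary_fq_names() and d.start_date is not None
    ]
    event_dates = [
        r.event_date
        for r in case.reactions
        if r.pt in dictionary
        and dictionary.soc(r.pt) == soc_filter
        and r.event_date is not None
    ]
    has_qualifying = any(
        r.pt in dictionary and dictionary.soc(r.pt) == soc_filter
        for r in case.reactions
    )
    if not has_qualifying:
        return Dropped(case.case_id, "no_qualifying_event")
    if not fq_starts or not event_dates:
        return Dropped(case.case_id, "missing")
    tto = (min(event_dates) - min(fq_starts)).days
    if tto < 0:
        return Dropped(case.case_id, "inconsistent")
    return TTOSample(
        case_id=case.case_id,
        exposure=exposure.category,
        tto_days=tto,
        sex=case.sex,
        age_group=derive_age_group(case.age_years),
        therapy=(
            "combination"
            if exposure.category == "combination"
            else "monotherapy"
        ),
    )


def dictionary_fq_names() -> frozenset[str]:
    from fqvigil.preprocess import FQ_NAMES

    return FQ_NAMES


def compute_tto_samples(
    cases: list[CaseReport],
    soc_filter: str,
    dictionary: TermDictionary,
) -> tuple[list[TTOSample], dict[str, int]]:
    """TTO samples for every FQ-exposed case with a qualifying event."""
    samples: list[TTOSample] = []
    drops: dict[str, int] = {}
    for case in cases:
        if classify_exposure(case).category == "background":
            continue
        result = compute_tto(case, soc_filter, dictionary)
        if isinstance(result, TTOSample):
            samples.append(result)
        else:
            drops[result.reason] = drops.get(result.reason, 0) + 1
    return samples, drops


def ecdf(samples: list[int] | list[TTOSample]) -> dict:
    """Right-continuous empirical CDF step points plus summary quantities.

    Returns ``{"points": [(t, F(t)), ...], "median": ..., "n": ...,
    "fraction_within_7_days": ...}``; F at the largest t is exactly 1.
    """
    values = [
        s.tto_days if isinstance(s, TTOSample) else int(s) for s in samples
    ]
    if not values:
        raise ValueError("ecdf requires at least one sample")
    arr = np.sort(np.asarray(values))
    n = len(arr)
    ts, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts)
    points = [(int(t), float(c) / n) for t, c in zip(ts, cum)]
    return {
        "points": points,
        "n": n,
        "median": float(np.median(arr)),
        "fraction_within_7_days": float(np.mean(arr <= 7)),
    }


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for the midrank-sum statistic.

    Enumerates the permutation distribution of the rank sum of the first
    group over all C(n1+n2, n1) assignments via dynamic programming on
    doubled midranks (integers even with ties), and sums the probability
    of deviations at least as large as observed.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    n1 = len(x)
    w_obs = int(ranks2[:n1].sum())
    total = int(ranks2.sum())
    # mean of the doubled rank sum: n1 * total / N (exact in rationals;
    # compare deviations as |N*w - n1*total| to stay in integers)
    n_total = len(pooled)
    dev_obs = abs(n_total * w_obs - n1 * total)
    # dp[j][s] = number of j-subsets of ranks2 with doubled-rank sum s
    dp = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for j in range(min(n1, n_total) - 1, -1, -1):
            if not dp[j]:
                continue
            nxt = dp[j + 1]
            for s, cnt in dp[j].items():
                nxt[s + r] = nxt.get(s + r, 0) + cnt
    n_extreme = sum(
        cnt
        for s, cnt in dp[n1].items()
        if abs(n_total * s - n1 * total) >= dev_obs
    )
    from math import comb

    return n_extreme / comb(n_total, n1)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact permutation p for group sizes ≤ 20 each; tie-corrected normal
    approximation (with continuity correction) otherwise.  The reported
    statistic is the rank sum of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    w = float(stats.rankdata(np.concatenate([x, y]))[: len(x)].sum())
    if len(x) <= EXACT_MAX_PER_GROUP and len(y) <= EXACT_MAX_PER_GROUP:
        p = _rank_sum_exact_p(x, y)
        method = "wilcoxon_exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        p = float(res.pvalue)
        method = "wilcoxon"
    return TestResult(statistic=w, df=None, p_value=min(p, 1.0), method=method)


def kruskal_wallis(groups: list) -> tuple[TestResult, dict]:
    """Tie-corrected Kruskal–Wallis omnibus plus BH-adjusted pairwise tests.

    Returns ``(omnibus, pairwise)`` where *pairwise* maps group-index pairs
    (i, j) to ``{"p": raw, "p_adjusted": BH}``; the pairwise Wilcoxon
    rank-sum p-values are adjusted as one family.  All observations
    identical → H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        omnibus = TestResult(
            statistic=0.0,
            df=len(arrays) - 1,
            p_value=1.0,
            method="kruskal_wallis",
        )
    else:
        stat, p = stats.kruskal(*arrays)
        omnibus = TestResult(
            statistic=float(stat),
            df=len(arrays) - 1,
            p_value=float(p),
            method="kruskal_wallis",
        )
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    raw = [wilcoxon_rank_sum(arrays[i], arrays[j]).p_value for i, j in pairs]
    adjusted = bh_adjust(raw)
    pairwise = {
        pair: {"p": raw[k], "p_adjusted": adjusted[k]}
        for k, pair in enumerate(pairs)
    }
    return omnibus, pairwise


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p(i) by m/i, enforce monotone non-decreasing
    from the largest rank down, cap at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


def tto_group_summary(
    samples: list[TTOSample], by: str
) -> tuple[dict, TestResult | None, dict | None]:
    """Per-group n/median/IQR/fraction≤7d plus the appropriate rank test.

    *by* is one of ``exposure``, ``sex``, ``age_group``, ``therapy``.
    Two groups → Wilcoxon rank-sum; three or more → Kruskal–Wallis with
    BH-adjusted pairwise comparisons (returned keyed by group names).
    """
    if by not in {"exposure", "sex", "age_group", "therapy"}:
        raise KeyError(f"unknown grouping {by!r}")
    grouped: dict[str, list[int]] = {}
    for s in samples:
        grouped.setdefault(getattr(s, by), []).append(s.tto_days)
    names = sorted(grouped)
    summary = {}
    for name in names:
        vals = np.asarray(grouped[name])
        summary[name] = {
            "n": int(vals.size),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "fraction_within_7_days": float(np.mean(vals <= 7)),
        }
    if len(names) < 2:
        return summary, None, None
    if len(names) == 2:
        test = wilcoxon_rank_sum(grouped[names[0]], grouped[names[1]])
        return summary, test, None
    omnibus, pairwise_idx = kruskal_wallis([grouped[n] for n in names])
    pairwise = {
        (names[i], names[j]): v for (i, j), v in pairwise_idx.items()
    }
    return summary, omnibus, pairwise
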