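"""Synthetic FAERS-like report generator with planted reporting odds ratios.

The generator emits case reports whose drug–event association structure is
known exactly: for exposure stratum *e* and preferred term *pt*, the odds
of reporting *pt* are ``psi(e, pt) × baseline_odds(pt)``, so the true
reporting odds ratio of the pair against the pooled remaining strata is
``psi`` whenever the other strata are left at ψ = 1.  On top of the event
mechanism it injects exact duplicates (cloned matching-key fields under a
fresh case id), per-field missingness, psychotropic co-medication, and
log-normal onset intervals — so deduplication, exclusion filtering,
disproportionality, time-to-onset and risk-factor code paths all see
realistic data with recoverable ground truth.

All randomness flows from one integer seed; sub-streams are derived by
counter so that, e.g., missingness masks do not perturb event draws.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from fqvigil.report_model import (
    CaseReport,
    DrugMention,
    ReactionMention,
    TermDictionary,
)

EPOCH = dt.date(2011, 1, 1)
N_DAYS = (dt.date(2024, 12, 31) - EPOCH).days  # 14-year reporting window

FQ_ATC = {
    "ciprofloxacin": "J01MA02",
    "levofloxacin": "J01MA12",
    "moxifloxacin": "J01MA14",
    "ofloxacin": "J01MA01",
    "gemifloxacin": "J01MA15",
    "delafloxacin": "J01MA21",
}

#: non-FQ co-medications used when building combination and background cases
OTHER_ANTIBIOTICS = [("metronidazole", "J01XD01"), ("amoxicillin", "J01CA04")]
OTHER_MEDS = [
    ("aspirin", "N02BA01"),
    ("levothyroxine", "H03AA01"),
    ("paracetamol", "N02BE01"),
]
BACKGROUND_DRUGS = [
    ("lisinopril", "C09AA03"),
    ("metformin", "A10BA02"),
    ("ibuprofen", "M01AE01"),
    ("omeprazole", "A02BC01"),
]
PSYCHOTROPICS = [("sertraline", "N06AB06"), ("diazepam", "N05BA01")]

INDICATIONS = [
    "urinary tract infection",
    "pneumonia",
    "sinusitis",
    "bronchitis",
    "skin infection",
    "hypertension",
    "pain",
]

COMBINATION_CATEGORIES = (
    "multiple_fqs",
    "fq_plus_antibiotics",
    "fq_plus_other_meds",
)

_AGE_RANGES = {
    "0-17": (0.0, 18.0),
    "18-34": (18.0, 35.0),
    "35-64": (35.0, 65.0),
    "65+": (65.0, 95.0),
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


def default_dictionary() -> TermDictionary:
    """Synthetic mini-dictionary of PT → (primary HLGT, primary SOC).

    A small stand-in for the licensed MedDRA hierarchy, covering the
    psychiatric and eye SOCs the pipeline screens plus background SOCs
    so that non-event reports carry plausible reactions.
    """
    psych = "psychiatric disorders"
    eye = "eye disorders"
    entries = {
        "anxiety": ("anxiety disorders and symptoms", psych),
        "panic attack": ("anxiety disorders and symptoms", psych),
        "insomnia": ("sleep disorders and disturbances", psych),
        "sleep disorder": ("sleep disorders and disturbances", psych),
        "delirium": ("deliria (including confusion)", psych),
        "confusional state": ("deliria (including confusion)", psych),
        "hallucination": ("disturbances in thinking and perception", psych),
        "depression": ("depressed mood disorders and disturbances", psych),
        "suicidal ideation": ("suicidal and self-injurious behaviours", psych),
        "completed suicide": ("suicidal and self-injurious behaviours", psych),
        "vision blurred": ("vision disorders", eye),
        "visual impairment": ("vision disorders", eye),
        "diplopia": ("vision disorders", eye),
        "eye pain": ("eye disorders NEC", eye),
        "dry eye": ("eye disorders NEC", eye),
        "photophobia": ("ocular sensory symptoms", eye),
        "vitreous floaters": (
            "ocular structural changes, deposits and degeneration", eye),
        "iris transillumination defect": (
            "ocular structural changes, deposits and degeneration", eye),
        "pigment dispersion syndrome": (
            "ocular structural changes, deposits and degeneration", eye),
        "eyelid oedema": (
            "ocular infections, irritations and inflammations", eye),
        "tendonitis": (
            "tendon, ligament and cartilage disorders",
            "musculoskeletal and connective tissue disorders"),
        "tendon rupture": (
            "tendon, ligament and cartilage disorders",
            "musculoskeletal and connective tissue disorders"),
        "peripheral neuropathy": (
            "peripheral neuropathies", "nervous system disorders"),
        "headache": ("headaches", "nervous system disorders"),
        "drug ineffective": (
            "therapeutic and nontherapeutic responses",
            "general disorders and administration site conditions"),
        "fatigue": (
            "general system disorders NEC",
            "general disorders and administration site conditions"),
        "nausea": (
            "gastrointestinal signs and symptoms",
            "gastrointestinal disorders"),
        "diarrhoea": (
            "gastrointestinal signs and symptoms",
            "gastrointestinal disorders"),
        "cardiac arrest": ("cardiac arrhythmias", "cardiac disorders"),
    }
    return TermDictionary(entries)


def default_exposure_probs(background: float = 0.5) -> dict[str, float]:
    """Exposure mix shaped like the observed FQ report composition.

    Monotherapy shares follow the per-FQ report totals and the combination
    stratum splits into its three subtypes; the remaining probability mass
    is the non-FQ background comparator.
    """
    counts = {
        "ciprofloxacin": 12970,
        "levofloxacin": 10636,
        "moxifloxacin": 4425,
        "ofloxacin": 514,
        "gemifloxacin": 82,
        "delafloxacin": 72,
        # combination subtypes: ~72.6% other meds / 14.8% multi-FQ /
        # 12.6% other antibiotics of 16196 combination reports
        "fq_plus_other_meds": 11763,
        "multiple_fqs": 2400,
        "fq_plus_antibiotics": 2033,
    }
    total = sum(counts.values())
    fq_mass = 1.0 - background
    probs = {k: fq_mass * v / total for k, v in counts.items()}
    probs["background"] = background
    return probs


def default_baseline_odds() -> dict[str, float]:
    """Per-PT reporting odds in the non-exposed (background) stratum."""
    return {
        "anxiety": 0.008,
        "panic attack": 0.002,
        "insomnia": 0.008,
        "sleep disorder": 0.003,
        "delirium": 0.002,
        "confusional state": 0.004,
        "hallucination": 0.003,
        "depression": 0.006,
        "suicidal ideation": 0.002,
        "completed suicide": 0.0008,
        "vision blurred": 0.006,
        "visual impairment": 0.004,
        "diplopia": 0.002,
        "eye pain": 0.004,
        "dry eye": 0.004,
        "photophobia": 0.002,
        "vitreous floaters": 0.001,
        "iris transillumination defect": 0.0002,
        "pigment dispersion syndrome": 0.0002,
        "eyelid oedema": 0.001,
        "tendonitis": 0.02,
        "tendon rupture": 0.01,
        "peripheral neuropathy": 0.01,
        "headache": 0.03,
        "drug ineffective": 0.04,
        "fatigue": 0.03,
        "nausea": 0.025,
        "diarrhoea": 0.02,
        "cardiac arrest": 0.003,
    }


def default_planted_or() -> dict[tuple[str, str], float]:
    """Planted true reporting odds ratios (exposure, PT) → ψ.

    Values echo the magnitude of the headline fluoroquinolone signals
    (anxiety ≈ 6, panic attack ≈ 17, photophobia ≈ 13, ...) across the
    widely used FQ strata, plus two moxifloxacin-specific anterior-segment
    signals at large ψ standing in for the extreme-tail iris findings.
    """
    broad = (
        "ciprofloxacin",
        "levofloxacin",
        "moxifloxacin",
        "multiple_fqs",
        "fq_plus_antibiotics",
        "fq_plus_other_meds",
    )
    psi: dict[tuple[str, str], float] = {}
    for exp in broad:
        psi[(exp, "anxiety")] = 6.25
        psi[(exp, "panic attack")] = 17.11
        psi[(exp, "insomnia")] = 6.22
        psi[(exp, "delirium")] = 9.58
        psi[(exp, "hallucination")] = 6.65
        psi[(exp, "suicidal ideation")] = 5.43
        psi[(exp, "vision blurred")] = 4.87
        psi[(exp, "visual impairment")] = 5.67
        psi[(exp, "photophobia")] = 12.54
        psi[(exp, "vitreous floaters")] = 16.96
        psi[(exp, "tendonitis")] = 4.0
        psi[(exp, "tendon rupture")] = 4.0
    psi[("ofloxacin", "eye pain")] = 5.91
    psi[("ofloxacin", "photophobia")] = 12.54
    psi[("moxifloxacin", "iris transillumination defect")] = 200.0
    psi[("moxifloxacin", "pigment dispersion syndrome")] = 100.0
    return psi


def default_demographics() -> dict:
    """Demographic distributions shaped like the report cohort.

    Age is not independent of the rest of the record: per-drug age
    profiles differ sharply (moxifloxacin reports skew elderly,
    ciprofloxacin younger), and serious/fatal outcomes concentrate in the
    elderly — both mirrored here so that imputation and risk-factor code
    paths see the dependence structure they exploit on real data.
    """
    return {
        "sex": {"male": 0.3725, "female": 0.5350, "unspecified": 0.0925},
        "age_group": {"0-17": 0.02, "18-34": 0.17, "35-64": 0.45, "65+": 0.36},
        # overrides the marginal for the listed exposure strata
        "age_group_by_exposure": {
            "ciprofloxacin": {
                "0-17": 0.014, "18-34": 0.29, "35-64": 0.55, "65+": 0.146,
            },
            "levofloxacin": {
                "0-17": 0.012, "18-34": 0.155, "35-64": 0.57, "65+": 0.263,
            },
            "moxifloxacin": {
                "0-17": 0.005, "18-34": 0.105, "35-64": 0.39, "65+": 0.50,
            },
            "ofloxacin": {
                "0-17": 0.16, "18-34": 0.26, "35-64": 0.38, "65+": 0.20,
            },
        },
        # elderly reports carry more fatal/hospitalised outcomes
        "outcomes_by_age_group": {
            "65+": {
                "died": 0.075,
                "life_threatening": 0.075,
                "hospitalized": 0.22,
                "disabled": 0.21,
                "other_serious": 0.33,
                "non_serious": 0.09,
            },
            "0-17": {
                "died": 0.01,
                "life_threatening": 0.04,
                "hospitalized": 0.12,
                "disabled": 0.18,
                "other_serious": 0.43,
                "non_serious": 0.22,
            },
        },
        "country": {
            "US": 0.32, "GB": 0.15, "DE": 0.10, "FR": 0.08, "JP": 0.06,
            "CA": 0.05, "IN": 0.04, "unspecified": 0.20,
        },
        "reporter": {
            "consumer": 0.65,
            "healthcare_professional": 0.30,
            "unspecified": 0.05,
        },
        "outcomes": {
            "died": 0.026,
            "life_threatening": 0.060,
            "hospitalized": 0.140,
            "disabled": 0.250,
            "other_serious": 0.400,
            "non_serious": 0.124,
        },
    }


def default_missing_rates() -> dict[str, float]:
    return {"age": 0.18, "sex": 0.07, "start_date": 0.25, "event_date": 0.25}


def default_tto_model() -> dict[str, tuple[float, float]]:
    """Per-exposure log-normal (μ, σ) onset-day parameters.

    Median onset ≈ exp(μ) days: ~2 days for most strata, delayed (~7.5
    days) for gemifloxacin, matching the observed fast-onset pattern.
    """
    base = (float(np.log(2.0)), 1.0)
    model = {exp: base for exp in FQ_ATC}
    for exp in COMBINATION_CATEGORIES:
        model[exp] = base
    model["gemifloxacin"] = (float(np.log(7.5)), 0.8)
    model["background"] = base
    return model


@dataclass
class SimConfig:
    """Full specification of one synthetic reporting-system dataset."""

    n_cases: int = 10000
    exposure_probs: dict[str, float] = field(
        default_factory=default_exposure_probs
    )
    baseline_event_odds: dict[str, float] = field(
        default_factory=default_baseline_odds
    )
    planted_or: dict[tuple[str, str], float] = field(
        default_factory=default_planted_or
    )
    demographic_marginals: dict = field(default_factory=default_demographics)
    missing_rates: dict[str, float] = field(
        default_factory=default_missing_rates
    )
    duplicate_fraction: float = 0.05
    psychotropic_rate: float = 0.03
    tto_model: dict[str, tuple[float, float]] = field(
        default_factory=default_tto_model
    )
    #: odds multipliers by demographic level, e.g. {"age_group": {"18-34": 2.5}}
    covariate_or: dict[str, dict[str, float]] = field(default_factory=dict)
    filler_pt: str = "drug ineffective"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigError("n_cases must be positive")
        if not (0 <= self.duplicate_fraction < 1):
            raise ConfigError("duplicate_fraction must be in [0, 1)")
        if not (0 <= self.psychotropic_rate < 1):
            raise ConfigError("psychotropic_rate must be in [0, 1)")
        for name, probs in [
            ("exposure_probs", self.exposure_probs),
            ("sex", self.demographic_marginals["sex"]),
            ("age_group", self.demographic_marginals["age_group"]),
            ("country", self.demographic_marginals["country"]),
            ("reporter", self.demographic_marginals["reporter"]),
            ("outcomes", self.demographic_marginals["outcomes"]),
        ] + [
            (f"age_group_by_exposure[{k}]", v)
            for k, v in self.demographic_marginals.get(
                "age_group_by_exposure", {}
            ).items()
        ] + [
            (f"outcomes_by_age_group[{k}]", v)
            for k, v in self.demographic_marginals.get(
                "outcomes_by_age_group", {}
            ).items()
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} has a negative probability")
        for (exp, pt), psi in self.planted_or.items():
            if psi < 0:
                raise ConfigError(f"planted psi for {(exp, pt)} is negative")
            if pt not in self.baseline_event_odds:
                raise ConfigError(f"planted PT {pt!r} has no baseline odds")
        if self.filler_pt not in self.baseline_event_odds:
            raise ConfigError("filler_pt must have a baseline odds entry")


@dataclass
class SimTruth:
    """Ground-truth ledger emitted alongside a simulated dataset."""

    planted_or: dict[tuple[str, str], float]
    #: realized event counts per (exposure, pt) over the analysis set
    #: (unique originals without psychotropic co-medication)
    realized_counts: dict[tuple[str, str], int]
    #: analysis-set stratum sizes per exposure category
    stratum_sizes: dict[str, int]
    #: (original_id, clone_id) pairs injected as duplicates
    duplicate_pairs: list[tuple[str, str]]
    #: case ids carrying psychotropic co-medication (pre-duplication)
    psychotropic_ids: list[str]


def true_ror(config: SimConfig, exposure: str, pt: str) -> float:
    """The analytic ROR the estimator must recover: ψ if planted, else 1."""
    if pt not in config.baseline_event_odds:
        raise KeyError(f"unknown PT {pt!r}")
    return config.planted_or.get((exposure, pt), 1.0)


def _stream(seed: int, k: int) -> np.random.Generator:
    # counter-derived sub-streams: field-level noise never perturbs events
    return np.random.default_rng([k, seed])


def _choice(rng, probs: dict[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p)


def simulate(config: SimConfig) -> tuple[list[CaseReport], SimTruth]:
    """Generate one dataset plus its ground-truth ledger.

    Same config (and seed) → byte-identical output.  Duplicates are cloned
    after generation with a fresh case id and identical matching-key
    fields, so deduplication can find them exactly.
    """
    config.validate()
    n = config.n_cases
    seed = config.seed

    categories = _choice(_stream(seed, 0), config.exposure_probs, n)

    demo_rng = _stream(seed, 1)
    marg = config.demographic_marginals
    sex = _choice(demo_rng, marg["sex"], n)
    age_group = _choice(demo_rng, marg["age_group"], n)
    for cat, dist in sorted(
        marg.get("age_group_by_exposure", {}).items()
    ):  # exposure-specific age profiles override the marginal
        mask = categories == cat
        m = int(mask.sum())
        if m:
            age_group[mask] = _choice(demo_rng, dist, m)
    ages = np.empty(n)
    for group, (lo, hi) in _AGE_RANGES.items():
        mask = age_group == group
        ages[mask] = lo + (hi - lo) * demo_rng.random(int(mask.sum()))
    ages = np.floor(ages)  # reported ages are whole years
    country = _choice(demo_rng, marg["country"], n)
    reporter = _choice(demo_rng, marg["reporter"], n)
    outcome = _choice(demo_rng, marg["outcomes"], n)
    for group, dist in sorted(
        marg.get("outcomes_by_age_group", {}).items()
    ):  # age-dependent outcome severity
        mask = age_group == group
        m = int(mask.sum())
        if m:
            outcome[mask] = _choice(demo_rng, dist, m)
    indication = demo_rng.choice(
        np.asarray(INDICATIONS, dtype=object), size=n
    )

    # per-case odds multiplier from demographic covariate effects
    cov_mult = np.ones(n)
    cov_fields = {"sex": sex, "age_group": age_group}
    for fld, level_or in config.covariate_or.items():
        values = cov_fields[fld]
        for level, mult in level_or.items():
            cov_mult[values == level] *= mult

    # event draws: odds(pt | case) = psi(category, pt) * baseline * cov_mult
    event_rng = _stream(seed, 2)
    pts = list(config.baseline_event_odds)
    psi_lookup = {
        pt: {
            exp: config.planted_or.get((exp, pt), 1.0)
            for exp in config.exposure_probs
        }
        for pt in pts
    }
    event_mat = np.zeros((n, len(pts)), dtype=bool)
    for j, pt in enumerate(pts):
        q = config.baseline_event_odds[pt]
        psi_map = psi_lookup[pt]
        psi = np.asarray([psi_map[c] for c in categories])
        odds = psi * q * cov_mult
        p = odds / (1.0 + odds)
        event_mat[:, j] = event_rng.random(n) < p

    # guarantee >= 1 reaction: cases with no event get the filler PT
    filler_j = pts.index(config.filler_pt)
    no_event = ~event_mat.any(axis=1)
    event_mat[no_event, filler_j] = True

    # dates: receive, FQ start, event = start + log-normal onset days
    date_rng = _stream(seed, 3)
    receive_off = date_rng.integers(0, N_DAYS + 1, size=n)
    start_off = receive_off - date_rng.integers(0, 31, size=n)
    mu = np.asarray([config.tto_model[c][0] for c in categories])
    sigma = np.asarray([config.tto_model[c][1] for c in categories])
    onset = np.rint(np.exp(mu + sigma * date_rng.standard_normal(n)))
    event_off = start_off + onset.astype(int)

    miss_rng = _stream(seed, 4)
    miss_age = miss_rng.random(n) < config.missing_rates.get("age", 0.0)
    miss_sex = miss_rng.random(n) < config.missing_rates.get("sex", 0.0)
    miss_start = miss_rng.random(n) < config.missing_rates.get(
        "start_date", 0.0
    )
    miss_event = miss_rng.random(n) < config.missing_rates.get(
        "event_date", 0.0
    )

    dup_rng = _stream(seed, 5)
    dup_mask = dup_rng.random(n) < config.duplicate_fraction

    psy_rng = _stream(seed, 6)
    psy_mask = psy_rng.random(n) < config.psychotropic_rate
    psy_pick = psy_rng.integers(0, len(PSYCHOTROPICS), size=n)

    drug_rng = _stream(seed, 7)
    # pre-draw drug choices used by combination / background categories
    fq_names = list(FQ_ATC)
    mono_probs = np.asarray(
        [config.exposure_probs.get(f, 0.0) for f in fq_names]
    )
    if mono_probs.sum() <= 0:
        mono_probs = np.ones(len(fq_names))
    mono_probs = mono_probs / mono_probs.sum()
    combo_fq = drug_rng.choice(len(fq_names), size=n, p=mono_probs)
    combo_fq2 = (combo_fq + 1 + drug_rng.integers(0, len(fq_names) - 1,
                                                  size=n)) % len(fq_names)
    abx_pick = drug_rng.integers(0, len(OTHER_ANTIBIOTICS), size=n)
    med_pick = drug_rng.integers(0, len(OTHER_MEDS), size=n)
    bg_pick = drug_rng.integers(0, len(BACKGROUND_DRUGS), size=n)

    event_rows, event_cols = np.nonzero(event_mat)
    case_pts: list[list[str]] = [[] for _ in range(n)]
    for i, j in zip(event_rows.tolist(), event_cols.tolist()):
        case_pts[i].append(pts[j])

    cases: list[CaseReport] = []
    duplicate_pairs: list[tuple[str, str]] = []
    psychotropic_ids: list[str] = []
    realized: dict[tuple[str, str], int] = {}
    stratum_sizes: dict[str, int] = {}

    for i in range(n):
        cat = categories[i]
        case_id = f"C{i:07d}"
        receive = EPOCH + dt.timedelta(days=int(receive_off[i]))
        start = (
            None
            if miss_start[i]
            else EPOCH + dt.timedelta(days=int(start_off[i]))
        )
        ev_date = (
            None
            if miss_event[i]
            else EPOCH + dt.timedelta(days=int(event_off[i]))
        )

        drugs: list[DrugMention] = []
        if cat in FQ_ATC:
            drugs.append(
                DrugMention(cat, "suspect", frozenset({FQ_ATC[cat]}), start)
            )
        elif cat == "multiple_fqs":
            f1, f2 = fq_names[combo_fq[i]], fq_names[combo_fq2[i]]
            drugs.append(
                DrugMention(f1, "suspect", frozenset({FQ_ATC[f1]}), start)
            )
            drugs.append(
                DrugMention(f2, "suspect", frozenset({FQ_ATC[f2]}), start)
            )
        elif cat == "fq_plus_antibiotics":
            f1 = fq_names[combo_fq[i]]
            name, atc = OTHER_ANTIBIOTICS[abx_pick[i]]
            drugs.append(
                DrugMention(f1, "suspect", frozenset({FQ_ATC[f1]}), start)
            )
            drugs.append(DrugMention(name, "concomitant", frozenset({atc})))
        elif cat == "fq_plus_other_meds":
            f1 = fq_names[combo_fq[i]]
            name, atc = OTHER_MEDS[med_pick[i]]
            drugs.append(
                DrugMention(f1, "suspect", frozenset({FQ_ATC[f1]}), start)
            )
            drugs.append(DrugMention(name, "concomitant", frozenset({atc})))
        else:  # background, non-FQ suspect
            name, atc = BACKGROUND_DRUGS[bg_pick[i]]
            drugs.append(
                DrugMention(name, "suspect", frozenset({atc}), start)
            )
        if psy_mask[i]:
            name, atc = PSYCHOTROPICS[psy_pick[i]]
            drugs.append(DrugMention(name, "concomitant", frozenset({atc})))
            psychotropic_ids.append(case_id)

        reactions = [ReactionMention(pt, ev_date) for pt in case_pts[i]]
        case = CaseReport(
            case_id=case_id,
            receive_date=receive,
            sex="unspecified" if miss_sex[i] else str(sex[i]),
            age_years=None if miss_age[i] else float(ages[i]),
            country=str(country[i]),
            reporter=str(reporter[i]),
            outcomes=frozenset({str(outcome[i])}),
            indications=frozenset({str(indication[i])}),
            drugs=drugs,
            reactions=reactions,
        )
        cases.append(case)

        if not psy_mask[i]:  # analysis-set ledger (survives preprocessing)
            stratum_sizes[cat] = stratum_sizes.get(cat, 0) + 1
            for pt in case_pts[i]:
                key = (cat, pt)
                realized[key] = realized.get(key, 0) + 1

    clones: list[CaseReport] = []
    for i in range(n):
        if dup_mask[i]:
            orig = cases[i]
            clone_id = orig.case_id + "-DUP"
            clones.append(
                CaseReport(
                    case_id=clone_id,
                    receive_date=orig.receive_date,
                    sex=orig.sex,
                    age_years=orig.age_years,
                    country=orig.country,
                    reporter=orig.reporter,
                    outcomes=orig.outcomes,
                    indications=orig.indications,
                    drugs=list(orig.drugs),
                    reactions=list(orig.reactions),
                )
            )
            duplicate_pairs.append((orig.case_id, clone_id))
    cases.extend(clones)

    truth = SimTruth(
        planted_or=dict(config.planted_or),
        realized_counts=realized,
        stratum_sizes=stratum_sizes,
        duplicate_pairs=duplicate_pairs,
        psychotropic_ids=psychotropic_ids,
    )
    return cases, truth
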