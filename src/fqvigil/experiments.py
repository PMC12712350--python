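"""Monte-Carlo validation experiments for the pipeline.

Each experiment generates synthetic datasets with known planted structure
and measures how the estimators behave: parameter recovery of a planted
reporting odds ratio, Wald-CI coverage, false-alarm rate of the signal
rule under the null, and recovery of a planted demographic odds ratio by
the univariate logistic screen.  These functions are the single source of
truth for both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fqvigil.disproportionality import (
    build_table,
    evaluate_signal,
    ror_estimate,
)
from fqvigil.report_model import TermDictionary
from fqvigil.risk_factors import risk_factor_screen, soc_outcome_flag
from fqvigil.synthetic_reports import (
    SimConfig,
    default_dictionary,
    simulate,
)

EVENT_PT = "anxiety"
EXPOSURE = "ciprofloxacin"


def two_stratum_config(
    n_cases: int,
    psi: float,
    seed: int,
    baseline_odds: float = 0.02,
    exposure_prob: float = 0.2,
) -> SimConfig:
    """One exposed stratum vs background, a single screened event term.

    Duplicates, missingness and psychotropic co-medication are switched
    off so the experiment isolates the estimator; the event mechanism is
    odds(event | exposed) = ψ × baseline odds, making ψ the exact true ROR.
    """
    return SimConfig(
        n_cases=n_cases,
        exposure_probs={EXPOSURE: exposure_prob,
                        "background": 1 - exposure_prob},
        baseline_event_odds={EVENT_PT: baseline_odds,
                             "drug ineffective": 0.04},
        planted_or=(
            {(EXPOSURE, EVENT_PT): psi} if psi != 1.0 else {}
        ),
        duplicate_fraction=0.0,
        psychotropic_rate=0.0,
        missing_rates={},
        seed=seed,
    )


def _estimate_once(
    config: SimConfig, dictionary: TermDictionary
) -> tuple[float, float, float, int]:
    cases, _ = simulate(config)
    table = build_table(cases, EXPOSURE, EVENT_PT, "PT", dictionary)
    ror, lo, hi = ror_estimate(table)
    return ror, lo, hi, table.a


@dataclass
class RecoveryResult:
    n_replicates: int
    in_band: int
    ci_covers_truth: int
    estimates: list[float]

    @property
    def in_band_fraction(self) -> float:
        return self.in_band / self.n_replicates

    @property
    def coverage(self) -> float:
        return self.ci_covers_truth / self.n_replicates


def ror_recovery(
    psi: float,
    band: tuple[float, float],
    n_cases: int,
    n_replicates: int,
    seed: int,
    baseline_odds: float = 0.02,
    exposure_prob: float = 0.2,
) -> RecoveryResult:
    """Fraction of replicates whose ROR estimate falls in *band* and whose
    95% Wald interval covers the planted ψ."""
    dictionary = default_dictionary()
    in_band = covers = 0
    estimates = []
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        config = two_stratum_config(
            n_cases, psi, int(rng.integers(0, 2**31 - 1)),
            baseline_odds, exposure_prob,
        )
        ror, lo, hi, _ = _estimate_once(config, dictionary)
        estimates.append(ror)
        in_band += band[0] <= ror <= band[1]
        covers += lo <= psi <= hi
    return RecoveryResult(n_replicates, in_band, covers, estimates)


@dataclass
class NullCalibrationResult:
    n_replicates: int
    n_signals: int
    ci_covers_one: int

    @property
    def signal_rate(self) -> float:
        return self.n_signals / self.n_replicates

    @property
    def coverage(self) -> float:
        return self.ci_covers_one / self.n_replicates


#: unassociated event terms screened in the null-calibration experiment
NULL_PTS = (
    "anxiety",
    "insomnia",
    "delirium",
    "hallucination",
    "vision blurred",
    "photophobia",
    "headache",
    "nausea",
)


def null_calibration(
    n_cases: int,
    n_replicates: int,
    seed: int,
    baseline_odds: float = 0.02,
    exposure_prob: float = 0.2,
) -> NullCalibrationResult:
    """All ψ = 1: rate at which the signal rule fires per screened
    (exposure, PT) pair, and Wald-CI coverage of 1 over the same pairs.

    Each replicate screens several independent null event terms, so the
    reported rates are per pair (the unit at which the rule operates)
    rather than per dataset.
    """
    dictionary = default_dictionary()
    fires = covers = total = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        config = SimConfig(
            n_cases=n_cases,
            exposure_probs={EXPOSURE: exposure_prob,
                            "background": 1 - exposure_prob},
            baseline_event_odds={
                **{pt: baseline_odds for pt in NULL_PTS},
                "drug ineffective": 0.04,
            },
            planted_or={},
            duplicate_fraction=0.0,
            psychotropic_rate=0.0,
            missing_rates={},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases, _ = simulate(config)
        for pt in NULL_PTS:
            table = build_table(cases, EXPOSURE, pt, "PT", dictionary)
            ror, lo, hi = ror_estimate(table)
            fires += evaluate_signal(ror, lo, table.a)
            covers += lo <= 1.0 <= hi
            total += 1
    return NullCalibrationResult(total, fires, covers)


def age_or_recovery(
    planted_or: float,
    n_cases: int,
    seed: int,
    age_level: str = "18-34",
) -> float:
    """Recover a planted age-group odds ratio via the logistic screen.

    The generator multiplies every event's odds by *planted_or* for cases
    in *age_level*; with exposure-level ψ left at 1 the marginal logistic
    odds ratio of that age level against the 0–17 reference equals the
    planted multiplier exactly.  Age groups are balanced so every level —
    in particular the 0–17 reference — carries enough events for a
    well-conditioned Wald interval.  Returns the fitted OR.
    """
    from fqvigil.synthetic_reports import default_demographics

    marginals = default_demographics()
    marginals["age_group"] = {
        "0-17": 0.25, "18-34": 0.25, "35-64": 0.25, "65+": 0.25,
    }
    marginals["age_group_by_exposure"] = {}
    config = SimConfig(
        n_cases=n_cases,
        exposure_probs={"ciprofloxacin": 1.0},
        baseline_event_odds={"anxiety": 0.05, "drug ineffective": 0.04},
        planted_or={},
        demographic_marginals=marginals,
        covariate_or={"age_group": {age_level: planted_or}},
        duplicate_fraction=0.0,
        psychotropic_rate=0.0,
        missing_rates={},
        seed=seed,
    )
    dictionary = default_dictionary()
    cases, _ = simulate(config)
    results = risk_factor_screen(
        cases,
        soc_outcome_flag(dictionary, "psychiatric disorders"),
        predictors=("age_group",),
    )
    by_level = {r.level: r for r in results}
    return float(by_level[age_level].or_estimate)
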