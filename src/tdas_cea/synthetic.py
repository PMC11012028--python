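"""Synthetic study-data generators.

The original inputs came from a five-hospital retrospective chart review
(severity at diagnosis and annual severity transitions, n=295), a
cross-sectional cost/utility survey of the same families, and a national
period life table none of which are deposited.  This module generates
statistically matched stand-ins for each: a Gompertz life table, patient-level
chart-review records with multinomial annual severity transitions, and
cost/utility survey records with Gamma-distributed costs and Beta-distributed
utilities.  Estimators (annual-risk transition estimation, sample moments)
support parameter-recovery tests that close the loop from raw records back
through the full cost-utility pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SeverityMix, TransitionRates

__all__ = [
    "SyntheticLifeTable",
    "ChartReviewRecord",
    "CostSurveyRecord",
    "make_life_table",
    "simulate_chart_review",
    "estimate_transition_rates",
    "simulate_cost_survey",
]

_SEV = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class SyntheticLifeTable:
    """Gompertz life table ``q(a) = min(1, c·exp(γ·a))`` with ``q(max_age)=1``."""

    c: float
    gamma: float
    max_age: int
    table: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.table.index, "qx": self.table.to_numpy()})


def make_life_table(
    c: float = 1e-4, gamma: float = 0.09, max_age: int = 100
) -> SyntheticLifeTable:
    """Monotone synthetic period life table on ages ``0..max_age``."""
    if c <= 0:
        raise ValueError("Gompertz level c must be positive")
    if gamma < 0:
        raise ValueError("Gompertz slope gamma must be non-negative")
    ages = np.arange(max_age + 1)
    q = np.minimum(1.0, c * np.exp(gamma * ages))
    q[-1] = 1.0  # closure: nobody survives past the terminal age
    return SyntheticLifeTable(
        c=c, gamma=gamma, max_age=max_age, table=pd.Series(q, index=ages)
    )


@dataclass(frozen=True)
class ChartReviewRecord:
    """One patient's annual severity trajectory from a simulated chart review."""

    patient_id: int
    strategy: str
    severity_at_diagnosis: str
    states: tuple[str, ...]  # severity per follow-up year, incl. year 0
    censor_year: int


_TRANSITION_NAMES = {
    ("mild", "moderate"): "mild_to_moderate",
    ("mild", "severe"): "mild_to_severe",
    ("moderate", "mild"): "moderate_to_mild",
    ("moderate", "severe"): "moderate_to_severe",
    ("severe", "mild"): "severe_to_mild",
    ("severe", "moderate"): "severe_to_moderate",
}


def _step_probs(tr: TransitionRates) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for origin in _SEV:
        targets = [s for s in _SEV if s != origin]
        p = np.array(
            [getattr(tr, _TRANSITION_NAMES[(origin, t)]) for t in targets]
        )
        stay = 1.0 - p.sum()
        if stay < 0:
            raise ValueError(f"transition probabilities out of {origin} exceed 1")
        out[origin] = (np.array(targets + [origin], dtype=object),
                       np.append(p, stay))
    return out


def simulate_chart_review(
    true_rates: TransitionRates,
    mix: SeverityMix,
    n: int = 295,
    years: int = 5,
    seed: int | None = None,
    strategy: str = "TDAS",
    censor_prob: float = 0.0,
) -> list[ChartReviewRecord]:
    """Simulate patient-level severity trajectories at the given annual rates.

    Initial severities are multinomial draws from ``mix``; each subsequent
    year the state moves by a multinomial draw at the annual transition
    probabilities.  ``censor_prob`` is an annual loss-to-follow-up risk
    (0 = complete follow-up); the real review's censoring structure is
    unreported, so it is exposed as a parameter.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    steps = _step_probs(true_rates)
    m = mix.normalized().as_array()
    initial = rng.choice(len(_SEV), size=n, p=m)
    records = []
    for pid in range(n):
        state = _SEV[initial[pid]]
        states = [state]
        censor = years
        for year in range(1, years + 1):
            if censor_prob > 0 and rng.random() < censor_prob:
                censor = year - 1
                break
            targets, probs = steps[state]
            state = targets[rng.choice(len(targets), p=probs)]
            states.append(state)
        records.append(
            ChartReviewRecord(
                patient_id=pid,
                strategy=strategy,
                severity_at_diagnosis=states[0],
                states=tuple(states),
                censor_year=censor,
            )
        )
    return records


def estimate_transition_rates(
    records: list[ChartReviewRecord],
) -> tuple[TransitionRates, dict[str, float]]:
    """Annual-risk estimates (events / person-years at risk) with binomial SEs.

    Emulates the study's survival-analysis estimation at the model's one-year
    cycle resolution.  Returns ``(rates, ses)``; a transition whose origin
    state has zero person-years is flagged with a NaN estimate.
    """
    person_years = {s: 0 for s in _SEV}
    events = {name: 0 for name in _TRANSITION_NAMES.values()}
    for rec in records:
        for a, b in zip(rec.states[:-1], rec.states[1:]):
            person_years[a] += 1
            if a != b:
                events[_TRANSITION_NAMES[(a, b)]] += 1
    rates = {}
    ses = {}
    for (origin, target), name in _TRANSITION_NAMES.items():
        py = person_years[origin]
        if py == 0:
            rates[name] = math.nan
            ses[name] = math.nan
        else:
            p = events[name] / py
            rates[name] = p
            ses[name] = math.sqrt(p * (1.0 - p) / py)
    return TransitionRates(**rates), ses


@dataclass(frozen=True)
class CostSurveyRecord:
    """One simulated cost/utility interview."""

    patient_id: int
    severity: str
    items: dict[str, float]
    utility: float


def simulate_cost_survey(
    cost_means_ses: dict[str, tuple[float, float]],
    utility_means_ses: dict[str, tuple[float, float]],
    n: int,
    seed: int | None = None,
) -> tuple[list[CostSurveyRecord], pd.DataFrame]:
    """Simulate interview records: Gamma cost items, Beta utilities.

    ``cost_means_ses`` maps item name -> (mean, SE); ``utility_means_ses``
    maps severity -> (mean, SE).  Severities are assigned uniformly.  Returns
    the records together with a moment table (sample mean/SE per item) for
    recovery comparisons against the inputs.
    """
    if n < 1:
        raise ValueError("need at least one respondent")
    rng = np.random.default_rng(seed)
    severities = [_SEV[i % len(_SEV)] for i in range(n)]
    draws: dict[str, np.ndarray] = {}
    for item, (mean, se) in cost_means_ses.items():
        if se <= 0 or mean <= 0:
            draws[item] = np.full(n, mean)
        else:
            shape, scale = (mean / se) ** 2, se**2 / mean
            draws[item] = rng.gamma(shape, scale, size=n)
    util_draws = np.empty(n)
    for i, s in enumerate(severities):
        mean, se = utility_means_ses[s]
        if se <= 0:
            util_draws[i] = mean
        else:
            nu = mean * (1.0 - mean) / se**2 - 1.0
            util_draws[i] = rng.beta(mean * nu, (1.0 - mean) * nu)
    records = [
        CostSurveyRecord(
            patient_id=i,
            severity=severities[i],
            items={item: float(v[i]) for item, v in draws.items()},
            utility=float(util_draws[i]),
        )
        for i in range(n)
    ]
    moments = pd.DataFrame(
        {
            "item": list(draws),
            "sample_mean": [v.mean() for v in draws.values()],
            "sample_se": [v.std(ddof=1) for v in draws.values()],
        }
    )
    return records, moments
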