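"""Societal per-state annual costs.

Assembles, for each ASD severity level, the annual cost of care from its
published components: direct medical (outpatient, inpatient weighted by the
severity-specific admission probability, therapy activities, instrument
purchase), direct non-medical (travel, food, accommodation and caregiver
accompaniment for outpatient visits and admissions), and caregiver costs at
home (hired caregiver salary plus forgone income of caregivers who quit
work).  Severity-specific admission probabilities are recovered by Bayes
inversion from the overall admission proportion and the severity shares among
admitted patients, using a pooled chart-review cohort mix.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import CostInputs, ModelParams, SeverityMix

__all__ = [
    "StateCostBreakdown",
    "severity_admission_prob",
    "annual_state_cost",
    "pooled_cohort_mix",
    "state_cost_vectors",
]

SEVERITIES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class StateCostBreakdown:
    """Annual USD cost components for one severity state."""

    outpatient_medical: float
    inpatient_medical: float
    instruments: float
    activities: float
    outpatient_nonmedical: float
    admission_nonmedical: float
    caregiver_home: float

    @property
    def total(self) -> float:
        return sum(getattr(self, f.name) for f in fields(self))

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d


def severity_admission_prob(
    severity: str,
    p_admit_overall: float,
    admitted_mix: SeverityMix,
    cohort_mix: SeverityMix,
) -> float:
    """P(admission | severity) by Bayes inversion, clamped to [0, 1].

    ``P(admit|s) = P(admit) * P(s|admit) / P(s)`` where ``P(s|admit)`` is the
    severity share among admitted patients and ``P(s)`` the cohort share.
    """
    idx = SEVERITIES.index(severity)
    p_s = float(cohort_mix.normalized().as_array()[idx])
    if p_s <= 0.0:
        raise ZeroDivisionError(
            f"cohort share for severity {severity!r} is zero; "
            "P(admission | severity) is undefined"
        )
    p_s_given_admit = float(admitted_mix.as_array()[idx])
    return float(np.clip(p_admit_overall * p_s_given_admit / p_s, 0.0, 1.0))


def annual_state_cost(
    severity: str, c: CostInputs, adm_prob: float
) -> StateCostBreakdown:
    """Annual societal cost components for one severity level.

    The instrument component is the expected acquisition outlay
    (cost x purchase proportion); whether it recurs annually or is charged
    once at model entry is decided by the caller (``instruments_one_time``).
    """
    s = severity
    outpatient_medical = c.outpatient_annual[s]
    inpatient_medical = adm_prob * c.admissions_per_year * c.inpatient_visit[s]
    instruments = c.instruments_cost[s] * c.instruments_prop[s]
    activities = c.activities_cost[s] * c.activities_prop[s]
    per_visit = (
        c.travel_outpatient
        + c.food_outpatient
        + c.accommodation_outpatient * c.p_accommodation_outpatient
        + c.caregiver_outpatient
    )
    outpatient_nonmedical = c.outpatient_visits[s] * per_visit
    per_admission = (
        c.travel_admission_patient
        + c.food_admission_patient
        + c.accommodation_admission_patient * c.p_accommodation_admission
        + c.travel_admission_caregiver
        + c.food_admission_caregiver
        + c.accommodation_admission_caregiver * c.p_accommodation_admission
        + c.caregiver_admission
    )
    admission_nonmedical = adm_prob * c.admissions_per_year * per_admission
    caregiver_home = (
        c.hired_caregiver_salary * c.p_hired_caregiver
        + c.lost_income * c.p_quit[s]
    )
    return StateCostBreakdown(
        outpatient_medical=outpatient_medical,
        inpatient_medical=inpatient_medical,
        instruments=instruments,
        activities=activities,
        outpatient_nonmedical=outpatient_nonmedical,
        admission_nonmedical=admission_nonmedical,
        caregiver_home=caregiver_home,
    )


def pooled_cohort_mix(params: ModelParams) -> SeverityMix:
    """Equal-weight average of the TDAS and ClinDx chart-review severity mixes.

    Used as the denominator mix in the Bayes inversion of admission
    probabilities; an explicit ``pooled_cohort_mix`` in the configuration
    overrides it.
    """
    if params.pooled_cohort_mix is not None:
        return params.pooled_cohort_mix
    a = params.severity_mix("tdas").as_array()
    b = params.severity_mix("clin").as_array()
    return SeverityMix(*(0.5 * (a + b)))


def state_cost_vectors(
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray, dict[str, StateCostBreakdown]]:
    """Annual and one-off per-state cost vectors over the five Markov states.

    Returns ``(annual, entry_one_time, breakdowns)`` where each vector is
    indexed (non-ASD, mild, moderate, severe, dead).  Non-ASD and dead accrue
    nothing.  With the ``instruments_one_time`` flag the instrument component
    moves from the annual vector to the entry vector.
    """
    c = params.cost_inputs
    cohort = pooled_cohort_mix(params)
    annual = np.zeros(5)
    entry = np.zeros(5)
    breakdowns: dict[str, StateCostBreakdown] = {}
    for i, s in enumerate(SEVERITIES, start=1):
        adm = severity_admission_prob(s, c.p_admission, c.admitted_mix, cohort)
        bd = annual_state_cost(s, c, adm)
        breakdowns[s] = bd
        if params.flags.instruments_one_time:
            annual[i] = bd.total - bd.instruments
            entry[i] = bd.instruments
        else:
            annual[i] = bd.total
    return annual, entry, breakdowns
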