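"""Follow-up-phase Markov cohort model.

States are (non-ASD, mild, moderate, severe, dead) with one-year cycles.
Each cycle applies age-specific background mortality — scaled by the ASD
mortality relative risk in the severity states — first, then redistributes
survivors across severity levels at the annual transition probabilities
(mortality-first composition keeps every row stochastic for any q).
Rewards (utilities, costs) accrue on start-of-cycle occupancy and are
discounted at the annual rate with cycle 0 undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostic_tree import EntryDistribution
from .params import EconSettings, MortalityInputs, TransitionRates, UtilitySet

__all__ = [
    "STATES",
    "TransitionMatrix",
    "CohortTrace",
    "StrategyOutcome",
    "build_transition_matrix",
    "transition_matrix_stack",
    "run_cohort",
    "accrue_outcomes",
]

STATES = ("non_asd", "mild", "moderate", "severe", "dead")
NON_ASD, MILD, MODERATE, SEVERE, DEAD = range(5)

#: A single-age 5x5 row-stochastic transition matrix.
TransitionMatrix = np.ndarray


class InvalidRatesError(ValueError):
    """Raised when an origin state's exit probabilities exceed one."""


def _offdiag(tr: TransitionRates) -> np.ndarray:
    """3x3 severity-to-severity annual probabilities, zero diagonal."""
    return np.array(
        [
            [0.0, tr.mild_to_moderate, tr.mild_to_severe],
            [tr.moderate_to_mild, 0.0, tr.moderate_to_severe],
            [tr.severe_to_mild, tr.severe_to_moderate, 0.0],
        ],
        dtype=float,
    )


def transition_matrix_stack(
    tr: TransitionRates,
    q_ages: np.ndarray,
    rr: float,
    state_rr: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-age transition matrices, shape ``(len(q_ages), 5, 5)``.

    Death probability from state s is ``min(1, q_age * state_rr(s))`` with
    ``state_rr`` defaulting to ``rr`` for the severity states and 1 for
    non-ASD; conditional on survival, severity states redistribute at the
    annual rates with the stay-probability as complement.
    """
    q_ages = np.asarray(q_ages, dtype=float)
    if np.any((q_ages < 0) | (q_ages > 1)):
        raise ValueError("q_age values must lie in [0, 1]")
    if rr <= 0:
        raise ValueError("mortality relative risk must be positive")
    off = _offdiag(tr)
    row_sums = off.sum(axis=1)
    if np.any(row_sums > 1.0 + 1e-12):
        bad = STATES[1 + int(np.argmax(row_sums))]
        raise InvalidRatesError(
            f"annual transition probabilities out of state {bad!r} sum to "
            f"{row_sums.max():.6g} > 1"
        )
    sev_step = off + np.diag(1.0 - row_sums)  # 3x3 conditional-on-survival step

    mult = np.ones(4)
    if state_rr is None:
        mult[1:] = rr
    else:
        for i, s in enumerate(STATES[:4]):
            mult[i] = state_rr.get(s, rr if i else 1.0)
    p_die = np.minimum(1.0, q_ages[:, None] * mult[None, :])  # (n, 4)

    n = len(q_ages)
    m = np.zeros((n, 5, 5))
    m[:, DEAD, DEAD] = 1.0
    m[:, NON_ASD, NON_ASD] = 1.0 - p_die[:, NON_ASD]
    m[:, NON_ASD, DEAD] = p_die[:, NON_ASD]
    surv = 1.0 - p_die[:, 1:4]  # (n, 3)
    m[:, 1:4, 1:4] = surv[:, :, None] * sev_step[None, :, :]
    m[:, 1:4, DEAD] = p_die[:, 1:4]
    return m


def build_transition_matrix(
    tr: TransitionRates,
    q_age: float,
    rr: float,
    state_rr: dict[str, float] | None = None,
) -> TransitionMatrix:
    """One-cycle 5x5 transition matrix at a given age."""
    return transition_matrix_stack(tr, np.array([q_age]), rr, state_rr)[0]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort occupancy over (non-ASD, mild, moderate, severe, dead)."""

    occupancy: np.ndarray  # (cycles + 1, 5); row 0 is the entry distribution
    ages: np.ndarray  # attained integer age at the start of each cycle

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(
    entry: EntryDistribution | np.ndarray,
    tr: TransitionRates,
    mort: MortalityInputs,
    settings: EconSettings,
) -> CohortTrace:
    """Propagate the entry distribution to ``max_age`` in one-year cycles.

    The number of cycles is ``max_age - floor(start_age)``; the life table is
    looked up at the integer (floored) attained age for each cycle.
    """
    if isinstance(entry, EntryDistribution):
        x0 = entry.as_state_vector()
    else:
        x0 = np.asarray(entry, dtype=float)
    age0 = int(math.floor(settings.start_age))
    n_cycles = settings.max_age - age0
    ages = age0 + np.arange(n_cycles + 1)
    lt = mort.life_table
    needed = ages[:-1]
    missing = sorted(set(needed.tolist()) - set(lt.index.tolist()))
    if missing:
        raise KeyError(f"life table is missing age {missing[0]}")
    q = lt.loc[needed].to_numpy(float)
    matrices = transition_matrix_stack(tr, q, mort.rr_asd)

    occ = np.empty((n_cycles + 1, 5))
    occ[0] = x0
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ matrices[t]
    return CohortTrace(occupancy=occ, ages=ages)


@dataclass(frozen=True)
class StrategyOutcome:
    """Lifetime totals (USD, QALY) for one diagnostic strategy."""

    total_cost_undisc: float
    total_cost_disc: float
    total_qaly_undisc: float
    total_qaly_disc: float
    #: per-state person-years, undiscounted / discounted (used for cost
    #: breakdowns: category cost = component rate . state_years)
    state_years_undisc: np.ndarray = field(default=None, repr=False)
    state_years_disc: np.ndarray = field(default=None, repr=False)
    cost_breakdown: dict[str, float] = field(default_factory=dict)


def accrue_outcomes(
    trace: CohortTrace,
    u: UtilitySet | np.ndarray,
    state_costs: np.ndarray,
    dx_cost: float,
    rate: float,
    entry_state_costs: np.ndarray | None = None,
    half_cycle: bool = False,
) -> StrategyOutcome:
    """Accumulate lifetime QALYs and costs from a cohort trace.

    Cycle ``t`` rewards are occupancy-weighted sums of per-state annual
    utilities and costs, discounted by ``(1 + rate)^-t`` (cycle 0
    undiscounted).  ``dx_cost`` and the optional one-off per-state
    ``entry_state_costs`` (e.g. instrument purchase at diagnosis) are charged
    at cycle 0 only.  With ``half_cycle`` rewards use the average of
    start-of-cycle and end-of-cycle occupancy.
    """
    if isinstance(u, UtilitySet):
        util = np.array([u.u_non_asd, u.u_mild, u.u_moderate, u.u_severe, 0.0])
    else:
        util = np.asarray(u, dtype=float)
    state_costs = np.asarray(state_costs, dtype=float)

    occ = trace.occupancy
    if half_cycle:
        rows = 0.5 * (occ[:-1] + occ[1:])
    else:
        rows = occ[:-1]
    n = rows.shape[0]
    disc = (1.0 + rate) ** -np.arange(n)

    years_undisc = rows.sum(axis=0)
    years_disc = (rows * disc[:, None]).sum(axis=0)

    qaly_undisc = float(years_undisc @ util)
    qaly_disc = float(years_disc @ util)
    cost_undisc = float(years_undisc @ state_costs) + dx_cost
    cost_disc = float(years_disc @ state_costs) + dx_cost
    if entry_state_costs is not None:
        one_off = float(occ[0] @ np.asarray(entry_state_costs, dtype=float))
        cost_undisc += one_off
        cost_disc += one_off
    return StrategyOutcome(
        total_cost_undisc=cost_undisc,
        total_cost_disc=cost_disc,
        total_qaly_undisc=qaly_undisc,
        total_qaly_disc=qaly_disc,
        state_years_undisc=years_undisc,
        state_years_disc=years_disc,
    )
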