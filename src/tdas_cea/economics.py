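"""Incremental cost-effectiveness algebra: ICERs, dominance, net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass

from .markov import StrategyOutcome

__all__ = ["ICERResult", "icer_result", "icer_from_deltas", "nmb"]


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is defined only when the cost/effect differences form a
    meaningful ratio (both positive, or both negative); otherwise the
    ``label`` carries the cost-effectiveness-plane verdict:

    - ``dominant``: more effective and no more costly
    - ``dominated``: less (or equally) effective and more costly
    - ``equal``: identical cost and effect
    - ``ICER``: a ratio is reported
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str


def icer_from_deltas(delta_cost: float, delta_qaly: float) -> ICERResult:
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return ICERResult(delta_cost, delta_qaly, None, "equal")
    if delta_qaly >= 0.0 and delta_cost <= 0.0:
        return ICERResult(delta_cost, delta_qaly, None, "dominant")
    if delta_qaly <= 0.0 and delta_cost >= 0.0:
        return ICERResult(delta_cost, delta_qaly, None, "dominated")
    # remaining: same-sign, nonzero differences -> ratio is meaningful
    return ICERResult(delta_cost, delta_qaly, delta_cost / delta_qaly, "ICER")


def icer_result(
    intervention: StrategyOutcome,
    comparator: StrategyOutcome,
    discounted: bool = True,
) -> ICERResult:
    """ICER of ``intervention`` vs ``comparator``.

    ``ICER = (cost_intervention - cost_comparator) /
    (QALY_intervention - QALY_comparator)`` on the chosen discounting mode.
    """
    if discounted:
        dc = intervention.total_cost_disc - comparator.total_cost_disc
        de = intervention.total_qaly_disc - comparator.total_qaly_disc
    else:
        dc = intervention.total_cost_undisc - comparator.total_cost_undisc
        de = intervention.total_qaly_undisc - comparator.total_qaly_undisc
    return icer_from_deltas(dc, de)


def nmb(outcome_delta: tuple[float, float], wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost``.

    Positive iff the intervention is cost-effective at willingness-to-pay
    ``wtp`` (USD/QALY); crosses zero exactly at the ICER.
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    delta_cost, delta_qaly = outcome_delta
    return wtp * delta_qaly - delta_cost
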