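"""Diagnostic-phase decision tree.

Each strategy (the TDAS instrument or standard clinical diagnosis) maps the
suspected-ASD cohort to a post-diagnosis distribution over entry states
{non-ASD, mild, moderate, severe}; children diagnosed late (after age five)
are assumed severe.  The tree also prices the diagnostic episode itself:
per-patient labor plus, for TDAS, training/instrument amortization and
per-patient maintenance and cloud charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DiagnosticCostInputs, DiagnosticPerformance, SeverityMix

__all__ = ["EntryDistribution", "entry_distribution", "diagnostic_cost_per_patient"]

STRATEGIES = ("TDAS", "ClinDx")


class DegenerateTreeError(ValueError):
    """Raised when the test-positive branch has no probability mass to split."""


@dataclass(frozen=True)
class EntryDistribution:
    """Post-diagnosis shares of the suspected cohort entering each state.

    ``share_delayed_component`` books the part of ``share_severe`` contributed
    by delayed diagnosis; ``share_false_positive`` the part of
    ``share_non_asd`` that went through a positive test.
    """

    share_non_asd: float
    share_mild: float
    share_moderate: float
    share_severe: float
    share_delayed_component: float = 0.0
    share_false_positive: float = 0.0

    def as_state_vector(self) -> np.ndarray:
        """Occupancy over (non-ASD, mild, moderate, severe, dead) at cycle 0."""
        return np.array(
            [self.share_non_asd, self.share_mild, self.share_moderate,
             self.share_severe, 0.0],
            dtype=float,
        )

    @property
    def share_asd(self) -> float:
        return self.share_mild + self.share_moderate + self.share_severe


def entry_distribution(
    strategy: str,
    perf: DiagnosticPerformance,
    mix: SeverityMix,
    renormalize_tp_fp: bool = True,
) -> EntryDistribution:
    """Resolve the decision tree for one strategy into entry-state shares.

    TDAS arm: the cohort splits into test-positives (``p_test_positive``) and
    negatives.  Positives split into true positives and false positives using
    the reported (p_true_positive, p_false_positive) pair renormalised to a
    branch distribution (the published pair sums to 1.0247); true positives
    split by the severity mix and false positives are non-ASD.  Among
    negatives, ``p_delayed_tdas`` resurface later as severe (delayed) and the
    rest stay non-ASD.

    ClinDx arm: ``p_diagnosed_clin`` of the cohort is diagnosed; of those,
    ``p_delayed_clin`` are delayed (severe) and the remainder split by the
    ClinDx severity mix; the undiagnosed are non-ASD.
    """
    mix = mix.normalized()
    m = mix.as_array()
    if strategy == "TDAS":
        p_pos = perf.p_test_positive
        pair_sum = perf.p_true_positive + perf.p_false_positive
        if pair_sum <= 0.0:
            raise DegenerateTreeError(
                "p_true_positive + p_false_positive is zero; the positive "
                "branch cannot be split"
            )
        if renormalize_tp_fp:
            t = perf.p_true_positive / pair_sum
            f = perf.p_false_positive / pair_sum
        else:
            t, f = perf.p_true_positive, perf.p_false_positive
        tp = p_pos * t
        fp = p_pos * f
        neg = 1.0 - p_pos
        delayed = neg * perf.p_delayed_tdas
        non_asd = fp + neg * (1.0 - perf.p_delayed_tdas)
        mild, moderate, severe = tp * m
        severe += delayed
        # Without renormalisation the pair may not exhaust the positives;
        # close the tree by keeping the remainder non-ASD.
        non_asd += p_pos * max(0.0, 1.0 - t - f)
        return EntryDistribution(
            share_non_asd=non_asd,
            share_mild=mild,
            share_moderate=moderate,
            share_severe=severe,
            share_delayed_component=delayed,
            share_false_positive=fp,
        )
    if strategy == "ClinDx":
        dx = perf.p_diagnosed_clin
        delayed = dx * perf.p_delayed_clin
        confirmed = dx * (1.0 - perf.p_delayed_clin)
        mild, moderate, severe = confirmed * m
        severe += delayed
        return EntryDistribution(
            share_non_asd=1.0 - dx,
            share_mild=mild,
            share_moderate=moderate,
            share_severe=severe,
            share_delayed_component=delayed,
        )
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def diagnostic_cost_per_patient(strategy: str, dc: DiagnosticCostInputs) -> float:
    """One-off diagnostic cost (USD) charged to every entrant in an arm.

    Labor is a per-month salary spread over the monthly diagnosis volume
    (``diagnoses_per_week * 52/12``).  TDAS additionally amortises provider
    training and instrument acquisition over a provider-year of diagnoses and
    adds the per-patient-year maintenance and cloud-storage charges.
    """
    if dc.diagnoses_per_week <= 0:
        raise ValueError("diagnoses_per_week must be positive")
    diagnoses_per_month = dc.diagnoses_per_week * 52.0 / 12.0
    if strategy == "ClinDx":
        return dc.labor_clin_per_month / diagnoses_per_month
    if strategy == "TDAS":
        amort = dc.amortization_diagnoses_per_provider_year
        return (
            dc.labor_tdas_per_month / diagnoses_per_month
            + dc.tdas_training_per_provider / amort
            + dc.tdas_instruments / amort
            + dc.tdas_maintenance_per_patient_year
            + dc.cloud_per_patient_year
        )
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
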