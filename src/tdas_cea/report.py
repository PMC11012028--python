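"""Orchestration: base-case, scenario, OWSA, PSA and CEAC runs with file output.

The deterministic pipeline is: decision tree (entry distribution and
per-patient diagnostic cost) -> per-state annual societal costs -> Markov
cohort trace to the model horizon -> discounted / undiscounted lifetime cost
and QALY accrual -> incremental comparison of TDAS against clinical
diagnosis.  ``run_full`` executes any subset of analyses and writes CSV/JSON
outputs plus a manifest describing the run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .costing import state_cost_vectors
from .diagnostic_tree import EntryDistribution, diagnostic_cost_per_patient, entry_distribution
from .economics import icer_result
from .markov import StrategyOutcome, accrue_outcomes, run_cohort
from .params import ModelParams, validate, write_config
from .sensitivity import (
    PSAResult,
    ceac,
    owsa_tornado,
    quadrant_shares,
    run_psa,
    tornado_frame,
)

__all__ = [
    "run_strategy",
    "run_strategies",
    "incremental_deltas",
    "run_base_case",
    "run_full",
    "RunManifest",
]

ANALYSES = ("base", "scenario", "owsa", "psa", "ceac")


def _clindx_mix(params: ModelParams, scenario: bool):
    return params.severity_mix("clin_scenario" if scenario else "clin")


def run_strategy(
    params: ModelParams, strategy: str, scenario: bool = False
) -> tuple[EntryDistribution, StrategyOutcome]:
    """Entry distribution and lifetime outcomes for one strategy."""
    perf = params.diagnostic_performance
    mix = (
        params.severity_mix("tdas")
        if strategy == "TDAS"
        else _clindx_mix(params, scenario)
    )
    entry = entry_distribution(
        strategy, perf, mix, renormalize_tp_fp=params.flags.renormalize_tp_fp
    )
    annual, entry_costs, breakdowns = state_cost_vectors(params)
    dx = diagnostic_cost_per_patient(strategy, params.diagnostic_costs)
    dx_total = dx + entry.share_false_positive * params.flags.fp_workup_cost
    trace = run_cohort(entry, params.transition_rates, params.mortality, params.econ)
    outcome = accrue_outcomes(
        trace,
        params.utilities,
        annual,
        dx_cost=dx_total,
        rate=params.econ.discount_rate,
        entry_state_costs=entry_costs,
        half_cycle=params.flags.half_cycle,
    )
    breakdown = {
        "diagnostic": dx_total,
        **{
            cat: float(
                sum(
                    getattr(breakdowns[s], cat) * outcome.state_years_disc[i]
                    for i, s in enumerate(("mild", "moderate", "severe"), start=1)
                )
            )
            for cat in (
                "outpatient_medical",
                "inpatient_medical",
                "activities",
                "outpatient_nonmedical",
                "admission_nonmedical",
                "caregiver_home",
            )
        },
    }
    outcome = replace(outcome, cost_breakdown=breakdown)
    return entry, outcome


def run_strategies(
    params: ModelParams, scenario: bool = False
) -> dict[str, tuple[EntryDistribution, StrategyOutcome]]:
    return {
        s: run_strategy(params, s, scenario=scenario) for s in ("TDAS", "ClinDx")
    }


def incremental_deltas(
    params: ModelParams, scenario: bool = False
) -> tuple[float, float]:
    """Discounted (ΔCost, ΔQALY) of TDAS vs ClinDx — the PSA/OWSA runner."""
    out = run_strategies(params, scenario=scenario)
    tdas, clin = out["TDAS"][1], out["ClinDx"][1]
    return (
        tdas.total_cost_disc - clin.total_cost_disc,
        tdas.total_qaly_disc - clin.total_qaly_disc,
    )


def run_base_case(params: ModelParams, scenario: bool = False) -> pd.DataFrame:
    """Deterministic run at the input means, shaped like a results table.

    One row per strategy with undiscounted and discounted total cost and
    QALYs; incremental columns (ΔC, ΔE, ICER) on the TDAS row.  The scenario
    variant swaps only the ClinDx severity mix for the alternative
    chart-review mix.
    """
    violations = validate(params)
    if violations:
        raise ValueError("invalid parameters:\n" + "\n".join(violations))
    out = run_strategies(params, scenario=scenario)
    rows = []
    tdas, clin = out["TDAS"][1], out["ClinDx"][1]
    for name, entry_outcome in out.items():
        entry, o = entry_outcome
        rows.append(
            {
                "strategy": name,
                "share_non_asd": entry.share_non_asd,
                "share_mild": entry.share_mild,
                "share_moderate": entry.share_moderate,
                "share_severe": entry.share_severe,
                "share_delayed": entry.share_delayed_component,
                "cost_undisc": o.total_cost_undisc,
                "qaly_undisc": o.total_qaly_undisc,
                "cost_disc": o.total_cost_disc,
                "qaly_disc": o.total_qaly_disc,
            }
        )
    df = pd.DataFrame(rows).set_index("strategy")
    for mode, disc in (("undisc", False), ("disc", True)):
        r = icer_result(tdas, clin, discounted=disc)
        df.loc["TDAS", f"delta_cost_{mode}"] = r.delta_cost
        df.loc["TDAS", f"delta_qaly_{mode}"] = r.delta_qaly
        df.loc["TDAS", f"icer_{mode}"] = math.nan if r.icer is None else r.icer
        df.loc["TDAS", f"label_{mode}"] = r.label
    return df.reset_index()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one orchestrated run."""

    config_hash: str
    seed: int | None
    version: str
    timestamp: str
    analyses: list[str]
    files: list[str]
    flags: dict
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _config_hash(params: ModelParams) -> str:
    text = yaml.safe_dump(write_config(params), sort_keys=True)
    lt = params.life_table
    text += "\n" + ",".join(f"{a}:{q:.9g}" for a, q in lt.items())
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_full(
    params: ModelParams,
    analyses: set[str] | None = None,
    seed: int | None = None,
    out_dir: str | Path = "results",
    iterations: int | None = None,
    wtp_grid: np.ndarray | None = None,
) -> RunManifest:
    """Execute the requested analyses and write CSV/JSON outputs + manifest.

    ``analyses`` is a subset of {base, scenario, owsa, psa, ceac}; PSA and
    CEAC share one set of draws.  If no seed is given one is drawn and
    recorded in the manifest, so every run is reproducible from its manifest.
    """
    if analyses is None:
        analyses = set(ANALYSES)
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    files: list[str] = []
    errors: dict[str, str] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files.append(name)

    psa_result: PSAResult | None = None
    for analysis in [a for a in ANALYSES if a in analyses]:
        try:
            if analysis == "base":
                _write(run_base_case(params), "base_case.csv")
            elif analysis == "scenario":
                _write(run_base_case(params, scenario=True), "scenario.csv")
            elif analysis == "owsa":
                _write(tornado_frame(owsa_tornado(params)), "tornado.csv")
            elif analysis == "psa":
                psa_result = run_psa(params, n=iterations, seed=seed)
                _write(psa_result.to_frame(), "psa_draws.csv")
                ne, se_, nw, sw = quadrant_shares(psa_result)
                wtp = params.econ.wtp_usd
                dpairs = (psa_result.delta_cost, psa_result.delta_qaly)
                prob_ce = float(
                    np.mean(wtp * dpairs[1] - dpairs[0] > 0)
                )
                _write(
                    pd.DataFrame(
                        [
                            {
                                "ne": ne,
                                "se": se_,
                                "nw": nw,
                                "sw": sw,
                                "wtp_usd": wtp,
                                "prob_cost_effective": prob_ce,
                                "n": psa_result.n,
                                "seed": psa_result.base_seed,
                            }
                        ]
                    ),
                    "psa_summary.csv",
                )
            elif analysis == "ceac":
                if psa_result is None:
                    psa_result = run_psa(params, n=iterations, seed=seed)
                    _write(psa_result.to_frame(), "psa_draws.csv")
                curve = ceac(psa_result, wtp_grid)
                _write(curve.to_frame(), "ceac.csv")
        except Exception as exc:  # partial failure -> manifest error section
            errors[analysis] = f"{type(exc).__name__}: {exc}"

    manifest = RunManifest(
        config_hash=_config_hash(params),
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        analyses=sorted(analyses),
        files=files,
        flags={
            "u_non_asd": params.flags.u_non_asd,
            "renormalize_tp_fp": params.flags.renormalize_tp_fp,
            "instruments_one_time": params.flags.instruments_one_time,
            "half_cycle": params.flags.half_cycle,
            "fp_workup_cost": params.flags.fp_workup_cost,
            "rr_se_log_scale": params.flags.rr_se_log_scale,
            "wtp_usd": params.econ.wtp_usd,
        },
        errors=errors,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
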