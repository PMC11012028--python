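"""Uncertainty analysis: distribution fitting, PSA, CEAC, tornado.

Parameter uncertainty is propagated by moment-matched parametric
distributions — Beta for probabilities and utilities, Dirichlet for severity
mixes (components drawn jointly so the shares sum to one), Gamma for costs,
and Log-normal for the mortality relative risk.  The probabilistic
sensitivity analysis reruns the whole decision-tree + Markov pipeline for
both strategies at each joint draw; summaries are the cost-effectiveness
plane quadrant shares and the cost-effectiveness acceptability curve.
One-way sensitivity analysis reruns the deterministic model at each
parameter's 95% CI (or ±20%) bounds to build a tornado table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import icer_from_deltas
from .params import ModelParams, ParamSpec, owsa_bounds

__all__ = [
    "FittedDistribution",
    "PSAResult",
    "TornadoEntry",
    "CEACCurve",
    "InfeasibleMomentsError",
    "fit_moment_distribution",
    "sample_params",
    "run_psa",
    "quadrant_shares",
    "ceac",
    "default_wtp_grid",
    "owsa_tornado",
]

log = logging.getLogger(__name__)


class InfeasibleMomentsError(ValueError):
    """Raised when a (mean, SE) pair cannot be matched by the stated family."""


@dataclass(frozen=True)
class FittedDistribution:
    """A sampling distribution with natural parameters matched to (mean, SE)."""

    family: str
    params: dict[str, float | np.ndarray]

    def mean_se(self) -> tuple[np.ndarray, np.ndarray]:
        """Implied mean and SE (per component for Dirichlet) — the round-trip."""
        p = self.params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            m = a / (a + b)
            se = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
            return np.array([m]), np.array([se])
        if self.family == "gamma":
            k, theta = p["shape"], p["scale"]
            return np.array([k * theta]), np.array([math.sqrt(k) * theta])
        if self.family == "lognormal":
            mu, sigma = p["mu_log"], p["sigma_log"]
            m = math.exp(mu + sigma**2 / 2.0)
            se = m * math.sqrt(math.expm1(sigma**2))
            return np.array([m]), np.array([se])
        if self.family == "dirichlet":
            # SE on the moment-matching scale (n_eff = a0): exact for the
            # binding (minimum-n_eff) component, conservative for the rest.
            a = np.asarray(p["alpha"], float)
            a0 = a.sum()
            m = a / a0
            se = np.sqrt(m * (1.0 - m) / a0)
            return m, se
        if self.family == "fixed":
            return np.array([p["value"]]), np.array([0.0])
        raise ValueError(self.family)


def fit_moment_distribution(
    spec: ParamSpec | list[ParamSpec], default_cv: float = 0.20
) -> FittedDistribution:
    """Method-of-moments fit of a spec (or a Dirichlet group of specs).

    Gamma rows without a reported SE use ``se = default_cv * mean`` (the ±20%
    dispersion rule).  The Dirichlet effective sample size is the minimum of
    the per-component ``m(1-m)/se²`` (the most conservative, widest-spread
    choice).
    """
    if isinstance(spec, list):
        means = np.array([s.mean for s in spec], float)
        ses = np.array(
            [s.se if s.se else default_cv * s.mean for s in spec], float
        )
        means = means / means.sum()
        with np.errstate(divide="ignore"):
            n_eff_each = means * (1.0 - means) / ses**2
        n_eff = float(np.min(n_eff_each[np.isfinite(n_eff_each)]))
        if n_eff <= 0:
            raise InfeasibleMomentsError("dirichlet: non-positive effective size")
        return FittedDistribution("dirichlet", {"alpha": means * n_eff})

    m, se = spec.mean, spec.se
    if spec.family == "fixed":
        return FittedDistribution("fixed", {"value": m})
    if not se:
        se = default_cv * m  # the ±20% dispersion rule for rows without a CI
    if se == 0.0:  # zero mean and no SE: degenerate
        return FittedDistribution("fixed", {"value": m})
    if spec.family == "beta":
        if se**2 >= m * (1.0 - m):
            raise InfeasibleMomentsError(
                f"{spec.name}: se²={se**2:.4g} >= mean(1-mean)={m*(1-m):.4g}; "
                "beta moments infeasible"
            )
        nu = m * (1.0 - m) / se**2 - 1.0
        return FittedDistribution("beta", {"alpha": m * nu, "beta": (1.0 - m) * nu})
    if spec.family == "gamma":
        if m <= 0:
            raise InfeasibleMomentsError(f"{spec.name}: gamma needs positive mean")
        return FittedDistribution("gamma", {"shape": (m / se) ** 2, "scale": se**2 / m})
    if spec.family == "lognormal":
        if m <= 0:
            raise InfeasibleMomentsError(f"{spec.name}: lognormal needs positive mean")
        sigma2 = math.log1p((se / m) ** 2)
        return FittedDistribution(
            "lognormal",
            {"mu_log": math.log(m) - sigma2 / 2.0, "sigma_log": math.sqrt(sigma2)},
        )
    if spec.family == "dirichlet":
        raise ValueError(
            f"{spec.name}: dirichlet components must be fitted as a group"
        )
    raise ValueError(f"{spec.name}: unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# Joint sampling
# ---------------------------------------------------------------------------


def _sampling_units(params: ModelParams, default_cv: float):
    """Deterministically ordered (names, fitted distribution) sampling units."""
    units: list[tuple[tuple[str, ...], FittedDistribution]] = []
    seen_groups: set[str] = set()
    for name, spec in params.specs.items():  # dict preserves layout order
        if spec.family == "dirichlet" and spec.group is not None:
            if spec.group in seen_groups:
                continue
            seen_groups.add(spec.group)
            members = [s for s in params.specs.values() if s.group == spec.group]
            fitted = fit_moment_distribution(members, default_cv)
            units.append((tuple(s.name for s in members), fitted))
        else:
            units.append(((name,), fit_moment_distribution(spec, default_cv)))
    return units


def _draw_unit(fitted: FittedDistribution, rng: np.random.Generator) -> np.ndarray:
    p = fitted.params
    if fitted.family == "fixed":
        return np.array([p["value"]])
    if fitted.family == "beta":
        return np.array([rng.beta(p["alpha"], p["beta"])])
    if fitted.family == "gamma":
        return np.array([rng.gamma(p["shape"], p["scale"])])
    if fitted.family == "lognormal":
        return np.array([rng.lognormal(p["mu_log"], p["sigma_log"])])
    if fitted.family == "dirichlet":
        return rng.dirichlet(np.asarray(p["alpha"], float))
    raise ValueError(fitted.family)


def sample_params(
    params: ModelParams, rng: np.random.Generator
) -> ModelParams:
    """One joint parameter draw; fixed parameters pass through unchanged.

    Dirichlet groups are drawn jointly, so sampled severity mixes sum to one
    exactly.  The same generator state always yields the same draw.
    """
    overrides: dict[str, float] = {}
    for names, fitted in _sampling_units(params, params.econ.default_cv):
        values = _draw_unit(fitted, rng)
        for n, v in zip(names, values):
            overrides[n] = float(v)
    return params.with_means(overrides)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental (cost, QALY) pairs from a probabilistic run."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n: int
    base_seed: int | None
    n_redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def _draw_is_valid(sampled: ModelParams) -> bool:
    tr = sampled.transition_rates
    return (
        tr.mild_to_moderate + tr.mild_to_severe <= 1.0
        and tr.moderate_to_mild + tr.moderate_to_severe <= 1.0
        and tr.severe_to_mild + tr.severe_to_moderate <= 1.0
    )


def run_psa(
    params: ModelParams,
    n: int | None = None,
    seed: int | None = None,
    runner=None,
    max_retries: int = 100,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n`` joint draws, full model reruns.

    Each draw samples every uncertain input, reruns the decision tree, the
    Markov cohort and the accrual for both strategies, and records the
    discounted incremental (cost, QALY) pair.  Draws producing invalid
    parameter sets (transition rows exceeding one) are re-drawn, up to
    ``max_retries`` per draw, with a log entry.
    """
    if runner is None:
        from .report import incremental_deltas as runner  # avoid import cycle
    if n is None:
        n = params.econ.psa_iterations
    if n < 1:
        raise ValueError("PSA needs at least one iteration")
    if seed is None:
        seed = params.econ.psa_seed
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    de = np.empty(n)
    n_redraws = 0
    for i in range(n):
        for attempt in range(max_retries + 1):
            sampled = sample_params(params, rng)
            if _draw_is_valid(sampled):
                break
            n_redraws += 1
            log.info("PSA draw %d invalid (attempt %d); re-drawing", i, attempt + 1)
        else:
            raise RuntimeError(f"draw {i}: no valid parameter set in {max_retries} retries")
        dc[i], de[i] = runner(sampled)
    return PSAResult(delta_cost=dc, delta_qaly=de, n=n, base_seed=seed,
                     n_redraws=n_redraws)


def quadrant_shares(psa: PSAResult) -> tuple[float, float, float, float]:
    """Cost-effectiveness-plane shares (NE, SE, NW, SW).

    NE: more effective, more costly; SE: more effective, cost-saving
    (dominant); NW: less effective, more costly (dominated); SW: less
    effective, cost-saving.
    """
    de, dc = psa.delta_qaly, psa.delta_cost
    ne = float(np.mean((de > 0) & (dc > 0)))
    se = float(np.mean((de > 0) & (dc <= 0)))
    nw = float(np.mean((de <= 0) & (dc > 0)))
    sw = float(np.mean((de <= 0) & (dc <= 0)))
    return ne, se, nw, sw


@dataclass(frozen=True)
class CEACCurve:
    """Probability of cost-effectiveness as a function of the WTP threshold."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[idx])


def default_wtp_grid() -> np.ndarray:
    """0 to 10,000 USD/QALY in steps of 100 (spans the base-case ICER and WTP)."""
    return np.arange(0.0, 10_100.0, 100.0)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Fraction of draws with positive net monetary benefit at each WTP."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("WTP grid must be strictly increasing")
    nmb = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=wtp_grid, probability=prob)


# ---------------------------------------------------------------------------
# One-way sensitivity (tornado)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    label_at_low: str = "ICER"
    label_at_high: str = "ICER"

    @property
    def width(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def _owsa_overrides(params: ModelParams, spec: ParamSpec, value: float) -> dict:
    """Overrides setting one parameter to ``value``.

    Dirichlet components are varied one at a time with complementary
    renormalisation: the other components of the group are rescaled to keep
    the mix summing to one.
    """
    if spec.group is None:
        return {spec.name: value}
    members = [s for s in params.specs.values() if s.group == spec.group]
    others = [s for s in members if s.name != spec.name]
    rest = sum(s.mean for s in others)
    total = rest + spec.mean
    target_rest = total - value  # keep the group total invariant
    scale = target_rest / rest if rest > 0 else 0.0
    overrides = {spec.name: value}
    for s in others:
        overrides[s.name] = s.mean * scale
    return overrides


def owsa_tornado(
    params: ModelParams,
    parameters: list[str] | None = None,
    runner=None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over ``parameters`` (default: all non-fixed).

    Each parameter is set to its low and high bound in turn, all else held at
    base case, and the deterministic model is rerun; entries are sorted by
    decreasing ICER excursion width.  Fixed parameters are skipped with a log
    entry.
    """
    if runner is None:
        from .report import incremental_deltas as runner
    if parameters is None:
        parameters = [n for n, s in params.specs.items() if s.family != "fixed"]
    entries: list[TornadoEntry] = []
    for name in parameters:
        spec = params.specs[name]
        if spec.family == "fixed":
            log.info("OWSA: skipping fixed parameter %s", name)
            continue
        lo, hi = owsa_bounds(spec, params.econ.default_cv)
        results = []
        for value in (lo, hi):
            dc, de = runner(params.with_means(_owsa_overrides(params, spec, value)))
            results.append(icer_from_deltas(dc, de))
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                icer_at_low=results[0].icer,
                icer_at_high=results[1].icer,
                label_at_low=results[0].label,
                label_at_high=results[1].label,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "label_at_low": [e.label_at_low for e in entries],
            "label_at_high": [e.label_at_high for e in entries],
            "width": [e.width for e in entries],
        }
    )
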