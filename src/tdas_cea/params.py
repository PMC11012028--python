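"""Model inputs: parameter specs, configuration loading, validation, OWSA bounds.

Every uncertain model input is carried as a :class:`ParamSpec` — a (mean,
standard error, distribution family) triple, optionally tied to a Dirichlet
group when several shares must sum to one.  The full input set for the
cost-utility model (diagnostic-phase probabilities, severity mixes, annual
severity-transition probabilities, mortality relative risk, utilities, all
societal cost components, diagnostic-strategy costs) lives in a nested YAML
configuration; a complete default configuration and a synthetic Thai-like
period life table are bundled with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParamSpec",
    "DiagnosticPerformance",
    "SeverityMix",
    "TransitionRates",
    "MortalityInputs",
    "UtilitySet",
    "CostInputs",
    "DiagnosticCostInputs",
    "EconSettings",
    "ModelFlags",
    "ModelParams",
    "PARAM_LAYOUT",
    "ALL_PARAM_NAMES",
    "load_params",
    "default_params",
    "write_config",
    "validate",
    "owsa_bounds",
    "load_life_table",
]

FAMILIES = ("beta", "dirichlet", "gamma", "lognormal", "fixed")

#: Section -> ordered mapping of parameter name -> (family, dirichlet group).
#: This is the canonical inventory of uncertain inputs; the configuration file
#: must supply exactly these names with their means and standard errors.
PARAM_LAYOUT: dict[str, dict[str, tuple[str, str | None]]] = {
    "diagnostic_phase": {
        "p_test_positive": ("beta", None),
        "p_true_positive": ("beta", None),
        "p_false_positive": ("beta", None),
        "p_delayed_tdas": ("beta", None),
        "p_diagnosed_clin": ("beta", None),
        "p_delayed_clin": ("beta", None),
    },
    "severity_mix_tdas": {
        "p_mild_tdas": ("dirichlet", "mix_tdas"),
        "p_moderate_tdas": ("dirichlet", "mix_tdas"),
        "p_severe_tdas": ("dirichlet", "mix_tdas"),
    },
    "severity_mix_clindx": {
        "p_mild_clin": ("dirichlet", "mix_clin"),
        "p_moderate_clin": ("dirichlet", "mix_clin"),
        "p_severe_clin": ("dirichlet", "mix_clin"),
    },
    "transitions": {
        "tp_mild_to_moderate": ("beta", None),
        "tp_mild_to_severe": ("fixed", None),
        "tp_moderate_to_mild": ("beta", None),
        "tp_moderate_to_severe": ("beta", None),
        "tp_severe_to_mild": ("beta", None),
        "tp_severe_to_moderate": ("beta", None),
    },
    "mortality": {
        "rr_asd": ("lognormal", None),
    },
    "utilities": {
        "u_mild": ("beta", None),
        "u_moderate": ("beta", None),
        "u_severe": ("beta", None),
    },
    "direct_medical": {
        "c_inpatient_mild": ("gamma", None),
        "c_inpatient_moderate": ("gamma", None),
        "c_inpatient_severe": ("gamma", None),
        "p_admission": ("beta", None),
        "p_admitted_mild": ("fixed", None),
        "p_admitted_moderate": ("fixed", None),
        "p_admitted_severe": ("fixed", None),
        "c_outpatient_mild": ("gamma", None),
        "c_outpatient_moderate": ("gamma", None),
        "c_outpatient_severe": ("gamma", None),
        "c_instruments_mild": ("gamma", None),
        "c_instruments_moderate": ("gamma", None),
        "c_instruments_severe": ("gamma", None),
        "p_instruments_mild": ("fixed", None),
        "p_instruments_moderate": ("fixed", None),
        "p_instruments_severe": ("fixed", None),
        "c_activities_mild": ("gamma", None),
        "c_activities_moderate": ("gamma", None),
        "c_activities_severe": ("gamma", None),
        "p_activities_mild": ("fixed", None),
        "p_activities_moderate": ("fixed", None),
        "p_activities_severe": ("fixed", None),
    },
    "direct_nonmedical": {
        "c_travel_outpatient": ("gamma", None),
        "c_food_outpatient": ("gamma", None),
        "c_accommodation_outpatient": ("gamma", None),
        "p_accommodation_outpatient": ("beta", None),
        "n_outpatient_visits_mild": ("gamma", None),
        "n_outpatient_visits_moderate": ("gamma", None),
        "n_outpatient_visits_severe": ("gamma", None),
        "c_caregiver_outpatient": ("gamma", None),
        "c_travel_admission_patient": ("gamma", None),
        "c_food_admission_patient": ("gamma", None),
        "c_accommodation_admission_patient": ("gamma", None),
        "p_accommodation_admission": ("beta", None),
        "c_travel_admission_caregiver": ("gamma", None),
        "c_food_admission_caregiver": ("gamma", None),
        "c_accommodation_admission_caregiver": ("gamma", None),
        "c_caregiver_admission": ("gamma", None),
        "n_admissions_per_year": ("fixed", None),
    },
    "caregiver_home": {
        "c_hired_caregiver": ("gamma", None),
        "p_hired_caregiver": ("fixed", None),
        "c_lost_income": ("gamma", None),
        "p_quit_mild": ("fixed", None),
        "p_quit_moderate": ("fixed", None),
        "p_quit_severe": ("fixed", None),
    },
    "diagnostic_costs": {
        "c_tdas_training": ("gamma", None),
        "c_tdas_instruments": ("gamma", None),
        "c_tdas_maintenance": ("gamma", None),
        "c_cloud": ("gamma", None),
        "c_labor_tdas": ("gamma", None),
        "c_labor_clin": ("gamma", None),
        "n_diagnoses_per_week": ("fixed", None),
        "n_amortization_diagnoses": ("fixed", None),
    },
}

ALL_PARAM_NAMES: tuple[str, ...] = tuple(
    name for section in PARAM_LAYOUT.values() for name in section
)

_NAME_TO_SECTION = {
    name: section for section, names in PARAM_LAYOUT.items() for name in names
}

# Parameters whose support is [0, 1] (probabilities, proportions, utilities).
_UNIT_INTERVAL_PREFIXES = ("p_", "u_", "tp_")


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model input: mean, standard error and sampling family."""

    name: str
    mean: float
    se: float | None
    family: str
    group: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    @property
    def unit_interval(self) -> bool:
        return self.name.startswith(_UNIT_INTERVAL_PREFIXES)


# ---------------------------------------------------------------------------
# Typed views over the flat spec table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticPerformance:
    p_test_positive: float
    p_true_positive: float
    p_false_positive: float
    p_delayed_tdas: float
    p_diagnosed_clin: float
    p_delayed_clin: float


@dataclass(frozen=True)
class SeverityMix:
    """Shares of mild/moderate/severe at diagnosis (normalised on demand)."""

    p_mild: float
    p_moderate: float
    p_severe: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_mild, self.p_moderate, self.p_severe], float)

    def normalized(self) -> "SeverityMix":
        a = self.as_array()
        a = a / a.sum()
        return SeverityMix(*a)


@dataclass(frozen=True)
class TransitionRates:
    """Annual probabilities of moving between ASD severity levels."""

    mild_to_moderate: float
    mild_to_severe: float
    moderate_to_mild: float
    moderate_to_severe: float
    severe_to_mild: float
    severe_to_moderate: float


@dataclass(frozen=True)
class MortalityInputs:
    life_table: pd.Series  # integer age -> annual all-cause death probability
    rr_asd: float


@dataclass(frozen=True)
class UtilitySet:
    u_mild: float
    u_moderate: float
    u_severe: float
    u_non_asd: float = 0.0


@dataclass(frozen=True)
class CostInputs:
    """All Table-style annual/per-event societal cost components (USD)."""

    inpatient_visit: dict[str, float]
    p_admission: float
    admitted_mix: SeverityMix
    outpatient_annual: dict[str, float]
    instruments_cost: dict[str, float]
    instruments_prop: dict[str, float]
    activities_cost: dict[str, float]
    activities_prop: dict[str, float]
    travel_outpatient: float
    food_outpatient: float
    accommodation_outpatient: float
    p_accommodation_outpatient: float
    outpatient_visits: dict[str, float]
    caregiver_outpatient: float
    travel_admission_patient: float
    food_admission_patient: float
    accommodation_admission_patient: float
    p_accommodation_admission: float
    travel_admission_caregiver: float
    food_admission_caregiver: float
    accommodation_admission_caregiver: float
    caregiver_admission: float
    admissions_per_year: float
    hired_caregiver_salary: float
    p_hired_caregiver: float
    lost_income: float
    p_quit: dict[str, float]


@dataclass(frozen=True)
class DiagnosticCostInputs:
    tdas_training_per_provider: float
    tdas_instruments: float
    tdas_maintenance_per_patient_year: float
    cloud_per_patient_year: float
    labor_tdas_per_month: float
    labor_clin_per_month: float
    diagnoses_per_week: float
    amortization_diagnoses_per_provider_year: float


@dataclass(frozen=True)
class EconSettings:
    discount_rate: float = 0.03
    wtp_thb: float = 160_000.0
    exchange_rate: float = 34.995  # THB per USD
    wtp_usd_override: float | None = None
    start_age: float = 3.52
    max_age: int = 100
    psa_iterations: int = 10_000
    psa_seed: int | None = None
    default_cv: float = 0.20

    @property
    def wtp_usd(self) -> float:
        if self.wtp_usd_override is not None:
            return float(self.wtp_usd_override)
        return self.wtp_thb / self.exchange_rate


@dataclass(frozen=True)
class ModelFlags:
    """Documented modelling decisions that can be switched in the config.

    u_non_asd
        Utility credited to children who leave the diagnostic phase without an
        ASD diagnosis (test-negatives, false positives, undiagnosed).  The
        default 0 implements diagnosed-pathway accounting: those children
        accrue neither QALYs nor costs in either arm.
    renormalize_tp_fp
        Treat (p_true_positive, p_false_positive) as a branch distribution
        among test-positives by renormalising the pair (default), rather than
        as sensitivity / 1-specificity on a prevalence-explicit tree.
    instruments_one_time
        Charge the instrument-purchase cost once at model entry instead of
        every cycle.
    half_cycle
        Apply half-cycle correction when accruing rewards.
    fp_workup_cost
        One-off cost (USD) attached to each false-positive child.
    rr_se_log_scale
        Interpret the SE of the mortality relative risk on the log scale
        instead of the natural scale.
    """

    u_non_asd: float = 0.0
    renormalize_tp_fp: bool = True
    instruments_one_time: bool = True
    half_cycle: bool = False
    fp_workup_cost: float = 0.0
    rr_se_log_scale: bool = False


_SEV = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class ModelParams:
    """Complete, validated input set for the cost-utility model."""

    specs: dict[str, ParamSpec]
    econ: EconSettings
    flags: ModelFlags
    life_table: pd.Series
    scenario_clindx_mix: SeverityMix
    pooled_cohort_mix: SeverityMix | None = None

    # -- raw access ---------------------------------------------------------

    def mean(self, name: str) -> float:
        return self.specs[name].mean

    def with_means(self, overrides: Mapping[str, float]) -> "ModelParams":
        """A copy with selected spec means replaced (used by PSA / OWSA)."""
        unknown = set(overrides) - set(self.specs)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        specs = dict(self.specs)
        for name, value in overrides.items():
            specs[name] = replace(specs[name], mean=float(value))
        return replace(self, specs=specs)

    # -- typed views --------------------------------------------------------

    @property
    def diagnostic_performance(self) -> DiagnosticPerformance:
        m = self.mean
        return DiagnosticPerformance(
            p_test_positive=m("p_test_positive"),
            p_true_positive=m("p_true_positive"),
            p_false_positive=m("p_false_positive"),
            p_delayed_tdas=m("p_delayed_tdas"),
            p_diagnosed_clin=m("p_diagnosed_clin"),
            p_delayed_clin=m("p_delayed_clin"),
        )

    def severity_mix(self, strategy: str) -> SeverityMix:
        key = {"TDAS": "tdas", "ClinDx": "clin"}.get(strategy, strategy)
        if key == "tdas":
            names = ("p_mild_tdas", "p_moderate_tdas", "p_severe_tdas")
        elif key == "clin":
            names = ("p_mild_clin", "p_moderate_clin", "p_severe_clin")
        elif key == "clin_scenario":
            return self.scenario_clindx_mix
        else:
            raise KeyError(f"unknown strategy {strategy!r}")
        return SeverityMix(*(self.mean(n) for n in names))

    @property
    def transition_rates(self) -> TransitionRates:
        m = self.mean
        return TransitionRates(
            mild_to_moderate=m("tp_mild_to_moderate"),
            mild_to_severe=m("tp_mild_to_severe"),
            moderate_to_mild=m("tp_moderate_to_mild"),
            moderate_to_severe=m("tp_moderate_to_severe"),
            severe_to_mild=m("tp_severe_to_mild"),
            severe_to_moderate=m("tp_severe_to_moderate"),
        )

    @property
    def mortality(self) -> MortalityInputs:
        return MortalityInputs(life_table=self.life_table, rr_asd=self.mean("rr_asd"))

    @property
    def utilities(self) -> UtilitySet:
        m = self.mean
        return UtilitySet(
            u_mild=m("u_mild"),
            u_moderate=m("u_moderate"),
            u_severe=m("u_severe"),
            u_non_asd=self.flags.u_non_asd,
        )

    @property
    def cost_inputs(self) -> CostInputs:
        m = self.mean
        per_sev = lambda stem: {s: m(f"{stem}_{s}") for s in _SEV}
        return CostInputs(
            inpatient_visit=per_sev("c_inpatient"),
            p_admission=m("p_admission"),
            admitted_mix=SeverityMix(*(m(f"p_admitted_{s}") for s in _SEV)),
            outpatient_annual=per_sev("c_outpatient"),
            instruments_cost=per_sev("c_instruments"),
            instruments_prop=per_sev("p_instruments"),
            activities_cost=per_sev("c_activities"),
            activities_prop=per_sev("p_activities"),
            travel_outpatient=m("c_travel_outpatient"),
            food_outpatient=m("c_food_outpatient"),
            accommodation_outpatient=m("c_accommodation_outpatient"),
            p_accommodation_outpatient=m("p_accommodation_outpatient"),
            outpatient_visits=per_sev("n_outpatient_visits"),
            caregiver_outpatient=m("c_caregiver_outpatient"),
            travel_admission_patient=m("c_travel_admission_patient"),
            food_admission_patient=m("c_food_admission_patient"),
            accommodation_admission_patient=m("c_accommodation_admission_patient"),
            p_accommodation_admission=m("p_accommodation_admission"),
            travel_admission_caregiver=m("c_travel_admission_caregiver"),
            food_admission_caregiver=m("c_food_admission_caregiver"),
            accommodation_admission_caregiver=m("c_accommodation_admission_caregiver"),
            caregiver_admission=m("c_caregiver_admission"),
            admissions_per_year=m("n_admissions_per_year"),
            hired_caregiver_salary=m("c_hired_caregiver"),
            p_hired_caregiver=m("p_hired_caregiver"),
            lost_income=m("c_lost_income"),
            p_quit=per_sev("p_quit"),
        )

    @property
    def diagnostic_costs(self) -> DiagnosticCostInputs:
        m = self.mean
        return DiagnosticCostInputs(
            tdas_training_per_provider=m("c_tdas_training"),
            tdas_instruments=m("c_tdas_instruments"),
            tdas_maintenance_per_patient_year=m("c_tdas_maintenance"),
            cloud_per_patient_year=m("c_cloud"),
            labor_tdas_per_month=m("c_labor_tdas"),
            labor_clin_per_month=m("c_labor_clin"),
            diagnoses_per_week=m("n_diagnoses_per_week"),
            amortization_diagnoses_per_provider_year=m("n_amortization_diagnoses"),
        )


# ---------------------------------------------------------------------------
# Loading / writing configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Raised when a configuration is incomplete or malformed."""


def _package_data(name: str):
    return importlib.resources.files("tdas_cea").joinpath("data", name)


def load_life_table(source) -> pd.Series:
    """Read a life table CSV with columns ``age,qx`` into an age-indexed Series."""
    if hasattr(source, "read"):
        df = pd.read_csv(source)
    else:
        df = pd.read_csv(Path(source))
    if not {"age", "qx"} <= set(df.columns):
        raise ConfigError("life table must have columns 'age' and 'qx'")
    s = pd.Series(df["qx"].to_numpy(float), index=df["age"].to_numpy(int))
    return s.sort_index()


def _parse_spec(name: str, entry, family: str, group: str | None) -> ParamSpec:
    if not isinstance(entry, Mapping) or "mean" not in entry:
        raise ConfigError(f"parameter {name!r} must be a mapping with a 'mean'")
    mean = float(entry["mean"])
    se = entry.get("se", None)
    se = None if se is None else float(se)
    fam = str(entry.get("family", family))
    grp = entry.get("group", group)
    return ParamSpec(name=name, mean=mean, se=se, family=fam, group=grp)


def load_params(source) -> "ModelParams":
    """Load a :class:`ModelParams` from a YAML file path, stream, or dict.

    The configuration must contain every parameter named in
    :data:`PARAM_LAYOUT`; missing sections or keys raise :class:`ConfigError`
    naming what is absent.  Values are stored verbatim — defaults are applied
    only to economic settings and decision flags, never to study inputs.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
        base_dir = Path.cwd()
    else:
        path = Path(source)
        cfg = yaml.safe_load(path.read_text())
        base_dir = path.parent

    specs: dict[str, ParamSpec] = {}
    for section, names in PARAM_LAYOUT.items():
        block = cfg.get(section)
        if block is None:
            raise ConfigError(f"missing configuration section {section!r}")
        for name, (family, group) in names.items():
            if name not in block:
                raise ConfigError(f"missing parameter {name!r} in section {section!r}")
            specs[name] = _parse_spec(name, block[name], family, group)
        extra = set(block) - set(names)
        if extra:
            raise ConfigError(f"unknown parameters in {section!r}: {sorted(extra)}")

    econ_cfg = dict(cfg.get("economics", {}))
    econ = EconSettings(**econ_cfg)
    flags = ModelFlags(**dict(cfg.get("flags", {})))

    scen = cfg.get("scenario_clindx_mix")
    if scen is None:
        raise ConfigError("missing configuration section 'scenario_clindx_mix'")
    scenario_mix = SeverityMix(*(float(scen[s]) for s in _SEV))

    lt_cfg = cfg.get("life_table")
    if lt_cfg in (None, "bundled"):
        with importlib.resources.as_file(
            _package_data("life_table_thai_synthetic.csv")
        ) as p:
            life_table = load_life_table(p)
    else:
        lt_path = Path(lt_cfg)
        if not lt_path.is_absolute():
            lt_path = base_dir / lt_path
        life_table = load_life_table(lt_path)

    pooled = cfg.get("pooled_cohort_mix")
    pooled_mix = (
        None if pooled is None else SeverityMix(*(float(pooled[s]) for s in _SEV))
    )

    return ModelParams(
        specs=specs,
        econ=econ,
        flags=flags,
        life_table=life_table,
        scenario_clindx_mix=scenario_mix,
        pooled_cohort_mix=pooled_mix,
    )


def default_params(**econ_overrides) -> ModelParams:
    """The bundled default configuration (all published input values)."""
    text = _package_data("default_config.yaml").read_text()
    params = load_params(yaml.safe_load(text))
    if econ_overrides:
        params = replace(params, econ=replace(params.econ, **econ_overrides))
    return params


def write_config(params: ModelParams) -> dict:
    """Serialise a parameter set back to the nested configuration mapping.

    ``load_params(write_config(p))`` reproduces every mean and SE exactly.
    """
    cfg: dict = {}
    for section, names in PARAM_LAYOUT.items():
        block = {}
        for name in names:
            spec = params.specs[name]
            entry = {"mean": spec.mean, "se": spec.se, "family": spec.family}
            if spec.group is not None:
                entry["group"] = spec.group
            block[name] = entry
        cfg[section] = block
    cfg["economics"] = {
        "discount_rate": params.econ.discount_rate,
        "wtp_thb": params.econ.wtp_thb,
        "exchange_rate": params.econ.exchange_rate,
        "wtp_usd_override": params.econ.wtp_usd_override,
        "start_age": params.econ.start_age,
        "max_age": params.econ.max_age,
        "psa_iterations": params.econ.psa_iterations,
        "psa_seed": params.econ.psa_seed,
        "default_cv": params.econ.default_cv,
    }
    cfg["flags"] = {
        "u_non_asd": params.flags.u_non_asd,
        "renormalize_tp_fp": params.flags.renormalize_tp_fp,
        "instruments_one_time": params.flags.instruments_one_time,
        "half_cycle": params.flags.half_cycle,
        "fp_workup_cost": params.flags.fp_workup_cost,
        "rr_se_log_scale": params.flags.rr_se_log_scale,
    }
    cfg["scenario_clindx_mix"] = {
        s: getattr(params.scenario_clindx_mix, f"p_{s}") for s in _SEV
    }
    if params.pooled_cohort_mix is not None:
        cfg["pooled_cohort_mix"] = {
            s: getattr(params.pooled_cohort_mix, f"p_{s}") for s in _SEV
        }
    cfg["life_table"] = "bundled"
    return cfg


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_MIX_TOL = 5e-3  # published shares are rounded to 4 decimals


def validate(params: ModelParams) -> list[str]:
    """Check every input invariant; return a list of human-readable violations.

    An empty list means the parameter set is internally consistent.  Violations
    are data, not exceptions, so a caller can report all of them at once.
    """
    v: list[str] = []

    for name, spec in params.specs.items():
        if spec.se is not None and spec.se < 0:
            v.append(f"{name}: standard error {spec.se} is negative")
        if spec.unit_interval and not (0.0 <= spec.mean <= 1.0):
            v.append(f"{name}: value {spec.mean} outside [0, 1]")
        if not spec.unit_interval and spec.mean < 0:
            v.append(f"{name}: value {spec.mean} is negative")
        if spec.family == "fixed" and spec.se not in (None, 0.0):
            v.append(f"{name}: fixed parameter carries nonzero SE {spec.se}")
        if spec.family in ("beta", "dirichlet") and not (0.0 <= spec.mean <= 1.0):
            v.append(f"{name}: {spec.family} mean {spec.mean} outside [0, 1]")

    for label, mix in (
        ("TDAS severity mix", params.severity_mix("tdas")),
        ("ClinDx severity mix", params.severity_mix("clin")),
        ("scenario ClinDx severity mix", params.scenario_clindx_mix),
        ("admitted severity shares", params.cost_inputs.admitted_mix),
    ):
        total = float(mix.as_array().sum())
        if abs(total - 1.0) > _MIX_TOL:
            v.append(f"{label}: severity mix sums to {total:.4g}")

    tr = params.transition_rates
    for origin, total in (
        ("mild", tr.mild_to_moderate + tr.mild_to_severe),
        ("moderate", tr.moderate_to_mild + tr.moderate_to_severe),
        ("severe", tr.severe_to_mild + tr.severe_to_moderate),
    ):
        if total > 1.0 + 1e-12:
            v.append(f"transitions from {origin}: off-diagonal sum {total:.4g} > 1")

    lt = params.life_table
    ages = lt.index.to_numpy()
    expected = np.arange(ages.min(), ages.max() + 1)
    if ages.min() > 0:
        v.append(f"life table: does not start at age 0 (starts at {ages.min()})")
    if not np.array_equal(ages, expected):
        missing = sorted(set(expected) - set(ages))
        v.append(f"life table: missing ages {missing[:5]}")
    bad = lt[(lt < 0) | (lt > 1)]
    for age, q in bad.items():
        v.append(f"life table: q({age}) = {q} outside [0, 1]")
    if ages.max() < params.econ.max_age:
        v.append(
            f"life table: ends at age {ages.max()} before max_age {params.econ.max_age}"
        )

    e = params.econ
    if not (0.0 <= e.discount_rate < 1.0):
        v.append(f"economics: discount rate {e.discount_rate} outside [0, 1)")
    if e.exchange_rate <= 0:
        v.append("economics: exchange rate must be positive")
    if not (e.start_age < e.max_age):
        v.append("economics: start_age must be below max_age")
    if params.mean("rr_asd") <= 0:
        v.append("rr_asd: relative risk must be positive")
    if not (0.0 <= params.flags.u_non_asd <= 1.0):
        v.append(f"flags: u_non_asd {params.flags.u_non_asd} outside [0, 1]")
    dc = params.diagnostic_costs
    if dc.diagnoses_per_week <= 0:
        v.append("n_diagnoses_per_week: must be positive")
    return v


# ---------------------------------------------------------------------------
# One-way sensitivity bounds
# ---------------------------------------------------------------------------


def owsa_bounds(
    spec: ParamSpec, default_cv: float = 0.20
) -> tuple[float, float]:
    """Low/high excursion for one-way sensitivity analysis.

    With a reported SE the bounds are the 95% CI ``mean ± 1.96·se`` clamped to
    the family support; without one, ``±default_cv`` (20%) of the mean.
    """
    if spec.family == "fixed":
        raise ValueError(f"parameter {spec.name!r} is fixed")
    if spec.se is not None and spec.se > 0:
        lo = spec.mean - 1.96 * spec.se
        hi = spec.mean + 1.96 * spec.se
    else:
        lo = (1.0 - default_cv) * spec.mean
        hi = (1.0 + default_cv) * spec.mean
    if spec.family in ("beta", "dirichlet") or spec.unit_interval:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    else:  # gamma / lognormal: non-negative support
        lo = max(lo, 0.0)
    return lo, hi
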