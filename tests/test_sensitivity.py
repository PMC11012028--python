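"""Distribution fitting, joint sampling, PSA summaries, CEAC, tornado."""

import dataclasses
import math

import numpy as np
import pytest

from tdas_cea.params import ALL_PARAM_NAMES, ParamSpec
from tdas_cea.sensitivity import (
    InfeasibleMomentsError,
    PSAResult,
    _sampling_units,
    ceac,
    fit_moment_distribution,
    owsa_tornado,
    quadrant_shares,
    run_psa,
    sample_params,
)


def test_beta_method_of_moments():
    f = fit_moment_distribution(ParamSpec("p", 0.8990, 0.0339, "beta"))
    nu = 0.8990 * 0.1010 / 0.0339**2 - 1  # 78.01
    assert f.params["alpha"] == pytest.approx(0.8990 * nu, rel=1e-9)
    assert f.params["beta"] == pytest.approx(0.1010 * nu, rel=1e-9)
    assert f.params["alpha"] == pytest.approx(70.13, abs=0.01)
    assert f.params["beta"] == pytest.approx(7.88, abs=0.01)


def test_gamma_moment_match():
    f = fit_moment_distribution(ParamSpec("c", 66.0, 11.0, "gamma"))
    assert f.params["shape"] == pytest.approx(36.0)
    assert f.params["scale"] == pytest.approx(11**2 / 66)  # 1.8333


def test_lognormal_natural_scale_match():
    f = fit_moment_distribution(ParamSpec("rr", 2.37, 0.0942, "lognormal"))
    sigma2 = math.log(1 + (0.0942 / 2.37) ** 2)
    assert f.params["sigma_log"] == pytest.approx(math.sqrt(sigma2), rel=1e-9)
    assert f.params["mu_log"] == pytest.approx(math.log(2.37) - sigma2 / 2, rel=1e-9)
    assert f.params["mu_log"] == pytest.approx(0.86210, abs=1e-4)
    assert f.params["sigma_log"] == pytest.approx(0.03973, abs=1e-4)


def test_dirichlet_min_component_effective_size():
    specs = [
        ParamSpec("p_mild_tdas", 0.1111, 0.0786, "dirichlet", "mix_tdas"),
        ParamSpec("p_moderate_tdas", 0.5069, 0.0585, "dirichlet", "mix_tdas"),
        ParamSpec("p_severe_tdas", 0.3819, 0.0655, "dirichlet", "mix_tdas"),
    ]
    f = fit_moment_distribution(specs)
    alpha = np.asarray(f.params["alpha"])
    # per-component n_eff: 15.99 / 73.04 / 55.02 -> minimum rule
    assert alpha.sum() == pytest.approx(16.0, abs=0.05)
    assert alpha == pytest.approx([1.78, 8.11, 6.11], abs=0.01)


def test_gamma_without_se_uses_default_cv():
    f = fit_moment_distribution(ParamSpec("c", 151.0, None, "gamma"), default_cv=0.2)
    se = 0.2 * 151.0
    assert f.params["shape"] == pytest.approx((151 / se) ** 2)  # = 25
    assert f.params["scale"] == pytest.approx(se**2 / 151)


def test_infeasible_beta_moments_raise():
    with pytest.raises(InfeasibleMomentsError):
        fit_moment_distribution(ParamSpec("p", 0.5, 0.6, "beta"))


def test_moment_round_trip_all_inputs(params):
    """Each fitted family reproduces the configured mean (and SE) to 1e-6."""
    for names, fitted in _sampling_units(params, params.econ.default_cv):
        means, ses = fitted.mean_se()
        specs = [params.specs[n] for n in names]
        input_means = np.array([s.mean for s in specs], float)
        if fitted.family == "dirichlet":
            input_means = input_means / input_means.sum()
        assert means == pytest.approx(input_means, rel=1e-6, abs=1e-12)
        if fitted.family == "fixed":
            continue
        input_ses = np.array(
            [s.se if s.se else params.econ.default_cv * s.mean for s in specs]
        )
        if fitted.family == "dirichlet":
            # the binding (min effective-size) component round-trips exactly;
            # the others are sampled more conservatively (wider)
            ratios = ses / input_ses
            assert ratios.min() == pytest.approx(1.0, rel=1e-6)
            assert np.all(ratios >= 1.0 - 1e-9)
        else:
            assert ses == pytest.approx(input_ses, rel=1e-6)


def test_same_seed_gives_identical_draws(params):
    a = sample_params(params, np.random.default_rng(42))
    b = sample_params(params, np.random.default_rng(42))
    for name in ALL_PARAM_NAMES:
        assert a.mean(name) == b.mean(name)
    c = sample_params(params, np.random.default_rng(43))
    assert any(a.mean(n) != c.mean(n) for n in ALL_PARAM_NAMES)


def _all_fixed(params):
    specs = {
        n: dataclasses.replace(s, family="fixed", se=None)
        for n, s in params.specs.items()
    }
    return dataclasses.replace(params, specs=specs)


def test_all_fixed_sampling_returns_base_means(params):
    fixed = _all_fixed(params)
    drawn = sample_params(fixed, np.random.default_rng(0))
    for name in ALL_PARAM_NAMES:
        assert drawn.mean(name) == params.mean(name)


def test_sampled_severity_mixes_sum_to_one(params):
    rng = np.random.default_rng(1)
    for _ in range(50):
        s = sample_params(params, rng)
        for arm in ("tdas", "clin"):
            assert s.severity_mix(arm).as_array().sum() == pytest.approx(1.0, abs=1e-12)


def test_sample_mean_recovers_input_mean(params):
    """10,000 draws of the test-positive probability average to ~0.8990."""
    rng = np.random.default_rng(7)
    fitted = fit_moment_distribution(params.specs["p_test_positive"])
    draws = rng.beta(fitted.params["alpha"], fitted.params["beta"], size=10_000)
    mc_se = 0.0339 / math.sqrt(10_000)
    assert abs(draws.mean() - 0.8990) < 3 * mc_se


# -- PSA ----------------------------------------------------------------------


def test_all_fixed_psa_degenerates_to_base_case(params):
    from tdas_cea.report import incremental_deltas

    fixed = _all_fixed(params)
    psa = run_psa(fixed, n=5, seed=0)
    dc0, de0 = incremental_deltas(params)
    assert np.all(psa.delta_cost == psa.delta_cost[0])
    assert psa.delta_cost[0] == pytest.approx(dc0, rel=1e-12)
    assert psa.delta_qaly[0] == pytest.approx(de0, rel=1e-12)


def test_single_draw_psa(params):
    psa = run_psa(params, n=1, seed=3)
    assert psa.n == 1 and psa.delta_cost.shape == (1,)


def test_psa_default_iteration_count(params):
    psa = run_psa(params, runner=lambda p: (0.0, 0.0))
    assert psa.n == params.econ.psa_iterations == 10_000


def test_psa_reproducible_under_seed(params):
    a = run_psa(params, n=20, seed=11)
    b = run_psa(params, n=20, seed=11)
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert np.array_equal(a.delta_qaly, b.delta_qaly)


def _toy_psa(points):
    dc, de = zip(*points)
    return PSAResult(
        delta_cost=np.array(dc, float), delta_qaly=np.array(de, float),
        n=len(points), base_seed=None,
    )


def test_quadrant_shares_hand_classification():
    # (cost, effect): NE, NW, SE
    psa = _toy_psa([(100, 1), (100, -1), (-50, 1)])
    assert quadrant_shares(psa) == pytest.approx((1 / 3, 1 / 3, 1 / 3, 0.0))


def test_quadrants_all_northeast():
    psa = _toy_psa([(10, 1)] * 4)
    assert quadrant_shares(psa) == (1.0, 0.0, 0.0, 0.0)


def test_quadrants_symmetric_cloud():
    rng = np.random.default_rng(5)
    n = 40_000
    psa = PSAResult(rng.normal(size=n), rng.normal(size=n), n, None)
    shares = np.array(quadrant_shares(psa))
    tol = 3 * math.sqrt(0.25 * 0.75 / n)
    assert shares == pytest.approx(np.full(4, 0.25), abs=tol)
    assert shares.sum() == pytest.approx(1.0)


def test_ceac_toy_points():
    psa = _toy_psa([(100, 1), (-50, 1), (100, -1)])
    curve = ceac(psa, np.array([75.0]))
    assert curve.probability[0] == pytest.approx(1 / 3)


def test_ceac_limits():
    psa = _toy_psa([(100, 1), (-50, 1), (100, -1), (-10, -2)])
    low = ceac(psa, np.array([0.0]))
    assert low.probability[0] == pytest.approx(np.mean(psa.delta_cost < 0))
    high = ceac(psa, np.array([1e12]))
    assert high.probability[0] == pytest.approx(np.mean(psa.delta_qaly > 0))


def test_ceac_requires_increasing_grid():
    psa = _toy_psa([(1, 1)])
    with pytest.raises(ValueError):
        ceac(psa, np.array([100.0, 50.0]))


def test_ceac_consistent_with_nmb_share(params):
    psa = run_psa(params, n=200, seed=9)
    wtp = params.econ.wtp_usd
    direct = np.mean(wtp * psa.delta_qaly - psa.delta_cost > 0)
    curve = ceac(psa, np.array([wtp]))
    assert curve.probability[0] == pytest.approx(direct)


# -- tornado ------------------------------------------------------------------


def test_tornado_sorted_by_width(params):
    entries = owsa_tornado(params, ["u_mild", "c_activities_severe", "p_admission"])
    widths = [e.width for e in entries]
    assert widths == sorted(widths, reverse=True)


def test_tornado_skips_fixed_parameters(params):
    entries = owsa_tornado(params, ["n_diagnoses_per_week", "u_mild"])
    assert [e.parameter for e in entries] == ["u_mild"]


def test_zero_width_bounds_give_zero_width(params):
    zeroed = params.with_means({"c_cloud": 0.0})
    entry = owsa_tornado(zeroed, ["c_cloud"])[0]
    assert entry.low == entry.high == 0.0
    assert entry.width == 0.0


def test_additive_cost_excursion_matches_rerun_oracle(params):
    """The TDAS maintenance charge enters ΔC with unit exposure: moving it by
    ±x shifts ΔC by exactly ±x, independently verified by a full rerun."""
    from tdas_cea.params import owsa_bounds
    from tdas_cea.report import incremental_deltas

    dc0, de0 = incremental_deltas(params)
    spec = params.specs["c_tdas_maintenance"]
    lo, hi = owsa_bounds(spec, params.econ.default_cv)
    for bound in (lo, hi):
        dc, de = incremental_deltas(params.with_means({"c_tdas_maintenance": bound}))
        assert dc == pytest.approx(dc0 + (bound - spec.mean), rel=1e-9)
        assert de == pytest.approx(de0, rel=1e-12)


def test_tornado_dirichlet_variation_keeps_mix_normalised(params):
    from tdas_cea.sensitivity import _owsa_overrides

    spec = params.specs["p_severe_clin"]
    total0 = params.severity_mix("clin").as_array().sum()
    for value in (0.4, 0.8):
        over = _owsa_overrides(params, spec, value)
        varied = params.with_means(over)
        assert varied.severity_mix("clin").as_array().sum() == pytest.approx(
            total0, abs=1e-12
        )
        assert varied.mean("p_severe_clin") == value
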