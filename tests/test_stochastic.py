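"""SSA simulation: determinism, closed-form means, mean matching, noise
ordering, and agreement with the master-equation oracle."""

import math

import numpy as np
import pytest

import _cme
from coldshock.analytic import analytic_omega_one_step
from coldshock.stochastic import (ConfigurationError, InconsistencyError,
                                  ModelVariant, RateSet, SimulationConfig,
                                  match_mean, relative_cv2, simulate,
                                  stationary_mean_protein,
                                  steady_state_moments)


def test_no_production_means_empty_cell(fast_config):
    rates = RateSet(k1=0.0, k2=0.05, lambda1=0.05, lambda2=0.005)
    res = simulate("one_step", rates, fast_config)
    assert not res.rna.any()
    assert not res.protein.any()


def test_seed_determinism(fast_rates, fast_config):
    a = simulate("one_step", fast_rates, fast_config)
    b = simulate("one_step", fast_rates, fast_config)
    assert np.array_equal(a.protein, b.protein)
    assert np.array_equal(a.rna, b.rna)
    c = simulate("one_step", fast_rates,
                 SimulationConfig(**{**fast_config.__dict__, "seed": 12}))
    assert not np.array_equal(a.protein, c.protein)


def test_one_step_mean_matches_closed_form(fast_rates, fast_config):
    """Pooled mean ~ k1*k2/(lambda1*lambda2) within 3 Monte-Carlo SEM."""
    res = simulate("one_step", fast_rates, fast_config)
    m = steady_state_moments(res)
    expected = stationary_mean_protein("one_step", fast_rates)
    assert expected == pytest.approx(20.0)
    assert abs(m.M - expected) < 3 * m.sem_mean


def test_one_step_omega_matches_analytic(fast_rates, fast_config):
    res = simulate("one_step", fast_rates, fast_config)
    m = steady_state_moments(res)
    expected = analytic_omega_one_step(fast_rates.k2, fast_rates.lambda1,
                                       fast_rates.lambda2)
    assert abs(m.omega - expected) < 3 * m.sem_omega


def test_moments_of_constant_samples():
    m = steady_state_moments(np.full(50, 7.0))
    assert m.M == pytest.approx(7.0)
    assert m.variance == pytest.approx(0.0)
    assert m.cv2 == pytest.approx(0.0)
    assert m.omega == pytest.approx(0.0)


def test_moments_of_gamma_reference():
    rng = np.random.default_rng(3)
    x = rng.gamma(4.0, 25.0, size=200_000)
    m = steady_state_moments(x)
    assert m.M == pytest.approx(100.0, rel=0.02)
    assert m.cv2 == pytest.approx(0.25, rel=0.05)
    assert m.skewness == pytest.approx(1.0, rel=0.1)


def test_zero_mean_flagged():
    m = steady_state_moments(np.zeros(100))
    assert m.flag_undefined


class TestMatchMean:
    def test_on_off_symmetric_switching_doubles_k1(self, fast_rates):
        matched = match_mean("on_off", fast_rates,
                             {"k_plus": 0.01, "k_minus": 0.01})
        assert matched.k1 == pytest.approx(2 * fast_rates.k1)

    def test_on_off_never_locking_is_identity(self, fast_rates):
        matched = match_mean("on_off", fast_rates,
                             {"k_plus": 0.01, "k_minus": 0.0})
        assert matched.k1 == pytest.approx(fast_rates.k1)

    def test_two_step_even_split(self, fast_rates):
        matched = match_mean("two_step", fast_rates)
        assert matched.k1a == pytest.approx(2 * fast_rates.k1)
        assert matched.k1b == pytest.approx(2 * fast_rates.k1)

    @pytest.mark.parametrize("variant, fixed", [
        ("on_off", {"k_plus": 0.01}),                         # underdetermined
        ("two_step", {"k1a": 0.3, "k1b": 0.3}),               # overdetermined
        ("one_step", {"k_plus": 1.0}),                        # no free params
    ])
    def test_bad_fixed_sets_rejected(self, fast_rates, variant, fixed):
        with pytest.raises(ConfigurationError):
            match_mean(variant, fast_rates, fixed)

    @pytest.mark.parametrize("variant, fixed", [
        ("on_off", {"k_plus": 0.02, "k_minus": 0.02}),
        ("two_step", None),
        ("two_step", {"k1a": 0.5}),
        ("two_step_on_off", {"k_plus": 0.05, "k_minus": 0.05}),
        ("dual_on_off", {"k_plus": 0.05, "k_minus": 0.05}),
    ])
    def test_analytic_mean_conserved(self, fast_rates, variant, fixed):
        matched = match_mean(variant, fast_rates, fixed)
        assert stationary_mean_protein(variant, matched) == pytest.approx(
            stationary_mean_protein("one_step", fast_rates))

    @pytest.mark.parametrize("variant, fixed", [
        ("on_off", {"k_plus": 0.02, "k_minus": 0.02}),
        ("two_step", None),
        ("two_step_on_off", {"k_plus": 0.05, "k_minus": 0.05}),
        ("dual_on_off", {"k_plus": 0.05, "k_minus": 0.05}),
    ])
    def test_simulated_mean_conserved(self, fast_rates, fast_config,
                                      variant, fixed):
        matched = match_mean(variant, fast_rates, fixed)
        mom_v = steady_state_moments(simulate(variant, matched, fast_config))
        ref_cfg = SimulationConfig(**{**fast_config.__dict__, "seed": 999})
        mom_r = steady_state_moments(simulate("one_step", fast_rates, ref_cfg))
        sem = math.hypot(mom_v.sem_mean, mom_r.sem_mean)
        assert abs(mom_v.M - mom_r.M) < 3 * sem


def test_noise_ordering_at_matched_mean(fast_rates, fast_config):
    """CV2(two-step) < CV2(one-step) < CV2(slow-switching ON-OFF)."""
    on = match_mean("on_off", fast_rates, {"k_plus": 0.005, "k_minus": 0.005})
    two = match_mean("two_step", fast_rates)
    r_on = relative_cv2("on_off", on, fast_rates, fast_config)
    r_two = relative_cv2("two_step", two, fast_rates, fast_config)
    assert r_on.ratio - r_on.sem_ratio > 1.0
    assert r_two.ratio + r_two.sem_ratio < 1.0


def test_relative_cv2_identity(fast_rates, fast_config):
    r = relative_cv2("one_step", fast_rates, fast_rates, fast_config)
    assert abs(r.ratio - 1.0) < 3 * r.sem_ratio


def test_relative_cv2_rejects_mismatched_means(fast_rates, fast_config):
    unmatched = RateSet(k1=0.3, k2=0.05, lambda1=0.05, lambda2=0.005,
                        k_plus=0.01, k_minus=0.01)
    with pytest.raises(InconsistencyError):
        relative_cv2("on_off", unmatched, fast_rates, fast_config)


def test_required_rates_enforced():
    with pytest.raises(ConfigurationError):
        RateSet(k1=0.1, k2=0.05, lambda1=0.05, lambda2=0.005).validate_for(
            ModelVariant.ON_OFF)  # missing k_plus
    with pytest.raises(ConfigurationError):
        RateSet(k1=-1.0)


class TestMasterEquationOracle:
    """Stationary SSA moments vs direct CME solution on truncated spaces."""

    CFG = SimulationConfig(horizon=2.5e5, n_runs=30, sample_interval=200.0,
                           seed=21)

    def test_one_step(self, fast_rates):
        M_cme, var_cme, cv2_cme = _cme.one_step_moments(
            fast_rates.k1, fast_rates.k2, fast_rates.lambda1,
            fast_rates.lambda2, rmax=14, pmax=90)
        m = steady_state_moments(simulate("one_step", fast_rates, self.CFG))
        assert m.M == pytest.approx(M_cme, rel=0.02)
        assert m.cv2 == pytest.approx(cv2_cme, rel=0.02)

    def test_on_off(self, fast_rates):
        rates = match_mean("on_off", fast_rates,
                           {"k_plus": 0.02, "k_minus": 0.02})
        M_cme, var_cme, cv2_cme = _cme.on_off_moments(
            rates.k1, rates.k_plus, rates.k_minus, rates.k2,
            rates.lambda1, rates.lambda2, rmax=20, pmax=160)
        m = steady_state_moments(simulate("on_off", rates, self.CFG))
        assert m.M == pytest.approx(M_cme, rel=0.02)
        assert m.cv2 == pytest.approx(cv2_cme, rel=0.02)
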