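"""Two-step priming simulator: calcium, rates, trains, recovery,
stochastic sampling."""

import numpy as np
import pytest
from dataclasses import replace

from synprime.simulator import (CaTransientParams, DEFAULT_CA_PARAMS,
                                HK_PARAMS, PrimingModelParams, Protocol,
                                SimState, WT_PARAMS, global_ca,
                                rate_constants, simulate_recovery,
                                simulate_train, simulate_train_stochastic)


class TestGlobalCa:
    def test_no_aps_is_resting(self):
        cap = CaTransientParams()
        t = np.linspace(0, 2, 7)
        np.testing.assert_allclose(global_ca(cap, [], t),
                                   np.full(7, cap.ca_rest))

    def test_single_transient_decay(self):
        cap = CaTransientParams(ca_increment_per_ap=100.0, tau_global=0.5)
        ca = global_ca(cap, [0.0], 0.5)
        assert ca == pytest.approx(cap.ca_rest + 100.0 / np.e)

    def test_train_summation_matches_geometric_sum(self):
        cap = CaTransientParams(ca_increment_per_ap=30.0, tau_global=0.15)
        ap = Protocol.regular_train(200.0, 25).ap_times
        t = ap[-1]
        q = np.exp(-0.005 / 0.15)
        expected = cap.ca_rest + 30.0 * (1 - q ** 25) / (1 - q)
        assert global_ca(cap, ap, t) == pytest.approx(expected, rel=1e-12)


class TestRateConstants:
    def test_at_rest(self):
        k1, k2 = rate_constants(WT_PARAMS, 50.0)
        assert (k1, k2) == (WT_PARAMS.k1_rest, WT_PARAMS.k2_rest)

    def test_calcium_insensitive_when_sigmas_zero(self):
        p = replace(WT_PARAMS, sigma1=0.0, sigma2=0.0)
        assert rate_constants(p, 5000.0) == (p.k1_rest, p.k2_rest)

    def test_unit_micromolar_step(self):
        k1, k2 = rate_constants(WT_PARAMS, 1050.0)
        assert k1 == pytest.approx(WT_PARAMS.k1_rest + WT_PARAMS.sigma1)
        assert k2 == pytest.approx(WT_PARAMS.k2_rest + WT_PARAMS.sigma2)

    def test_cap_and_monotonicity(self):
        p = replace(WT_PARAMS, rate_cap=2.0)
        ks = [rate_constants(p, ca)[0] for ca in (50, 500, 5000, 5e6)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        assert ks[-1] == 2.0


class TestRestingState:
    def test_f_ts_identity(self):
        assert WT_PARAMS.resting_f_ts == pytest.approx(
            WT_PARAMS.k2_rest / (WT_PARAMS.k2_rest + WT_PARAMS.b2))

    def test_resting_state_is_stationary(self):
        # one quiet second of integration moves occupancies < 0.1%
        s0 = WT_PARAMS.resting_state()
        r = simulate_train(WT_PARAMS, DEFAULT_CA_PARAMS,
                           Protocol([1.0]), initial_state=s0)
        assert r.m1 == pytest.approx(WT_PARAMS.p_fusion_0 * s0.TS, rel=1e-3)

    def test_f_ts_monotone_in_rates(self):
        up = replace(WT_PARAMS, k2_rest=WT_PARAMS.k2_rest * 2)
        down = replace(WT_PARAMS, b2=WT_PARAMS.b2 * 2)
        assert up.resting_f_ts > WT_PARAMS.resting_f_ts > down.resting_f_ts

    def test_with_frp_and_with_f_ts(self):
        p = WT_PARAMS.with_f_ts(0.4).with_frp(1234.0)
        assert p.resting_f_ts == pytest.approx(0.4)
        assert p.resting_frp == pytest.approx(1234.0)


class TestSimulateTrain:
    def test_site_conservation_along_trace(self):
        r = simulate_train(WT_PARAMS, protocol=Protocol.regular_train(200, 25),
                           record_trace=True)
        totals = r.trace.sum(axis=1)
        np.testing.assert_allclose(totals, WT_PARAMS.N_total, rtol=1e-9)

    def test_first_response_is_p_times_ts(self):
        r = simulate_train(WT_PARAMS, protocol=Protocol.regular_train(100, 3))
        assert r.m1 == pytest.approx(
            WT_PARAMS.p_fusion_0 * WT_PARAMS.resting_state().TS, rel=1e-9)

    def test_geometric_depletion_limit(self):
        p = PrimingModelParams(k1_rest=0, sigma1=0, b1=0, k2_rest=0,
                               sigma2=0, b2=0, p_fusion_0=0.3,
                               ap_conversion=0.0, facilitation_gain=0.0)
        s0 = SimState(t=0.0, ES=0.0, LS=0.0, TS=1000.0, TSL=0.0, ERS=0.0,
                      p_fusion_now=0.3, ca_now=float("nan"))
        r = simulate_train(p, protocol=Protocol.regular_train(100, 12),
                           initial_state=s0)
        exact = 1000 * 0.3 * 0.7 ** np.arange(12)
        np.testing.assert_allclose(r.m, exact, rtol=1e-9)

    def test_dt_halving_stability(self):
        a = simulate_train(WT_PARAMS, protocol=Protocol.regular_train(200, 40),
                           dt=1e-4)
        b = simulate_train(WT_PARAMS, protocol=Protocol.regular_train(200, 40),
                           dt=5e-5)
        assert np.max(np.abs(a.m - b.m) / b.m) < 1e-3

    def test_accuracy_selfcheck_passes_at_defaults(self):
        simulate_train(WT_PARAMS, protocol=Protocol.regular_train(333, 20),
                       check_accuracy=True)

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            simulate_train(WT_PARAMS, protocol=Protocol([0.0]), dt=1e-3)

    def test_labile_states_route_released_sites(self):
        p = replace(WT_PARAMS, labile_enabled=True)
        r = simulate_train(p, protocol=Protocol.regular_train(200, 5))
        assert r.final_state.ERS > 0
        np.testing.assert_allclose(r.final_state.total, p.N_total, rtol=1e-9)


class TestSimulateRecovery:
    def test_long_interval_returns_to_unity(self):
        f, _ = simulate_recovery(WT_PARAMS, intervals=[150.0])
        assert f[0] == pytest.approx(1.0, abs=0.01)

    def test_short_interval_near_zero(self):
        f, _ = simulate_recovery(WT_PARAMS, intervals=[0.003])
        assert abs(f[0]) < 0.05

    def test_calcium_sensitive_recruitment_accelerates_recovery(self):
        fast, _ = simulate_recovery(WT_PARAMS, intervals=[0.25, 0.5])
        slow, _ = simulate_recovery(replace(WT_PARAMS, sigma1=0.0),
                                    intervals=[0.25, 0.5])
        assert np.all(fast > slow)

    def test_intervals_validated(self):
        with pytest.raises(ValueError):
            simulate_recovery(WT_PARAMS, intervals=[0.5, 0.25])


class TestStochasticMode:
    def test_full_release_no_replenishment(self):
        p = PrimingModelParams(k1_rest=0, sigma1=0, b1=0, k2_rest=0,
                               sigma2=0, b2=0, p_fusion_0=1.0,
                               p_fusion_max=1.0, ap_conversion=0.0,
                               facilitation_gain=0.0, N_total=500)
        s0 = SimState(t=0.0, ES=0.0, LS=0.0, TS=500.0, TSL=0.0, ERS=0.0,
                      p_fusion_now=1.0, ca_now=float("nan"))
        r = simulate_train_stochastic(p, protocol=Protocol.regular_train(100, 4),
                                      seed=5, initial_state=s0)
        np.testing.assert_array_equal(r.m, [500, 0, 0, 0])

    def test_seed_reproducibility(self):
        a = simulate_train_stochastic(WT_PARAMS,
                                      protocol=Protocol.regular_train(200, 15),
                                      seed=99)
        b = simulate_train_stochastic(WT_PARAMS,
                                      protocol=Protocol.regular_train(200, 15),
                                      seed=99)
        np.testing.assert_array_equal(a.m, b.m)

    def test_integer_conservation(self):
        r = simulate_train_stochastic(WT_PARAMS,
                                      protocol=Protocol.regular_train(200, 25),
                                      seed=11)
        assert r.final_state.total == pytest.approx(round(WT_PARAMS.N_total))

    def test_expectation_matches_mean_field(self):
        p = WT_PARAMS.with_frp(1500.0)
        proto = Protocol.regular_train(200, 20)
        mf = simulate_train(p, protocol=proto).m
        rng = np.random.default_rng(0)
        reps = np.array([simulate_train_stochastic(p, protocol=proto,
                                                   seed=rng).m
                         for _ in range(400)])
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        z = np.abs(reps.mean(axis=0) - mf) / np.maximum(se, 1e-9)
        # 20 simultaneous comparisons: allow a modest multiplicity margin
        assert z.max() < 3.5


class TestGenotypeContrast:
    def test_hk_style_shift_reproduces_qualitative_pattern(self):
        wt333 = simulate_train(WT_PARAMS, protocol=Protocol.regular_train(333, 40))
        hk333 = simulate_train(HK_PARAMS, protocol=Protocol.regular_train(333, 40))
        assert hk333.m1 > wt333.m1                       # larger initial release
        assert hk333.m[-5:].mean() < wt333.m[-5:].mean() # lower steady state
        fw, _ = simulate_recovery(WT_PARAMS, intervals=[0.5])
        fh, _ = simulate_recovery(HK_PARAMS, intervals=[0.5])
        assert fw[0] > fh[0]                             # slower HK recovery
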