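"""Regulatory primitives, right-hand sides and model reductions."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from rhorac.circuit_model import (
    HillSpec,
    LoadingSpec,
    MirnaSpec,
    Schedule,
    SignalInput,
    detailed_rhs,
    effective_rhs,
    lift_to_detailed,
    lift_to_reduced,
    loading_rate,
    locked_mu,
    mirna_inhibition,
    parameters_from_dict,
    parameters_to_dict,
    reduced_rhs,
    shifted_hill,
    signal_response,
)
from rhorac.steady_state import find_fixed_points, jacobian

hill_specs = st.builds(
    HillSpec,
    threshold=st.floats(1.0, 1e6),
    coefficient=st.integers(1, 8),
    fold_change=st.floats(0.0, 50.0),
)
mirna_specs = st.builds(
    MirnaSpec,
    half_effect=st.floats(1.0, 1e5),
    coefficient=st.integers(1, 6),
)


class TestShiftedHill:
    @settings(deadline=None, max_examples=100)
    @given(spec=hill_specs)
    def test_limit_identities(self, spec):
        """H(0)=1, H(X0)=(1+lam)/2 and H(inf)=lam for any parameters."""
        assert shifted_hill(0.0, spec) == 1.0
        assert shifted_hill(spec.threshold, spec) == pytest.approx(
            (1.0 + spec.fold_change) / 2.0)
        assert shifted_hill(1e12 * spec.threshold, spec) == pytest.approx(
            spec.fold_change, abs=1e-6 * (1 + spec.fold_change))

    @settings(deadline=None, max_examples=50)
    @given(spec=hill_specs, x=st.floats(0.0, 1e7))
    def test_bounded_between_one_and_fold_change(self, spec, x):
        h = shifted_hill(x, spec)
        lo, hi = sorted((1.0, spec.fold_change))
        assert lo - 1e-12 <= h <= hi + 1e-12

    def test_monotone_direction_follows_fold_change(self):
        xs = np.linspace(0, 2000, 100)
        act = shifted_hill(xs, HillSpec(500, 4, 5.0))
        rep = shifted_hill(xs, HillSpec(500, 4, 0.2))
        assert np.all(np.diff(act) >= 0)
        assert np.all(np.diff(rep) <= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            shifted_hill(-1.0, HillSpec(500, 4, 2.0))


class TestMirnaInhibition:
    @settings(deadline=None, max_examples=100)
    @given(spec=mirna_specs)
    def test_no_effect_at_zero_and_half_effect_at_mu0(self, spec):
        assert mirna_inhibition(0.0, spec) == 1.0
        assert mirna_inhibition(spec.half_effect, spec) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(spec=mirna_specs)
    def test_strictly_decreasing_to_zero(self, spec):
        mus = np.geomspace(1e-3, 1e4, 60) * spec.half_effect
        p = mirna_inhibition(mus, spec)
        assert np.all(np.diff(p) <= 0)
        mid = (mus > 0.1 * spec.half_effect) & (mus < 10 * spec.half_effect)
        assert np.all(np.diff(p[mid]) < 0)
        assert np.all(p <= 1.0) and np.all(p >= 0.0)
        assert p[-1] < 1e-3

    def test_strong_silencing_value(self):
        # ten-fold excess over mu0 with n=2: P = 1/(1 + 100)
        spec = MirnaSpec(half_effect=500.0, coefficient=2)
        assert mirna_inhibition(5000.0, spec) == pytest.approx(1.0 / 101.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            mirna_inhibition(-5.0, MirnaSpec(300, 1))


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"threshold": 0.0, "coefficient": 2, "fold_change": 1.0},
        {"threshold": 100.0, "coefficient": 0, "fold_change": 1.0},
        {"threshold": 100.0, "coefficient": 2, "fold_change": -0.1},
    ])
    def test_bad_hill_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HillSpec(**kwargs)

    def test_unknown_regulator_rejected(self):
        with pytest.raises(ValueError):
            LoadingSpec(1.0, (("nonsense", HillSpec(100, 2, 2.0)),))

    def test_loading_rate_positive_for_positive_folds(self, params):
        env = {"rac1_gtp": 500.0, "rhoa_gtp": 800.0, "grb2": 0.0, "gab1": 0.0}
        assert loading_rate(params.loading_rac1, env) > 0
        assert loading_rate(params.loading_rhoa, env) > 0

    def test_gdi_fast_equilibrium_ratio(self, params):
        assert params.gdi_timescale_ratio() >= 100.0
        params.validate()


class TestEffectiveRhs:
    def test_pure_decay_when_production_silenced(self, params):
        """With both productions fully silenced the only dynamics left is
        first-order decay: both rates strictly negative."""
        silenced = dataclasses.replace(
            params,
            g_rac1=1e-9, g_rhoa_basal=1e-9, g_rhoa_exc=1e-9)
        rates = effective_rhs([100.0, 100.0], silenced, SignalInput())
        assert np.all(rates < 0)

    def test_zero_at_located_fixed_points(self, params):
        sig = locked_mu(100.0)
        ss = find_fixed_points(params, sig)
        for p in ss.points:
            res = effective_rhs(p.state, params, sig)
            assert np.max(np.abs(res)) < 1e-6

    def test_symmetric_circuit_has_symmetric_rhs(self, symmetric_params):
        for x in (10.0, 250.0, 900.0):
            d = effective_rhs([x, x], symmetric_params, locked_mu(50.0))
            assert d[0] == pytest.approx(d[1], rel=1e-9)

    def test_standalone_limit_is_exact(self, params):
        """P(0) = 1 exactly, so the coupled model at mu = 0 IS the
        standalone circuit bit for bit (changing mu0 cannot matter)."""
        other = dataclasses.replace(
            params,
            mirna_rhoa=MirnaSpec(7.0, 3), mirna_rac1=MirnaSpec(11.0, 2))
        state = np.array([[123.0, 456.0], [900.0, 40.0]])
        a = effective_rhs(state, params, locked_mu(0.0))
        b = effective_rhs(state, other, locked_mu(0.0))
        assert np.array_equal(a, b)

    def test_jacobian_finite_difference_consistency(self, params):
        """C1 smoothness on the positive orthant: central differences at
        two step sizes agree."""
        sig = locked_mu(30.0)
        x = np.array([400.0, 500.0])
        j1 = jacobian(x, params, sig, rel_step=1e-5)
        j2 = jacobian(x, params, sig, rel_step=1e-7)
        assert np.allclose(j1, j2, rtol=1e-3, atol=1e-6)


class TestDetailedModel:
    def test_total_protein_balance_at_fixed_points(self, params):
        """Summing the three pools of one GTPase leaves production minus
        uniform degradation, so g * P = k * total at any fixed point."""
        sig = locked_mu(100.0)
        ss = find_fixed_points(params, sig)
        for p in ss.stable:
            y = lift_to_detailed(p.state, params, sig)
            assert np.max(np.abs(detailed_rhs(y, params, sig))) < 1e-6
            total_rac = y[0] + y[1] + y[2]
            total_rho = y[3] + y[4] + y[5]
            p_rac = mirna_inhibition(sig.mu2, params.mirna_rac1)
            assert params.g_rac1 * p_rac == pytest.approx(
                params.k_rac1 * total_rac, rel=1e-8)
            prod_rho = (params.g_rhoa_basal + params.g_rhoa_exc
                        * shifted_hill(y[3], params.rhoa_selfact)) \
                * mirna_inhibition(sig.mu1, params.mirna_rhoa)
            assert prod_rho == pytest.approx(params.k_rhoa * total_rho, rel=1e-8)

    def test_reduced_model_shares_fixed_points(self, params):
        sig = locked_mu(15.0)
        for p in find_fixed_points(params, sig).stable:
            y4 = lift_to_reduced(p.state, params, sig)
            assert np.max(np.abs(reduced_rhs(y4, params, sig))) < 1e-6

    def test_six_variable_flow_returns_to_lifted_fixed_point(self, params):
        """The fast-GDI reduction is consistent: perturbing the detailed
        model around a lifted stable state relaxes back to it."""
        sig = locked_mu(0.0)
        p = find_fixed_points(params, sig).stable[0]
        y0 = lift_to_detailed(p.state, params, sig)
        sol = solve_ivp(lambda t, y: detailed_rhs(np.maximum(y, 0), params, sig),
                        (0.0, 200.0), y0 * 1.05, method="LSODA",
                        rtol=1e-9, atol=1e-8)
        assert sol.success
        assert np.allclose(sol.y[:, -1], y0, rtol=1e-4)

    def test_zero_production_decays_to_origin(self, params):
        silenced = dataclasses.replace(
            params, g_rac1=1e-9, g_rhoa_basal=1e-9, g_rhoa_exc=1e-9)
        y0 = np.full(6, 200.0)
        sol = solve_ivp(lambda t, y: detailed_rhs(np.maximum(y, 0), silenced,
                                                  SignalInput()),
                        (0.0, 50.0), y0, method="LSODA", rtol=1e-9, atol=1e-10)
        assert np.all(np.abs(sol.y[:, -1]) < 1e-3)


class TestSignals:
    def test_signal_response_basal_half_and_monotone(self, params):
        assert signal_response(0.0, "grb2", params) == 0.0
        half = signal_response(params.grb2_thresh, "grb2", params)
        sat = signal_response(1e12, "grb2", params)
        assert half == pytest.approx(sat / 2.0, rel=1e-6)
        levels = [signal_response(h, "gab1", params)
                  for h in np.linspace(0, 2e6, 20)]
        assert np.all(np.diff(levels) >= 0)

    def test_unknown_signal_name_rejected(self, params):
        with pytest.raises(ValueError):
            signal_response(100.0, "erk", params)

    def test_schedule_validation_and_clamping(self):
        with pytest.raises(ValueError):
            Schedule(((0.0, 5.0), (0.0, 3.0)))
        with pytest.raises(ValueError):
            Schedule(((0.0, -1.0),))
        s = Schedule(((0.0, 100.0), (10.0, 0.0)))
        assert s(-5.0) == 100.0 and s(5.0) == 50.0 and s(20.0) == 0.0

    def test_signal_input_resolves_schedules(self):
        sig = SignalInput(mu1=Schedule(((0.0, 100.0), (10.0, 0.0))), mu2=40.0)
        assert not sig.is_static
        at5 = sig.at(5.0)
        assert at5.mu1 == 50.0 and at5.mu2 == 40.0 and at5.is_static

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            SignalInput(mu1=-1.0)


def test_parameter_serialization_round_trip(params):
    d = parameters_to_dict(params)
    again = parameters_from_dict(json.loads(json.dumps(d)))
    assert parameters_to_dict(again) == d
    assert again.grb2_thresh == params.grb2_thresh
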