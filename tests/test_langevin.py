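"""Stochastic simulation, landscapes and basin statistics."""

import numpy as np
import pytest

from rhorac.circuit_model import lift_to_reduced, locked_mu, reduced_rhs
from rhorac.langevin import (
    BASIN_LABELS,
    LangevinTrajectory,
    _dwell_filter,
    build_landscape,
    drift_reduced,
    simulate_langevin,
)
from rhorac.steady_state import find_fixed_points


@pytest.fixture(scope="module")
def steady_mu0(params):
    return find_fixed_points(params, locked_mu(0.0))


class TestSimulator:
    def test_compiled_drift_matches_reference_rhs(self, params, rng):
        sig = locked_mu(37.0)
        for _ in range(20):
            x = rng.uniform(0, 2000, size=4)
            assert np.allclose(drift_reduced(x, params, sig),
                               reduced_rhs(x, params, sig), rtol=1e-12)

    def test_noiseless_run_tracks_deterministic_flow(self, params, steady_mu0):
        """With noise off, Euler-Maruyama is plain Euler: starting slightly
        off an attractor it must relax onto it."""
        sig = locked_mu(0.0)
        x0 = lift_to_reduced(steady_mu0.stable[0].state, params, sig) * 1.2
        traj = simulate_langevin(params, sig, t_total=60.0, dt=0.002,
                                 seed=0, thin=10, x0=x0, noise_level=0.0)
        target = lift_to_reduced(steady_mu0.stable[0].state, params, sig)
        assert np.allclose(traj.samples[-1], target, rtol=1e-3)

    def test_same_seed_reproduces_trajectory(self, params):
        sig = locked_mu(0.0)
        a = simulate_langevin(params, sig, t_total=50.0, dt=0.01, seed=42)
        b = simulate_langevin(params, sig, t_total=50.0, dt=0.01, seed=42)
        c = simulate_langevin(params, sig, t_total=50.0, dt=0.01, seed=43)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_counts_stay_non_negative(self, params):
        traj = simulate_langevin(params, locked_mu(2000.0), t_total=200.0,
                                 dt=0.01, seed=5, noise_level=400.0)
        assert np.all(traj.samples >= 0.0)

    def test_coarse_dt_rejected(self, params):
        with pytest.raises(ValueError, match="dt"):
            simulate_langevin(params, locked_mu(0.0), t_total=1.0, dt=2.0)


class TestLandscape:
    def test_uniform_trajectory_gives_flat_potential(self, params, rng):
        samples = np.empty((400_000, 4))
        samples[:, 0] = rng.uniform(0, 2000, 400_000)     # rac1_gtp
        samples[:, 2] = rng.uniform(0, 1200, 400_000)     # rhoa_gtp
        samples[:, 1] = samples[:, 3] = 100.0
        traj = LangevinTrajectory(samples=samples, dt=0.01, thin=10,
                                  t_total=40_000.0, seed=0, noise_level=1.0)
        ls = build_landscape(traj, find_fixed_points(params, locked_mu(0.0)),
                             params, bins=20)
        spread = np.nanmax(ls.potential) - np.nanmin(ls.potential)
        assert spread < 0.5        # Poisson noise only

    def test_dwell_filter_suppresses_short_excursions(self):
        base = np.zeros(100, dtype=np.int64)
        blip = base.copy()
        blip[40:45] = 2            # 5-sample excursion: below dwell threshold
        assert np.array_equal(_dwell_filter(blip, dwell=10), base)
        real = base.copy()
        real[40:60] = 2            # 20-sample visit: a genuine transition
        filtered = _dwell_filter(real, dwell=10)
        assert np.all(filtered[40:60] == 2)
        assert np.all(filtered[60:] == 0)  # the return also persists

    def test_occupancy_sums_to_one(self, params, steady_mu0):
        traj = simulate_langevin(params, locked_mu(0.0), t_total=2000.0,
                                 dt=0.01, seed=3)
        ls = build_landscape(traj, steady_mu0, params)
        assert sum(ls.occupancy.values()) == pytest.approx(1.0)
        assert np.all(np.diag(ls.transitions) == 0)
        assert ls.basin_potentials["HL"] == pytest.approx(
            -np.log(ls.hist.max() / ls.hist.sum()), abs=1e-9)

    def test_moderate_microrna_removes_hh_and_boosts_ll(self, params):
        """At mu = 1000 the A/M state is deterministically gone and the
        collective E/M basin dominates compared with mu = 0."""
        occ = {}
        for mu in (0.0, 1000.0):
            sig = locked_mu(mu)
            ss = find_fixed_points(params, sig)
            traj = simulate_langevin(params, sig, t_total=3e4, dt=0.01, seed=11)
            ls = build_landscape(traj, ss, params)
            occ[mu] = ls.occupancy
        assert occ[1000.0]["LL"] > occ[0.0]["LL"]
        ss1000 = find_fixed_points(params, locked_mu(1000.0))
        assert "HH" not in {p.label for p in ss1000.stable}

    def test_high_microrna_suppresses_escape_from_collective_state(self, params):
        """Raising mu progressively traps the E/M basin: the per-hour rate
        of leaving LL drops by well over an order of magnitude."""
        rate = {}
        for mu in (0.0, 1000.0, 3000.0):
            sig = locked_mu(mu)
            ss = find_fixed_points(params, sig)
            traj = simulate_langevin(params, sig, t_total=3e4, dt=0.01, seed=11)
            ls = build_landscape(traj, ss, params)
            exits = ls.transitions[BASIN_LABELS.index("LL"), :].sum()
            rate[mu] = exits / max(ls.occupancy["LL"] * 3e4, 1e-9)
        assert rate[3000.0] < rate[1000.0] < rate[0.0]
        assert rate[3000.0] < 0.05 * rate[0.0]

    def test_nearest_rule_uses_deterministic_attractors(self, params, steady_mu0):
        traj = simulate_langevin(params, locked_mu(0.0), t_total=2000.0,
                                 dt=0.01, seed=3)
        ls = build_landscape(traj, steady_mu0, params, basin_rule="nearest")
        # only labels of deterministic stable states can appear
        stable_labels = {p.label for p in steady_mu0.stable}
        assert {l for l, o in ls.occupancy.items() if o > 0} <= stable_labels

    def test_burn_in_longer_than_trajectory_rejected(self, params, steady_mu0):
        traj = simulate_langevin(params, locked_mu(0.0), t_total=50.0,
                                 dt=0.01, seed=3)
        with pytest.raises(ValueError):
            build_landscape(traj, steady_mu0, params, burn_in=100.0)
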