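import numpy as np
import pytest

import thermocrm as tc
from thermocrm.dynamics import (CommunityState, _rhs_flat_fast,
                                _fast_rhs_args, rhs)
from thermocrm.kinetics import growth_rate


def abiotic_community(M=4, span=6.0e5, **kw):
    """A community with no species: pure chemostat."""
    net = tc.build_network(M, span)
    cfg = tc.RegimeConfig(M=M, B=1, delta_G_total=span, **kw)
    return tc.Community(network=net, species=[], cell=cfg.cell, config=cfg)


class TestRhs:
    def test_abiotic_chemostat(self):
        com = abiotic_community()
        cfg = com.config
        state = CommunityState(C=np.array([0.02, 0.01, 0.0, 0.005]),
                               N=np.zeros(0), phi_R=np.zeros(0),
                               a=np.zeros(0))
        dy = rhs(0.0, state.pack(), com.flat(), com.cell,
                 cfg.supply_vector(), cfg.rho, np.zeros(0))
        expected = cfg.supply_vector() - cfg.rho * state.C
        np.testing.assert_allclose(dy, expected, rtol=1e-14)

    def test_balanced_species_has_zero_population_derivative(self, cell):
        """A species with lambda = d sits exactly at its balance point."""
        net = tc.build_network(3, 3.0e5)
        d = 1.0e-5
        sp = tc.Species(id="x", reactions=np.array([0]), k=np.array([1.0]),
                        K_S=np.array([1e-4]), r=np.array([5.0]),
                        eta=np.array([0.5]), nu=np.array([1.0]), d=d)
        cfg = tc.RegimeConfig(M=3, B=1, delta_G_total=3.0e5, d=d)
        com = tc.Community(network=net, species=[sp], cell=cell, config=cfg)
        # choose (a, phi_R) with gamma(a) f_b phi_R / n_R = d exactly
        a = cell.gamma_half
        phi = d / growth_rate(a, 1.0, cell)
        state = CommunityState(C=np.array([1e-3, 1e-5, 0.0]),
                               N=np.array([1e8]), phi_R=np.array([phi]),
                               a=np.array([a]))
        dy = rhs(0.0, state.pack(), com.flat(), com.cell,
                 cfg.supply_vector(), cfg.rho, np.ones(1))
        # zero up to round-off of lambda*N (phi solved in floating point)
        assert dy[3] == pytest.approx(0.0, abs=1e-10 * d * 1e8)

    def test_energy_causality_without_metabolites(self, cell):
        """With all metabolite pools empty, no ATP is produced and the
        internal pool only drains (translation cost + growth dilution)."""
        net = tc.build_network(3, 3.0e5)
        sp = tc.Species(id="x", reactions=np.array([0]), k=np.array([2.0]),
                        K_S=np.array([1e-4]), r=np.array([5.0]),
                        eta=np.array([0.5]), nu=np.array([1.0]), d=1e-5)
        cfg = tc.RegimeConfig(M=3, B=1, delta_G_total=3.0e5)
        com = tc.Community(network=net, species=[sp], cell=cell, config=cfg)
        state = CommunityState(C=np.zeros(3), N=np.array([1e6]),
                               phi_R=np.array([0.2]), a=np.array([2e8]))
        dy = rhs(0.0, state.pack(), com.flat(), com.cell,
                 cfg.supply_vector(), cfg.rho, np.ones(1))
        da = dy[-1]
        assert da < 0.0
        lam = growth_rate(2e8, 0.2, cell)
        assert da == pytest.approx(-cell.chi * cell.m * lam - 2e8 * lam,
                                   rel=1e-12)

    def test_fast_path_matches_reference(self, headline_scaled_config):
        com = tc.generate_community(None, headline_scaled_config, seed=42)
        flat = com.flat()
        cfg = headline_scaled_config
        rng = np.random.default_rng(0)
        y = tc.initial_state(com).pack()
        y[:cfg.M] = rng.lognormal(-8, 2, cfg.M)
        y[cfg.M + 2 * cfg.B:] = rng.lognormal(15, 3, cfg.B)
        active = np.ones(cfg.B)
        ref = rhs(0.0, y, flat, com.cell, cfg.supply_vector(), cfg.rho, active)
        fast = _rhs_flat_fast(0.0, y, *_fast_rhs_args(
            flat, com.cell, cfg.supply_vector(), cfg.rho, active))
        np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-300)

    def test_nonfinite_state_rejected(self, cell):
        net = tc.build_network(3, 3.0e5)
        sp = tc.Species(id="x", reactions=np.array([0]), k=np.array([1.0]),
                        K_S=np.array([1e-4]), r=np.array([5.0]),
                        eta=np.array([0.5]), nu=np.array([1.0]), d=1e-5)
        cfg = tc.RegimeConfig(M=3, B=1, delta_G_total=3.0e5)
        com = tc.Community(network=net, species=[sp], cell=cell, config=cfg)
        y = tc.initial_state(com).pack()
        y[0] = np.nan
        with pytest.raises(tc.IntegrationError):
            rhs(0.0, y, com.flat(), com.cell, cfg.supply_vector(), cfg.rho,
                np.ones(1))


class TestIntegrate:
    def test_abiotic_convergence_to_supply_balance(self):
        """C1 -> kappa/rho (closed-form chemostat equilibrium)."""
        com = abiotic_community(t_final=1.0e7)
        traj = tc.integrate(com)
        cfg = com.config
        assert traj.C[-1, 0] == pytest.approx(cfg.kappa / cfg.rho, rel=1e-6)
        assert np.all(traj.C[-1, 1:] < 1e-12)
        # closed form along the way: C1(t) = (kappa/rho)(1 - exp(-rho t))
        mid = traj.n_samples // 2
        t_mid = traj.t[mid]
        expected = cfg.kappa / cfg.rho * (1 - np.exp(-cfg.rho * t_mid))
        assert traj.C[mid, 0] == pytest.approx(expected, rel=1e-6)

    def test_mass_bookkeeping_along_trajectory(self, syntrophy_run):
        """d(sum C)/dt = total supply - rho * sum C: conversion between
        metabolites neither creates nor destroys matter."""
        com, traj, _, _ = syntrophy_run
        cfg = com.config
        flat = com.flat()
        supply = cfg.supply_vector()
        for idx in range(0, traj.n_samples, 100):
            state = traj.state_at(idx)
            active = (state.N > 0).astype(float)
            dy = rhs(state.t, state.pack(), flat, com.cell, supply, cfg.rho,
                     active)
            dC_sum = dy[:flat.M].sum()
            expected = supply.sum() - cfg.rho * np.maximum(state.C, 0).sum()
            scale = max(abs(expected), supply.sum())
            assert dC_sum == pytest.approx(expected, abs=1e-9 * scale)

    def test_non_negativity_of_sampled_states(self, small_assembly_run):
        _, traj, _, _ = small_assembly_run
        for arr in (traj.C, traj.N, traj.phi_R, traj.a):
            assert arr.min() > -1e-12

    def test_extinct_species_clamped_and_logged(self, pollution_run):
        com, traj, state, report = pollution_run
        # species A goes extinct; clamped to exactly zero and logged
        assert state.N[0] == 0.0
        ext = traj.events[traj.events["kind"] == "extinction"]
        assert "A" in set(ext["label"])

    def test_survivors_share_ribosome_fraction(self, small_assembly_run):
        """All survivors converge on one ribosome fraction: saturation
        constants are shared, so the balance lambda = d pins (a, phi_R)."""
        com, traj, state, report = small_assembly_run
        assert report["converged"]
        thr = com.config.extinction_threshold
        phi = state.phi_R[state.N > thr]
        assert len(phi) >= 2
        assert phi.max() - phi.min() < 1e-6

    def test_trajectory_hdf5_roundtrip(self, pollution_run, tmp_path):
        _, traj, _, _ = pollution_run
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = tc.Trajectory.from_hdf5(path)
        np.testing.assert_allclose(back.t, traj.t)
        np.testing.assert_allclose(back.N, traj.N)
        np.testing.assert_allclose(back.sigma, traj.sigma)
        assert back.species_ids == traj.species_ids
        assert back.config.M == traj.config.M
        assert len(back.events) == len(traj.events)


class TestSteadyState:
    def test_abiotic_report(self):
        com = abiotic_community(t_final=1.0e7)
        traj = tc.integrate(com)
        state, report = tc.steady_state(traj, com)
        assert report["survivors"] == 0
        assert report["converged"]

    def test_converged_run_small_percapita_imbalance(self, syntrophy_run):
        com, traj, state, report = syntrophy_run
        assert report["converged"]
        assert report["max_percap_dN"] < 1e-7
        assert report["survivor_ids"] == ["A", "C"]
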