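import dataclasses

import numpy as np
import pytest
from scipy import stats

import thermocrm as tc
from thermocrm.community import MODE_RATIOS, generate_species
from thermocrm.network import equilibrium_constant, eta_max


@pytest.fixture(scope="module")
def rev_config():
    return tc.RegimeConfig(M=8, B=10, delta_G_total=1.5e6,
                           kinetics_mode="reversible", seed=5)


@pytest.fixture(scope="module")
def network(rev_config):
    return tc.build_network(rev_config.M, rev_config.delta_G_total)


class TestGenerateSpecies:
    def test_invariants_over_many_draws(self, network, rev_config):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sp = generate_species(network, rev_config, rng)
            assert 1 <= len(sp.reactions) <= 5
            assert len(np.unique(sp.reactions)) == len(sp.reactions)
            assert sp.nu.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(sp.nu >= 0)
            assert np.all(sp.k > 0) and np.all(sp.K_S > 0) and np.all(sp.r > 0)
            assert np.all(sp.eta >= tc.ETA_MIN - 1e-12)

    def test_eta_respects_reaction_ceiling(self, network, rev_config):
        rng = np.random.default_rng(1)
        cell = rev_config.cell
        for _ in range(200):
            sp = generate_species(network, rev_config, rng)
            hi, _ = eta_max(network.delta_G0[sp.reactions],
                            rev_config.equilibrium_ratio,
                            cell.delta_G_ATP, cell.T)
            assert np.all(sp.eta <= np.maximum(hi, tc.ETA_MIN) + 1e-12)

    def test_michaelis_menten_mode_keeps_K_large(self, network):
        """In M-M mode every sampled reaction still has K >= 1e5 at its
        sampled eta, i.e. the dynamics stay effectively irreversible."""
        cfg = tc.RegimeConfig(M=8, B=10, delta_G_total=1.5e6,
                              kinetics_mode="michaelis_menten", seed=5)
        assert cfg.equilibrium_ratio == MODE_RATIOS["michaelis_menten"]
        rng = np.random.default_rng(2)
        cell = cfg.cell
        for _ in range(100):
            sp = generate_species(network, cfg, rng)
            K = equilibrium_constant(network.delta_G0[sp.reactions], sp.eta,
                                     cell.delta_G_ATP, cell.T)
            degenerate = sp.eta_degenerate
            assert np.all(K[~degenerate] >= 1e5 * (1 - 1e-9))

    def test_reaction_count_uniform(self, network, rev_config):
        rng = np.random.default_rng(3)
        counts = np.bincount([len(generate_species(network, rev_config,
                                                   rng).reactions)
                              for _ in range(3000)], minlength=6)[1:]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-3


class TestGenerateCommunity:
    def test_headline_dimensions(self):
        cfg = tc.RegimeConfig(M=25, B=250, delta_G_total=5.0e6, seed=9)
        com = tc.generate_community(None, cfg, seed=9)
        assert com.B == 250
        assert com.network.n_reactions == 47

    def test_determinism_bit_identical(self, rev_config):
        a = tc.generate_community(None, rev_config, seed=77)
        b = tc.generate_community(None, rev_config, seed=77)
        for sa, sb in zip(a.species, b.species):
            np.testing.assert_array_equal(sa.reactions, sb.reactions)
            for f in ("k", "K_S", "r", "eta", "nu"):
                np.testing.assert_array_equal(getattr(sa, f), getattr(sb, f))

    def test_growing_B_preserves_earlier_species(self):
        """Seed streams are spawned per species, so enlarging the community
        leaves the earlier draws untouched."""
        small = tc.RegimeConfig(M=8, B=5, delta_G_total=1.5e6, seed=13)
        big = dataclasses.replace(small, B=9)
        ca = tc.generate_community(None, small, seed=13)
        cb = tc.generate_community(None, big, seed=13)
        for sa, sb in zip(ca.species, cb.species[:5]):
            np.testing.assert_array_equal(sa.reactions, sb.reactions)
            np.testing.assert_array_equal(sa.k, sb.k)

    def test_initial_state_equal_abundance(self, rev_config):
        com = tc.generate_community(None, rev_config, seed=21)
        state = tc.initial_state(com)
        assert len(state.pack()) == rev_config.M + 3 * rev_config.B
        assert np.all(state.N == rev_config.N0)
        assert np.all(state.C == 0.0)
        # initial ribosome fraction consistent with initial energy
        from thermocrm.kinetics import ideal_ribosome_fraction
        np.testing.assert_allclose(
            state.phi_R, ideal_ribosome_fraction(state.a, com.cell))

    def test_single_species_state_dimension(self):
        cfg = tc.RegimeConfig(M=4, B=1, delta_G_total=6.0e5, seed=2)
        com = tc.generate_community(None, cfg, seed=2)
        assert len(tc.initial_state(com).pack()) == 4 + 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tc.RegimeConfig(M=8, B=0, delta_G_total=1e6)
        with pytest.raises(ValueError):
            tc.RegimeConfig(M=1, B=5, delta_G_total=1e6)
        with pytest.raises(ValueError):
            tc.RegimeConfig(M=8, B=5, delta_G_total=1e6,
                            kinetics_mode="nonsense")


class TestSerialisation:
    def test_species_table_roundtrip(self, rev_config, tmp_path):
        com = tc.generate_community(None, rev_config, seed=31)
        path = tmp_path / "species.csv"
        com.to_csv(path)
        back = tc.Community.from_csv(path, com.network, cell=com.cell)
        assert back.B == com.B
        for sa, sb in zip(com.species, back.species):
            np.testing.assert_array_equal(sa.reactions, sb.reactions)
            np.testing.assert_allclose(sa.eta, sb.eta, rtol=1e-15)

    def test_config_yaml_roundtrip(self, rev_config, tmp_path):
        path = tmp_path / "cfg.yaml"
        rev_config.to_yaml(path)
        back = tc.RegimeConfig.from_yaml(path)
        assert back == rev_config

    def test_unknown_config_key_named(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("M: 8\nB: 5\ndelta_G_total: 1.0e6\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            tc.RegimeConfig.from_yaml(path)


class TestFixtures:
    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            tc.make_fixture("nonsense_demo")

    def test_syntrophy_topology(self):
        com = tc.make_fixture("syntrophy_demo")
        ids = [sp.id for sp in com.species]
        assert ids == ["A", "B", "C"]
        a, b, c = com.species
        # A and B share reaction 1->2; A has the higher ATP yield
        assert a.reactions[0] == b.reactions[0]
        assert a.eta[0] > b.eta[0]
        # C consumes the shared waste product (2->3)
        assert com.network.substrates[c.reactions[0]] == 1
        # only metabolite 1 supplied
        assert com.config.supply_vector()[0] > 0
        assert np.all(com.config.supply_vector()[1:] == 0)

    def test_pollution_topology(self):
        com = tc.make_fixture("pollution_demo")
        a, b = com.species
        # A: 2->3, B: the two-step 1->3; metabolites 1 and 2 supplied
        assert com.network.substrates[a.reactions[0]] == 1
        assert com.network.products[a.reactions[0]] == 2
        assert com.network.substrates[b.reactions[0]] == 0
        assert com.network.products[b.reactions[0]] == 2
        supply = com.config.supply_vector()
        assert supply[0] > 0 and supply[1] > 0 and supply[2] == 0
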