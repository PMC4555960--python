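"""Single-generation simulation behaviour: limits, scenarios, invariants."""

import math

import numpy as np
import pytest

from cole1sim.simulate import (SCENARIOS, InitialConditions, apply_scenario,
                               generation_time, integrate, pcn_delta,
                               simulate_generation)
from cole1sim.network import (KineticParameters, Reaction, ReactionNetwork,
                              Species)
from cole1sim.units import molecules_to_molar


class TestGenerationTime:
    @pytest.mark.parametrize("mu, minutes", [
        (0.278, 150), (0.305, 136), (0.302, 138), (0.283, 147),
        (0.256, 162), (math.log(2), 60),
    ])
    def test_doubling_time_matches_reported_tables(self, mu, minutes):
        assert round(generation_time(mu)) == minutes

    @pytest.mark.parametrize("mu", [0.0, -1.0])
    def test_nonpositive_growth_rate_rejected(self, mu):
        with pytest.raises(ValueError):
            generation_time(mu)


class TestScenarios:
    def test_normal_scales_only_k24_by_one_percent(self, high_params):
        p, mu = apply_scenario(high_params, "normal", 0.305)
        assert p[24] == pytest.approx(7.99e-8)
        assert p[3] == high_params[3]
        assert mu == 0.305

    def test_modified_trna_leaves_everything_at_full_value(self, high_params):
        p, mu = apply_scenario(high_params, "modified_trna", 0.09)
        assert p.k == high_params.k
        assert mu == 0.09

    def test_starvation_scales_all_rates_and_growth_by_tenth(self,
                                                             high_params):
        p, mu = apply_scenario(high_params, "starvation", 0.090)
        assert mu == pytest.approx(0.009)
        for i in high_params.k:
            assert p[i] == pytest.approx(0.1 * high_params[i])
        # k24 factor restored to 1, so only the global 0.1 applies
        assert p[24] == pytest.approx(7.99e-7)

    def test_scenario_factor_table(self):
        assert (SCENARIOS["normal"].k24_factor,
                SCENARIOS["normal"].global_k_factor,
                SCENARIOS["normal"].mu_factor) == (0.01, 1, 1)
        assert (SCENARIOS["starvation"].k24_factor,
                SCENARIOS["starvation"].global_k_factor,
                SCENARIOS["starvation"].mu_factor) == (1, 0.1, 0.1)
        assert (SCENARIOS["modified_trna"].k24_factor,
                SCENARIOS["modified_trna"].global_k_factor,
                SCENARIOS["modified_trna"].mu_factor) == (1, 1, 1)


class TestDilutionLimit:
    def test_all_rates_zero_gives_pure_exponential_decay(self, low_network,
                                                         low_params):
        """With every k = 0 and the full dilution term, each species decays
        as exp(-mu t / 60); at mu = ln2 per hour, one hour halves it."""
        zero = low_params.scaled(0.0)
        ic = InitialConditions(rnaI=100, rnaII=50, pcn_measured=40,
                               mu=math.log(2))
        traj = simulate_generation(ic, low_network, zero, 60.0,
                                   dilution="all", n_points=61,
                                   rtol=1e-11, atol=1e-16)
        y0 = ic.state_vector(low_network)
        for i in np.nonzero(y0)[0]:
            expected = y0[i] * np.exp(-math.log(2) / 60.0 * traj.times_min)
            np.testing.assert_allclose(traj.concentrations[:, i], expected,
                                       rtol=1e-6)
        assert traj.final_pcn == pytest.approx(traj.initial_pcn / 2, rel=1e-6)
        assert pcn_delta(traj) < 0

    def test_plasmid_exempt_mode_keeps_plasmids_constant(self, low_network,
                                                         low_params):
        zero = low_params.scaled(0.0)
        ic = InitialConditions(rnaI=100, rnaII=50, pcn_measured=40,
                               mu=math.log(2))
        traj = simulate_generation(ic, low_network, zero, 60.0)
        assert traj.final_pcn == pytest.approx(traj.initial_pcn, rel=1e-9)
        i = low_network.index["RNAI"]
        assert traj.concentrations[-1, i] == pytest.approx(
            traj.concentrations[0, i] / 2, rel=1e-6)


class TestEquilibrium:
    def test_reversible_pair_reaches_mass_action_equilibrium(self):
        """With mu = 0 a lone A + B <-> AB pair equilibrates so that
        [AB]/([A][B]) = k_on/k_off (closed form of the two-reaction
        subsystem)."""
        species = [Species("A", "free-RNA"), Species("B", "free-RNA"),
                   Species("AB", "complex")]
        reactions = [
            Reaction("f", 3, (("A", 1), ("B", 1)), (("AB", 1),)),
            Reaction("b", 4, (("AB", 1),), (("A", 1), ("B", 1))),
        ]
        net = ReactionNetwork(species, reactions, "low")
        k_on, k_off = 1e7, 2.0
        params = KineticParameters({3: k_on, 4: k_off}, "low")
        y0 = np.array([molecules_to_molar(1000), molecules_to_molar(800), 0.0])
        traj = integrate(y0, net, params, 2000.0, mu_per_h=0.0, n_points=5)
        a, b, ab = traj.concentrations[-1]
        assert ab / (a * b) == pytest.approx(k_on / k_off, rel=1e-4)


class TestSimulateGeneration:
    def test_vanishing_duration_returns_initial_copy_number(self, low_network,
                                                            low_params):
        ic = InitialConditions(6, 0.44, 46, 0.283)
        traj = simulate_generation(ic, low_network, low_params, 1e-9)
        assert traj.final_pcn == pytest.approx(23.0, abs=1e-6)

    def test_nonpositive_duration_rejected(self, low_network, low_params):
        ic = InitialConditions(6, 0.44, 46, 0.283)
        with pytest.raises(ValueError):
            simulate_generation(ic, low_network, low_params, 0.0)

    def test_negative_initial_conditions_rejected(self):
        with pytest.raises(ValueError):
            InitialConditions(-1, 0, 46, 0.3)

    def test_state_starts_from_half_measured_pcn(self, low_network):
        ic = InitialConditions(6, 0.44, 46, 0.283)
        y0 = ic.state_vector(low_network)
        assert y0[low_network.index["pDNA"]] == pytest.approx(
            molecules_to_molar(23.0))
        assert y0[low_network.index["Rom"]] == 0.0
        assert y0[low_network.index["tRNA"]] == 0.0

    def test_non_negativity_over_full_run(self, calibrated_high):
        from cole1sim.study import simulate_timepoint
        traj = simulate_timepoint(calibrated_high, "T3", n_points=200)
        assert traj.concentrations.min() >= -1e-8 * traj.concentrations.max()

    def test_trajectory_csv_is_bit_identical_across_runs(self, low_network,
                                                         low_params,
                                                         tmp_path):
        ic = InitialConditions(17, 1, 48, 0.302)
        paths = []
        for tag in ("a", "b"):
            traj = simulate_generation(ic, low_network, low_params, 138.0)
            p = tmp_path / f"traj_{tag}.csv"
            traj.to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestRegulationProperties:
    def test_rom_layer_lowers_final_copy_number(self, low_network,
                                                high_network, low_params):
        """At equal shared constants and initial state, the network with
        the Rom reactions produces no more plasmids than the one without
        (Rom represses replication)."""
        shared = {i: v for i, v in low_params.k.items()}
        high_like = KineticParameters(
            {i: v for i, v in shared.items()
             if i not in (1, 2, 13, 20, 23)}, "high")
        ic = InitialConditions(17, 1, 48, 0.302)
        with_rom = simulate_generation(ic, low_network, low_params, 138.0)
        without = simulate_generation(ic, high_network, high_like, 138.0)
        assert with_rom.final_pcn <= without.final_pcn

    def test_final_pcn_monotone_in_trna_synthesis(self, calibrated_high):
        """Raising k24 (more uncharged tRNA) never lowers the final copy
        number, all else equal."""
        from cole1sim.study import initial_conditions
        ic = initial_conditions("high", "T3")
        finals = []
        for factor in (1e-2, 1e-1, 1.0, 10.0):
            params = calibrated_high.params.scaled(1.0, {24: factor})
            traj = simulate_generation(ic, calibrated_high.network, params,
                                       347.0, n_points=8)
            finals.append(traj.final_pcn)
        assert all(b >= a - 1e-6 for a, b in zip(finals, finals[1:]))

    def test_trna_free_limit_ignores_initial_trna_pool(self, high_network,
                                                       high_params):
        """With tRNA synthesis and every tRNA-binding constant at zero, the
        trajectory does not depend on the initial tRNA pool (the antisense
        core decouples from the tRNA layer)."""
        params = high_params.replace(k24=0.0, k14=0.0, k15=0.0, k9=0.0)
        ic = InitialConditions(345, 75, 5806, 0.09)
        base = ic.state_vector(high_network)
        loaded = base.copy()
        loaded[high_network.index["tRNA"]] = molecules_to_molar(1e5)
        runs = [integrate(y0, high_network, params, 100.0, 0.09, n_points=11,
                          rtol=1e-11, atol=1e-16)
                for y0 in (base, loaded)]
        mask = [i for i, s in enumerate(high_network.species)
                if s.name != "tRNA"]
        np.testing.assert_allclose(runs[0].concentrations[:, mask],
                                   runs[1].concentrations[:, mask],
                                   rtol=1e-7, atol=1e-16)
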