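"""Reaction-network construction and ODE simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arpsyn import reaction_model as rm


def sim(net, initial, t_end=600.0, n=61):
    t = np.linspace(0.0, t_end, n)
    return rm.simulate(net, initial, t)


class TestConstruction:
    def test_oligomerization_on_rates_fixed_at_barbed_end_value(self):
        net = rm.build_actin_alone()
        # 11.6 /uM/s == 1.16e7 /M/s, the barbed-end monomer on-rate
        oligo = [net.params[n] for n in ("kf2", "kf3", "kf4")]
        assert all(p.value == 11.6 for p in oligo)
        assert rm.K_ON_BARBED * 1e6 == pytest.approx(1.16e7)

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_dip1_variant_monomer_chain(self, n):
        net = rm.build_dip1_model(n)
        assert [f"DCA{i}" for i in range(1, n + 1)] == [
            s for s in net.species if s.startswith("DCA")]
        # exactly one irreversible activation step ends the chain
        acts = [r for r in net.reactions
                if "E_dip" in r.products and "E_dip" not in r.reactants]
        assert len(acts) == 1
        src = list(acts[0].reactants)[0]
        assert src == ("DC" if n == 0 else f"DCA{n}")

    @pytest.mark.parametrize("n", [-1, 4, 7])
    def test_invalid_monomer_count_rejected(self, n):
        with pytest.raises(ValueError, match="invalid variant"):
            rm.build_dip1_model(n)

    def test_synergy_mask_controls_floated_flags(self):
        net = rm.build_synergy_model({"km9", "km10", "k11"})
        assert sorted(net.floated()) == ["k11", "km10", "km9"]
        with pytest.raises(ValueError, match="invalid variant"):
            rm.build_synergy_model(set())
        with pytest.raises(ValueError, match="invalid variant"):
            rm.build_synergy_model({"kon"})

    def test_rate_constant_validation(self):
        with pytest.raises(ValueError):
            rm.RateConstant("k", -1.0)
        with pytest.raises(ValueError):
            rm.RateConstant("k", 5.0, fixed=False, bounds=(0.0, 1.0))

    def test_every_reaction_conserves_actin(self):
        # construction itself verifies stoichiometric conservation
        for n in range(4):
            rm.build_dip1_model(n)
        rm.build_actin_alone()


class TestSimulation:
    def test_zero_nucleation_gives_no_polymer(self):
        net = rm.build_actin_alone({"kn2": 0.0, "kn3": 0.0, "kn4": 0.0})
        res = sim(net, {"G": 3.0})
        assert np.all(res.filamentous == 0.0)
        assert np.all(res.ends_spontaneous == 0.0)

    def test_frozen_system_is_constant(self):
        net = rm.build_dip1_model(1)
        zeros = {name: 0.0 for name in net.params}
        net = net.with_values(zeros)
        res = sim(net, {"G": 3.0, "C": 0.05, "D": 1.0})
        for s, value in (("G", 3.0), ("C", 0.05), ("D", 1.0)):
            assert np.allclose(res[s], value, atol=1e-12)

    def test_preformed_ends_follow_single_exponential(self):
        """With nucleation off, elongation from fixed ends is first order:
        G(t) = C_c + (G0 - C_c) exp(-k_on E0 t)."""
        net = rm.build_actin_alone({"kf2": 0.0})
        g0, e0 = 3.0, 0.001
        t = np.linspace(0.0, 600.0, 121)
        res = rm.simulate(net, {"G": g0, "E_spont": e0}, t)
        expected = rm.CRITICAL_CONC + (g0 - rm.CRITICAL_CONC) * np.exp(
            -rm.K_ON_BARBED * e0 * t)
        assert np.max(np.abs(res["G"] - expected)) < 1e-3

    def test_elongation_steady_state_is_critical_concentration(self):
        net = rm.build_actin_alone({"kf2": 0.0})
        res = sim(net, {"G": 3.0, "E_spont": 0.005}, t_end=5000.0)
        assert res["G"][-1] == pytest.approx(rm.CRITICAL_CONC, abs=1e-4)

    def test_disabled_dip1_pathway_matches_actin_alone(self):
        t = np.linspace(0.0, 800.0, 81)
        # tight atol: nucleation flux through nM-scale pools amplifies
        # tolerance-level differences over the lag phase
        dip = rm.simulate(rm.build_dip1_model(1, overrides={"k9": 0.0}),
                          {"G": 3.0, "C": 0.05, "D": 5.0}, t, atol=1e-10)
        alone = rm.simulate(rm.build_actin_alone(), {"G": 3.0}, t, atol=1e-10)
        assert np.all(dip.ends_dip1 == 0.0)
        assert np.allclose(dip.filamentous, alone.filamentous, atol=1e-6)

    def test_repeat_runs_bit_identical(self):
        net = rm.build_dip1_model(1)
        a = sim(net, {"G": 3.0, "C": 0.05, "D": 2.0})
        b = sim(net, {"G": 3.0, "C": 0.05, "D": 2.0})
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_rk4_oracle_on_toy_network(self):
        """A 3-species elongation network must match an independently coded
        fixed-step RK4 integration of the same mass-action ODEs."""
        net = rm.build_actin_alone({"kf2": 0.0})
        kon, koff = rm.K_ON_BARBED, rm.K_OFF_BARBED
        e0 = 0.002

        def rhs(y):
            g, f = y
            dep = koff * e0 * f / (f + 1e-8)
            return np.array([-kon * e0 * g + dep, kon * e0 * g - dep])

        h = 0.002
        y = np.array([3.0, 0.0])
        t_report = np.arange(0.0, 200.0 + 1e-9, 20.0)
        oracle = [y.copy()]
        t_now = 0.0
        for t_next in t_report[1:]:
            while t_now < t_next - 1e-12:
                k1 = rhs(y)
                k2 = rhs(y + h / 2 * k1)
                k3 = rhs(y + h / 2 * k2)
                k4 = rhs(y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t_now += h
            oracle.append(y.copy())
        oracle = np.array(oracle)

        res = rm.simulate(net, {"G": 3.0, "E_spont": e0}, t_report)
        assert np.allclose(res["G"], oracle[:, 0], rtol=1e-4)
        assert np.allclose(res.filamentous, oracle[:, 1], rtol=1e-4, atol=1e-8)

    def test_simulation_input_validation(self):
        net = rm.build_actin_alone()
        with pytest.raises(ValueError):
            rm.simulate(net, {"G": -1.0}, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            rm.simulate(net, {"G": 1.0}, np.array([1.0, 2.0]))
        with pytest.raises(KeyError):
            rm.simulate(net, {"D": 1.0}, np.array([0.0, 1.0]))


class TestInvariants:
    @settings(max_examples=15, deadline=None)
    @given(
        g0=st.floats(0.5, 6.0),
        c0=st.floats(0.0, 0.1),
        d0=st.floats(0.0, 10.0),
        n=st.integers(0, 3),
    )
    def test_mass_conservation_and_nonnegativity(self, g0, c0, d0, n):
        net = rm.build_dip1_model(n)
        t = np.linspace(0.0, 400.0, 41)
        res = rm.simulate(net, {"G": g0, "C": c0, "D": d0}, t)
        total = res.total_actin(net)
        assert np.max(np.abs(total - g0)) < 1e-6 * max(g0, 1.0)
        assert res.concentrations.min() >= -1e-9

    def test_depolymerization_stops_without_polymer(self):
        net = rm.build_actin_alone({"kf2": 0.0})
        # ends present, no G, no F: nothing can move
        res = sim(net, {"E_spont": 0.01}, t_end=50.0, n=11)
        assert np.allclose(res.filamentous, 0.0, atol=1e-12)
        assert np.allclose(res["G"], 0.0, atol=1e-12)


class TestSerialization:
    def test_params_tsv_roundtrip(self, tmp_path):
        net = rm.build_synergy_model({"k11"})
        path = tmp_path / "params.tsv"
        rm.params_to_tsv(net.params, path)
        loaded = rm.params_from_tsv(path)
        assert set(loaded) == set(net.params)
        for name, p in net.params.items():
            assert loaded[name].value == pytest.approx(p.value)
            assert loaded[name].fixed == p.fixed

    def test_network_yaml_roundtrip(self, tmp_path):
        net = rm.build_dip1_model(2, overrides={"k11": 0.123})
        path = tmp_path / "net.yaml"
        rm.network_to_yaml(net, path)
        loaded = rm.network_from_yaml(path)
        assert loaded.variant == net.variant
        assert loaded.n_monomer_steps == 2
        assert loaded.params["k11"].value == pytest.approx(0.123)

    def test_simulation_result_tidy_tsv(self, tmp_path):
        import pandas as pd
        net = rm.build_actin_alone()
        res = sim(net, {"G": 3.0}, t_end=100.0, n=6)
        path = tmp_path / "sim.tsv"
        res.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["time_s", "species", "concentration_uM"]
        assert len(df) == 6 * len(net.species)
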