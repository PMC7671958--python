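"""Network builders, membrane dynamics and the compiled integrator."""

import numpy as np
import pytest

from pulsegate.kinetics import GATE_KINDS, GatingKinetics, tau_x, x_inf
from pulsegate.network import (ChemicalSynapse, CompartmentParams,
                               NetworkSpec, build_network)
from pulsegate.pulses import generate_pulse_times
from pulsegate.simulate import (IntegrationFault, electrical_current,
                                membrane_derivative, reference_rhs,
                                simulate, synapse_derivative, _pack)


# --------------------------------------------------------------------------
# kinetics sanity


class TestKinetics:
    def test_tau_positive_and_inf_bounded(self):
        V = np.linspace(-120, 60, 361)
        for kind in GATE_KINDS:
            assert np.all(tau_x(V, kind) > 0)
            inf = x_inf(V, kind)
            assert np.all((inf >= 0) & (inf <= 1))

    def test_h_current_resets_during_spikes(self):
        # activation collapses and speeds up at spike voltages
        assert x_inf(30.0, "m_AR") < 1e-6
        assert tau_x(30.0, "m_AR") < 1.0 < tau_x(-70.0, "m_AR")

    def test_slow_classification_threshold(self):
        kin = GatingKinetics({"m_AR": 0.10})
        assert kin.is_slow("m_AR") and kin.is_slow("m_KM")
        assert not kin.is_slow("h_Na") and not kin.is_slow("m_CaH")


# --------------------------------------------------------------------------
# single-term dynamics against closed forms


class TestMembraneDerivative:
    def _bare(self, **g):
        full_g = {"L": 0.0, "Na": 0.0, "K": 0.0, "AR": 0.0, "KM": 0.0,
                  "CaH": 0.0}
        full_g.update(g)
        E = {"L": -65.0, "Na": 50.0, "K": -95.0, "AR": -35.0, "KM": -95.0,
             "CaH": 125.0}
        return CompartmentParams("x", 0.9, 0.0, full_g, E)

    def test_no_currents_gives_zero(self):
        p = self._bare()
        assert membrane_derivative(-55.0, {}, p) == 0.0

    def test_leak_only_at_reversal(self):
        p = self._bare(L=2.0)
        p.J = 4.5
        assert membrane_derivative(-65.0, {}, p) == pytest.approx(-4.5 / 0.9)

    def test_full_cell_matches_term_by_term_oracle(self):
        spec = build_network("fs_si_ib")
        comp = spec.compartments["IB_da"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            V = rng.uniform(-90, 30)
            gating = {k: rng.uniform(0, 1) for k in comp.gate_kinds}
            got = membrane_derivative(V, gating, comp, I_syn=1.3, I_el=-0.7)
            # oracle: sum each ionic current independently
            g, E = comp.g, comp.E
            m0 = 1.0 / (1.0 + np.exp((-V - 34.5) / 10.0))
            terms = [
                g["L"] * (V - E["L"]),
                g["Na"] * m0 ** 3 * gating["h_Na"] * (V - E["Na"]),
                g["K"] * gating["m_K"] ** 4 * (V - E["K"]),
                g["AR"] * gating["m_AR"] * (V - E["AR"]),
                g["KM"] * gating["m_KM"] * (V - E["KM"]),
                g["CaH"] * gating["m_CaH"] ** 2 * (V - E["CaH"]),
            ]
            want = (-comp.J - 1.3 - (-0.7) - 0.0 - sum(terms)) / comp.C
            assert got == pytest.approx(want, rel=1e-14)

    def test_gating_outside_unit_interval_rejected(self):
        spec = build_network("fs_si_ib")
        comp = spec.compartments["SI"]
        with pytest.raises(ValueError, match="outside"):
            membrane_derivative(-60.0, {k: 1.5 for k in comp.gate_kinds},
                                comp)


class TestSynapseAndCoupling:
    def test_synapse_drive_vanishes_at_hyperpolarised_vpre(self):
        got = synapse_derivative(0.4, -70.0, 8.0, 0.5)
        assert got == pytest.approx(-0.4 / 8.0, abs=1e-5)

    def test_synapse_zero_state_depolarised(self):
        assert synapse_derivative(0.0, 0.0, 8.0, 0.5) == pytest.approx(2.0)

    def test_synapse_steady_state_saturating_vpre(self):
        # ds/dt = 0 with tanh -> 1 gives s* = 2 tau_d / (tau_r + 2 tau_d)
        td, tr = 8.0, 0.5
        s_star = 2 * td / (tr + 2 * td)
        assert synapse_derivative(s_star, 1e3, td, tr) == pytest.approx(0.0)

    def test_electrical_current_antisymmetric(self):
        assert electrical_current(-60.0, -60.0, 3.0) == 0.0
        assert electrical_current(-50.0, -70.0, 0.0) == 0.0
        a = electrical_current(-50.0, -70.0, 2.0)
        b = electrical_current(-70.0, -50.0, 2.0)
        assert a + b == 0.0

    def test_gating_relaxation_matches_closed_form(self):
        # constant-V relaxation: x(t) = x_inf + (x0 - x_inf) e^{-t/tau}
        kin = GatingKinetics()
        V, x0, t = -60.0, 0.9, 12.0
        for kind in GATE_KINDS:
            tau = kin.tau(V, kind)
            inf = kin.x_inf(V, kind)
            # integrate dx/dt = (inf - x)/tau with RK4 steps
            x, dt = x0, 0.01
            for _ in range(int(t / dt)):
                k1 = (inf - x) / tau
                k2 = (inf - (x + dt * k1 / 2)) / tau
                k3 = (inf - (x + dt * k2 / 2)) / tau
                k4 = (inf - (x + dt * k3)) / tau
                x += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            want = inf + (x0 - inf) * np.exp(-t / tau)
            assert x == pytest.approx(want, abs=1e-10)


# --------------------------------------------------------------------------
# builders


class TestBuildNetwork:
    def test_full4_topology(self):
        spec = build_network("full4")
        assert set(spec.compartments) == {"RS", "FS", "SI", "IB_soma",
                                          "IB_a", "IB_da", "IB_db"}
        assert len(spec.compartments) == 7
        assert len(spec.couplings) == 3

    def test_fs_si_2inputs_inherits_kinetics(self):
        spec = build_network("fs_si_2inputs")
        assert "IB_soma" not in spec.compartments
        by_label = {s.label: s for s in spec.synapses}
        # input-2 synapses inherit the former IB->FS / IB->SI kinetics
        assert by_label["input2->SI"].tau_r == pytest.approx(2.5)
        assert by_label["input2->FS"].tau_r == pytest.approx(0.25)
        # input-1 synapses inherit the former RS->FS / RS->SI kinetics
        assert by_label["input1->SI"].tau_d == pytest.approx(1.0)

    def test_si_only_has_inhibitory_input2(self):
        spec = build_network("si_only")
        by_label = {s.label: s for s in spec.synapses}
        assert by_label["input2->SI"].V0 == -80.0
        assert by_label["input2->SI"].tau_d == pytest.approx(8.0)  # FS->SI

    def test_unknown_config_and_variant(self):
        with pytest.raises(ValueError, match="unknown config_id"):
            build_network("nope")
        with pytest.raises(KeyError, match="variant"):
            build_network("full4", ("bogus",))

    def test_variant_changes_parameters(self):
        base = build_network("fs_si_ib")
        fast = build_network("fs_si_ib", ("fast_h",))
        s0 = base.compartments["IB_da"].kinetics.tau_scale["m_AR"]
        s1 = fast.compartments["IB_da"].kinetics.tau_scale["m_AR"]
        assert s1 == pytest.approx(0.75 * s0)

    def test_ib_has_exactly_seven_slow_variables(self):
        spec = build_network("fs_si_ib")
        slow = spec.slow_variables("IB")
        assert len(slow) == 7
        assert "syn:SI->IB" in slow and "syn:IB_a->IB_db" in slow

    def test_undeclared_endpoint_rejected(self):
        si = build_network("si_only").compartments["SI"]
        with pytest.raises(ValueError, match="undeclared"):
            NetworkSpec("si_only", {"SI": si},
                        [ChemicalSynapse("ghost", "SI", 1, -80, 8, 0.5)],
                        [], [])


# --------------------------------------------------------------------------
# integrator


class TestSimulate:
    def test_zero_conductance_network_is_constant(self):
        comp = CompartmentParams(
            "x", 1.0, 0.0,
            {c: 0.0 for c in ("L", "Na", "K", "AR", "KM", "CaH")},
            {c: 0.0 for c in ("L", "Na", "K", "AR", "KM", "CaH")})
        spec = NetworkSpec("si_only", {"x": comp}, [], [], [])
        y0 = np.array([-55.0])
        res = simulate(spec, {}, 50.0, initial=y0)
        assert np.allclose(res.V("x"), -55.0)

    def test_compiled_rhs_matches_reference(self):
        """Compiled kernel == pure-python term-by-term dynamics."""
        spec = build_network("fs_si_ib")
        packed, labels, comps = _pack(spec)
        nstate = len(labels)
        rng = np.random.default_rng(7)
        from pulsegate.simulate import _rhs
        for _ in range(10):
            y = np.empty(nstate)
            nc = packed["nc"]
            y[:nc] = rng.uniform(-90, 30, nc)
            y[nc:] = rng.uniform(0, 1, nstate - nc)
            y[-len(spec.drives):] = rng.uniform(-70, 25, len(spec.drives))
            dy = np.empty(nstate)
            iacc = np.empty(nc)
            _rhs(y, dy, iacc, packed["nc"], packed["ng"], packed["ns"],
                 packed["nd"], packed["C"], packed["J"], packed["gL"],
                 packed["VL"], packed["gNa"], packed["VNa"], packed["gK"],
                 packed["VK"], packed["gAR"], packed["VAR"], packed["gKM"],
                 packed["VKM"], packed["gCaH"], packed["VCaH"],
                 packed["comp_gate"], packed["gate_comp"],
                 packed["gate_kind"], packed["gate_tsc"],
                 packed["syn_src"], packed["syn_tgt"], packed["syn_g"],
                 packed["syn_V0"], packed["syn_td"], packed["syn_tr"],
                 packed["el_a"], packed["el_b"], packed["el_g"])
            want = reference_rhs(spec, y)
            np.testing.assert_allclose(dy, want, rtol=1e-12, atol=1e-12)

    def test_bitwise_reproducibility(self):
        spec = build_network("si_only")
        d = {"input1": generate_pulse_times(40, 0, 400),
             "input2": generate_pulse_times(16.357, 0, 400)}
        a = simulate(spec, d, 400.0)
        b = simulate(spec, d, 400.0)
        assert np.array_equal(a.states, b.states)
        assert all(np.array_equal(a.spikes[c], b.spikes[c])
                   for c in a.spikes)

    def test_dimensionless_states_stay_in_unit_interval(self,
                                                        fs_si_ib_40hz):
        _, _, res = fs_si_ib_40hz
        for lbl in res.gating_labels + res.synapse_labels:
            tr = res[lbl]
            assert tr.min() >= 0.0 and tr.max() <= 1.0

    def test_self_convergence_under_dt_halving(self):
        spec = build_network("fs_si_2inputs")
        d = {"input1": generate_pulse_times(40, 0, 1500),
             "input2": generate_pulse_times(16.357, 0, 1500)}
        r1 = simulate(spec, d, 1500.0, dt=0.02)
        r2 = simulate(spec, d, 1500.0, dt=0.01)
        for c in ("FS", "SI"):
            a, b = r1.spikes[c], r2.spikes[c]
            assert len(a) == len(b)
            assert np.max(np.abs(a - b)) < 0.1

    def test_coarse_dt_rejected(self):
        spec = build_network("si_only")
        with pytest.raises(ValueError, match="dt"):
            simulate(spec, {}, 10.0, dt=0.2)

    def test_divergence_raises_integration_fault(self):
        # a pathological self-exciting compartment blows up
        comp = CompartmentParams(
            "x", 0.01, -500.0,
            {"L": 0.0, "Na": 0.0, "K": 0.0, "AR": 0.0, "KM": 0.0,
             "CaH": 0.0},
            {c: 0.0 for c in ("L", "Na", "K", "AR", "KM", "CaH")})
        spec = NetworkSpec("si_only", {"x": comp}, [], [], [])
        with pytest.raises(IntegrationFault):
            simulate(spec, {}, 100.0)


# --------------------------------------------------------------------------
# behaviour of the standard configurations


class TestNetworkBehaviour:
    def test_full4_free_run_beta1_pattern(self):
        """Undriven network: RS/SI in phase, IB in anti-phase, beta1-band
        common rate, FS faster."""
        spec = build_network("full4")
        res = simulate(spec, {}, 6000.0)
        rs = res.spikes["RS"]; rs = rs[rs > 1500]
        si = res.spikes["SI"]; si = si[si > 1500]
        a = res.spikes["IB_a"]; a = a[a > 1500]
        on = a[np.concatenate([[0], np.nonzero(np.diff(a) > 15)[0] + 1])]
        rate = 1000.0 * (len(rs) - 1) / (rs[-1] - rs[0])
        assert 13.0 <= rate <= 18.5  # beta1 band
        si_rate = 1000.0 * (len(si) - 1) / (si[-1] - si[0])
        assert si_rate == pytest.approx(rate, rel=0.05)
        lag_si = np.mean([np.min(np.abs(si - t)) for t in rs])
        lag_ib = np.mean([np.min(np.abs(on - t)) for t in rs])
        assert lag_si < 2.0  # RS and SI in phase
        assert lag_ib > 10.0  # IB out of phase
        fs = res.spikes["FS"]; fs = fs[fs > 1500]
        fs_rate = 1000.0 * (len(fs) - 1) / (fs[-1] - fs[0])
        assert fs_rate > 1.8 * rate  # FS fires on both half-cycles

    def test_driven_full4_si_tracks_pulses(self, full4_driven_40hz):
        """40 Hz drive: every SI spike trails an input pulse by < 3 ms."""
        _, train, res = full4_driven_40hz
        si = res.spikes["SI"]; si = si[si > 2000]
        lat = si - train.times[np.searchsorted(train.times, si) - 1]
        assert lat.max() < 3.0
        # and never on consecutive pulses
        pos = np.searchsorted(train.times, si + 1e-6)
        assert np.diff(pos).min() >= 2

    def test_fs_si_2inputs_silent_without_drives(self):
        spec = build_network("fs_si_2inputs")
        res = simulate(spec, {}, 2000.0)
        for c in ("FS", "SI"):
            assert len(res.spikes[c][res.spikes[c] > 500]) <= 2

    def test_jittered_inputs_preserve_gating(self):
        """5% interval jitter on both drives: the SI cell still fires in
        phase with input-1, never on consecutive pulses, at roughly the
        slow-drive rate."""
        spec = build_network("fs_si_2inputs")
        d = {"input1": generate_pulse_times(40.0, 0.05, 6000.0, seed=21),
             "input2": generate_pulse_times(16.357, 0.05, 6000.0, seed=22)}
        res = simulate(spec, d, 6000.0)
        si = res.spikes["SI"]; si = si[si > 1500]
        t1 = d["input1"].times
        lat = si - t1[np.searchsorted(t1, si) - 1]
        assert lat.max() < 3.0
        assert np.diff(np.searchsorted(t1, si + 1e-6)).min() >= 2
        rate = 1000.0 * (len(si) - 1) / (si[-1] - si[0])
        realized_f2 = 1000.0 / np.mean(np.diff(d["input2"].times))
        assert rate == pytest.approx(realized_f2, rel=0.08)
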