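"""Cable model: closed-form electrics, discretization, integrator accuracy."""

import math

import numpy as np
import pytest

import dendrotopo as dt
from dendrotopo.cable import CurrentStep, SimulationError

from conftest import straight_cable


class TestLengthConstant:
    def test_worked_value(self):
        p = dt.PassiveParams(g_leak=3.17e-4, ra=50.0)
        assert dt.length_constant(1.0, p) == pytest.approx(397.2, abs=0.2)

    def test_quadrupling_diameter_doubles(self):
        p = dt.PassiveParams(g_leak=3.17e-4, ra=50.0)
        assert dt.length_constant(4.0, p) == \
            pytest.approx(2 * dt.length_constant(1.0, p))

    def test_quadrupling_leak_halves(self):
        p1 = dt.PassiveParams(g_leak=3.17e-4, ra=50.0)
        p4 = dt.PassiveParams(g_leak=4 * 3.17e-4, ra=50.0)
        assert dt.length_constant(1.0, p4) == \
            pytest.approx(dt.length_constant(1.0, p1) / 2)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            dt.length_constant(0.0, dt.PassiveParams())


class TestElectrodeConstants:
    def test_axial_resistance_30_mohm(self):
        # 10 um x 1 um cylinder at Ra = 235.6 Ohm*cm emulates the 30 MOhm
        # access resistance of a sharp electrode
        assert dt.section_axial_resistance(10, 1, 235.6) == \
            pytest.approx(30.0, rel=0.005)

    def test_resistance_scaling(self):
        r = dt.section_axial_resistance(10, 1, 100.0)
        assert dt.section_axial_resistance(20, 1, 100.0) == pytest.approx(2 * r)
        assert dt.section_axial_resistance(10, 2, 100.0) == pytest.approx(r / 4)

    def test_capacitance_2_pf(self):
        # same cylinder at Cm = 6.4 uF/cm^2 emulates ~2 pF
        assert dt.section_membrane_capacitance(10, 1, 6.4) == \
            pytest.approx(2.0, rel=0.01)

    def test_capacitance_additive(self):
        whole = dt.section_membrane_capacitance(10, 1, 1.0)
        halves = 2 * dt.section_membrane_capacitance(5, 1, 1.0)
        assert whole == pytest.approx(halves)
        assert dt.section_membrane_capacitance(10, 1, 0.0) == 0.0


class TestBiexp:
    def test_peak_equals_gmax(self):
        k = dt.SynapseKinetics()
        t = np.linspace(0, 10, 200001)
        g = dt.biexp_conductance(t, k)
        assert g.max() == pytest.approx(0.27, rel=1e-6)

    def test_zero_at_onset(self):
        k = dt.SynapseKinetics()
        assert dt.biexp_conductance(0.0, k) == 0.0
        assert dt.biexp_conductance(-1.0, k) == 0.0

    def test_peak_time_closed_form(self):
        k = dt.SynapseKinetics(tau_rise=0.2, tau_decay=1.1)
        tp = dt.biexp_peak_time(k)
        assert tp == pytest.approx(0.4167, abs=5e-4)
        t = np.linspace(0, 5, 500001)
        g = dt.biexp_conductance(t, k)
        assert t[np.argmax(g)] == pytest.approx(tp, abs=1e-4)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            dt.SynapseKinetics(tau_rise=1.1, tau_decay=0.2)


class TestDiscretize:
    def test_nseg_from_ceil_rule(self):
        # 100 um dendrite, lambda ~ 397.2 um -> 0.1 lambda = 39.72 -> 3 seg
        m = straight_cable(n_nodes=51, length=100.0, radius=0.5)
        p = dt.PassiveParams(g_leak=3.17e-4, ra=50.0)
        model = dt.discretize(m, p)
        assert model.grids[0].nseg == 3

    def test_short_section_single_segment(self):
        m = straight_cable(n_nodes=5, length=10.0, radius=0.5)
        model = dt.discretize(m, dt.PassiveParams(g_leak=3.17e-4, ra=50.0))
        assert model.grids[0].nseg == 1

    def test_bound_holds_on_toy_dn(self, toy_dn, passive_params):
        model = dt.discretize(toy_dn, passive_params)
        assert model.max_seg_frac() <= 0.1 + 1e-12

    def test_soma_single_compartment(self, toy_dn, passive_params):
        model = dt.discretize(toy_dn, passive_params)
        soma = model.soma_comp()
        assert model.comp_label[soma] == "soma"
        r = toy_dn.soma_diameter / 2
        assert model.area[soma] == pytest.approx(4 * math.pi * r * r * 1e-8)


class TestElectrode:
    def test_attach_twice_rejected(self, toy_dn, passive_params):
        model = dt.discretize(toy_dn, passive_params)
        dt.attach_electrode(model)
        with pytest.raises(ValueError, match="already"):
            dt.attach_electrode(model)

    def test_steady_state_ohms_law(self, toy_dn, passive_params):
        """Voltage drop between electrode tip and soma equals I times the
        electrode access resistance at steady state (within the small seal
        leak)."""
        model = dt.discretize(toy_dn, passive_params)
        dt.attach_electrode(model)
        tip = model.electrode_comps[-1]
        amp = -0.002
        tr = dt.simulate(model, 150, 0.05,
                         stimuli=[CurrentStep(tip, 10, 150, amp)])
        dv = tr.voltage[-1, tip] - tr.voltage[-1, model.soma_comp()]
        expected = amp * dt.section_axial_resistance(10, 1, 235.6)
        assert dv == pytest.approx(expected, rel=0.08)


class TestSimulate:
    def test_resting_fixed_point(self, toy_model):
        tr = dt.simulate(toy_model, duration=100, dt=0.025)
        assert np.abs(tr.voltage - toy_model.params.e_rev).max() < 1e-9

    def test_rc_step_closed_form(self):
        """Single-compartment soma: V follows I R (1 - exp(-t/tau))."""
        nodes = [dt.SkeletonNode(1, -1, np.zeros(3), 5.0, "soma")]
        p = dt.PassiveParams(cm=1.0, g_leak=3.17e-4, ra=50.0, e_rev=-60.0)
        model = dt.discretize(dt.Morphology(nodes), p)
        amp = 0.01
        tr = dt.simulate(model, 50, 0.025, stimuli=[CurrentStep(0, 5, 50, amp)])
        area = 4 * math.pi * 25e-8                  # cm^2
        r_in = 1.0 / (p.g_leak * area) * 1e-6       # MOhm
        tau = p.cm * 1e-3 / p.g_leak                # ms
        vinf = amp * r_in
        theory = np.where(tr.time >= 5,
                          -60 + vinf * (1 - np.exp(-(tr.time - 5) / tau)), -60)
        err = np.abs(tr.voltage[:, 0] - theory).max() / vinf
        assert err < 0.01

    def test_sealed_cable_attenuation(self):
        """Steady-state attenuation over one length constant ~ 1/cosh(1)."""
        p = dt.PassiveParams(cm=1.0, g_leak=3.17e-4, ra=50.0, e_rev=-60.0)
        lam = dt.length_constant(1.0, p)
        m = straight_cable(n_nodes=401, length=lam, radius=0.5)
        model = dt.discretize(m, p, max_frac=0.01)
        tr = dt.simulate(model, 400, 0.1, stimuli=[CurrentStep(0, 0, 400, 1e-3)])
        v = tr.voltage[-1] + 60.0
        ratio = v[model.grids[0].comp_start + model.grids[0].nseg - 1] / v[0]
        assert ratio == pytest.approx(1 / math.cosh(1.0), rel=0.01)

    def test_sealed_cable_input_resistance(self):
        """R_in of a sealed cable of length L = lambda is R_inf coth(1)."""
        p = dt.PassiveParams(cm=1.0, g_leak=3.17e-4, ra=50.0, e_rev=-60.0)
        lam = dt.length_constant(1.0, p)
        m = straight_cable(n_nodes=401, length=lam, radius=0.5)
        model = dt.discretize(m, p, max_frac=0.01)
        amp = 1e-3
        tr = dt.simulate(model, 400, 0.1, stimuli=[CurrentStep(0, 0, 400, amp)])
        r_in = (tr.voltage[-1, 0] + 60.0) / amp     # MOhm
        ri = p.ra * 1e-2 / (math.pi * 0.25)         # MOhm per um
        r_inf = ri * lam
        assert r_in == pytest.approx(r_inf / math.tanh(1.0), rel=0.01)

    def test_superposition_of_current_stimuli(self, toy_model):
        e = toy_model.params.e_rev
        s1 = CurrentStep(toy_model.soma_comp(), 5, 20, 0.01)
        s2 = CurrentStep(toy_model.siz_comp, 2, 25, 0.02)
        t1 = dt.simulate(toy_model, 30, 0.025, stimuli=[s1])
        t2 = dt.simulate(toy_model, 30, 0.025, stimuli=[s2])
        t12 = dt.simulate(toy_model, 30, 0.025, stimuli=[s1, s2])
        err = np.abs((t12.voltage - e)
                     - (t1.voltage - e) - (t2.voltage - e)).max()
        assert err < 1e-6

    def test_sublinearity_of_synapse_sets(self, toy_model, clustered_map):
        """Composite peak of any co-activated set never exceeds the sum of
        individual peaks (conductance shunting)."""
        e = toy_model.params.e_rev
        siz = toy_model.siz_comp
        ids = [r.synapse_id for r in clustered_map.records]
        singles = {}
        for sid in ids:
            tr = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=[sid],
                             onset_times=1.0)
            singles[sid] = tr.peak_depolarization(siz, e)
        rng = np.random.default_rng(11)
        for _ in range(20):
            size = int(rng.integers(2, 20))
            chosen = list(rng.choice(ids, size=size, replace=False))
            tr = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=chosen,
                             onset_times=1.0)
            comp = tr.peak_depolarization(siz, e)
            assert comp <= sum(singles[s] for s in chosen) + 1e-9
            assert comp >= max(singles[s] for s in chosen) - 1e-6

    def test_voltage_bounded_by_reversals(self, toy_model, clustered_map):
        """With only leak and excitatory conductances, voltages stay within
        [E_rev, E_syn]: exactly for the monotone backward-Euler scheme, and
        within the (non-monotone) trapezoid scheme's local truncation error
        for Crank-Nicolson."""
        ids = [r.synapse_id for r in clustered_map.records]
        be = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=ids,
                         onset_times=1.0, method="backward_euler")
        assert be.voltage.min() >= toy_model.params.e_rev - 1e-9
        assert be.voltage.max() <= -10.0 + 1e-9
        cn = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=ids,
                         onset_times=1.0)
        assert cn.voltage.min() >= toy_model.params.e_rev - 1e-3
        assert cn.voltage.max() <= -10.0 + 1e-3

    def test_convergence_dt_and_grid_halving(self, toy_dn, passive_params,
                                             clustered_map):
        sid = clustered_map.records[0].synapse_id
        peaks = {}
        for mf in (0.1, 0.05):
            model = dt.build_model(toy_dn, passive_params, clustered_map,
                                   max_frac=mf)
            for step in (0.025, 0.0125):
                tr = dt.simulate(model, 30, step, active_synapse_ids=[sid],
                                 onset_times=1.0)
                peaks[(mf, step)] = tr.peak_depolarization(model.siz_comp,
                                                           passive_params.e_rev)
        base = peaks[(0.1, 0.025)]
        assert abs(peaks[(0.1, 0.0125)] - base) / base < 0.005
        assert abs(peaks[(0.05, 0.025)] - base) / base < 0.005

    def test_invalid_dt_and_method(self, toy_model):
        with pytest.raises(ValueError):
            dt.simulate(toy_model, 10, 0.0)
        with pytest.raises(ValueError):
            dt.simulate(toy_model, 10, 0.025, method="explicit")

    def test_backward_euler_agrees_with_cn(self, toy_model, clustered_map):
        sid = clustered_map.records[0].synapse_id
        e = toy_model.params.e_rev
        a = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=[sid],
                        onset_times=1.0, method="cn")
        b = dt.simulate(toy_model, 30, 0.025, active_synapse_ids=[sid],
                        onset_times=1.0, method="backward_euler")
        pa = a.peak_depolarization(toy_model.siz_comp, e)
        pb = b.peak_depolarization(toy_model.siz_comp, e)
        assert pa == pytest.approx(pb, rel=0.05)
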