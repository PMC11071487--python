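"""Protocols: democracy scan, co-activation, cluster experiment, passive fit."""

import numpy as np
import pytest

import dendrotopo as dt
from dendrotopo.protocols import CurrentClampProtocol, run_current_clamp

from conftest import straight_cable


FIT_PROTOCOL = CurrentClampProtocol(dt=0.05, duration=60.0, t_on=5.0,
                                    t_off=40.0)


def cable_with_siz(length=400.0):
    """Unbranched cable whose SIZ is annotated at the proximal end."""
    m = straight_cable(n_nodes=201, length=length)
    m.meta["siz_node"] = 1
    return m


class TestDemocracyScan:
    def test_attenuation_monotone_on_uniform_cable(self, passive_params):
        m = cable_with_siz()
        recs = [dt.SynapseRecord(i + 1, 1, "LC4",
                                 m.nodes[20 * i + 10].position.copy(), 50)
                for i in range(10)]
        smap = dt.map_to_skeleton(recs, m)
        model = dt.build_model(m, passive_params, smap)
        scan = dt.democracy_scan(model, smap).table
        ordered = scan.sort_values("dist_to_siz_um")
        assert (np.diff(ordered.siz_peak_mv.to_numpy()) <= 1e-12).all()

    def test_synapse_at_siz_local_equals_siz_peak(self, passive_params):
        m = cable_with_siz()
        recs = [dt.SynapseRecord(1, 1, "LC4", m.nodes[1].position.copy(), 50),
                dt.SynapseRecord(2, 1, "LC4", m.nodes[150].position.copy(), 50)]
        smap = dt.map_to_skeleton(recs, m)
        model = dt.build_model(m, passive_params, smap)
        scan = dt.democracy_scan(model, smap).table
        at_siz = scan[scan.synapse_id == 1].iloc[0]
        assert at_siz.local_peak_mv == pytest.approx(at_siz.siz_peak_mv,
                                                     rel=1e-6)

    def test_siz_peaks_compressed_relative_to_local(self, toy_model,
                                                    clustered_map):
        """The arbor normalizes single-synapse impact: variability of SIZ
        peaks is far below variability of local peaks."""
        scan = dt.democracy_scan(toy_model, clustered_map).table
        cv = lambda x: x.std() / x.mean()
        assert cv(scan.siz_peak_mv) < cv(scan.local_peak_mv)


class TestActivateNeuron:
    def test_single_synapse_neuron_linearity_one(self, toy_dn, passive_params):
        recs = [dt.SynapseRecord(1, 7, "LC4",
                                 toy_dn.nodes[300].position.copy(), 50)]
        smap = dt.map_to_skeleton(recs, toy_dn)
        model = dt.build_model(toy_dn, passive_params, smap)
        res = dt.activate_neuron(model, smap, 7)
        assert res.n_synapses == 1
        assert res.linearity_index == pytest.approx(1.0, abs=1e-9)

    def test_unknown_neuron_rejected(self, toy_model, clustered_map):
        with pytest.raises(KeyError):
            dt.activate_neuron(toy_model, clustered_map, 99999)

    def test_colocated_pair_shunts_more_than_separated(self, passive_params):
        """Two synapses in one compartment depolarize the probe less than an
        equally-weighted pair far apart on a symmetric cable."""
        m = cable_with_siz()
        mid = m.nodes[100].position.copy()
        near = [dt.SynapseRecord(1, 1, "LC4", mid, 50),
                dt.SynapseRecord(2, 1, "LC4", mid, 50)]
        # symmetric about the midpoint: equal individual SIZ peaks
        far = [dt.SynapseRecord(1, 1, "LC4", m.nodes[80].position.copy(), 50),
               dt.SynapseRecord(2, 1, "LC4", m.nodes[120].position.copy(), 50)]
        peaks = []
        for recs in (near, far):
            smap = dt.map_to_skeleton(recs, m)
            model = dt.build_model(m, passive_params, smap)
            peaks.append(dt.activate_neuron(model, smap, 1).composite_peak_mv)
        assert peaks[0] <= peaks[1]

    def test_composite_bounded_by_sum(self, toy_model, clustered_map):
        res = dt.activate_neuron(toy_model, clustered_map, 1)
        assert 0 < res.linearity_index <= 1.0 + 1e-12


class TestRandomSetCurve:
    def test_monotone_load_and_shunting(self, toy_model, clustered_map):
        counts = [1, 5, 20, 60, len(clustered_map)]
        results = dt.random_set_curve(toy_model, clustered_map, counts,
                                      n_reps=3, seed=0)
        mean_peak = {}
        mean_lin = {}
        for c in counts:
            rs = [r for r in results if r.n_synapses == c]
            mean_peak[c] = np.mean([r.composite_peak_mv for r in rs])
            mean_lin[c] = np.mean([r.linearity_index for r in rs])
        peaks = [mean_peak[c] for c in counts]
        lins = [mean_lin[c] for c in counts]
        assert all(a <= b + 1e-9 for a, b in zip(peaks, peaks[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(lins, lins[1:]))

    def test_full_population_deterministic(self, toy_model, clustered_map):
        n = len(clustered_map)
        a = dt.random_set_curve(toy_model, clustered_map, [n], seed=0)
        b = dt.random_set_curve(toy_model, clustered_map, [n], seed=99)
        assert len(a) == len(b) == 1
        assert a[0].composite_peak_mv == b[0].composite_peak_mv

    def test_count_exceeding_population_rejected(self, toy_model,
                                                 clustered_map):
        with pytest.raises(ValueError):
            dt.random_set_curve(toy_model, clustered_map,
                                [len(clustered_map) + 1])


@pytest.fixture(scope="module")
def cluster_result(toy_model, clustered_map):
    return dt.clustered_vs_random_experiment(toy_model, clustered_map,
                                             n_synapses=15, n_sets=30, seed=0)


class TestClusterExperiment:

    def test_close_group_has_wider_peak_variance(self, cluster_result):
        result = cluster_result
        df = result.table
        v_close = df.loc[df.group == "close", "composite_peak_mv"].var()
        v_rand = df.loc[df.group == "random", "composite_peak_mv"].var()
        assert v_close > v_rand
        assert result.levene_p < 0.05

    def test_close_distance_range_covers_random_range(self, cluster_result):
        result = cluster_result
        df = result.table
        d_close = df.loc[df.group == "close", "mean_dist_to_siz_um"]
        d_rand = df.loc[df.group == "random", "mean_dist_to_siz_um"]
        assert d_close.min() <= d_rand.min() + 1e-9
        assert d_close.max() >= d_rand.max() - 1e-9

    def test_proximal_close_set_beats_distal_close_set(self, cluster_result):
        """Composite EPSP of close sets covaries with distance to the SIZ."""
        df = cluster_result.table
        close = df[df.group == "close"].sort_values("mean_dist_to_siz_um")
        assert close.iloc[0].composite_peak_mv > close.iloc[-1].composite_peak_mv

    def test_deterministic_given_seed(self, toy_model, clustered_map):
        a = dt.clustered_vs_random_experiment(toy_model, clustered_map,
                                              n_synapses=5, n_sets=1, seed=3)
        b = dt.clustered_vs_random_experiment(toy_model, clustered_map,
                                              n_synapses=5, n_sets=1, seed=3)
        assert a.table.equals(b.table)

    def test_single_group_present_with_matching_counts(self, cluster_result):
        result = cluster_result
        # the clustered generator gives every neuron exactly 15 synapses
        assert (result.table.group == "single").sum() == 10
        assert not result.warnings

    def test_single_group_omitted_with_warning(self, toy_model, clustered_map):
        res = dt.clustered_vs_random_experiment(toy_model, clustered_map,
                                                n_synapses=7, n_sets=5, seed=0)
        assert res.warnings
        assert "single" not in set(res.table.group)


class TestFitPassive:
    def test_self_fit_recovers_parameters(self, toy_dn):
        true = dt.PassiveParams(cm=0.8, g_leak=3.17e-4, ra=50.0, e_rev=-61.15)
        t, v = dt.make_target_trace(toy_dn, true, FIT_PROTOCOL, noise_sd=0.0,
                                    seed=0)
        fit = dt.fit_passive(toy_dn, (t, v), FIT_PROTOCOL)
        # the optimum must essentially reproduce the zero-residual target
        # (RMS below a microvolt; the exact zero sits at the true params)
        rms = np.sqrt(fit.final_error / len(t))
        assert rms < 1e-3
        assert fit.params.g_leak == pytest.approx(true.g_leak, rel=0.05)
        assert fit.params.e_rev == pytest.approx(true.e_rev, rel=0.05)
        assert fit.params.cm == pytest.approx(true.cm, rel=0.05)

    def test_objective_equals_brute_force_residual(self, toy_dn):
        true = dt.PassiveParams(cm=0.8, g_leak=3.17e-4, ra=50.0, e_rev=-61.15)
        t, v = dt.make_target_trace(toy_dn, true, FIT_PROTOCOL, noise_sd=0.05,
                                    seed=1)
        probe = dt.PassiveParams(cm=1.0, g_leak=4e-4, ra=100.0, e_rev=-60.0)
        point = {k: (getattr(probe, k), getattr(probe, k))
                 for k in ("cm", "g_leak", "ra", "e_rev")}
        fit = dt.fit_passive(toy_dn, (t, v), FIT_PROTOCOL, bounds=point)
        t_sim, v_sim = run_current_clamp(toy_dn, probe, FIT_PROTOCOL)
        brute = float(np.sum((v_sim - np.interp(t_sim, t, v)) ** 2))
        assert fit.final_error == pytest.approx(brute, rel=1e-12)
        assert all(fit.bound_hit.values())

    def test_reproducible(self, toy_dn):
        true = dt.PassiveParams(cm=0.8, g_leak=3.17e-4, ra=50.0, e_rev=-61.15)
        t, v = dt.make_target_trace(toy_dn, true, FIT_PROTOCOL, noise_sd=0.05,
                                    seed=2)
        point = {"cm": (0.7, 0.9), "g_leak": (2e-4, 5e-4),
                 "ra": (50.0, 50.0), "e_rev": (-62.0, -60.0)}
        a = dt.fit_passive(toy_dn, (t, v), FIT_PROTOCOL, bounds=point)
        b = dt.fit_passive(toy_dn, (t, v), FIT_PROTOCOL, bounds=point)
        assert a.final_error == b.final_error
        assert a.params == b.params
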