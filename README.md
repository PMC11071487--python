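# dendrotopo

Passive multicompartment cable models and synapse-topography statistics
for EM-reconstructed neurons.

Connectome datasets give a neuron's full dendritic morphology together
with the position, presynaptic identity, and detection confidence of every
input synapse. `dendrotopo` turns that information into quantitative
answers to two families of questions about dendritic integration in
insect descending neurons (and any neuron with comparable data):

* **How are synapses organized on the arbor?** Per-neuron synapse spread
  (mean pairwise path distance), nearest-neighbor same-neuron clustering
  against identity-shuffled nulls, retinotopy regression of synapse path
  distance on receptive-field centroid distance, and anatomical
  receptive-field estimation (quadratic surface fit, per-neuron footprint
  polygons and centroids, hemisphere-bias tests).

* **What does that organization do to passive integration?** A branched
  passive cable model built directly from the SWC skeleton — sections
  discretized so no segment exceeds 0.1 of its length constant, axial
  conductances from conical-frustum geometry, bi-exponential conductance
  synapses, an electrode model for fitting somatic current-clamp
  recordings — integrated with an implicit Hines-ordered solver (one O(N)
  tree solve per time step).

The core quantities, in the field's standard notation:

* Length constant per section: `λ = sqrt(d / (4 R_a g_leak))`.
* Synaptic conductance: `g(t) = gmax · f · (e^(−t/τ_d) − e^(−t/τ_r))`,
  peak-normalized to `gmax` (defaults τ_r = 0.2 ms, τ_d = 1.1 ms,
  gmax = 0.27 nS, E_syn = −10 mV — cholinergic values).
* Synapse spread of a group of n synapses:
  `s = Σ_{j<k} D(s_j, s_k) / (n(n−1)/2)`, with `D` the path distance
  along the arbor.
* EPSP amplitude: peak of `V − E_rev` at a probe; the composite EPSP of a
  set is the same for simultaneous activation; the linearity index is
  composite peak / Σ individual peaks.

A seeded synthetic-data module generates toy descending-neuron
morphologies (soma–tether–axon backbone, tapering binary dendritic tree,
annotated spike initiation zone), synapse maps with controllable
clustering or retinotopy, centroid fields with hemisphere bias, and noisy
current-clamp traces from known parameters — so the entire pipeline is
testable without any dataset downloads.

## Worked example

```python
import dendrotopo as dt

# toy DN: 34 sections, 1350 um total length, SIZ annotated on the axon
morph = dt.make_toy_dn(dt.ToyDNSpec(seed=1))
params = dt.PassiveParams(cm=0.8, g_leak=3.17e-4, ra=50.0, e_rev=-61.15)

# 10 presynaptic neurons x 15 synapses, clustered along the arbor
spec = dt.SynapsePlacementSpec(seed=0, n_neurons=10, synapses_per_neuron=15,
                               mode="clustered", sigma_cluster=8.0)
smap = dt.map_to_skeleton(dt.place_synapses(morph, spec).records, morph)
model = dt.build_model(morph, params, smap)

scan = dt.democracy_scan(model, smap).table
print(scan.local_peak_mv.min(), scan.local_peak_mv.max())  # 0.413 1.436
print(scan.siz_peak_mv.min(), scan.siz_peak_mv.max())      # 0.339 0.380

nn = dt.nn_shuffle_test(smap, n_shuffles=99, seed=0)
print(nn.observed_pct, nn.shuffle_pcts.mean(), nn.perm_p)  # 76.4 9.6 0.01

exp = dt.clustered_vs_random_experiment(model, smap, n_synapses=15,
                                        n_sets=50, seed=0)
print(exp.levene_p)                                        # 2.7e-05
```

Reading the output: local EPSP peaks vary ~3.5-fold across synapse
locations while peaks at the spike initiation zone are compressed into a
~12% band — the morphology passively normalizes single-synapse impact
("synaptic democracy"). The nearest-neighbor test finds 76% of NN synapse
pairs share a presynaptic neuron versus ~10% in identity-shuffled nulls
(permutation p = 0.01): the generator's clustering is detected. In the
close-versus-random experiment, path-clustered 15-synapse sets produce a
significantly wider range of composite EPSPs than dispersed sets
(Levene p = 2.7e-05), because a tight cluster's impact covaries with its
distance to the spike initiation zone.

The same pipeline is scriptable from a shell:

```sh
dendrotopo synth dn --seed 1 -o toy.swc
dendrotopo synth synapses toy.swc --mode clustered --sigma 8 -o syn.csv
dendrotopo syn map toy.swc syn.csv --cleft-min 30 -o mapped.csv
dendrotopo topo nn toy.swc mapped.csv --shuffles 99
dendrotopo proto cluster toy.swc mapped.csv -n 15 --sets 50 -o cluster.csv
```

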