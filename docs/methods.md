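# Methods

This note documents the models and numerical choices behind `dendrotopo`,
what its synthetic data do and do not emulate, and the package's known
limitations.

## Passive cable model

**Assumptions.** The membrane is purely passive: a uniform specific
capacitance `Cm` (µF/cm²), leak conductance density `g_leak` (S/cm²) with
reversal `E_rev` (mV), and axial resistivity `Ra` (Ω·cm) over the whole
cell. No voltage-gated conductances, no spines, no synaptic plasticity.
Synapses are conductance-based with identical kinetics and peak
conductance everywhere — the standard simplification for insect EM models,
supported by the near-uniform synaptic contact areas observed in fly EM
volumes. The spike initiation zone (SIZ) enters as an annotated node
(its location is an experimental observation, not derivable from the
skeleton); "EPSP amplitude" always means the peak of `V − E_rev` at a
probe.

**Geometry.** The SWC skeleton is split into sections: maximal unbranched,
label-homogeneous runs of nodes. Membrane area uses the conical-frustum
lateral area per parent–child edge, because radii taper along EM
skeletons and frusta track mesh surface areas much better than constant
radius cylinders. The soma is a single spherical compartment of area
`4πr²`; edges leaving the soma are treated as cylinders of the child's
caliber (a frustum from the soma radius would fabricate membrane).
An equivalent-cylinder axon appended for truncated reconstructions is
flagged internally and its area computed as `π·d·L` exactly, so total
area grows by exactly the detailed axon's area.

**Discretization.** Each section's DC length constant is
`λ = sqrt(d/(4·Ra·g_leak))` with `d` the length-weighted mean diameter
(the DC form is used; the frequency-dependent `λ_f` would only shrink
segments further at these time scales). Sections are split into
`nseg = ceil(L / (max_frac·λ))` equal segments, `max_frac = 0.1` by
default. Compartments sit at segment centers; axial conductances are the
reciprocal of the frustum resistance integral `∫ Ra/(π r(x)²) dx` between
adjacent centers, which is exact for linear taper
(`R = Ra·L/(π r₁ r₂)` per stretch). Branch vertices get explicit
zero-area junction nodes, preserving the exact star topology of the
resistive network at branch points; without them, sibling branches couple
through the parent's half-segment twice, a first-order spatial error that
dominated convergence tests. Junction nodes cost nothing extra: they are
ordinary (capacitance-free) unknowns of the tree system.

**Synapse coupling.** A synapse's conductance is distributed over the two
grid anchors flanking its arc position (segment centers, plus the junction
nodes at section ends) with linear weights. This keeps transfer impedances
to remote probes second-order accurate in the segment length; with plain
nearest-center placement, halving `max_frac` moved SIZ peaks by ~2%,
versus ~0.4% with weighted coupling. Synapses sharing a compartment sum
their conductances. Local peak readout uses the nearest center.

**Integration.** The tree system is advanced implicitly with
Hines-ordered elimination (children eliminated into parents, then one
back-substitution): O(N) per step, unconditionally stable. The default
scheme is Crank–Nicolson, implemented as a half-step backward-Euler solve
at the interval midpoint followed by extrapolation, with synaptic
conductances evaluated analytically at the midpoint and entering the
system matrix (implicit treatment — stable for hundreds of co-active
synapses). CN was chosen over backward Euler as the default because the
synaptic rise time (0.2 ms) is only 8 time steps at dt = 0.025 ms and the
package's convergence requirement (halving dt changes peaks by < 0.5%)
calls for second-order accuracy; backward Euler remains available
(`method="backward_euler"`). One consequence: CN is not monotone, so
voltages can undershoot `E_rev` by the local truncation error (observed
~3·10⁻⁴ mV at synchronous onset of 150 synapses); BE respects the
`[E_rev, E_syn]` bounds exactly. NaN/instability aborts the run with a
diagnostic. Peak extraction refines the sampled maximum with a parabola
through its three neighbors, removing grid-sampling bias from convergence
comparisons.

**Electrode.** The recording electrode is a passive cylinder in series
with the soma: 10 µm × 1 µm with Ra = 235.6 Ω·cm (≈30 MΩ access
resistance), Cm = 6.4 µF/cm² (≈2 pF), and a seal leak of
3.798·10⁻⁴ S/cm². The stated seal-resistance pairing (8 GΩ) is internally
inconsistent with that density by ~5% (1/(3.798e-4 · π·10⁻³ cm²) ≈
8.4 GΩ); the density is stored as given and the discrepancy documented
rather than reconciled. The cylinder is split into 8 compartments plus a
zero-area node at the free end where current is injected and voltage
recorded, so the full access resistance separates the recording point
from the soma. Whether recordings are taken at the electrode end or the
soma node is configurable (`record="electrode"|"soma"`); the electrode
end is the default since that is what an amplifier sees.

## Simulation protocols

* **Democracy scan** — one simulation per synapse with identical
  kinetics; records the local peak, the SIZ peak, and the path distance
  to the SIZ.
* **Neuron/set activation** — simultaneous activation of a synapse set at
  one onset; reports the composite SIZ peak and the linearity index
  (composite / Σ individual). Individual peaks are computed once and
  reused across sets.
* **Close vs random experiment** — per set of size n: *random* draws n
  synapses uniformly without replacement; *close* draws a random anchor
  synapse and its n−1 nearest neighbors by path distance along the arbor
  (Euclidean available as a sensitivity flag); *single* co-activates every
  presynaptic neuron whose synapse count equals n (±`single_tolerance`,
  default exact; the group is omitted with a warning when empty).
  Composite-peak variance is compared close-vs-random with Levene's test;
  groups are compared with Kruskal–Wallis followed by Dunn's post-hoc test
  with Bonferroni adjustment. Dunn's test is implemented in-package from
  rank sums with tie correction (no post-hoc library is a dependency).
* **Passive fit** — bounded minimization of the summed squared voltage
  residual between a simulated and an averaged experimental current-clamp
  trace, over (Cm, g_leak, Ra, E_rev). Bounds default to the
  experimentally plausible ranges Ra ∈ [30, 400] Ω·cm,
  Cm ∈ [0.6, 2.6] µF/cm², with wide defaults for g_leak
  ([5·10⁻⁵, 2·10⁻³] S/cm²) and E_rev ([−80, −40] mV). The optimizer is
  deterministic: L-BFGS-B on the unit-normalized box, restarted from the
  box center plus the 8 inner-half-box corners over (Cm, g_leak, E_rev)
  with Ra at midpoint. The residual window defaults to the full trace and
  is configurable. The default test pulse is −10 pA for 35 ms through the
  electrode: following the experimental convention of using the largest
  pulse that keeps the response passive, it deflects the toy DN by
  ~1.8 mV (< 2 mV) and makes all four parameters identifiable above the
  noise floor of a 20-sweep average (recovery within ~2% across seeds);
  at −2 pA the Cm/Ra directions are noise-degenerate.

## Topography statistics

All synapse–synapse distances are path distances along the arbor
(addresses are `(section, arc-offset)` pairs; the distance is computed
via root-distances and lowest common ancestors and is an exact tree
metric). Euclidean mode exists for comparison only.

* **Spread** of an n-synapse group: pair sum divided by `n(n−1)/2`
  unique pairs (the prose definition). A `1/n²` prefactor variant is
  selectable because that normalization also circulates; the two are
  never silently interchanged.
* **Nearest-neighbor clustering** — each synapse is paired with its
  nearest other synapse; exact distance ties resolve to the lowest
  synapse id (near-ties at machine precision are treated as distinct, so
  the pair set equals a brute-force argmin exactly). Unordered pairs are
  deduplicated. The null permutes presynaptic identities over fixed
  positions (seeded, one stream per shuffle index, so shuffle k does not
  depend on the number of shuffles requested). Two statistics are
  reported: the one-sample t of shuffle percentages against the observed
  value (the conventional summary; strongly anticonservative as a
  detection test because it scales the shuffle spread by 1/√n_shuffles),
  and the exact permutation p-value
  `(1 + #{shuffle ≥ observed})/(n_shuffles + 1)`, which is calibrated at
  any shuffle count and is what the calibration suite uses (≥ 19 shuffles
  for p < 0.05 to be attainable; the protocol default of 10 shuffles
  mirrors common practice for effect-size displays).
* **Retinotopy regression** — for every unique presynaptic-neuron pair,
  x = Euclidean centroid distance in field coordinates, y = mean path
  distance over all cross-neuron synapse pairs; ordinary least squares
  with the slope's t-test p-value. Requires ≥ 3 neurons, every neuron
  with a centroid.

## Receptive fields

The population surface is a least-squares quadratic
`w = a₀ + a₁u + a₂v + a₃u² + a₄uv + a₅v²` in the pooled cloud's PCA
frame (axis signs fixed deterministically by making each axis's
largest-magnitude component positive). Per-neuron footprints are the
convex hull of the projected points — the "polygon" is concretized as a
hull since a concave outline is under-determined; the centroid is the
mean of the projected points (polygon-area centroid behind a flag,
deduplication of repeated points behind a flag, default off to mirror raw
point clouds). A similarity transform (rotation + uniform scale +
translation; reflection behind a flag) fixed by exactly two landmark
correspondences maps field coordinates to eye coordinates. Hemisphere
bias is a two-sided exact binomial test against 0.5; centroids exactly on
the dividing line are excluded from n and reported. A population may
borrow another population's surface (`surface=`/`--surface-from`) for the
case where its own dendritic bias distorts the fit.

## Synthetic data

The generators produce the statistical structure each analysis assumes,
not realistic EM anatomy:

* **Toy DN** — soma–tether–axon backbone with the SIZ on the axon distal
  to the tether–axon junction (the experimentally observed arrangement),
  plus a binary dendritic tree with exact branch lengths (40 µm), exact
  per-level diameter taper (1.6 µm trunk, ×0.8 per level, depth 4) and
  seeded 3-D branch directions. Node spacing ~2 µm. Totals are declared
  in a section plan so summaries can be checked against bookkeeping.
  Scale (≈1.35 mm total length, λ ≈ 300–400 µm) puts dendritic tips at
  ~0.5 λ from the SIZ — enough attenuation range for the normalization
  and shunting phenomena to be visible, while small enough that the whole
  suite runs in seconds.
* **Synapse placement** — `random`: uniform over dendritic length
  (sampled via per-node length weights); `clustered`: per-neuron anchor,
  then nodes weighted by `exp(−d_path/σ)` — a one-parameter family whose
  σ→0 and σ→∞ limits bracket tight clustering and uniformity;
  `retinotopic`: the anchor's normalized depth along a designated main
  dendritic path follows the neuron's centroid coordinate (a strength
  parameter interpolates toward random). Cleft scores are discrete
  uniform on [0, 100], so the default quality threshold of 30 removes a
  predictable ~30%. Synapse coordinates are jittered 0.2 µm off the
  skeleton so mapping is non-trivial but unambiguous.
* **Centroid fields** — unit-square centroids with hemisphere membership
  Bernoulli(bias).
* **Target traces** — clean simulation with known parameters plus
  white-noise sweeps, averaged (default 20 sweeps, σ = 0.05 mV), mirroring
  averaged experimental hyperpolarizing-pulse recordings.

What passing tests therefore show: the statistics detect the structure
they claim to detect and stay calibrated on nulls, and the solver is
accurate against cable theory. What they do not show: behavior on real
EM morphologies (thousands of irregular sections, radius noise,
reconstruction artifacts) or real synapse maps; absolute EPSP magnitudes
of specific identified neurons are out of reach without those data.

## Problem sizes and tolerances

The default test/acceptance configuration uses the seed-1 toy DN
(34 sections, ~75 compartments), 150 mapped synapses (10 neurons × 15),
dt = 0.025 ms for activation protocols and 0.05 ms for fitting,
99 shuffles for permutation tests, 20 null seeds for clustering
calibration and 40 for retinotopy, and 50 sets per group in the
close-versus-random experiment. Reference accuracies at these sizes:
RC step response within 0.01% of closed form, sealed-cable attenuation
within 0.8% of `1/cosh(L/λ)`, superposition exact to 10⁻¹² mV,
dt-halving changes SIZ peaks by ~0.01%, grid-halving by ~0.4%.

## Known limitations

* No active conductances; spike threshold phenomena, dendritic spikes and
  plasticity are outside scope by design.
* Nearest-node synapse mapping (not nearest point on an edge) follows the
  convention of matching against every skeleton coordinate; with ~2 µm
  node spacing the difference is below the discretization length.
* The similarity landmark calibration stops at 2-D field coordinates; no
  angular (deg of visual field) mapping is attempted.
* The PCA frame of the quadratic surface is canonical only up to the
  deterministic sign convention; populations should be compared within
  one fitted frame (or after landmark calibration), not across
  independently fitted frames.
* Sections are label-homogeneous by construction, so a label change
  forces a section boundary even without a branch point; this is
  intentional (electrical parameters and bookkeeping are per-label) but
  means section counts differ from label-agnostic segmentations.
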