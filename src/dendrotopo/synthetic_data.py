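"""Seeded generators for morphologies, synapse maps, centroid fields and
target traces.

These emulate the statistical structure each analysis stage assumes — a
soma/tether/axon backbone with a tapering binary dendritic tree and an
annotated spike-initiation zone; synapse placements that are uniform,
path-distance-clustered, or retinotopically anchored; centroid fields with
a controllable hemisphere bias; and noisy small-current-clamp voltage
traces from known passive parameters.  Every generator is a pure function
of its spec: the same spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .morphology import Morphology, SkeletonNode
from .synapses import SynapseRecord
from .cable import PassiveParams

__all__ = [
    "ToyDNSpec",
    "SynapsePlacementSpec",
    "PlacedSynapses",
    "make_toy_dn",
    "place_synapses",
    "write_synapse_table",
    "make_centroid_field",
    "make_target_trace",
]


@dataclass
class ToyDNSpec:
    """Plan for a toy descending-neuron skeleton.

    The backbone mirrors insect unipolar anatomy: a spherical soma hangs
    off a thin tether that joins the neurite at the junction between the
    axon and the dendritic tree; the spike initiation zone (SIZ) sits on
    the axon, distal to that tether-axon junction.
    """

    seed: int = 1
    soma_diameter: float = 8.0      # um
    tether_length: float = 30.0     # um
    tether_diameter: float = 0.8
    axon_length: float = 80.0       # um
    axon_diameter: float = 1.5
    siz_offset: float = 15.0        # um distal to the tether-axon junction
    depth: int = 4                  # binary-tree depth of the dendrite
    branch_length: float = 40.0     # um per branch
    root_diameter: float = 1.6      # dendrite trunk diameter, um
    taper_ratio: float = 0.8        # diameter multiplier per level
    node_spacing: float = 2.0       # target inter-node distance, um

    def section_plan(self) -> dict:
        """Declared bookkeeping for the summarize oracle."""
        n_dendrite = 2 ** (self.depth + 1) - 1
        total = (self.tether_length + self.axon_length
                 + n_dendrite * self.branch_length)
        return {
            "n_sections": 3 + n_dendrite,  # soma + tether + axon + dendrites
            "n_tips": 2 ** self.depth,
            "total_length_um": total,
            "n_dendrite_sections": n_dendrite,
        }


def _unit(v):
    return v / np.linalg.norm(v)


def _branch_nodes(nodes, next_id, start_id, start_pos, direction, length,
                  diameter, label, spacing):
    """Append a straight run of nodes; returns (ids, last_id, next_id)."""
    n_seg = max(1, int(math.ceil(length / spacing)))
    step = length / n_seg
    parent = start_id
    pos = np.asarray(start_pos, float)
    last = start_id
    for j in range(1, n_seg + 1):
        nid = next_id
        next_id += 1
        nodes.append(SkeletonNode(nid, parent, pos + direction * (step * j),
                                  diameter / 2.0, label))
        parent = nid
        last = nid
    return last, next_id


def make_toy_dn(spec: ToyDNSpec | None = None) -> Morphology:
    """Generate a toy DN morphology with SIZ annotation.

    Deterministic given ``spec`` (branch directions come from the seeded
    generator; branch lengths and radii are exact, so the section plan's
    totals hold to machine precision).
    """
    spec = spec or ToyDNSpec()
    rng = np.random.default_rng(spec.seed)
    nodes: list[SkeletonNode] = []
    next_id = 1

    # soma at origin (root)
    soma_id = next_id
    nodes.append(SkeletonNode(soma_id, -1, np.zeros(3), spec.soma_diameter / 2.0,
                              "soma"))
    next_id += 1
    # tether: soma -> junction, along +z
    tether_dir = np.array([0.0, 0.0, 1.0])
    junction, next_id = _branch_nodes(
        nodes, next_id, soma_id, np.zeros(3), tether_dir, spec.tether_length,
        spec.tether_diameter, "tether", spec.node_spacing)
    junction_pos = nodes[-1].position

    # axon from the junction along +y; SIZ node at siz_offset
    axon_dir = np.array([0.0, 1.0, 0.0])
    last, next_id = _branch_nodes(
        nodes, next_id, junction, junction_pos, axon_dir, spec.axon_length,
        spec.axon_diameter, "axon", spec.node_spacing)
    # SIZ = axon node nearest the requested offset from the junction
    axon_nodes = [n for n in nodes if n.label == "axon"]
    siz_node = min(axon_nodes,
                   key=lambda n: abs(np.linalg.norm(n.position - junction_pos)
                                     - spec.siz_offset)).node_id

    # binary dendritic tree from the junction, growing along -y
    def grow(parent_id, parent_pos, direction, level):
        nonlocal next_id
        diam = spec.root_diameter * spec.taper_ratio ** level
        last, nid = _branch_nodes(nodes, next_id, parent_id, parent_pos,
                                  direction, spec.branch_length, diam,
                                  "dendrite", spec.node_spacing)
        next_id = nid
        end_pos = nodes[-1].position
        if level < spec.depth:
            # two daughters: rotate the parent direction by +/- ~40 degrees
            # around a random axis perpendicular to it
            perp = rng.standard_normal(3)
            perp -= perp.dot(direction) * direction
            perp = _unit(perp)
            for sign in (1.0, -1.0):
                ang = math.radians(40.0)
                d = _unit(math.cos(ang) * direction + sign * math.sin(ang) * perp)
                grow(last, end_pos, d, level + 1)

    grow(junction, junction_pos, np.array([0.0, -1.0, 0.0]), 0)

    meta = {"source_id": f"toy-dn-seed{spec.seed}", "siz_node": siz_node,
            "section_plan": spec.section_plan()}
    return Morphology(nodes, unit="um", meta=meta)


# ---------------------------------------------------------------------------
# synapse placement

@dataclass
class SynapsePlacementSpec:
    """Controls for placing per-neuron synapse groups on the dendrite.

    Modes: ``random`` (uniform over dendritic length), ``clustered``
    (per-neuron anchor, exponential path-distance kernel with scale
    ``sigma_cluster``) and ``retinotopic`` (anchor depth along the main
    dendritic path follows the neuron's centroid coordinate with the given
    strength, synapses clustered around the anchor).
    """

    seed: int = 0
    n_neurons: int = 10
    synapses_per_neuron: int | tuple[int, int] = 15
    mode: str = "random"            # random | clustered | retinotopic
    sigma_cluster: float = 10.0     # um, path-distance kernel scale
    retinotopy_strength: float = 1.0
    cleft_low: int = 0              # cleft scores ~ discrete uniform
    cleft_high: int = 100
    position_jitter: float = 0.2    # um offset of cleft coordinate from skeleton
    pre_type: str = "LCtoy"


@dataclass
class PlacedSynapses:
    records: list[SynapseRecord]
    centroids: pd.DataFrame | None   # neuron_id, u, v (retinotopic mode)
    anchor_nodes: dict[int, int]     # neuron_id -> anchor node (clustered modes)


def _dendrite_weights(morph: Morphology):
    """Dendrite node ids with length weights (half of incident edges)."""
    ids = []
    w = []
    for nid, n in morph.nodes.items():
        if n.label != "dendrite":
            continue
        tot = 0.0
        if n.parent_id != -1:
            tot += 0.5 * morph.edge_length(n.parent_id, nid)
        for c in morph.children[nid]:
            tot += 0.5 * morph.edge_length(nid, c)
        ids.append(nid)
        w.append(tot)
    ids = np.array(ids)
    w = np.array(w)
    return ids, w / w.sum()


def _path_dists_from(morph: Morphology, src: int, targets: np.ndarray):
    return np.array([morph.node_path_distance(src, int(t)) for t in targets])


def _main_dendrite_path(morph: Morphology) -> list[int]:
    """Nodes of the root-most dendrite trunk followed along first children
    down to a tip: the designated retinotopy axis."""
    dend = [nid for nid, n in morph.nodes.items() if n.label == "dendrite"]
    start = min(dend, key=lambda n: morph.rootdist[n])
    path = [start]
    cur = start
    while True:
        kids = [c for c in morph.children[cur]
                if morph.nodes[c].label == "dendrite"]
        if not kids:
            break
        cur = kids[0]
        path.append(cur)
    return path


def place_synapses(morph: Morphology,
                   spec: SynapsePlacementSpec | None = None) -> PlacedSynapses:
    """Sample a synapse table on the dendrites of a morphology."""
    spec = spec or SynapsePlacementSpec()
    if spec.mode not in ("random", "clustered", "retinotopic"):
        raise ValueError(f"unknown placement mode {spec.mode!r}")
    if spec.mode in ("clustered", "retinotopic") and spec.sigma_cluster <= 0:
        raise ValueError("sigma_cluster must be positive in clustered modes")
    rng = np.random.default_rng(spec.seed)
    ids, weights = _dendrite_weights(morph)

    main_path = _main_dendrite_path(morph)
    main_dists = np.array([morph.rootdist[n] for n in main_path])
    main_dists = main_dists - main_dists[0]

    records: list[SynapseRecord] = []
    anchors: dict[int, int] = {}
    centroid_rows = []
    syn_id = 1
    for neuron in range(1, spec.n_neurons + 1):
        if isinstance(spec.synapses_per_neuron, tuple):
            lo, hi = spec.synapses_per_neuron
            n_syn = int(rng.integers(lo, hi + 1))
        else:
            n_syn = int(spec.synapses_per_neuron)
        if spec.mode == "random":
            chosen = rng.choice(ids, size=n_syn, p=weights)
        else:
            if spec.mode == "clustered":
                anchor = int(rng.choice(ids, p=weights))
            else:  # retinotopic
                u = (neuron - 0.5) / spec.n_neurons
                v = float(rng.uniform())
                centroid_rows.append({"neuron_id": neuron, "u": u, "v": v})
                t = spec.retinotopy_strength * u \
                    + (1 - spec.retinotopy_strength) * float(rng.uniform())
                target = t * main_dists[-1]
                anchor = int(main_path[int(np.argmin(np.abs(main_dists - target)))])
            anchors[neuron] = anchor
            d = _path_dists_from(morph, anchor, ids)
            w = np.exp(-d / spec.sigma_cluster) * weights
            chosen = rng.choice(ids, size=n_syn, p=w / w.sum())
        for nid in chosen:
            pos = morph.nodes[int(nid)].position
            jitter = rng.standard_normal(3)
            jitter = jitter / np.linalg.norm(jitter) * spec.position_jitter
            score = int(rng.integers(spec.cleft_low, spec.cleft_high + 1))
            records.append(SynapseRecord(syn_id, neuron, spec.pre_type,
                                         pos + jitter, score))
            syn_id += 1
    centroids = pd.DataFrame(centroid_rows) if centroid_rows else None
    return PlacedSynapses(records, centroids, anchors)


def write_synapse_table(records: list[SynapseRecord], path) -> None:
    """Write records in the standard synapse-table schema (CSV, um)."""
    pd.DataFrame([{
        "synapse_id": r.synapse_id, "pre_id": r.pre_neuron_id,
        "pre_type": r.pre_type_label,
        "x": r.position[0], "y": r.position[1], "z": r.position[2],
        "cleft_score": r.cleft_score,
    } for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# centroid fields and target traces

def make_centroid_field(n: int, bias: float = 0.5, seed: int = 0,
                        axis: str = "u") -> pd.DataFrame:
    """Centroids in the unit field with hemisphere membership
    Bernoulli(bias) along ``axis`` (favored hemisphere is the upper half)."""
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    upper = rng.uniform(size=n) < bias
    coord = np.where(upper, 0.5 + 0.5 * rng.uniform(size=n),
                     0.5 * rng.uniform(size=n))
    df = pd.DataFrame({"neuron_id": np.arange(1, n + 1), "u": u, "v": v})
    df[axis] = coord
    return df


def make_target_trace(morph: Morphology, true_params: PassiveParams,
                      protocol=None, noise_sd: float = 0.05, seed: int = 0,
                      n_sweeps: int = 20, path=None):
    """Simulate a small current-clamp response with known parameters, add
    white noise per sweep, and average — the synthetic analogue of averaged
    experimental hyperpolarizing-pulse recordings.

    Returns ``(time_ms, voltage_mV)``; also writes a two-column delimited
    trace file if ``path`` is given.
    """
    from .protocols import CurrentClampProtocol, run_current_clamp
    protocol = protocol or CurrentClampProtocol()
    rng = np.random.default_rng(seed)
    t, v = run_current_clamp(morph, true_params, protocol)
    if noise_sd > 0:
        sweeps = v[None, :] + rng.normal(0.0, noise_sd, size=(n_sweeps, v.size))
        v = sweeps.mean(axis=0)
    if path is not None:
        np.savetxt(path, np.column_stack([t, v]), fmt="%.9g",
                   header="time_ms voltage_mV")
    return t, v
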