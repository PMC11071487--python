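"""Synapse tables: loading, quality filtering, skeleton mapping, shuffling.

Synapse records come from automated EM synapse detection: a 3-D cleft
coordinate, the presynaptic neuron it belongs to, a cell-type label, and a
detection-confidence score (``cleft_score``).  Records are mapped onto a
skeleton by nearest node in Euclidean distance, after which all topography
statistics and simulations address them by ``(section_id, arc_offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import Morphology, convert_nm_to_um

__all__ = [
    "SynapseRecord",
    "SynapseMap",
    "read_synapse_table",
    "write_synapse_map",
    "read_synapse_map",
    "filter_by_cleft_score",
    "map_to_skeleton",
    "shuffle_identities",
]

REQUIRED_COLUMNS = ["synapse_id", "pre_id", "pre_type", "x", "y", "z", "cleft_score"]


@dataclass
class SynapseRecord:
    synapse_id: int
    pre_neuron_id: int
    pre_type_label: str
    position: np.ndarray  # (3,) um
    cleft_score: int
    mapped_address: tuple[int, float] | None = None  # (section_id, offset um)
    node_id: int | None = None  # nearest skeleton node


@dataclass
class SynapseMap:
    """Synapse records bound to a morphology, with filter provenance."""

    records: list[SynapseRecord]
    morphology: Morphology
    cleft_threshold: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def require_mapped(self) -> None:
        unmapped = [r.synapse_id for r in self.records if r.mapped_address is None]
        if unmapped:
            raise ValueError(f"unmapped synapses: {unmapped[:5]}...")

    def by_neuron(self) -> dict[int, list[SynapseRecord]]:
        groups: dict[int, list[SynapseRecord]] = {}
        for r in self.records:
            groups.setdefault(r.pre_neuron_id, []).append(r)
        return groups

    def neuron_ids(self) -> list[int]:
        return sorted({r.pre_neuron_id for r in self.records})


def read_synapse_table(path) -> list[SynapseRecord]:
    """Read a delimited synapse table (CSV/TSV) with the standard schema.

    Required columns: synapse_id, pre_id, pre_type, x, y, z, cleft_score.
    A comment line ``# UNITS nm`` switches coordinate interpretation to
    nanometres (converted to um on read).
    """
    path = Path(path)
    unit = "um"
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0].upper() == "UNITS":
                unit = parts[1].lower()
        else:
            break
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"synapse table missing column(s): {missing}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-numeric or non-finite synapse coordinate")
    if unit == "nm":
        coords = convert_nm_to_um(coords)
    return [
        SynapseRecord(int(row.synapse_id), int(row.pre_id), str(row.pre_type),
                      coords[i], int(row.cleft_score))
        for i, row in enumerate(df.itertuples(index=False))
    ]


def filter_by_cleft_score(records: list[SynapseRecord], threshold: int = 30,
                          inclusive: bool = True) -> list[SynapseRecord]:
    """Keep records whose detection confidence passes the quality threshold.

    The default keeps ``cleft_score >= 30`` (inclusive); ``inclusive=False``
    switches to a strict comparison.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if inclusive:
        return [r for r in records if r.cleft_score >= threshold]
    return [r for r in records if r.cleft_score > threshold]


def map_to_skeleton(records: list[SynapseRecord], morph: Morphology,
                    cleft_threshold: int | None = None) -> SynapseMap:
    """Assign each synapse to its nearest skeleton node (Euclidean distance).

    Ties are broken toward the lowest node id, making the mapping
    deterministic.  Already-mapped records are re-mapped to the same
    address (idempotent).
    """
    if not morph.nodes:
        raise ValueError("empty morphology")
    node_ids = np.array(sorted(morph.nodes), dtype=int)
    pts = np.stack([morph.nodes[n].position for n in node_ids])
    mapped = []
    for r in records:
        d2 = np.sum((pts - r.position) ** 2, axis=1)
        best = int(node_ids[int(np.argmin(d2))])  # argmin returns first tie = lowest id
        addr = morph.address_of_node(best)
        mapped.append(replace(r, mapped_address=addr, node_id=best))
    return SynapseMap(mapped, morph, cleft_threshold=cleft_threshold)


def shuffle_identities(smap: SynapseMap, n_shuffles: int = 10,
                       seed: int = 0) -> list[SynapseMap]:
    """Generate shuffled maps by permuting presynaptic identities over
    fixed synapse positions.

    Each shuffle permutes the ``(pre_neuron_id, pre_type_label)`` columns
    while every location (and the multiset of identities) is preserved —
    the null model in which which-neuron-made-which-synapse is random.
    Shuffle ``k`` uses its own seeded stream, so it is stable regardless of
    ``n_shuffles``.
    """
    if len(smap.records) < 2:
        raise ValueError("need at least 2 records to shuffle")
    out = []
    for k in range(n_shuffles):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        perm = rng.permutation(len(smap.records))
        recs = []
        for i, r in enumerate(smap.records):
            src = smap.records[int(perm[i])]
            recs.append(replace(r, pre_neuron_id=src.pre_neuron_id,
                                pre_type_label=src.pre_type_label))
        out.append(SynapseMap(recs, smap.morphology,
                              cleft_threshold=smap.cleft_threshold))
    return out


def write_synapse_map(smap: SynapseMap, path) -> None:
    """Persist a mapped synapse table as CSV with mapping columns added."""
    rows = []
    for r in smap.records:
        sid, off = r.mapped_address if r.mapped_address else (None, None)
        rows.append({
            "synapse_id": r.synapse_id, "pre_id": r.pre_neuron_id,
            "pre_type": r.pre_type_label,
            "x": r.position[0], "y": r.position[1], "z": r.position[2],
            "cleft_score": r.cleft_score,
            "section_id": sid, "arc_offset_um": off, "node_id": r.node_id,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_synapse_map(path, morph: Morphology) -> SynapseMap:
    """Load a persisted synapse map CSV back against a morphology."""
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        addr = None
        if not pd.isna(row.section_id):
            addr = (int(row.section_id), float(row.arc_offset_um))
        recs.append(SynapseRecord(
            int(row.synapse_id), int(row.pre_id), str(row.pre_type),
            np.array([row.x, row.y, row.z], float), int(row.cleft_score),
            mapped_address=addr,
            node_id=None if pd.isna(row.node_id) else int(row.node_id)))
    return SynapseMap(recs, morph)
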