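"""Skeleton morphologies: SWC I/O, validation, sections, and tree geometry.

A morphology is a rooted tree of labeled, radius-bearing nodes (the usual
SWC picture of an EM-derived skeleton).  Nodes are grouped into *sections*:
maximal unbranched runs of nodes sharing one morphological label.  Sections
are the unit at which the cable model assigns passive properties and
discretizes, and section-relative arc addresses ``(section_id, offset_um)``
are the coordinate system used for synapse positions and path distances.

All coordinates, radii and lengths are in micrometres.  SWC files may carry
a ``# UNITS nm`` directive, in which case values are converted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SkeletonNode",
    "Section",
    "Morphology",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "convert_nm_to_um",
    "summarize",
    "path_distance",
    "append_equivalent_cylinder_axon",
]

#: SWC structure-identifier -> morphological label.  Code 5 (first custom
#: code) designates the soma tether, a distinct element in insect neurons.
SWC_LABELS = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite", 5: "tether"}
LABEL_CODES = {"soma": 1, "axon": 2, "dendrite": 3, "tether": 5, "other": 6}


class MorphologyError(ValueError):
    """Raised for structurally invalid skeletons (the message names the
    offending node or line)."""


@dataclass
class SkeletonNode:
    node_id: int
    parent_id: int  # -1 for the root
    position: np.ndarray  # (3,) um
    radius: float  # um
    label: str = "other"


@dataclass
class Section:
    """A maximal unbranched, label-homogeneous run of nodes.

    ``node_ids`` is the geometric polyline: for a non-root section its first
    entry is the attachment node (owned by the parent-ending section), so the
    leading edge is part of this section's length.  ``owned_ids`` partition
    the node set across sections.
    """

    section_id: int
    node_ids: list[int]
    owned_ids: list[int]
    label: str
    length: float
    mean_diameter: float
    parent_section: int | None = None
    length_constant: float | None = None
    uniform_diameter: float | None = None  # set for equivalent-cylinder sections


class Morphology:
    """Validated rooted tree of skeleton nodes with a section partition."""

    def __init__(self, nodes: list[SkeletonNode], unit: str = "um",
                 meta: dict | None = None):
        self.unit = unit
        self.meta = dict(meta or {})
        self.nodes: dict[int, SkeletonNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise MorphologyError(f"duplicate node id {n.node_id}")
            self.nodes[n.node_id] = n
        self._validate()
        self._index()
        self._build_sections()

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id == -1]
        if not roots:
            raise MorphologyError("no root node (parent_id -1) found")
        if len(roots) > 1:
            raise MorphologyError(f"multiple roots: nodes {sorted(roots)}")
        for n in self.nodes.values():
            if n.parent_id != -1 and n.parent_id not in self.nodes:
                raise MorphologyError(
                    f"node {n.node_id} references missing parent {n.parent_id}")
            if not n.radius > 0:
                raise MorphologyError(
                    f"node {n.node_id} has non-positive radius {n.radius}")
            if not np.all(np.isfinite(n.position)):
                raise MorphologyError(f"node {n.node_id} has non-finite position")
        # cycle check: every node must reach the root
        root = roots[0]
        for nid in self.nodes:
            seen = set()
            cur = nid
            while cur != root:
                if cur in seen:
                    raise MorphologyError(f"cycle detected at node {nid}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
        self.root_id = root

    def _index(self) -> None:
        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id != -1:
                self.children[n.parent_id].append(n.node_id)
        for kids in self.children.values():
            kids.sort()
        # depth and path distance from root, per node
        self.depth: dict[int, int] = {self.root_id: 0}
        self.rootdist: dict[int, float] = {self.root_id: 0.0}
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            for c in self.children[nid]:
                self.depth[c] = self.depth[nid] + 1
                self.rootdist[c] = self.rootdist[nid] + self.edge_length(nid, c)
                stack.append(c)

    def edge_length(self, parent: int, child: int) -> float:
        return float(np.linalg.norm(
            self.nodes[child].position - self.nodes[parent].position))

    # -- sections ------------------------------------------------------
    def _build_sections(self) -> None:
        """Split the tree into sections at branch points, terminals, and
        label changes.  Every node is owned by exactly one section."""
        self.sections: list[Section] = []
        self.node_section: dict[int, int] = {}
        equiv = {int(k): float(v)
                 for k, v in self.meta.get("equiv_cylinder_nodes", {}).items()}

        def finish(polyline: list[int], owned: list[int], parent_sec: int | None):
            sid = len(self.sections)
            length = sum(self.edge_length(a, b)
                         for a, b in zip(polyline[:-1], polyline[1:]))
            if length > 0:
                num = sum(self.edge_length(a, b)
                          * (self.nodes[a].radius + self.nodes[b].radius)
                          for a, b in zip(polyline[:-1], polyline[1:]))
                mean_d = num / length
            else:
                mean_d = 2.0 * self.nodes[polyline[0]].radius
            label = self.nodes[owned[0]].label
            sec = Section(sid, list(polyline), list(owned), label, length, mean_d,
                          parent_section=parent_sec)
            if all(n in equiv for n in owned) and len({equiv[n] for n in owned}) == 1:
                sec.uniform_diameter = equiv[owned[0]]
                sec.mean_diameter = sec.uniform_diameter
            self.sections.append(sec)
            for n in owned:
                self.node_section[n] = sid
            return sid

        # (start node, attachment node or None, parent section)
        stack: list[tuple[int, int | None, int | None]] = [(self.root_id, None, None)]
        while stack:
            start, attach, parent_sec = stack.pop()
            polyline = [attach] if attach is not None else []
            owned = []
            cur = start
            while True:
                polyline.append(cur)
                owned.append(cur)
                kids = self.children[cur]
                if (len(kids) == 1
                        and self.nodes[kids[0]].label == self.nodes[cur].label
                        and (kids[0] in equiv) == (cur in equiv)):
                    cur = kids[0]
                else:
                    break
            sid = finish(polyline, owned, parent_sec)
            for c in self.children[cur]:
                stack.append((c, cur, sid))

    # -- queries -------------------------------------------------------
    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)

    def surface_area(self) -> float:
        """Membrane area: frustum lateral area per edge, a sphere for the
        soma node, and exact cylinders for equivalent-cylinder sections."""
        area = 0.0
        for sec in self.sections:
            if sec.uniform_diameter is not None:
                area += math.pi * sec.uniform_diameter * sec.length
                continue
            for a, b in zip(sec.node_ids[:-1], sec.node_ids[1:]):
                na, nb = self.nodes[a], self.nodes[b]
                L = self.edge_length(a, b)
                if na.label == "soma":
                    area += 2.0 * math.pi * nb.radius * L
                else:
                    slant = math.hypot(L, na.radius - nb.radius)
                    area += math.pi * (na.radius + nb.radius) * slant
        for n in self.nodes.values():
            if n.label == "soma":
                area += 4.0 * math.pi * n.radius ** 2
        return area

    @property
    def soma_diameter(self) -> float | None:
        soma = [n for n in self.nodes.values() if n.label == "soma"]
        return 2.0 * soma[0].radius if soma else None

    def section_arc(self, section_id: int) -> np.ndarray:
        """Cumulative arc length at each polyline node of a section."""
        cache = getattr(self, "_arc_cache", None)
        if cache is None:
            cache = self._arc_cache = {}
        if section_id not in cache:
            sec = self.sections[section_id]
            pts = [self.nodes[n].position for n in sec.node_ids]
            seg = [0.0] + [float(np.linalg.norm(b - a))
                           for a, b in zip(pts[:-1], pts[1:])]
            cache[section_id] = np.cumsum(seg)
        return cache[section_id]

    def address_of_node(self, node_id: int) -> tuple[int, float]:
        """Arc address of a node within its owning section."""
        sid = self.node_section[node_id]
        sec = self.sections[sid]
        arc = self.section_arc(sid)
        idx = sec.node_ids.index(node_id)
        return sid, float(arc[idx])

    def point_at_address(self, section_id: int, offset: float) -> np.ndarray:
        sec = self.sections[section_id]
        arc = self.section_arc(section_id)
        if offset < -1e-9 or offset > arc[-1] + 1e-9:
            raise MorphologyError(
                f"offset {offset} outside section {section_id} (length {arc[-1]})")
        if len(sec.node_ids) == 1:
            return self.nodes[sec.node_ids[0]].position.copy()
        i = int(np.searchsorted(arc, min(max(offset, 0.0), arc[-1]), side="right")) - 1
        i = min(max(i, 0), len(arc) - 2)
        a, b = sec.node_ids[i], sec.node_ids[i + 1]
        seg = arc[i + 1] - arc[i]
        t = 0.0 if seg == 0 else (offset - arc[i]) / seg
        return (1 - t) * self.nodes[a].position + t * self.nodes[b].position

    def _address_edge(self, section_id: int, offset: float):
        """Flanking nodes of an arc address and the within-edge distances
        (node, distance to address) for both ends."""
        sec = self.sections[section_id]
        arc = self.section_arc(section_id)
        if offset < -1e-9 or offset > arc[-1] + 1e-9:
            raise MorphologyError(
                f"offset {offset} outside section {section_id} (length {arc[-1]})")
        offset = min(max(offset, 0.0), float(arc[-1]))
        if len(sec.node_ids) == 1:
            n = sec.node_ids[0]
            return (n, 0.0), (n, 0.0)
        i = int(np.searchsorted(arc, offset, side="right")) - 1
        i = min(max(i, 0), len(arc) - 2)
        a, b = sec.node_ids[i], sec.node_ids[i + 1]
        return (a, offset - float(arc[i])), (b, float(arc[i + 1]) - offset)

    def node_lca(self, u: int, v: int) -> int:
        while self.depth[u] > self.depth[v]:
            u = self.nodes[u].parent_id
        while self.depth[v] > self.depth[u]:
            v = self.nodes[v].parent_id
        while u != v:
            u = self.nodes[u].parent_id
            v = self.nodes[v].parent_id
        return u

    def node_path_distance(self, u: int, v: int) -> float:
        w = self.node_lca(u, v)
        return self.rootdist[u] + self.rootdist[v] - 2.0 * self.rootdist[w]

    def copy_nodes(self) -> list[SkeletonNode]:
        return [SkeletonNode(n.node_id, n.parent_id, n.position.copy(),
                             n.radius, n.label) for n in self.nodes.values()]


def path_distance(morph: Morphology,
                  point_a: tuple[int, float],
                  point_b: tuple[int, float]) -> float:
    """Length of the unique tree path between two arc addresses (um).

    Addresses are ``(section_id, offset_um)``.  The distance is a metric on
    the tree: symmetric, zero iff the addresses coincide, and satisfying the
    triangle inequality.
    """
    sa, oa = point_a
    sb, ob = point_b
    if sa == sb:
        # same section: the polyline is a simple path
        morph._address_edge(sa, oa)
        morph._address_edge(sb, ob)
        return abs(oa - ob)
    (a1, da1), (a2, da2) = morph._address_edge(sa, oa)
    (b1, db1), (b2, db2) = morph._address_edge(sb, ob)
    best = math.inf
    for u, du in ((a1, da1), (a2, da2)):
        for v, dv in ((b1, db1), (b2, db2)):
            d = du + morph.node_path_distance(u, v) + dv
            best = min(best, d)
    return best


def convert_nm_to_um(coordinates):
    """Divide nanometre coordinates by 1000.  Accepts scalars or arrays."""
    arr = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinate in nm -> um conversion")
    return arr / 1000.0


def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a validated :class:`Morphology`.

    Honoured '#' directives: ``# UNITS nm|um`` (default um) and
    ``# SIZ <node_id>`` marking the experimentally localized spike
    initiation zone.  A sidecar ``<stem>.json`` with
    ``{source_id, siz_node, notes}``, if present, populates provenance
    metadata.
    """
    path = Path(path)
    unit = "um"
    meta: dict = {}
    nodes: list[SkeletonNode] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0].upper() == "UNITS":
                unit = parts[1].lower()
            elif len(parts) >= 2 and parts[0].upper() == "SIZ":
                meta["siz_node"] = int(parts[1])
            continue
        cols = line.split()
        if len(cols) != 7:
            raise MorphologyError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            nid = int(cols[0]); code = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            pid = int(cols[6])
        except ValueError as exc:
            raise MorphologyError(f"line {lineno}: non-numeric field ({exc})") from exc
        if nid in seen:
            raise MorphologyError(f"line {lineno}: duplicate node id {nid}")
        seen.add(nid)
        nodes.append(SkeletonNode(nid, pid, np.array([x, y, z], float), r,
                                  SWC_LABELS.get(code, "other")))
    if unit == "nm":
        for n in nodes:
            n.position = convert_nm_to_um(n.position)
            n.radius = float(convert_nm_to_um(n.radius))
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Morphology(nodes, unit="um", meta=meta)


def write_swc(morph: Morphology, path) -> None:
    """Write the node table as SWC (um, with SIZ directive if annotated)."""
    lines = ["# UNITS um"]
    if morph.meta.get("siz_node") is not None:
        lines.append(f"# SIZ {morph.meta['siz_node']}")
    for n in morph.nodes.values():
        code = LABEL_CODES.get(n.label, 6)
        x, y, z = (f"{v:.17g}" for v in n.position)
        lines.append(f"{n.node_id} {code} {x} {y} {z} {n.radius:.17g} {n.parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def summarize(morph: Morphology) -> dict:
    """Section count, mean section length, total length, surface area and
    soma diameter — the standard morphological summary of a skeleton."""
    n_sec = len(morph.sections)
    total = morph.total_length
    return {
        "n_nodes": len(morph.nodes),
        "n_sections": n_sec,
        "mean_section_length_um": total / n_sec if n_sec else 0.0,
        "total_length_um": total,
        "surface_area_um2": morph.surface_area(),
        "soma_diameter_um": morph.soma_diameter,
    }


def append_equivalent_cylinder_axon(morph: Morphology, detailed_area: float,
                                    target_length: float) -> Morphology:
    """Append a single-cylinder axon preserving a detailed axon's membrane area.

    The cylinder has length ``target_length`` and diameter
    ``detailed_area / (pi * target_length)``, attached at the distal-most
    axon-labeled terminal (the axon stump where the detailed reconstruction
    was truncated).  The returned morphology's surface area exceeds the
    input's by exactly ``detailed_area``.
    """
    if detailed_area <= 0 or target_length <= 0:
        raise ValueError("detailed_area and target_length must be positive")
    stumps = [nid for nid, n in morph.nodes.items()
              if n.label == "axon" and not morph.children[nid]]
    if not stumps:
        raise MorphologyError("no axon stump: morphology has no terminal axon node")
    stump = max(stumps, key=lambda nid: (morph.rootdist[nid], nid))
    diameter = detailed_area / (math.pi * target_length)
    snode = morph.nodes[stump]
    parent = morph.nodes[snode.parent_id] if snode.parent_id != -1 else None
    if parent is not None:
        direction = snode.position - parent.position
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    else:
        direction = np.array([1.0, 0.0, 0.0])
    new_id = max(morph.nodes) + 1
    nodes = morph.copy_nodes()
    nodes.append(SkeletonNode(new_id, stump,
                              snode.position + direction * target_length,
                              diameter / 2.0, "axon"))
    meta = dict(morph.meta)
    equiv = dict(meta.get("equiv_cylinder_nodes", {}))
    equiv[new_id] = diameter
    meta["equiv_cylinder_nodes"] = equiv
    return Morphology(nodes, unit=morph.unit, meta=meta)
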