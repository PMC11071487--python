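"""Passive compartmental cable model on a skeleton morphology.

The morphology's sections are discretized into compartments (no segment
longer than ``max_frac`` of the section's DC length constant), axial
conductances are derived from conical-frustum geometry and the axial
resistivity, and the resulting tree-structured linear system is advanced
with an implicit integrator (Crank-Nicolson by default, backward Euler
optionally) using Hines-ordered elimination: one O(N) solve per step.

Unit conventions (specific units as in the experimental literature):
lengths um, Cm uF/cm^2, g_leak S/cm^2, Ra Ohm*cm, voltages mV, time ms,
currents nA, synaptic conductances nS.  Internally the solver works in
mV / ms / nA / uS / nF, which form a consistent set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology, Section

__all__ = [
    "PassiveParams",
    "SynapseKinetics",
    "ElectrodeSpec",
    "CompartmentalModel",
    "CurrentStep",
    "SynapseInstance",
    "Trace",
    "length_constant",
    "discretize",
    "section_axial_resistance",
    "section_membrane_capacitance",
    "biexp_conductance",
    "biexp_peak_time",
    "simulate",
    "attach_electrode",
    "SimulationError",
]

UM2_TO_CM2 = 1e-8
OHM_CM_TO_MOHM_UM = 1e-2  # 1 Ohm*cm = 1e4 Ohm*um = 1e-2 MOhm*um


class SimulationError(RuntimeError):
    """Numerical failure (NaN / instability) during integration."""


@dataclass
class PassiveParams:
    """Uniform passive membrane properties."""

    cm: float = 1.0        # uF/cm^2
    g_leak: float = 3.17e-4  # S/cm^2
    ra: float = 50.0       # Ohm*cm
    e_rev: float = -60.0   # mV

    def __post_init__(self):
        if self.cm <= 0 or self.g_leak <= 0 or self.ra <= 0:
            raise ValueError("cm, g_leak and ra must be positive")


@dataclass
class SynapseKinetics:
    """Bi-exponential conductance synapse (cholinergic defaults)."""

    tau_rise: float = 0.2   # ms
    tau_decay: float = 1.1  # ms
    gmax: float = 0.27      # nS
    e_syn: float = -10.0    # mV

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.gmax <= 0:
            raise ValueError("gmax must be positive")


@dataclass
class ElectrodeSpec:
    """Sharp-electrode model: a passive cylinder in series with the soma.

    Defaults emulate a 30 MOhm access resistance, 2 pF capacitance and an
    8 GOhm seal, distributed over a 10 um x 1 um cylinder.
    """

    length: float = 10.0      # um
    diameter: float = 1.0     # um
    ra: float = 235.6         # Ohm*cm  (total ~30 MOhm)
    g_leak: float = 3.798e-4  # S/cm^2  (seal)
    cm: float = 6.4           # uF/cm^2 (total ~2 pF)
    n_comp: int = 8

    def __post_init__(self):
        if min(self.length, self.diameter, self.ra, self.cm) <= 0:
            raise ValueError("electrode geometry must be positive")


# ---------------------------------------------------------------------------
# closed-form per-section quantities

def length_constant(section_or_diameter, params: PassiveParams) -> float:
    """DC length constant lambda = sqrt(d / (4 Ra g_leak)), in um.

    Accepts a :class:`Section` (uses its mean diameter) or a diameter in um.
    """
    d = (section_or_diameter.mean_diameter
         if isinstance(section_or_diameter, Section) else float(section_or_diameter))
    if d <= 0:
        raise ValueError("zero or negative diameter")
    d_cm = d * 1e-4
    lam_cm = math.sqrt(d_cm / (4.0 * params.ra * params.g_leak))
    return lam_cm * 1e4


def section_axial_resistance(length: float, diameter: float, ra: float) -> float:
    """Axial resistance of a uniform cylinder, in MOhm."""
    if min(length, diameter, ra) <= 0:
        raise ValueError("arguments must be positive")
    r = diameter / 2.0
    return ra * OHM_CM_TO_MOHM_UM * length / (math.pi * r * r)


def section_membrane_capacitance(length: float, diameter: float, cm: float) -> float:
    """Membrane capacitance of a cylinder's lateral area, in pF."""
    if length <= 0 or diameter <= 0 or cm < 0:
        raise ValueError("length and diameter must be positive, cm >= 0")
    area_cm2 = math.pi * diameter * length * UM2_TO_CM2
    return cm * area_cm2 * 1e6  # uF -> pF


def biexp_peak_time(kinetics: SynapseKinetics) -> float:
    """Time to peak of the bi-exponential waveform (ms after onset)."""
    t1, t2 = kinetics.tau_rise, kinetics.tau_decay
    return (t1 * t2) / (t2 - t1) * math.log(t2 / t1)


def biexp_conductance(t, kinetics: SynapseKinetics, onset: float = 0.0):
    """Bi-exponential synaptic conductance g(t) in nS, peak-normalized to gmax.

    g(t) = gmax * f * (exp(-(t-onset)/tau_decay) - exp(-(t-onset)/tau_rise))
    with f chosen so the peak equals gmax; zero before onset.
    """
    t1, t2 = kinetics.tau_rise, kinetics.tau_decay
    tp = biexp_peak_time(kinetics)
    f = 1.0 / (math.exp(-tp / t2) - math.exp(-tp / t1))
    tt = np.asarray(t, dtype=float) - onset
    g = np.where(tt >= 0,
                 kinetics.gmax * f * (np.exp(-np.clip(tt, 0, None) / t2)
                                      - np.exp(-np.clip(tt, 0, None) / t1)),
                 0.0)
    return g if g.shape else float(g)


# ---------------------------------------------------------------------------
# discretization

@dataclass
class _SectionGrid:
    comp_start: int
    nseg: int
    h: float          # segment length, um
    lam: float | None
    attach_comp: int | None = None  # proximal anchor (junction/soma comp)


@dataclass
class SynapseInstance:
    """A conductance synapse coupled to the grid.

    The conductance is split over the (at most two) compartment centers
    flanking the synapse's arc position with linear weights, which keeps
    the transfer impedance to remote probes second-order accurate in the
    segment length.  ``comp`` is the nearest center (used for local
    voltage readout)."""

    synapse_id: int
    comp: int
    kinetics: SynapseKinetics
    comps: tuple[int, ...] = ()
    weights: tuple[float, ...] = ()


@dataclass
class CurrentStep:
    comp: int
    t_on: float
    t_off: float
    amplitude: float  # nA


class CompartmentalModel:
    """Discretized passive electrical model of a morphology.

    Compartment arrays (index ``i``, parent ``parent[i] < i``):
    ``g_axial`` uS to parent, ``g_m`` uS leak, ``c`` nF, ``area`` cm^2.
    """

    def __init__(self, morph: Morphology, params: PassiveParams,
                 max_frac: float = 0.1):
        self.morph = morph
        self.params = params
        self.max_frac = max_frac
        self.parent: list[int] = []
        self.g_axial: list[float] = []
        self.g_m: list[float] = []
        self.c: list[float] = []
        self.area: list[float] = []
        self.comp_label: list[str] = []
        self.grids: dict[int, _SectionGrid] = {}
        self.synapses: list[SynapseInstance] = []
        self.electrode_comps: list[int] | None = None
        self._build()
        self.siz_comp = None
        siz = morph.meta.get("siz_node")
        if siz is not None:
            self.siz_comp = self.comp_at_address(*morph.address_of_node(int(siz)))

    # -- geometry helpers ---------------------------------------------
    def _section_profile(self, sec: Section):
        """Arc positions and effective radii along a section polyline."""
        m = self.morph
        arc = m.section_arc(sec.section_id)
        radii = np.array([m.nodes[n].radius for n in sec.node_ids], float)
        labels = [m.nodes[n].label for n in sec.node_ids]
        if sec.uniform_diameter is not None:
            radii[:] = sec.uniform_diameter / 2.0
        elif labels[0] == "soma" and len(radii) > 1:
            # the attachment edge into a soma sphere is treated as a
            # cylinder of the child's caliber, not a giant frustum
            radii[0] = radii[1]
        return arc, radii

    def _partial(self, arc, radii, a, b):
        """(lateral area um^2, axial resistance MOhm) of the stretch [a, b]."""
        area = 0.0
        res = 0.0
        ra = self.params.ra
        for i in range(len(arc) - 1):
            lo, hi = arc[i], arc[i + 1]
            L = hi - lo
            if L <= 0 or hi <= a or lo >= b:
                continue
            s0, s1 = max(lo, a), min(hi, b)
            t0, t1 = (s0 - lo) / L, (s1 - lo) / L
            r0 = radii[i] + (radii[i + 1] - radii[i]) * t0
            r1 = radii[i] + (radii[i + 1] - radii[i]) * t1
            slant_per = math.hypot(L, radii[i + 1] - radii[i]) / L
            area += math.pi * (r0 + r1) * (s1 - s0) * slant_per
            res += ra * OHM_CM_TO_MOHM_UM * (s1 - s0) / (math.pi * r0 * r1)
        return area, res

    # -- construction --------------------------------------------------
    def _add_comp(self, parent: int, g_att: float, area_cm2: float,
                  label: str, gm=None, c=None, p=None) -> int:
        idx = len(self.parent)
        self.parent.append(parent)
        self.g_axial.append(g_att)
        self.area.append(area_cm2)
        p = p or self.params
        self.g_m.append(p.g_leak * area_cm2 * 1e6 if gm is None else gm)
        self.c.append(p.cm * area_cm2 * 1e3 if c is None else c)
        self.comp_label.append(label)
        return idx

    def _attach_point(self, sec: Section) -> tuple[int, bool]:
        """Compartment index a child section's first compartment hooks to.

        For isopotential (soma / zero-length) parents this is the parent
        compartment itself; otherwise a zero-area junction node is placed
        at the shared branch vertex (created once, reused by siblings) so
        that branch points keep their exact star topology."""
        psec = self.morph.sections[sec.parent_section]
        g = self.grids[psec.section_id]
        if psec.label == "soma" or psec.length == 0:
            return g.comp_start, True
        vertex = sec.node_ids[0]
        if vertex in self.vertex_comp:
            return self.vertex_comp[vertex], False
        arc, radii = self._section_profile(psec)
        _, r_half = self._partial(arc, radii, psec.length - 0.5 * g.h,
                                  psec.length)
        idx = self._add_comp(g.comp_start + g.nseg - 1, 1.0 / max(r_half, 1e-12),
                             0.0, "junction")
        self.vertex_comp[vertex] = idx
        return idx, False

    def _build(self):
        m, p = self.morph, self.params
        self.vertex_comp: dict[int, int] = {}
        order = sorted(range(len(m.sections)),
                       key=lambda s: self._sec_depth(s))
        for sid in order:
            sec = m.sections[sid]
            if sec.label == "soma" or sec.length == 0:
                sphere = sum(4.0 * math.pi * m.nodes[n].radius ** 2
                             for n in sec.owned_ids
                             if m.nodes[n].label == "soma")
                area_cm2 = sphere * UM2_TO_CM2
                if sec.parent_section is None:
                    parent, g_att = -1, 0.0
                else:
                    attach, _ = self._attach_point(sec)
                    parent, g_att = attach, 1.0 / 1e-9  # fused to the vertex
                idx = self._add_comp(parent, g_att, area_cm2, sec.label)
                self.grids[sid] = _SectionGrid(idx, 1, sec.length, None,
                                               attach_comp=parent if parent >= 0
                                               else None)
                continue
            lam = length_constant(sec, p)
            sec.length_constant = lam
            nseg = max(1, math.ceil(sec.length / (self.max_frac * lam)))
            h = sec.length / nseg
            arc, radii = self._section_profile(sec)
            start = None
            attach_comp = None
            for j in range(nseg):
                a_um2, _ = self._partial(arc, radii, j * h, (j + 1) * h)
                if j == 0:
                    _, r_half = self._partial(arc, radii, 0.0, 0.5 * h)
                    if sec.parent_section is None:
                        parent, g_att = -1, 0.0
                    else:
                        parent, _direct = self._attach_point(sec)
                        attach_comp = parent
                        g_att = 1.0 / max(r_half, 1e-12)
                else:
                    parent = len(self.parent) - 1
                    _, r_link = self._partial(arc, radii, (j - 0.5) * h,
                                              (j + 0.5) * h)
                    g_att = 1.0 / r_link
                idx = self._add_comp(parent, g_att, a_um2 * UM2_TO_CM2,
                                     sec.label)
                if j == 0:
                    start = idx
            self.grids[sid] = _SectionGrid(start, nseg, h, lam,
                                           attach_comp=attach_comp)
        self._freeze()

    def _freeze(self):
        self.parent_arr = np.asarray(self.parent, dtype=np.int64)
        self.g_axial_arr = np.asarray(self.g_axial, dtype=np.float64)
        self.g_m_arr = np.asarray(self.g_m, dtype=np.float64)
        self.c_arr = np.asarray(self.c, dtype=np.float64)

    def _sec_depth(self, sid: int) -> int:
        d = 0
        sec = self.morph.sections[sid]
        while sec.parent_section is not None:
            sec = self.morph.sections[sec.parent_section]
            d += 1
        return d

    # -- addressing -----------------------------------------------------
    @property
    def n_comp(self) -> int:
        return len(self.parent)

    def comp_at_address(self, section_id: int, offset: float) -> int:
        g = self.grids[section_id]
        if g.nseg == 1 or g.h == 0:
            return g.comp_start
        j = min(g.nseg - 1, max(0, int(offset / g.h)))
        return g.comp_start + j

    def soma_comp(self) -> int:
        for sid, g in self.grids.items():
            if self.morph.sections[sid].label == "soma":
                return g.comp_start
        raise ValueError("no soma section in morphology")

    def max_seg_frac(self, params: PassiveParams | None = None) -> float:
        """max over sections of (segment length / lambda); <= max_frac by
        construction."""
        p = params or self.params
        worst = 0.0
        for sid, g in self.grids.items():
            sec = self.morph.sections[sid]
            if sec.label == "soma" or sec.length == 0:
                continue
            worst = max(worst, g.h / length_constant(sec, p))
        return worst

    # -- elements -------------------------------------------------------
    def add_synapse(self, synapse_id: int, address: tuple[int, float],
                    kinetics: SynapseKinetics) -> int:
        section_id, offset = address
        comp = self.comp_at_address(section_id, offset)
        g = self.grids[section_id]
        sec = self.morph.sections[section_id]
        # interpolation anchors: proximal junction/soma, segment centers,
        # distal junction (exists when the section has children)
        anchors: list[tuple[float, int]] = []
        if g.attach_comp is not None:
            anchors.append((0.0, g.attach_comp))
        if g.h > 0:
            anchors.extend(((j + 0.5) * g.h, g.comp_start + j)
                           for j in range(g.nseg))
        else:
            anchors.append((0.0, g.comp_start))
        distal = self.vertex_comp.get(sec.node_ids[-1])
        if distal is not None:
            anchors.append((sec.length, distal))
        pos = [a[0] for a in anchors]
        i = int(np.searchsorted(pos, offset, side="right")) - 1
        if i < 0:
            comps, weights = (anchors[0][1],), (1.0,)
        elif i >= len(anchors) - 1:
            comps, weights = (anchors[-1][1],), (1.0,)
        else:
            span = pos[i + 1] - pos[i]
            w = (offset - pos[i]) / span if span > 0 else 0.0
            comps = (anchors[i][1], anchors[i + 1][1])
            weights = (1.0 - w, w)
        self.synapses.append(SynapseInstance(synapse_id, comp, kinetics,
                                             comps, weights))
        return len(self.synapses) - 1

    def add_synapses_from_map(self, smap, kinetics: SynapseKinetics) -> None:
        smap.require_mapped()
        for r in smap.records:
            self.add_synapse(r.synapse_id, r.mapped_address, kinetics)

    def synapse_index(self) -> dict[int, int]:
        return {s.synapse_id: i for i, s in enumerate(self.synapses)}


def discretize(morph: Morphology, params: PassiveParams,
               max_frac: float = 0.1) -> CompartmentalModel:
    """Build a compartmental model with no segment longer than
    ``max_frac`` of its section's length constant."""
    return CompartmentalModel(morph, params, max_frac=max_frac)


def attach_electrode(model: CompartmentalModel,
                     spec: ElectrodeSpec | None = None) -> CompartmentalModel:
    """Append an electrode cylinder in series at the soma.

    The electrode is split into ``spec.n_comp`` compartments plus a
    zero-area terminal node at the free end, where current is injected and
    voltage recorded; the full access resistance therefore lies between
    soma and recording point.  Modifies and returns the model.
    """
    if model.electrode_comps is not None:
        raise ValueError("electrode already attached")
    spec = spec or ElectrodeSpec()
    soma = model.soma_comp()
    n = spec.n_comp
    h = spec.length / n
    a_seg = math.pi * spec.diameter * h * UM2_TO_CM2  # cm^2
    r_seg = section_axial_resistance(h, spec.diameter, spec.ra)  # MOhm
    comps = []
    prev = soma
    for j in range(n):
        idx = model.n_comp
        # first link: soma (isopotential) to first center = half segment
        r_link = r_seg / 2.0 if j == 0 else r_seg
        model.parent.append(prev)
        model.g_axial.append(1.0 / r_link)
        model.area.append(a_seg)
        model.g_m.append(spec.g_leak * a_seg * 1e6)
        model.c.append(spec.cm * a_seg * 1e3)
        model.comp_label.append("electrode")
        comps.append(idx)
        prev = idx
    # zero-area free-end node
    idx = model.n_comp
    model.parent.append(prev)
    model.g_axial.append(1.0 / (r_seg / 2.0))
    model.area.append(0.0)
    model.g_m.append(0.0)
    model.c.append(0.0)
    model.comp_label.append("electrode_tip")
    comps.append(idx)
    model.electrode_comps = comps
    model._freeze()
    return model


# ---------------------------------------------------------------------------
# integration

@dataclass
class Trace:
    """Simulation output: uniform time grid (ms) and per-compartment
    voltages (mV)."""

    time: np.ndarray            # (nsteps+1,)
    voltage: np.ndarray         # (nsteps+1, n_comp)
    stimulus: list = field(default_factory=list)

    def v(self, comp: int) -> np.ndarray:
        return self.voltage[:, comp]

    def peak_depolarization(self, comp: int, baseline: float) -> float:
        """Peak of (V - baseline) with parabolic refinement of the sampled
        maximum (reduces grid-sampling bias in convergence comparisons)."""
        v = self.voltage[:, comp] - baseline
        k = int(np.argmax(v))
        if 0 < k < len(v) - 1:
            y0, y1, y2 = v[k - 1], v[k], v[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                return float(y1 - (y2 - y0) ** 2 / (8 * denom))
        return float(v[k])



def _kernel_impl(parent, a, gm, c, e_rev, syn_comp, Gs, GEs, stim_comp, I,
                 v0, n_steps, dt_eff, cn):
    """Hines-ordered implicit stepper (numba-jitted when available)."""
    n = parent.shape[0]
    V = np.empty((n_steps + 1, n))
    for i in range(n):
        V[0, i] = v0[i]
    cdt = np.empty(n)
    d_base = np.empty(n)
    for i in range(n):
        cdt[i] = c[i] / dt_eff
        d_base[i] = cdt[i] + gm[i] + a[i]
    for i in range(1, n):
        d_base[parent[i]] += a[i]
    d = np.empty(n)
    b = np.empty(n)
    v = np.empty(n)
    for step in range(n_steps):
        for i in range(n):
            d[i] = d_base[i]
            b[i] = cdt[i] * V[step, i] + gm[i] * e_rev
        for k in range(syn_comp.shape[0]):
            d[syn_comp[k]] += Gs[k, step]
            b[syn_comp[k]] += GEs[k, step]
        for k in range(stim_comp.shape[0]):
            b[stim_comp[k]] += I[k, step]
        for i in range(n - 1, 0, -1):
            f = a[i] / d[i]
            d[parent[i]] -= f * a[i]
            b[parent[i]] += f * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + a[i] * v[parent[i]]) / d[i]
        if cn:
            for i in range(n):
                V[step + 1, i] = 2.0 * v[i] - V[step, i]
        else:
            for i in range(n):
                V[step + 1, i] = v[i]
    return V


try:
    from numba import njit as _njit
    _KERNEL = _njit(cache=True)(_kernel_impl)
except Exception:  # pragma: no cover - numba is normally present
    _KERNEL = _kernel_impl


def simulate(model: CompartmentalModel, duration: float = 50.0,
             dt: float = 0.025, stimuli: list[CurrentStep] | None = None,
             active_synapse_ids: list[int] | None = None,
             onset_times=None, method: str = "cn",
             v_init: float | None = None) -> Trace:
    """Integrate the passive model and return voltages at all compartments.

    ``active_synapse_ids`` selects synapse instances by their synapse_id;
    ``onset_times`` is a scalar or per-synapse list of event times (ms).
    With no stimulus the model rests exactly at ``e_rev``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("cn", "backward_euler"):
        raise ValueError(f"unknown method {method!r}")
    cn = method == "cn"
    n_steps = int(round(duration / dt))
    p = model.params
    v0 = np.full(model.n_comp, p.e_rev if v_init is None else v_init)

    # synaptic conductance time courses, grouped by compartment
    active: list[tuple[SynapseInstance, float]] = []
    if active_synapse_ids:
        idx = model.synapse_index()
        if onset_times is None:
            onset_times = 1.0
        if np.isscalar(onset_times):
            onset_times = [float(onset_times)] * len(active_synapse_ids)
        for sid, t0 in zip(active_synapse_ids, onset_times):
            if sid not in idx:
                raise KeyError(f"no synapse instance with id {sid}")
            active.append((model.synapses[idx[sid]], float(t0)))

    # evaluation times: t_{n+1} for BE, interval midpoints for CN
    t_eval = (np.arange(n_steps) + (0.5 if cn else 1.0)) * dt
    comp_groups: dict[int, list[tuple[SynapseInstance, float, float]]] = {}
    for inst, t0 in active:
        comps = inst.comps or (inst.comp,)
        weights = inst.weights or (1.0,)
        for comp, w in zip(comps, weights):
            if w > 0:
                comp_groups.setdefault(comp, []).append((inst, t0, w))
    syn_comp = np.array(sorted(comp_groups), dtype=np.int64)
    Gs = np.zeros((len(syn_comp), n_steps))
    GEs = np.zeros((len(syn_comp), n_steps))
    for k, comp in enumerate(syn_comp):
        for inst, t0, w in comp_groups[comp]:
            g_us = w * biexp_conductance(t_eval, inst.kinetics, onset=t0) * 1e-3
            Gs[k] += g_us
            GEs[k] += g_us * inst.kinetics.e_syn
    stimuli = stimuli or []
    stim_comp = np.array([s.comp for s in stimuli], dtype=np.int64)
    I = np.zeros((len(stimuli), n_steps))
    for k, s in enumerate(stimuli):
        I[k] = np.where((t_eval >= s.t_on) & (t_eval < s.t_off), s.amplitude, 0.0)

    dt_eff = dt / 2.0 if cn else dt
    V = _KERNEL(model.parent_arr, model.g_axial_arr, model.g_m_arr,
                model.c_arr, p.e_rev, syn_comp, Gs, GEs, stim_comp, I,
                v0, n_steps, dt_eff, cn)
    if not np.all(np.isfinite(V)):
        raise SimulationError(
            "non-finite voltage encountered; check dt and parameters")
    time = np.arange(n_steps + 1) * dt
    return Trace(time=time, voltage=V,
                 stimulus=[(s.comp, s.t_on, s.t_off, s.amplitude) for s in stimuli])
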