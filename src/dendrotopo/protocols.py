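"""Simulation experiments over a compartmental model and mapped synapses.

The protocols mirror the standard questions asked of a passive model with
EM-mapped synapses:

* ``democracy_scan`` — activate each synapse alone; does the dendrite
  normalize single-synapse EPSP amplitudes at the spike initiation zone?
* ``activate_neuron`` / ``random_set_curve`` — co-activate synapse sets of
  growing size; how quickly does shunting make summation sublinear?
* ``clustered_vs_random_experiment`` — compare composite EPSPs of
  path-clustered ("close") versus dispersed ("random") synapse sets and
  real single-neuron sets.
* ``fit_passive`` — bounded least-squares fit of the passive parameters to
  an averaged small-current-clamp trace recorded through a model electrode.

Every protocol is deterministic given its seed and settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import dunn_bonferroni
from .cable import (CompartmentalModel, CurrentStep, ElectrodeSpec,
                    PassiveParams, SynapseKinetics, attach_electrode,
                    discretize, simulate)
from .morphology import Morphology, path_distance
from .synapses import SynapseMap

__all__ = [
    "DemocracyScan",
    "ActivationResult",
    "FitResult",
    "CurrentClampProtocol",
    "run_current_clamp",
    "build_model",
    "democracy_scan",
    "activate_neuron",
    "random_set_curve",
    "clustered_vs_random_experiment",
    "ClusterExperimentResult",
    "fit_passive",
]

DEFAULT_ONSET = 1.0  # ms


def build_model(morph: Morphology, params: PassiveParams, smap: SynapseMap,
                kinetics: SynapseKinetics | None = None,
                max_frac: float = 0.1) -> CompartmentalModel:
    """Discretize a morphology and instantiate every mapped synapse."""
    model = discretize(morph, params, max_frac=max_frac)
    model.add_synapses_from_map(smap, kinetics or SynapseKinetics())
    return model


def _siz(model: CompartmentalModel) -> int:
    if model.siz_comp is None:
        raise ValueError("model has no SIZ probe (no siz_node annotation)")
    return model.siz_comp


def _siz_address(model: CompartmentalModel):
    siz = int(model.morph.meta["siz_node"])
    return model.morph.address_of_node(siz)


def _composite_peak(model, synapse_ids, duration, dt, onset=DEFAULT_ONSET):
    tr = simulate(model, duration=duration, dt=dt,
                  active_synapse_ids=list(synapse_ids), onset_times=onset)
    return tr.peak_depolarization(_siz(model), model.params.e_rev), tr


# ---------------------------------------------------------------------------
# single-synapse normalization ("synaptic democracy")

@dataclass
class DemocracyScan:
    """Per-synapse local and SIZ EPSP peaks with distance to the SIZ."""

    table: pd.DataFrame  # synapse_id, pre_id, local_peak_mv, siz_peak_mv,
    #                      dist_to_siz_um


def democracy_scan(model: CompartmentalModel, smap: SynapseMap,
                   duration: float = 50.0, dt: float = 0.025) -> DemocracyScan:
    """Activate each mapped synapse individually with identical kinetics."""
    smap.require_mapped()
    siz_addr = _siz_address(model)
    rows = []
    for r in smap.records:
        tr = simulate(model, duration=duration, dt=dt,
                      active_synapse_ids=[r.synapse_id],
                      onset_times=DEFAULT_ONSET)
        comp = model.comp_at_address(*r.mapped_address)
        rows.append({
            "synapse_id": r.synapse_id,
            "pre_id": r.pre_neuron_id,
            "local_peak_mv": tr.peak_depolarization(comp, model.params.e_rev),
            "siz_peak_mv": tr.peak_depolarization(_siz(model),
                                                  model.params.e_rev),
            "dist_to_siz_um": path_distance(model.morph, r.mapped_address,
                                            siz_addr),
        })
    return DemocracyScan(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# co-activation

@dataclass
class ActivationResult:
    descriptor: object          # neuron id or (count, rep, seed)
    n_synapses: int
    composite_peak_mv: float
    linearity_index: float      # composite / sum of individual peaks
    mean_dist_to_siz_um: float | None = None


def _individual_peaks(model: CompartmentalModel, smap: SynapseMap,
                      duration: float, dt: float) -> dict[int, float]:
    scan = democracy_scan(model, smap, duration=duration, dt=dt)
    return dict(zip(scan.table["synapse_id"], scan.table["siz_peak_mv"]))


def activate_neuron(model: CompartmentalModel, smap: SynapseMap,
                    pre_neuron_id: int, duration: float = 50.0,
                    dt: float = 0.025,
                    individual_peaks: dict[int, float] | None = None
                    ) -> ActivationResult:
    """Co-activate all synapses of one presynaptic neuron at a single onset."""
    groups = smap.by_neuron()
    if pre_neuron_id not in groups:
        raise KeyError(f"neuron {pre_neuron_id} not in synapse map")
    recs = groups[pre_neuron_id]
    ids = [r.synapse_id for r in recs]
    peak, _ = _composite_peak(model, ids, duration, dt)
    if individual_peaks is None:
        sub = SynapseMap(recs, smap.morphology)
        individual_peaks = _individual_peaks(model, sub, duration, dt)
    total = sum(individual_peaks[i] for i in ids)
    siz_addr = _siz_address(model)
    mean_d = float(np.mean([path_distance(model.morph, r.mapped_address,
                                          siz_addr) for r in recs]))
    return ActivationResult(pre_neuron_id, len(ids), peak,
                            peak / total if total > 0 else float("nan"),
                            mean_d)


def random_set_curve(model: CompartmentalModel, smap: SynapseMap,
                     counts, n_reps: int = 5, seed: int = 0,
                     duration: float = 50.0, dt: float = 0.025
                     ) -> list[ActivationResult]:
    """Composite EPSP versus number of co-activated, randomly drawn synapses.

    For each count, ``n_reps`` seeded draws without replacement (a single
    deterministic set when the count equals the population size).
    """
    smap.require_mapped()
    all_ids = [r.synapse_id for r in smap.records]
    pop = len(all_ids)
    indiv = _individual_peaks(model, smap, duration, dt)
    out = []
    for count in counts:
        if not 1 <= count <= pop:
            raise ValueError(f"count {count} outside [1, {pop}]")
        reps = 1 if count == pop else n_reps
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(count), rep]))
            ids = (list(all_ids) if count == pop
                   else list(rng.choice(all_ids, size=count, replace=False)))
            peak, _ = _composite_peak(model, ids, duration, dt)
            total = sum(indiv[i] for i in ids)
            out.append(ActivationResult((int(count), rep, int(seed)), count,
                                        peak, peak / total))
    return out


# ---------------------------------------------------------------------------
# close vs random vs single-neuron sets

@dataclass
class ClusterExperimentResult:
    table: pd.DataFrame     # group, set_id, n, composite_peak_mv, mean_dist
    levene_stat: float      # close vs random composite-peak variance
    levene_p: float
    kruskal_stat: float
    kruskal_p: float
    dunn_p: dict            # pairwise Bonferroni-adjusted p-values
    warnings: list[str] = field(default_factory=list)


def clustered_vs_random_experiment(model: CompartmentalModel, smap: SynapseMap,
                                   n_synapses: int = 15, n_sets: int = 50,
                                   seed: int = 0, duration: float = 50.0,
                                   dt: float = 0.025,
                                   neighbor_metric: str = "path",
                                   single_tolerance: int = 0
                                   ) -> ClusterExperimentResult:
    """Composite EPSPs of close, random, and single-neuron synapse sets.

    *Close* sets take a random anchor synapse and its n-1 nearest neighbors
    (path distance along the arbor by default); *random* sets draw n
    synapses uniformly; the *single* group co-activates every neuron whose
    synapse count equals ``n_synapses`` (within ``single_tolerance``).
    Variance of the composite peaks is compared close-vs-random with
    Levene's test; groups are compared with Kruskal-Wallis followed by
    Dunn's post-hoc test with Bonferroni adjustment.
    """
    if n_synapses < 2:
        raise ValueError("n_synapses must be >= 2")
    smap.require_mapped()
    from .topography import pairwise_distances
    recs = smap.records
    ids = np.array([r.synapse_id for r in recs])
    D = pairwise_distances(smap, metric=neighbor_metric)
    siz_addr = _siz_address(model)
    dist_to_siz = {r.synapse_id: path_distance(model.morph, r.mapped_address,
                                               siz_addr) for r in recs}

    rows = []

    def run_set(group, set_id, chosen_ids):
        peak, _ = _composite_peak(model, chosen_ids, duration, dt)
        rows.append({
            "group": group, "set_id": set_id, "n": len(chosen_ids),
            "composite_peak_mv": peak,
            "mean_dist_to_siz_um": float(np.mean([dist_to_siz[i]
                                                  for i in chosen_ids])),
        })

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    for k in range(n_sets):
        chosen = rng.choice(ids, size=n_synapses, replace=False)
        run_set("random", k, [int(i) for i in chosen])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    for k in range(n_sets):
        anchor = int(rng.integers(len(ids)))
        order = np.argsort(D[anchor], kind="stable")
        chosen = [int(ids[j]) for j in order[:n_synapses]]  # anchor is own 0-NN
        run_set("close", k, chosen)

    warnings = []
    singles = [nid for nid, g in smap.by_neuron().items()
               if abs(len(g) - n_synapses) <= single_tolerance]
    if singles:
        for k, nid in enumerate(sorted(singles)):
            g = smap.by_neuron()[nid]
            run_set("single", k, [r.synapse_id for r in g])
    else:
        warnings.append(f"no neuron with {n_synapses} synapses; "
                        "single group omitted")

    df = pd.DataFrame(rows)
    close = df.loc[df.group == "close", "composite_peak_mv"].to_numpy()
    rand = df.loc[df.group == "random", "composite_peak_mv"].to_numpy()
    if min(close.size, rand.size) >= 2:
        lev = stats.levene(close, rand)
    else:
        lev = type("L", (), {"statistic": float("nan"),
                             "pvalue": float("nan")})()
    groups = {g: df.loc[df.group == g, "composite_peak_mv"].to_numpy()
              for g in df.group.unique()}
    if len(groups) >= 2:
        kw = stats.kruskal(*groups.values())
        dunn = dunn_bonferroni(groups)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    else:  # pragma: no cover - needs both close and random, always present
        kw_stat = kw_p = float("nan")
        dunn = {}
    return ClusterExperimentResult(df, float(lev.statistic), float(lev.pvalue),
                                   kw_stat, kw_p, dunn, warnings)


# ---------------------------------------------------------------------------
# passive-parameter fitting

@dataclass
class CurrentClampProtocol:
    """Small current injection through a somatic electrode.

    Defaults emulate a brief hyperpolarizing test pulse; the recording and
    injection site is the electrode free end (``record="electrode"``), or
    the soma itself (``record="soma"``).  The default amplitude follows the
    experimental convention of using the largest pulse that keeps the
    response passive (below ~2 mV deviation): -10 pA deflects the toy DN
    by ~1.8 mV.
    """

    amplitude_na: float = -0.010   # -10 pA
    t_on: float = 10.0             # ms
    t_off: float = 60.0
    duration: float = 100.0
    dt: float = 0.025
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    record: str = "electrode"
    max_frac: float = 0.1


def run_current_clamp(morph: Morphology, params: PassiveParams,
                      protocol: CurrentClampProtocol):
    """Simulate the current-clamp protocol; returns (time_ms, voltage_mV)."""
    model = discretize(morph, params, max_frac=protocol.max_frac)
    if protocol.electrode is not None:
        attach_electrode(model, protocol.electrode)
        site = (model.electrode_comps[-1] if protocol.record == "electrode"
                else model.soma_comp())
        inj = model.electrode_comps[-1]
    else:
        site = inj = model.soma_comp()
    tr = simulate(model, duration=protocol.duration, dt=protocol.dt,
                  stimuli=[CurrentStep(inj, protocol.t_on, protocol.t_off,
                                       protocol.amplitude_na)])
    return tr.time, tr.v(site)


DEFAULT_BOUNDS = {
    "cm": (0.6, 2.6),          # uF/cm^2, plausible experimental range
    "g_leak": (5e-5, 2e-3),    # S/cm^2
    "ra": (30.0, 400.0),       # Ohm*cm
    "e_rev": (-80.0, -40.0),   # mV
}

PARAM_ORDER = ("cm", "g_leak", "ra", "e_rev")


@dataclass
class FitResult:
    params: PassiveParams
    final_error: float            # summed squared residual, mV^2
    bound_hit: dict[str, bool]
    n_evaluations: int
    protocol: CurrentClampProtocol
    converged: bool = True


def _sse(morph, protocol, target_t, target_v, window):
    t_ref = None

    def objective(x):
        p = PassiveParams(cm=x[0], g_leak=x[1], ra=x[2], e_rev=x[3])
        t, v = run_current_clamp(morph, p, protocol)
        tv = np.interp(t, target_t, target_v)
        if window is not None:
            mask = (t >= window[0]) & (t <= window[1])
            return float(np.sum((v[mask] - tv[mask]) ** 2))
        return float(np.sum((v - tv) ** 2))

    return objective


def fit_passive(morph: Morphology, target_trace, protocol=None,
                bounds: dict | None = None, window=None,
                optimizer_settings: dict | None = None) -> FitResult:
    """Fit (Cm, g_leak, Ra, E_rev) to an averaged current-clamp trace.

    ``target_trace`` is ``(time_ms, voltage_mV)`` arrays or an Nx2 array;
    it is resampled onto the simulation grid.  The objective is the summed
    squared voltage residual over the full trace (or ``window=(t0, t1)``).
    Minimization is deterministic: bounded L-BFGS-B restarted from a fixed
    grid of 8 interior lattice points (corners of the inner half-box over
    Cm, g_leak, E_rev, with Ra at its midpoint) plus the box center.
    """
    protocol = protocol or CurrentClampProtocol()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    settings = {"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10}
    settings.update(optimizer_settings or {})
    if isinstance(target_trace, tuple):
        target_t, target_v = (np.asarray(a, float) for a in target_trace)
    else:
        arr = np.asarray(target_trace, float)
        target_t, target_v = arr[:, 0], arr[:, 1]

    lo = np.array([bounds[k][0] for k in PARAM_ORDER])
    hi = np.array([bounds[k][1] for k in PARAM_ORDER])
    objective = _sse(morph, protocol, target_t, target_v, window)
    n_evals = 0

    def counted(x):
        nonlocal n_evals
        n_evals += 1
        return objective(lo + x * (hi - lo))

    if np.all(hi == lo):  # collapsed box: evaluate the point
        p = PassiveParams(*lo)
        return FitResult(p, objective(lo), {k: True for k in PARAM_ORDER},
                         1, protocol)

    span = hi - lo
    center = np.full(4, 0.5)
    starts = [center]
    for a in (0.25, 0.75):
        for b in (0.25, 0.75):
            for c in (0.25, 0.75):
                starts.append(np.array([a, b, 0.5, c]))  # cm, g_leak, ra, e_rev

    best_x, best_f = None, np.inf
    converged = False
    for x0 in starts:
        x0 = np.where(span > 0, x0, 0.0)
        res = optimize.minimize(counted, x0, method="L-BFGS-B",
                                bounds=[(0.0, 1.0)] * 4,
                                options=settings)
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
            converged = bool(res.success)
    x = lo + best_x * span
    p = PassiveParams(cm=x[0], g_leak=x[1], ra=x[2], e_rev=x[3])
    eps = 1e-6
    hit = {k: bool(best_x[i] < eps or best_x[i] > 1 - eps)
           for i, k in enumerate(PARAM_ORDER) if span[i] > 0}
    hit.update({k: True for i, k in enumerate(PARAM_ORDER) if span[i] == 0})
    return FitResult(p, best_f, hit, n_evals, protocol, converged=converged)
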