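"""Steady-state chain (multi-node) model of dendrite, soma and inhibition.

The canonical configuration is the two-compartment circuit: a dendritic node
carrying the NMDA conductance, a leak ``g_dL`` and an optional shunting
conductance ``g_dI``, coupled through an axial conductance ``g_a`` to a
somatic node with leak ``g_sL`` and optional shunt ``g_sI``. The module
generalizes this to an N-node passive chain so that on-path inhibition
placements can be probed in the same steady-state framework.

Because every element except the NMDA conductance is ohmic, the network seen
from the NMDA node collapses to a Thevenin equivalent (one conductance, one
effective reversal), reducing the chain to the single-compartment problem of
:mod:`nmdashunt.nmda`; voltages at the remaining nodes then follow from the
passive divider relations. Two scalar summaries drive the whole analysis:

* the input (total leak) conductance at a node - everything the NMDA current
  must overcome, so the spike threshold scales with it; and
* the dendrite-to-soma attenuation factor - the ratio of steady
  depolarizations, which divides the spike height seen at the soma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nmda
from .nmda import NMDAParams, SingleCompartment, SpikeMetrics

__all__ = [
    "ChainNode",
    "ChainModel",
    "TheveninEquivalent",
    "ChainSolution",
    "InhibitionConfig",
    "two_compartment",
    "thevenin",
    "input_conductance",
    "attenuation",
    "solve_chain",
    "chain_spike_threshold",
    "io_curve_sweep",
    "effect_scatter",
    "reversal_sweep",
]


@dataclass(frozen=True)
class ChainNode:
    """Passive elements at one node of the chain (nS, mV)."""

    g_leak: float
    g_inh: float = 0.0
    e_leak: float = -70.0
    e_inh: float = -70.0

    def __post_init__(self) -> None:
        if self.g_leak <= 0:
            raise ValueError("g_leak must be positive")
        if self.g_inh < 0:
            raise ValueError("g_inh must be non-negative")


@dataclass(frozen=True)
class ChainModel:
    """An ordered chain of passive nodes with one NMDA node.

    ``axial[i]`` couples ``nodes[i]`` and ``nodes[i+1]``. The NMDA conductance
    sits at ``nodes[nmda_node]``; the output voltage is read at
    ``nodes[record_node]`` (the soma in the canonical two-node case).
    """

    nodes: tuple[ChainNode, ...]
    axial: tuple[float, ...]
    nmda_node: int = 0
    record_node: int = -1

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        axial = tuple(float(a) for a in self.axial)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "axial", axial)
        if len(nodes) < 2:
            raise ValueError("a chain needs at least two nodes")
        if len(axial) != len(nodes) - 1:
            raise ValueError("need len(axial) == len(nodes) - 1")
        if any(a <= 0 for a in axial):
            raise ValueError("axial conductances must be positive")
        n = len(nodes)
        object.__setattr__(self, "nmda_node", range(n)[self.nmda_node])
        object.__setattr__(self, "record_node", range(n)[self.record_node])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def with_inhibition(self, node: int, g_inh: float, e_inh: float | None = None) -> "ChainModel":
        """Copy of the model with the shunt at ``node`` replaced."""
        nodes = list(self.nodes)
        kwargs = {"g_inh": g_inh}
        if e_inh is not None:
            kwargs["e_inh"] = e_inh
        nodes[node] = replace(nodes[node], **kwargs)
        return replace(self, nodes=tuple(nodes))

    def resting_potentials(self) -> np.ndarray:
        """Node voltages with no excitation (mV), from the linear network."""
        g, b = _linear_system(self)
        return np.linalg.solve(g, b)


@dataclass(frozen=True)
class TheveninEquivalent:
    """Effective conductance and reversal seen at a node (nS, mV)."""

    g_total: float
    e_eff: float


@dataclass(frozen=True)
class ChainSolution:
    """Steady-state voltages for one excitation level."""

    v_dend: float
    v_soma: float
    n_syn: float
    voltages: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class InhibitionConfig:
    """One inhibition condition for an effect sweep."""

    location: str  # "dendritic" or "somatic" (or a node index as str)
    g_inh: float
    e_inh: float = -70.0
    config_id: str = ""

    def node_index(self, model: ChainModel) -> int:
        if self.location == "dendritic":
            return model.nmda_node
        if self.location == "somatic":
            return model.record_node
        return int(self.location)


def two_compartment(
    g_dL: float = 1.0,
    g_dI: float = 0.0,
    g_a: float = 4.0,
    g_sL: float = 6.0,
    g_sI: float = 0.0,
    e_leak: float = -70.0,
    e_inh: float = -70.0,
) -> ChainModel:
    """Canonical dendrite + soma circuit (defaults: the worked example set)."""
    dend = ChainNode(g_leak=g_dL, g_inh=g_dI, e_leak=e_leak, e_inh=e_inh)
    soma = ChainNode(g_leak=g_sL, g_inh=g_sI, e_leak=e_leak, e_inh=e_inh)
    return ChainModel(nodes=(dend, soma), axial=(g_a,), nmda_node=0, record_node=1)


def _node_parallel(node: ChainNode, g_beyond: float, ge_beyond: float) -> tuple[float, float]:
    """Collapse a node's own elements with the already-reduced far side."""
    g = node.g_leak + node.g_inh + g_beyond
    ge = node.g_leak * node.e_leak + node.g_inh * node.e_inh + ge_beyond
    return g, ge


def _reduce_toward(model: ChainModel, target: int, direction: int) -> tuple[float, float]:
    """Thevenin (g, g*E) of the half-chain on one side of ``target``.

    ``direction`` is +1 for the nodes above ``target``, -1 for those below.
    Working from the far end, each node's elements are combined in parallel
    with the already-collapsed tail, then pushed through the axial conductance
    toward the target (series combination leaves the reversal unchanged).
    """
    if direction > 0:
        order = range(model.n_nodes - 1, target, -1)  # far end first
    else:
        order = range(0, target)  # node 0 is the far end on this side
    g_acc, ge_acc = 0.0, 0.0
    for j in order:
        g_par, ge_par = _node_parallel(model.nodes[j], g_acc, ge_acc)
        # axial conductance between node j and its neighbor toward the target
        ax = model.axial[j - 1] if direction > 0 else model.axial[j]
        g_ser = ax * g_par / (ax + g_par)
        e_par = ge_par / g_par if g_par > 0 else 0.0
        g_acc, ge_acc = g_ser, g_ser * e_par
    return g_acc, ge_acc


def thevenin(model: ChainModel, node: int | None = None) -> TheveninEquivalent:
    """Thevenin equivalent of the whole passive network seen at ``node``.

    Includes the node's own leak and shunt; the NMDA conductance is excluded
    (it is the source the equivalent is computed for).
    """
    node = model.nmda_node if node is None else range(model.n_nodes)[node]
    g_lo, ge_lo = _reduce_toward(model, node, direction=-1)
    g_hi, ge_hi = _reduce_toward(model, node, direction=+1)
    own = model.nodes[node]
    g = own.g_leak + own.g_inh + g_lo + g_hi
    ge = own.g_leak * own.e_leak + own.g_inh * own.e_inh + ge_lo + ge_hi
    return TheveninEquivalent(g_total=g, e_eff=ge / g)


def input_conductance(model: ChainModel, node: int | None = None) -> float:
    """Total leak (input) conductance seen at ``node``, nS."""
    return thevenin(model, node).g_total


def _conductance_matrix(model: ChainModel) -> np.ndarray:
    n = model.n_nodes
    g = np.zeros((n, n))
    for i, node in enumerate(model.nodes):
        g[i, i] += node.g_leak + node.g_inh
    for i, ga in enumerate(model.axial):
        g[i, i] += ga
        g[i + 1, i + 1] += ga
        g[i, i + 1] -= ga
        g[i + 1, i] -= ga
    return g


def _linear_system(model: ChainModel) -> tuple[np.ndarray, np.ndarray]:
    g = _conductance_matrix(model)
    b = np.array(
        [n.g_leak * n.e_leak + n.g_inh * n.e_inh for n in model.nodes]
    )
    return g, b


def attenuation(model: ChainModel, from_node: int, to_node: int) -> float:
    """Steady-state voltage attenuation factor between two nodes (>= 1).

    Ratio of depolarizations (voltage above rest) at the source vs. the
    target for a passive current source at ``from_node``, evaluated with all
    reversal potentials at rest so the network is purely resistive.
    """
    from_node = range(model.n_nodes)[from_node]
    to_node = range(model.n_nodes)[to_node]
    if from_node == to_node:
        raise ValueError("from_node and to_node must differ")
    g = _conductance_matrix(model)
    inj = np.zeros(model.n_nodes)
    inj[from_node] = 1.0
    u = np.linalg.solve(g, inj)
    return float(u[from_node] / u[to_node])


def _equivalent_compartment(model: ChainModel) -> SingleCompartment:
    th = thevenin(model, model.nmda_node)
    return SingleCompartment(g_leak=th.g_total, e_leak=th.e_eff, g_inh=0.0)


def solve_chain(model: ChainModel, params: NMDAParams, p: float = 1.0) -> ChainSolution:
    """Steady-state chain voltages for one excitation level.

    The NMDA node is solved on its Thevenin equivalent (multi-root rule:
    nearest rest); the remaining node voltages follow from the passive
    divider relations, sweeping outward from the NMDA node.
    """
    comp = _equivalent_compartment(model)
    v_nmda = nmda.solve_vm(comp, params, p)
    n = model.n_nodes
    volts = [0.0] * n
    volts[model.nmda_node] = v_nmda
    # propagate upward then downward from the solved node
    for j in range(model.nmda_node + 1, n):
        g_beyond, ge_beyond = _reduce_toward(model, j, direction=+1)
        node = model.nodes[j]
        ga = model.axial[j - 1]
        num = (
            ga * volts[j - 1]
            + node.g_leak * node.e_leak
            + node.g_inh * node.e_inh
            + ge_beyond
        )
        volts[j] = num / (ga + node.g_leak + node.g_inh + g_beyond)
    for j in range(model.nmda_node - 1, -1, -1):
        g_beyond, ge_beyond = _reduce_toward(model, j, direction=-1)
        node = model.nodes[j]
        ga = model.axial[j]
        num = (
            ga * volts[j + 1]
            + node.g_leak * node.e_leak
            + node.g_inh * node.e_inh
            + ge_beyond
        )
        volts[j] = num / (ga + node.g_leak + node.g_inh + g_beyond)
    return ChainSolution(
        v_dend=volts[model.nmda_node],
        v_soma=volts[model.record_node],
        n_syn=params.n_syn * p,
        voltages=tuple(volts),
    )


def chain_spike_threshold(
    model: ChainModel,
    params: NMDAParams,
    n_max: float = 10000.0,
    resolution: float = 1.0,
) -> tuple[SpikeMetrics, ChainSolution]:
    """Spike threshold of the chain plus the full solution at threshold.

    The metrics' ``height_mV`` refers to the NMDA node; the returned
    :class:`ChainSolution` also carries the somatic voltage at threshold.
    """
    comp = _equivalent_compartment(model)
    metrics = nmda.spike_threshold(comp, params, n_max=n_max, resolution=resolution)
    sol = solve_chain(model, params.with_n_syn(metrics.threshold_nsyn))
    return metrics, sol


def io_curve_sweep(
    model: ChainModel,
    params: NMDAParams,
    n_syn_grid,
    record_nodes=None,
):
    """Peak (p=1) depolarization vs. channel count at each recorded node.

    Returns a dict mapping node index to an :class:`~nmdashunt.io_curves.IOCurve`
    of depolarizations (mV above that node's rest).
    """
    from .io_curves import IOCurve

    n_syn_grid = np.asarray(n_syn_grid, dtype=float)
    if np.any(np.diff(n_syn_grid) <= 0):
        raise ValueError("n_syn_grid must be strictly increasing")
    if record_nodes is None:
        record_nodes = [model.nmda_node, model.record_node]
    rests = model.resting_potentials()
    responses = {j: [] for j in record_nodes}
    for n in n_syn_grid:
        sol = solve_chain(model, params.with_n_syn(float(n)))
        for j in record_nodes:
            responses[j].append(sol.voltages[j] - rests[j])
    return {
        j: IOCurve(
            stimulus=n_syn_grid.copy(),
            response=np.array(responses[j]),
            condition="model",
            meta={"node": int(j)},
        )
        for j in record_nodes
    }


def _asymptotic_somatic_height(
    model: ChainModel, params: NMDAParams, threshold_nsyn: float, factor: float = 3.0
) -> float:
    """Somatic depolarization on the spike plateau (at ``factor`` x threshold)."""
    rests = model.resting_potentials()
    sol = solve_chain(model, params.with_n_syn(factor * threshold_nsyn))
    return sol.v_soma - rests[model.record_node]


def effect_scatter(
    model: ChainModel,
    configs,
    params: NMDAParams | None = None,
    resolution: float = 0.01,
    height_factor: float = 3.0,
) -> pd.DataFrame:
    """Joint % change of spike threshold and somatic spike height per config.

    Each :class:`InhibitionConfig` is applied to a copy of ``model`` (which
    serves as the no-inhibition control). Threshold changes are ratios of the
    threshold channel counts; height changes are ratios of the somatic
    depolarization on the spike plateau, both relative to control.
    """
    params = params or NMDAParams()
    ctrl_metrics, _ = chain_spike_threshold(model, params, resolution=resolution)
    ctrl_height = _asymptotic_somatic_height(
        model, params, ctrl_metrics.threshold_nsyn, height_factor
    )
    rows = []
    for i, cfg in enumerate(configs):
        node = cfg.node_index(model)
        m = model.with_inhibition(node, cfg.g_inh, cfg.e_inh)
        metrics, _ = chain_spike_threshold(m, params, resolution=resolution)
        height = _asymptotic_somatic_height(
            m, params, metrics.threshold_nsyn, height_factor
        )
        rows.append(
            {
                "config_id": cfg.config_id or f"cfg{i}",
                "location": cfg.location,
                "g_inh_nS": cfg.g_inh,
                "e_inh_mV": cfg.e_inh,
                "d_threshold_pct": 100.0
                * (metrics.threshold_nsyn / ctrl_metrics.threshold_nsyn - 1.0),
                "d_height_pct": 100.0 * (height / ctrl_height - 1.0),
                "height_dend_mV": metrics.depolarization_mV,
            }
        )
    return pd.DataFrame(rows)


def reversal_sweep(
    model: ChainModel,
    e_inh_values,
    configs,
    params: NMDAParams | None = None,
    resolution: float = 0.01,
) -> pd.DataFrame:
    """Effect scatter repeated for several inhibitory reversal potentials."""
    frames = []
    for e_inh in e_inh_values:
        shifted = [replace(c, e_inh=float(e_inh)) for c in configs]
        df = effect_scatter(model, shifted, params=params, resolution=resolution)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
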