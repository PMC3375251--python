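"""Time-dependent multicompartment cable model (ball-and-stick surrogate).

A soma (sphere-equivalent cylinder) plus one unbranched, optionally tapered
dendritic cable, discretized into short iso-potential compartments. Each
compartment carries leak, capacitance, and low densities of Hodgkin-Huxley
Na+/K+ channels; synaptic conductances (AMPA, NMDA with voltage-dependent
magnesium block, GABA_A) are biexponential time courses attached at chosen
dendritic positions or at the soma. The cable equation is integrated
implicitly (backward Euler by default, Crank-Nicolson optionally) on the
tridiagonal compartment system.

The module reproduces, on the surrogate morphology, the location-dependent
phenomenology of dendritic NMDA spikes: i/o curves of peak depolarization vs.
number of activated excitatory synapses, and the differential effect of
co-localized, distal, on-path and somatic inhibition on spike threshold and
height.

Units: µm, ms, mV, nS, pA, pF (so that nS*mV = pA and pF*mV/ms = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .nmda import NMDAParams, mg_block
from .io_curves import IOCurve, fit_io, compare

__all__ = [
    "Section",
    "Morphology",
    "MembraneParams",
    "SynapsePopulation",
    "TraceSet",
    "SimulationError",
    "build_ball_and_stick",
    "write_swc",
    "read_swc",
    "compile_compartments",
    "simulate",
    "passive_steady_state",
    "excitatory_populations",
    "inhibitory_population",
    "cable_io_curve",
    "location_sweep",
    "timing_sweep",
    "GABA_KINETICS",
]

MAX_SEGMENT_UM = 10.0

#: GABA_A biexponential (rise, decay) time constants in ms, labels as printed
#: in the source parameter table (the "short" pair has the 100 ms decay).
GABA_KINETICS = {"short": (0.5, 100.0), "long": (0.5, 2.0)}


class SimulationError(RuntimeError):
    """Numerical instability (NaN or out-of-bounds voltage) during a run."""


@dataclass(frozen=True)
class Section:
    """One unbranched stretch of dendrite.

    ``parent`` is the index of the parent section, or -1 for the soma.
    Diameter tapers linearly from ``diam_proximal`` to ``diam_distal``.
    """

    length: float
    diam_proximal: float
    diam_distal: float
    n_segments: int
    parent: int = -1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diam_proximal <= 0 or self.diam_distal <= 0:
            raise ValueError("section geometry must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.length / self.n_segments > MAX_SEGMENT_UM:
            raise ValueError(
                f"segment length {self.length / self.n_segments:.2f} um exceeds "
                f"{MAX_SEGMENT_UM} um; increase n_segments"
            )


@dataclass(frozen=True)
class Morphology:
    """Soma plus a chain of dendritic sections."""

    soma_diam: float
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", tuple(self.sections))
        if self.soma_diam <= 0:
            raise ValueError("soma_diam must be positive")
        for i, sec in enumerate(self.sections):
            expected_parent = -1 if i == 0 else i - 1
            if sec.parent != expected_parent:
                raise ValueError(
                    "sections must form a chain rooted at the soma "
                    f"(section {i} has parent {sec.parent})"
                )

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)


def build_ball_and_stick(
    dend_length: float = 200.0,
    diam_proximal: float = 1.5,
    diam_distal: float = 0.8,
    soma_diam: float = 20.0,
    seg_length: float = 2.0,
) -> Morphology:
    """Default surrogate morphology: a soma and one tapered dendrite."""
    if dend_length < 200.0:
        raise ValueError("dendrite must be at least 200 um long")
    n_seg = max(1, math.ceil(dend_length / seg_length))
    sec = Section(
        length=dend_length,
        diam_proximal=diam_proximal,
        diam_distal=diam_distal,
        n_segments=n_seg,
        parent=-1,
    )
    return Morphology(soma_diam=soma_diam, sections=(sec,))


def write_swc(morph: Morphology, path) -> None:
    """Write the morphology as SWC (soma point + dendrite point chain)."""
    lines = ["# generated by nmdashunt (ball-and-stick surrogate)"]
    lines.append(f"1 1 0 0 0 {morph.soma_diam / 2.0:.17g} -1")
    idx = 2
    x0 = 0.0
    parent = 1
    for sec in morph.sections:
        xs = x0 + np.linspace(0.0, sec.length, sec.n_segments + 1)
        radii = np.linspace(sec.diam_proximal, sec.diam_distal, sec.n_segments + 1) / 2.0
        for x, r in zip(xs, radii):
            lines.append(f"{idx} 3 {x:.17g} 0 0 {r:.17g} {parent}")
            parent = idx
            idx += 1
        x0 += sec.length
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path) -> Morphology:
    """Read a chain morphology written by :func:`write_swc`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n, t, x, y, z, r, parent = line.split()
            rows.append((int(n), int(t), float(x), float(y), float(z), float(r), int(parent)))
    soma = [row for row in rows if row[1] == 1]
    if len(soma) != 1:
        raise ValueError("expected exactly one soma point")
    soma_diam = 2.0 * soma[0][5]
    dend = [row for row in rows if row[1] == 3]
    if not dend:
        raise ValueError("no dendrite points found")
    dend.sort(key=lambda row: row[0])
    xs = np.array([row[2] for row in dend])
    radii = np.array([row[5] for row in dend])
    # points come as one chain; a repeated x marks nothing - single section
    sec = Section(
        length=float(xs[-1] - xs[0]),
        diam_proximal=float(2 * radii[0]),
        diam_distal=float(2 * radii[-1]),
        n_segments=len(dend) - 1,
        parent=-1,
    )
    return Morphology(soma_diam=soma_diam, sections=(sec,))


@dataclass(frozen=True)
class MembraneParams:
    """Passive and active membrane parameters per region.

    ``r_m`` in Ohm*cm^2, ``c_m`` in uF/cm^2, ``r_a`` in Ohm*cm, channel
    densities in pS/um^2. The dendritic Na density is a flagged
    interpretation of a source value printed in volume units.
    """

    r_m_soma: float = 20000.0
    r_m_dend: float = 10000.0
    c_m_soma: float = 1.0
    c_m_dend: float = 2.0
    r_a: float = 100.0
    #: lumped conductance/capacitance at the soma standing in for the rest of
    #: the dendritic tree, sized to the somatic input resistance measured in
    #: layer-5 cells (~60 MOhm) with a ~20 ms membrane time constant
    g_load_nS: float = 15.0
    c_load_pF: float = 300.0
    gbar_na_soma: float = 25.0
    gbar_na_dend: float = 3.0
    gbar_k_soma: float = 3.0
    gbar_k_dend: float = 0.03
    e_rest: float = -70.0
    e_na: float = 50.0
    e_k: float = -77.0

    def __post_init__(self) -> None:
        for name in ("r_m_soma", "r_m_dend", "c_m_soma", "c_m_dend", "r_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gbar_na_soma", "gbar_na_dend", "gbar_k_soma", "gbar_k_dend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def passive(self) -> "MembraneParams":
        """Copy with all voltage-gated channel densities zeroed."""
        return replace(
            self, gbar_na_soma=0.0, gbar_na_dend=0.0, gbar_k_soma=0.0, gbar_k_dend=0.0
        )


@dataclass(frozen=True)
class SynapsePopulation:
    """A cluster of identical synapses around one dendritic position.

    ``center_um`` is distance from the soma along the dendrite (0 targets the
    soma itself); synapses are spread ``spacing_um`` apart around the center.
    ``stimulus`` is ``"single_pulse"`` (all synapses fire once at
    ``onset_ms``) or ``"poisson"`` (independent trains at ``rate_hz``).
    """

    kind: str  # "AMPA", "NMDA", or "GABA_A"
    center_um: float
    count: int
    g_peak_per_syn: float
    tau_rise: float
    tau_decay: float
    e_rev: float
    spacing_um: float = 0.5
    onset_ms: float = 10.0
    stimulus: str = "single_pulse"
    rate_hz: float = 50.0
    nmda: NMDAParams = field(default_factory=NMDAParams)

    def __post_init__(self) -> None:
        if self.kind not in ("AMPA", "NMDA", "GABA_A"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.g_peak_per_syn < 0:
            raise ValueError("g_peak_per_syn must be non-negative")

    def positions(self) -> np.ndarray:
        offs = (np.arange(self.count) - (self.count - 1) / 2.0) * self.spacing_um
        return np.maximum(self.center_um + offs, 0.0)


@dataclass
class Compartments:
    """Compiled electrical skeleton of the morphology (soma is index 0)."""

    x_um: np.ndarray  # position of compartment center along the path
    area_um2: np.ndarray
    c_pF: np.ndarray
    g_leak_nS: np.ndarray
    gbar_na_nS: np.ndarray
    gbar_k_nS: np.ndarray
    g_axial_nS: np.ndarray  # coupling between i and i+1, length n-1

    @property
    def n(self) -> int:
        return len(self.x_um)

    def nearest(self, x_um: float) -> int:
        """Compartment index closest to a path position (0 = soma)."""
        return int(np.argmin(np.abs(self.x_um - x_um)))


def compile_compartments(morph: Morphology, membrane: MembraneParams) -> Compartments:
    """Discretize the morphology into compartments with electrical constants."""
    # soma as an iso-potential cylinder of length == diameter
    lengths = [morph.soma_diam]
    diams = [morph.soma_diam]
    centers = [0.0]
    is_soma = [True]
    x0 = 0.0
    for sec in morph.sections:
        seg_len = sec.length / sec.n_segments
        for j in range(sec.n_segments):
            frac = (j + 0.5) / sec.n_segments
            d = sec.diam_proximal + (sec.diam_distal - sec.diam_proximal) * frac
            lengths.append(seg_len)
            diams.append(d)
            centers.append(x0 + (j + 0.5) * seg_len)
            is_soma.append(False)
        x0 += sec.length
    lengths = np.array(lengths)
    diams = np.array(diams)
    centers = np.array(centers)
    is_soma = np.array(is_soma)

    area = np.pi * diams * lengths  # um^2
    r_m = np.where(is_soma, membrane.r_m_soma, membrane.r_m_dend)
    c_m = np.where(is_soma, membrane.c_m_soma, membrane.c_m_dend)
    # 1 S/cm^2 == 10 nS/um^2 ; 1 uF/cm^2 == 0.01 pF/um^2
    g_leak = area * 10.0 / r_m
    c = area * 0.01 * c_m
    # the surrogate tree load sits at the soma and leaks to rest
    g_leak[0] += membrane.g_load_nS
    c[0] += membrane.c_load_pF
    gbar_na = area * np.where(is_soma, membrane.gbar_na_soma, membrane.gbar_na_dend) / 1000.0
    gbar_k = area * np.where(is_soma, membrane.gbar_k_soma, membrane.gbar_k_dend) / 1000.0

    # axial conductance between adjacent compartments: two half-cylinders in
    # series; computed in cm then converted to nS
    um = 1e-4  # cm per um
    half_r = membrane.r_a * (lengths * um / 2.0) / (np.pi * (diams * um / 2.0) ** 2)
    g_ax = 1.0 / (half_r[:-1] + half_r[1:]) * 1e9  # S -> nS
    return Compartments(
        x_um=centers,
        area_um2=area,
        c_pF=c,
        g_leak_nS=g_leak,
        gbar_na_nS=gbar_na,
        gbar_k_nS=gbar_k,
        g_axial_nS=g_ax,
    )


@dataclass
class TraceSet:
    """Voltage traces for every compartment on a shared time grid."""

    t_ms: np.ndarray
    v_mV: np.ndarray  # (n_t, n_comp)
    x_um: np.ndarray
    baseline_index: int = 0
    soma_balance_max_pA: float = 0.0
    meta: dict = field(default_factory=dict)

    def site_index(self, x_um: float) -> int:
        return int(np.argmin(np.abs(self.x_um - x_um)))

    def trace(self, x_um: float) -> np.ndarray:
        return self.v_mV[:, self.site_index(x_um)]

    def peak_depolarization(self, x_um: float) -> float:
        """Peak voltage above the pre-stimulus baseline at a site, mV."""
        v = self.trace(x_um)
        return float(np.max(v[self.baseline_index:]) - v[self.baseline_index])

    def to_frame(self, sites_um) -> pd.DataFrame:
        frames = []
        for x in sites_um:
            i = self.site_index(x)
            frames.append(
                pd.DataFrame(
                    {"t_ms": self.t_ms, "site_um": self.x_um[i], "v_mV": self.v_mV[:, i]}
                )
            )
        return pd.concat(frames, ignore_index=True)


# --- Hodgkin-Huxley kinetics (standard squid-derived rate functions) -------


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0), x / np.expm1(x / y)
    )
    return out


def hh_rates(v):
    """(alpha, beta) for m, h, n at voltage ``v`` (mV), rates in 1/ms."""
    v = np.asarray(v, dtype=float)
    a_m = 0.1 * _vtrap(-(v + 40.0), 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(-(v + 55.0), 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return (a_m, b_m), (a_h, b_h), (a_n, b_n)


def _gates_steady(v):
    (a_m, b_m), (a_h, b_h), (a_n, b_n) = hh_rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def _biexp_waveform(t, onset, tau_rise, tau_decay):
    """Normalized (peak 1) biexponential conductance time course."""
    tp = math.log(tau_decay / tau_rise) * tau_decay * tau_rise / (tau_decay - tau_rise)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    dt_ = np.maximum(t - onset, 0.0)
    w = (np.exp(-dt_ / tau_decay) - np.exp(-dt_ / tau_rise)) / norm
    return np.where(t >= onset, w, 0.0)


def _population_events(pop: SynapsePopulation, t_stop: float, rng) -> list[np.ndarray]:
    """Per-synapse event times."""
    if pop.stimulus == "single_pulse":
        return [np.array([pop.onset_ms])] * pop.count
    if pop.stimulus == "poisson":
        if rng is None:
            raise ValueError("poisson stimulation requires an rng (seeded)")
        events = []
        for _ in range(pop.count):
            n = rng.poisson(pop.rate_hz * (t_stop - pop.onset_ms) / 1000.0)
            events.append(np.sort(rng.uniform(pop.onset_ms, t_stop, size=n)))
        return events
    raise ValueError(f"unknown stimulus {pop.stimulus!r}")


def simulate(
    morph: Morphology,
    membrane: MembraneParams,
    populations,
    t_stop: float,
    dt: float = 0.025,
    method: str = "backward_euler",
    rng=None,
    i_inject_pA: float = 0.0,
    inject_site_um: float = 0.0,
) -> TraceSet:
    """Integrate the discretized cable equation with implicit time stepping.

    Synaptic conductance time courses are evaluated analytically on the time
    grid; NMDA conductances are additionally scaled by the magnesium block at
    the previous step's voltage. Gates use exponential integration. Raises
    :class:`SimulationError` on numerical instability.
    """
    if dt > 0.025 + 1e-12:
        raise ValueError("dt must be <= 0.025 ms")
    if method not in ("backward_euler", "crank_nicolson"):
        raise ValueError(f"unknown method {method!r}")
    comps = compile_compartments(morph, membrane)
    n = comps.n
    n_steps = int(round(t_stop / dt))
    t_grid = np.arange(n_steps + 1) * dt

    # accumulate synaptic conductance (and conductance*reversal) per
    # compartment per time point; NMDA kept separate for the Mg block
    g_syn = np.zeros((n_steps + 1, n))
    ge_syn = np.zeros((n_steps + 1, n))
    g_nmda = np.zeros((n_steps + 1, n))
    ge_nmda = np.zeros((n_steps + 1, n))
    nmda_pars = None
    onsets = []
    for pop in populations:
        onsets.append(pop.onset_ms)
        events = _population_events(pop, t_stop, rng)
        idxs = [comps.nearest(x) for x in pop.positions()]
        for syn_events, ci in zip(events, idxs):
            w = np.zeros(n_steps + 1)
            for t0 in syn_events:
                w += _biexp_waveform(t_grid, t0, pop.tau_rise, pop.tau_decay)
            g = pop.g_peak_per_syn * w
            if pop.kind == "NMDA":
                g_nmda[:, ci] += g
                ge_nmda[:, ci] += g * pop.e_rev
                nmda_pars = pop.nmda
            else:
                g_syn[:, ci] += g
                ge_syn[:, ci] += g * pop.e_rev

    inj = np.zeros(n)
    if i_inject_pA:
        inj[comps.nearest(inject_site_um)] = i_inject_pA

    # constant axial part of the system matrix
    lap_diag = np.zeros(n)
    lap_diag[:-1] += comps.g_axial_nS
    lap_diag[1:] += comps.g_axial_nS

    v = np.full(n, membrane.e_rest)
    m, h, gn = _gates_steady(v)
    vs = np.empty((n_steps + 1, n))
    vs[0] = v
    balance_max = 0.0
    ab = np.zeros((3, n))
    theta = 1.0 if method == "backward_euler" else 0.5

    for k in range(n_steps):
        g_na = comps.gbar_na_nS * m**3 * h
        g_k = comps.gbar_k_nS * gn**4
        mg = mg_block(v, nmda_pars) if nmda_pars is not None else 0.0
        gnm = g_nmda[k + 1] * mg
        genm = ge_nmda[k + 1] * mg
        g_mem = comps.g_leak_nS + g_na + g_k + g_syn[k + 1] + gnm
        ge_mem = (
            comps.g_leak_nS * membrane.e_rest
            + g_na * membrane.e_na
            + g_k * membrane.e_k
            + ge_syn[k + 1]
            + genm
        )
        diag = comps.c_pF / dt + theta * (g_mem + lap_diag)
        rhs = comps.c_pF / dt * v + ge_mem + inj
        if theta != 1.0:
            # Crank-Nicolson: half of the conductive current is explicit
            i_axial = np.zeros(n)
            dv = np.diff(v)
            i_axial[:-1] += comps.g_axial_nS * dv
            i_axial[1:] -= comps.g_axial_nS * dv
            rhs += (1.0 - theta) * (-(g_mem * v) + i_axial)
        ab[0, 1:] = -theta * comps.g_axial_nS
        ab[1, :] = diag
        ab[2, :-1] = -theta * comps.g_axial_nS
        v_new = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(v_new)) or v_new.max() > 80.0 or v_new.min() < -150.0:
            raise SimulationError(
                f"integration unstable at t={t_grid[k + 1]:.3f} ms "
                f"(v range {np.nanmin(v_new):.1f}..{np.nanmax(v_new):.1f} mV); "
                "reduce dt or conductances"
            )
        # current-balance residual at the soma (row 0 of the solved system)
        r0 = ab[1, 0] * v_new[0] + ab[0, 1] * v_new[1] - rhs[0]
        balance_max = max(balance_max, abs(float(r0)))
        # gate update at the new voltage (exponential integrator)
        (a_m, b_m), (a_h, b_h), (a_n, b_n) = hh_rates(v_new)
        for gate, (a, b) in ((0, (a_m, b_m)), (1, (a_h, b_h)), (2, (a_n, b_n))):
            tau = 1.0 / (a + b)
            inf = a * tau
            decay = -np.expm1(-dt / tau)
            if gate == 0:
                m = m + (inf - m) * decay
            elif gate == 1:
                h = h + (inf - h) * decay
            else:
                gn = gn + (inf - gn) * decay
        v = v_new
        vs[k + 1] = v

    baseline_index = 0
    if onsets:
        baseline_index = max(0, int(math.floor(min(onsets) / dt)) - 1)
    return TraceSet(
        t_ms=t_grid,
        v_mV=vs,
        x_um=comps.x_um,
        baseline_index=baseline_index,
        soma_balance_max_pA=balance_max,
        meta={"dt": dt, "method": method},
    )


def passive_steady_state(
    morph: Morphology,
    membrane: MembraneParams,
    inject_site_um: float,
    i_pA: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state depolarization profile for a constant current injection.

    Voltage-gated and synaptic conductances are excluded: the linear system
    (leak + axial Laplacian) is solved directly. Returns ``(x_um, u_mV)``
    with ``u`` the depolarization above rest.
    """
    comps = compile_compartments(morph, membrane)
    n = comps.n
    g = np.zeros((n, n))
    np.fill_diagonal(g, comps.g_leak_nS)
    for i, ga in enumerate(comps.g_axial_nS):
        g[i, i] += ga
        g[i + 1, i + 1] += ga
        g[i, i + 1] -= ga
        g[i + 1, i] -= ga
    inj = np.zeros(n)
    inj[comps.nearest(inject_site_um)] = i_pA
    u = np.linalg.solve(g, inj)
    return comps.x_um.copy(), u


# --- protocol helpers -------------------------------------------------------


def excitatory_populations(
    n_syn: int,
    center_um: float = 125.0,
    ampa_g_peak: float = 6.0,
    nmda_ampa_ratio: float = 1.0,
    onset_ms: float = 20.0,
    spacing_um: float = 0.5,
    nmda_params: NMDAParams | None = None,
) -> list[SynapsePopulation]:
    """Co-localized AMPA + NMDA populations for ``n_syn`` synapses."""
    if n_syn < 1:
        return []
    nmda_params = nmda_params or NMDAParams()
    ampa = SynapsePopulation(
        kind="AMPA",
        center_um=center_um,
        count=n_syn,
        g_peak_per_syn=ampa_g_peak,
        tau_rise=0.05,
        tau_decay=0.5,
        e_rev=0.0,
        spacing_um=spacing_um,
        onset_ms=onset_ms,
    )
    nmda_pop = SynapsePopulation(
        kind="NMDA",
        center_um=center_um,
        count=n_syn,
        g_peak_per_syn=ampa_g_peak * nmda_ampa_ratio,
        tau_rise=nmda_params.tau_fast,
        tau_decay=nmda_params.tau_slow,
        e_rev=nmda_params.e_nmda,
        spacing_um=spacing_um,
        onset_ms=onset_ms,
        nmda=nmda_params,
    )
    return [ampa, nmda_pop] if nmda_ampa_ratio > 0 else [ampa]


def inhibitory_population(
    g_peak_total: float,
    location_um: float = 125.0,
    kinetics: str = "short",
    onset_ms: float = 10.0,
    e_rev: float = -70.0,
    count: int = 10,
) -> SynapsePopulation:
    """A GABA_A cluster with total peak conductance spread over ``count`` sites.

    ``kinetics`` picks a (rise, decay) pair from :data:`GABA_KINETICS`; the
    onset default leads the excitation by 10 ms, mimicking iontophoresis.
    """
    tau_rise, tau_decay = GABA_KINETICS[kinetics]
    return SynapsePopulation(
        kind="GABA_A",
        center_um=location_um,
        count=count,
        g_peak_per_syn=g_peak_total / count,
        tau_rise=tau_rise,
        tau_decay=tau_decay,
        e_rev=e_rev,
        spacing_um=0.5,
        onset_ms=onset_ms,
    )


def cable_io_curve(
    morph: Morphology,
    membrane: MembraneParams,
    n_syn_grid,
    inhibition: SynapsePopulation | None = None,
    exc_center_um: float = 125.0,
    ampa_g_peak: float = 6.0,
    nmda_ampa_ratio: float = 1.0,
    exc_onset_ms: float = 20.0,
    t_stop: float = 70.0,
    dt: float = 0.025,
    record_sites_um=(0.0,),
    nmda_params: NMDAParams | None = None,
    condition: str | None = None,
) -> dict[float, IOCurve]:
    """Peak-depolarization i/o curves vs. number of excitatory synapses.

    Returns one :class:`IOCurve` per requested recording site (path distance
    in µm; 0 is the soma).
    """
    n_syn_grid = np.asarray(n_syn_grid)
    peaks = {x: [] for x in record_sites_um}
    for n_syn in n_syn_grid:
        pops = excitatory_populations(
            int(n_syn),
            center_um=exc_center_um,
            ampa_g_peak=ampa_g_peak,
            nmda_ampa_ratio=nmda_ampa_ratio,
            onset_ms=exc_onset_ms,
            nmda_params=nmda_params,
        )
        if inhibition is not None:
            pops = pops + [inhibition]
        if not pops:
            for x in record_sites_um:
                peaks[x].append(0.0)
            continue
        tr = simulate(morph, membrane, pops, t_stop=t_stop, dt=dt)
        for x in record_sites_um:
            peaks[x].append(tr.peak_depolarization(x))
    cond = condition or ("inhibited" if inhibition is not None else "control")
    return {
        x: IOCurve(
            stimulus=n_syn_grid.astype(float),
            response=np.array(peaks[x]),
            condition=cond,
            meta={"site_um": x},
        )
        for x in record_sites_um
    }


def location_sweep(
    morph: Morphology,
    membrane: MembraneParams,
    placements,
    n_syn_grid=None,
    exc_center_um: float = 125.0,
    ampa_g_peak: float = 6.0,
    nmda_ampa_ratio: float = 1.0,
    gaba_kinetics: str = "short",
    t_stop: float = 70.0,
    dt: float = 0.025,
    nmda_params: NMDAParams | None = None,
) -> pd.DataFrame:
    """Effect of inhibition placement/strength on threshold and height.

    ``placements`` is an iterable of ``(label, location_um, g_inh_total_nS)``
    with ``location_um=0`` meaning the soma. For each placement an i/o curve
    at the soma is simulated, fitted, and compared to the no-inhibition
    control; the returned frame has one row per placement.
    """
    if n_syn_grid is None:
        n_syn_grid = np.arange(0, 37, 3)
    common = dict(
        n_syn_grid=n_syn_grid,
        exc_center_um=exc_center_um,
        ampa_g_peak=ampa_g_peak,
        nmda_ampa_ratio=nmda_ampa_ratio,
        t_stop=t_stop,
        dt=dt,
        nmda_params=nmda_params,
        record_sites_um=(0.0, exc_center_um),
    )
    ctrl = cable_io_curve(morph, membrane, inhibition=None, **common)
    ctrl_fit = fit_io(ctrl[0.0])
    rows = []
    for label, loc, g_inh in placements:
        inh = inhibitory_population(
            g_peak_total=g_inh, location_um=loc, kinetics=gaba_kinetics
        )
        curves = cable_io_curve(morph, membrane, inhibition=inh, **common)
        f = fit_io(curves[0.0])
        eff = compare(ctrl_fit, f)
        rows.append(
            {
                "placement": label,
                "location_um": loc,
                "g_inh_nS": g_inh,
                "d_threshold_pct": eff.d_threshold_pct,
                "d_height_pct": eff.d_height_pct,
                "d_subslope_pct": eff.d_subslope_pct,
            }
        )
    return pd.DataFrame(rows)


def timing_sweep(
    morph: Morphology,
    membrane: MembraneParams,
    conditions,
    g_inh_dend: float = 8.0,
    g_inh_soma: float = 90.0,
    exc_center_um: float = 125.0,
    n_syn_grid=None,
    **kwargs,
) -> pd.DataFrame:
    """Sensitivity of the location effect to GABA kinetics and onset lead.

    ``conditions`` is an iterable of ``(kinetics_label, onset_lead_ms)``;
    each is run for a dendritic (co-localized) and a somatic placement.
    """
    if n_syn_grid is None:
        n_syn_grid = np.arange(0, 37, 3)
    exc_onset = kwargs.pop("exc_onset_ms", 20.0)
    common = dict(
        n_syn_grid=n_syn_grid,
        exc_center_um=exc_center_um,
        exc_onset_ms=exc_onset,
        record_sites_um=(0.0,),
        **kwargs,
    )
    ctrl_fit = fit_io(cable_io_curve(morph, membrane, inhibition=None, **common)[0.0])
    rows = []
    for kin, lead in conditions:
        for placement, loc, g in (
            ("dendritic", exc_center_um, g_inh_dend),
            ("somatic", 0.0, g_inh_soma),
        ):
            inh = inhibitory_population(
                g_peak_total=g,
                location_um=loc,
                kinetics=kin,
                onset_ms=exc_onset - lead,
            )
            f = fit_io(cable_io_curve(morph, membrane, inhibition=inh, **common)[0.0])
            eff = compare(ctrl_fit, f)
            rows.append(
                {
                    "placement": placement,
                    "kinetics": kin,
                    "onset_lead_ms": lead,
                    "g_inh_nS": g,
                    "d_threshold_pct": eff.d_threshold_pct,
                    "d_height_pct": eff.d_height_pct,
                }
            )
    return pd.DataFrame(rows)
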