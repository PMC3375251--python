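"""Single-compartment steady-state NMDA spike model.

A patch of dendritic membrane is reduced to one electrical node carrying a
passive leak conductance, an optional shunting (GABAergic) conductance, and a
population of ``n_syn`` glutamate-bound NMDA channels. The NMDA conductance is
the product of a normalized biexponential time course ``p(t)`` and a
voltage-dependent magnesium-block factor, so at the moment of peak gating the
circuit is fully characterized by its instantaneous I-V relations. Capacitive
currents are ignored: the membrane potential is the voltage at which the
inward NMDA current balances the outward leak + inhibitory current
(Kirchhoff's current law). Because the NMDA I-V relation has a region of
negative slope, the current-balance equation can have multiple solutions; the
solution closest to the resting potential is taken, which makes the peak
response jump discontinuously - the NMDA spike - once the channel count
crosses threshold.

Voltages are in mV, conductances in nS, currents in pA, times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NMDAParams",
    "SingleCompartment",
    "IVCurve",
    "SpikeMetrics",
    "NoRootError",
    "ThresholdNotFoundError",
    "mg_block",
    "nmda_p",
    "gating_peak_time",
    "nmda_conductance",
    "kcl_residual",
    "find_equilibria",
    "solve_vm",
    "iv_curves",
    "spike_threshold",
    "quasi_static_trace",
]

#: Voltage margin (mV) added around [e_leak, e_nmda] when searching for roots.
SEARCH_MARGIN_MV = 20.0
#: Coarse scan step (mV) used to bracket sign changes of the KCL residual.
SCAN_STEP_MV = 0.1
#: Tolerance (mV) to which bracketed roots are refined.
ROOT_XTOL_MV = 1e-6


class NoRootError(RuntimeError):
    """No voltage balancing the membrane currents was found."""


class ThresholdNotFoundError(RuntimeError):
    """No spiking channel count was found below the search ceiling."""


@dataclass(frozen=True)
class NMDAParams:
    """Parameters of the NMDA channel population.

    n_syn
        Number of glutamate-activated NMDA channels (dimensionless, >= 0).
    g_unit
        Unblocked single-channel conductance in nS (default 50 pS).
    e_nmda
        Reversal potential in mV.
    tau_fast, tau_slow
        Rise and decay time constants of the conductance time course in ms.
    mg_conc
        Extracellular Mg2+ concentration in mM.
    mg_eta
        Mg block concentration constant in mM.
    mg_gamma
        Mg block voltage sensitivity in 1/mV.
    """

    n_syn: float = 20.0
    g_unit: float = 0.05
    e_nmda: float = 0.0
    tau_fast: float = 2.1
    tau_slow: float = 18.8
    mg_conc: float = 1.0
    mg_eta: float = 3.57
    mg_gamma: float = 0.10

    def __post_init__(self) -> None:
        if not self.tau_slow > self.tau_fast > 0:
            raise ValueError(
                f"need tau_slow > tau_fast > 0, got {self.tau_slow}, {self.tau_fast}"
            )
        if self.g_unit <= 0:
            raise ValueError("g_unit must be positive")
        if self.mg_conc < 0:
            raise ValueError("mg_conc must be non-negative")
        if self.n_syn < 0:
            raise ValueError("n_syn must be non-negative")
        if self.mg_eta <= 0:
            raise ValueError("mg_eta must be positive")

    def with_n_syn(self, n_syn: float) -> "NMDAParams":
        return replace(self, n_syn=n_syn)

    @property
    def g_total_peak(self) -> float:
        """Total unblocked NMDA conductance at peak gating, nS."""
        return self.n_syn * self.g_unit


@dataclass(frozen=True)
class SingleCompartment:
    """Passive elements of the single-node circuit (nS, mV)."""

    g_leak: float = 1.0
    e_leak: float = -70.0
    g_inh: float = 0.0
    e_inh: float = -70.0

    def __post_init__(self) -> None:
        if self.g_leak <= 0:
            raise ValueError("g_leak must be positive")
        if self.g_inh < 0:
            raise ValueError("g_inh must be non-negative")

    @property
    def v_rest(self) -> float:
        """Resting potential: the zero-excitation equilibrium, mV."""
        g = self.g_leak + self.g_inh
        return (self.g_leak * self.e_leak + self.g_inh * self.e_inh) / g


@dataclass(frozen=True)
class IVCurve:
    """Current-voltage relation of one circuit branch on a voltage grid."""

    voltages: np.ndarray
    currents: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if v.ndim != 1 or v.shape != i.shape:
            raise ValueError("voltages and currents must be matching 1-D arrays")
        if not np.all(np.diff(v) > 0):
            raise ValueError("voltage grid must be strictly increasing")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"v_mV": self.voltages, "i": self.currents})


@dataclass(frozen=True)
class SpikeMetrics:
    """Spike threshold expressed as a channel count, and the spike height.

    ``height_mV`` is the absolute membrane potential of the depolarized
    equilibrium at the threshold channel count; depolarization relative to
    rest is ``height_mV - v_rest``.
    """

    threshold_nsyn: float
    height_mV: float
    v_rest: float
    g_unit: float

    @property
    def threshold_nS(self) -> float:
        """Threshold expressed as total peak NMDA conductance, nS."""
        return self.threshold_nsyn * self.g_unit

    @property
    def depolarization_mV(self) -> float:
        return self.height_mV - self.v_rest


def mg_block(v, params: NMDAParams):
    """Fraction of NMDA channels not blocked by Mg2+ at voltage ``v`` (mV).

    Exponential (Jahr-Stevens form) block
    ``1 / (1 + (mg/eta) * exp(-gamma * v))``: strictly increasing in ``v``,
    tending to 1 at depolarized potentials, identically 1 without Mg2+.
    """
    v = np.asarray(v, dtype=float)
    frac = 1.0 / (1.0 + (params.mg_conc / params.mg_eta) * np.exp(-params.mg_gamma * v))
    return frac if frac.ndim else float(frac)


def gating_peak_time(params: NMDAParams) -> float:
    """Time (ms) at which the biexponential gating reaches its maximum."""
    tf, ts = params.tau_fast, params.tau_slow
    return math.log(ts / tf) * ts * tf / (ts - tf)


def nmda_p(t, params: NMDAParams):
    """Normalized NMDA gating time course, difference of exponentials.

    ``p(t) = (exp(-t/tau_slow) - exp(-t/tau_fast)) / norm`` with the
    normalization chosen so that ``max_t p(t) = 1`` exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tp = gating_peak_time(params)
    norm = math.exp(-tp / params.tau_slow) - math.exp(-tp / params.tau_fast)
    p = (np.exp(-t / params.tau_slow) - np.exp(-t / params.tau_fast)) / norm
    return p if p.ndim else float(p)


def nmda_conductance(v, params: NMDAParams, p: float = 1.0):
    """Effective NMDA conductance (nS) at voltage ``v`` and gating ``p``."""
    return params.n_syn * params.g_unit * p * mg_block(v, params)


def kcl_residual(v, comp: SingleCompartment, params: NMDAParams, p: float = 1.0):
    """Net outward membrane current (pA) at voltage ``v``.

    Zero at an equilibrium; negative where the inward NMDA current dominates.
    """
    v = np.asarray(v, dtype=float)
    i_out = comp.g_leak * (v - comp.e_leak) + comp.g_inh * (v - comp.e_inh)
    i_nmda_out = nmda_conductance(v, params, p) * (v - params.e_nmda)
    r = i_out + i_nmda_out
    return r if r.ndim else float(r)


def _search_window(comp: SingleCompartment, params: NMDAParams) -> tuple[float, float]:
    lo = min(comp.e_leak, comp.e_inh) - SEARCH_MARGIN_MV
    hi = params.e_nmda + SEARCH_MARGIN_MV
    return lo, hi


def find_equilibria(
    comp: SingleCompartment,
    params: NMDAParams,
    p: float = 1.0,
    scan_step: float = SCAN_STEP_MV,
) -> list[float]:
    """All voltages balancing the currents, ascending.

    Sign changes of the KCL residual are bracketed on a coarse voltage scan
    and refined by Brent's method to :data:`ROOT_XTOL_MV`.
    """
    lo, hi = _search_window(comp, params)
    grid = np.arange(lo, hi + scan_step, scan_step)
    res = kcl_residual(grid, comp, params, p)
    roots: list[float] = []
    sign = np.sign(res)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(
            float(
                brentq(
                    kcl_residual,
                    grid[i],
                    grid[i + 1],
                    args=(comp, params, p),
                    xtol=ROOT_XTOL_MV,
                )
            )
        )
    for v in grid[sign == 0]:
        roots.append(float(v))
    return sorted(roots)


def solve_vm(comp: SingleCompartment, params: NMDAParams, p: float = 1.0) -> float:
    """Membrane potential (mV) solving the current-balance equation.

    When several voltages balance the currents, the one closest to the
    resting potential is returned.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("gating value p must lie in [0, 1]")
    if params.n_syn * p == 0:
        return comp.v_rest
    roots = find_equilibria(comp, params, p)
    if not roots:
        raise NoRootError(
            f"no current-balance root in {_search_window(comp, params)} mV"
        )
    rest = comp.v_rest
    return min(roots, key=lambda v: abs(v - rest))


def iv_curves(
    comp: SingleCompartment,
    params: NMDAParams,
    p: float = 1.0,
    dv: float = 0.1,
) -> tuple[IVCurve, IVCurve]:
    """(NMDA, leak) branch I-V curves on a shared voltage grid.

    The NMDA curve is the inward current ``g_nmda(V) * (E_nmda - V)``; the
    leak curve is the outward leak + inhibitory current plotted with the same
    sign convention, so that curve intersections are circuit equilibria.
    """
    v = np.arange(comp.e_leak - 10.0, params.e_nmda + 10.0 + dv, dv)
    i_nmda = nmda_conductance(v, params, p) * (params.e_nmda - v)
    i_leak = comp.g_leak * (v - comp.e_leak) + comp.g_inh * (v - comp.e_inh)
    return IVCurve(v, i_nmda, "NMDA"), IVCurve(v, i_leak, "leak")


def _classify_scan(
    comp: SingleCompartment, params: NMDAParams, n_grid: np.ndarray
) -> tuple[int, float | None, list[float]]:
    """Scan ``n_grid`` upward; return (index of first spiking entry, separatrix,
    per-entry nearest-rest voltages).

    A channel count spikes when its only equilibrium lies on the depolarized
    branch. While the circuit is bistable the middle (unstable) equilibrium
    separates the branches and is remembered as the separatrix; if the
    bistable window is narrower than the grid, the discontinuous jump of the
    nearest-rest voltage marks the transition instead.
    """
    rest = comp.v_rest
    jump_min = 0.25 * (params.e_nmda - rest)
    v_sep: float | None = None
    v_prev: float | None = None
    volts: list[float] = []
    for idx, n in enumerate(n_grid):
        pars = params.with_n_syn(float(n))
        if pars.n_syn == 0:
            volts.append(rest)
            v_prev = rest
            continue
        roots = find_equilibria(comp, pars)
        if not roots:
            raise NoRootError("no current-balance root during threshold scan")
        v = min(roots, key=lambda r: abs(r - rest))
        volts.append(v)
        if len(roots) >= 3:
            v_sep = roots[-2]  # unstable equilibrium below the upper branch
        elif v_sep is not None and v > v_sep:
            return idx, v_sep, volts
        elif v_prev is not None and v - v_prev > jump_min:
            return idx, v_sep, volts
        v_prev = v
    return -1, v_sep, volts


def spike_threshold(
    comp: SingleCompartment,
    params: NMDAParams,
    n_max: float = 10000.0,
    resolution: float = 1.0,
) -> SpikeMetrics:
    """Smallest channel count producing an NMDA spike at peak gating.

    The channel-count axis is scanned in integer steps (``resolution=1``); a
    fractional ``resolution`` refines the transition by bisection. The spike
    height is the membrane potential at the threshold count.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n_grid = np.arange(0.0, n_max + 1.0)
    idx, v_sep, volts = _classify_scan(comp, params, n_grid)
    if idx < 0:
        raise ThresholdNotFoundError(f"no spike threshold below n_syn={n_max}")
    n_hi = float(n_grid[idx])
    n_lo = float(n_grid[idx - 1]) if idx > 0 else 0.0
    if v_sep is None:
        v_sep = 0.5 * (volts[idx - 1] + volts[idx])
    if resolution < 1.0:
        rest = comp.v_rest
        while n_hi - n_lo > resolution:
            mid = 0.5 * (n_lo + n_hi)
            v = solve_vm(comp, params.with_n_syn(mid))
            if v > v_sep:
                n_hi = mid
            else:
                n_lo = mid
    height = solve_vm(comp, params.with_n_syn(n_hi))
    return SpikeMetrics(
        threshold_nsyn=n_hi,
        height_mV=height,
        v_rest=comp.v_rest,
        g_unit=params.g_unit,
    )


def quasi_static_trace(
    comp: SingleCompartment, params: NMDAParams, t_grid
) -> np.ndarray:
    """Voltage trace under the quasi-static (capacitance-free) approximation.

    At each time the membrane is assumed to equilibrate instantly to the
    current gating value ``p(t)``; suprathreshold channel counts therefore
    show a discontinuous jump onto the spike plateau.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    p = nmda_p(t_grid, params)
    return np.array([solve_vm(comp, params, float(pi)) for pi in p])
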