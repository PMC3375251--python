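"""Independent brute-force oracles used to validate the solvers.

These deliberately avoid the package's root-finding and network-reduction
code paths: equilibria are located by scanning a dense voltage grid for sign
changes of the raw current-balance residual, and chain circuits are handled
by eliminating the passive nodes with a direct linear solve (voltages are
affine in the NMDA-node voltage).
"""

import numpy as np

from nmdashunt.nmda import NMDAParams, SingleCompartment, mg_block

DENSE_DV = 0.001


def dense_grid_vm(comp: SingleCompartment, params: NMDAParams, p: float = 1.0) -> float:
    """Nearest-rest equilibrium from a 0.001 mV grid scan of the residual."""
    v = np.arange(comp.e_leak - 20.0, params.e_nmda + 20.0, DENSE_DV)
    g_n = params.n_syn * params.g_unit * p * mg_block(v, params)
    res = (
        comp.g_leak * (v - comp.e_leak)
        + comp.g_inh * (v - comp.e_inh)
        + g_n * (v - params.e_nmda)
    )
    sign = np.sign(res)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise RuntimeError("no root on dense grid")
    roots = 0.5 * (v[idx] + v[idx + 1])
    rest = comp.v_rest
    return float(roots[np.argmin(np.abs(roots - rest))])


def dense_grid_chain_vm(model, params: NMDAParams, p: float = 1.0) -> float:
    """Nearest-rest NMDA-node voltage of a chain, via linear elimination.

    For a fixed NMDA-node voltage the remaining nodes form a linear network;
    their voltages are affine in it, so the full nonlinear residual at the
    NMDA node can be evaluated on a dense grid directly.
    """
    n = model.n_nodes
    d = model.nmda_node
    others = [j for j in range(n) if j != d]
    # linear system for the passive nodes: A x = b + c * v_d
    a = np.zeros((len(others), len(others)))
    b = np.zeros(len(others))
    c = np.zeros(len(others))
    pos = {j: i for i, j in enumerate(others)}
    for j in others:
        i = pos[j]
        node = model.nodes[j]
        a[i, i] += node.g_leak + node.g_inh
        b[i] += node.g_leak * node.e_leak + node.g_inh * node.e_inh
        for k, ga in ((j - 1, model.axial[j - 1] if j > 0 else None),
                      (j + 1, model.axial[j] if j < n - 1 else None)):
            if ga is None:
                continue
            a[i, i] += ga
            if k == d:
                c[i] += ga
            else:
                a[i, pos[k]] -= ga
    x0 = np.linalg.solve(a, b)
    x1 = np.linalg.solve(a, c)

    node = model.nodes[d]
    e_lo = min(nd.e_leak for nd in model.nodes)
    v = np.arange(e_lo - 20.0, params.e_nmda + 20.0, DENSE_DV)
    g_n = params.n_syn * params.g_unit * p * mg_block(v, params)
    res = (
        node.g_leak * (v - node.e_leak)
        + node.g_inh * (v - node.e_inh)
        + g_n * (v - params.e_nmda)
    )
    for k, ga in ((d - 1, model.axial[d - 1] if d > 0 else None),
                  (d + 1, model.axial[d] if d < n - 1 else None)):
        if ga is None:
            continue
        xk = x0[pos[k]] + x1[pos[k]] * v
        res += ga * (v - xk)
    sign = np.sign(res)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise RuntimeError("no root on dense grid")
    roots = 0.5 * (v[idx] + v[idx + 1])
    rest = model.resting_potentials()[d]
    return float(roots[np.argmin(np.abs(roots - rest))])


def threshold_by_exhaustive_scan(comp: SingleCompartment, params: NMDAParams, n_max: int) -> int:
    """Threshold channel count located by the largest jump of the dense-grid
    equilibrium over an exhaustive integer scan."""
    volts = [comp.v_rest]
    for n in range(1, n_max + 1):
        volts.append(dense_grid_vm(comp, params.with_n_syn(float(n))))
    jumps = np.diff(volts)
    return int(np.argmax(jumps)) + 1


def origin_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and its R^2 (about zero)."""
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    return slope, 1.0 - ss_res / ss_tot
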