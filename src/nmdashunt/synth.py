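"""Seeded generators of slice-like I/O curves with known ground truth.

The generative model emulates the i/o curves measured at the soma in slice
experiments: responses rise linearly with stimulus strength below the NMDA
spike threshold, jump onto a logistic (sigmoidal) branch at threshold, and
saturate at the spike height. Measurement noise is i.i.d. Gaussian on the
peak responses. Inhibition conditions are emulated by multiplicative shifts
of the threshold (with the subthreshold slope stretched correspondingly) and
of the height, exactly the two axes of the effect plane used to summarize
slice and model data.

Every generator takes an explicit seed; identical seeds give identical
curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from .io_curves import IOCurve

__all__ = ["IOTruth", "PairedTruth", "gen_io", "gen_pair"]


@dataclass(frozen=True)
class IOTruth:
    """Ground-truth i/o curve parameters.

    The subthreshold line ``sub_slope * s`` holds for stimuli below
    ``s_half``; from ``s_half`` on, the response follows the logistic
    ``v_max / (1 + exp(-(s - s_half) / k))``. Defaults place the threshold
    mid-grid with a sigmoid width comparable to the level spacing, so the
    suprathreshold jump (not the sigmoid's own rise) marks the threshold, as
    in recorded NMDA-spike i/o curves.
    """

    sub_slope: float = 0.5  # mV per stimulus unit
    v_max: float = 20.0  # mV
    s_half: float = 8.0  # stimulus units
    k: float = 1.0  # stimulus units
    noise_sd: float = 0.3  # mV
    n_levels: int = 12
    s_max: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_levels < 5:
            raise ValueError("need at least 5 stimulus levels")
        if self.k <= 0 or self.v_max <= 0 or self.s_max <= 0:
            raise ValueError("k, v_max and s_max must be positive")

    @property
    def spacing(self) -> float:
        return self.s_max / self.n_levels

    def levels(self) -> np.ndarray:
        return np.linspace(self.spacing, self.s_max, self.n_levels)

    def model(self, stimulus) -> np.ndarray:
        s = np.asarray(stimulus, dtype=float)
        sigmoid = self.v_max / (1.0 + np.exp(-(s - self.s_half) / self.k))
        return np.where(s < self.s_half, self.sub_slope * s, sigmoid)


@dataclass(frozen=True)
class PairedTruth:
    """A control truth plus the inhibition-induced effect to apply.

    The test condition multiplies the threshold by ``1 + d_threshold_pct/100``
    (dividing the subthreshold slope by the same factor, as a shunt stretches
    the subthreshold limb) and the height by ``1 + d_height_pct/100``.
    """

    control: IOTruth
    d_threshold_pct: float = 0.0
    d_height_pct: float = 0.0
    seed: int = 0

    def test_truth(self) -> IOTruth:
        ft = 1.0 + self.d_threshold_pct / 100.0
        fh = 1.0 + self.d_height_pct / 100.0
        if ft <= 0 or fh <= 0:
            raise ValueError("effects must keep threshold and height positive")
        return replace(
            self.control,
            s_half=self.control.s_half * ft,
            sub_slope=self.control.sub_slope / ft,
            v_max=self.control.v_max * fh,
        )


def gen_io(truth: IOTruth, condition: str = "control") -> IOCurve:
    """One noisy i/o curve drawn from the ground-truth model."""
    rng = np.random.default_rng(truth.seed)
    s = truth.levels()
    r = truth.model(s)
    if truth.noise_sd > 0:
        r = r + rng.normal(0.0, truth.noise_sd, size=s.shape)
    return IOCurve(
        stimulus=s,
        response=r,
        condition=condition,
        meta={"truth": asdict(truth)},
    )


def gen_pair(paired: PairedTruth) -> tuple[IOCurve, IOCurve]:
    """A (control, inhibited) curve pair on a shared stimulus grid.

    The grid keeps the control level spacing but is extended to cover twice
    the larger of the two thresholds, so shifted sigmoids stay inside the
    sampled range. The applied ground-truth effect is echoed in both curves'
    ``meta``.
    """
    ctrl_truth = paired.control
    test_truth = paired.test_truth()
    spacing = ctrl_truth.spacing
    s_max = max(
        ctrl_truth.s_max,
        2.0 * max(ctrl_truth.s_half, test_truth.s_half) + 2.0 * ctrl_truth.k,
    )
    n_levels = max(ctrl_truth.n_levels, math.ceil(s_max / spacing))
    grid = dict(n_levels=n_levels, s_max=n_levels * spacing)
    seeds = np.random.SeedSequence(paired.seed).spawn(2)
    ctrl = gen_io(
        replace(ctrl_truth, seed=int(seeds[0].generate_state(1)[0] % 2**31), **grid),
        condition="control",
    )
    test = gen_io(
        replace(test_truth, seed=int(seeds[1].generate_state(1)[0] % 2**31), **grid),
        condition="inhibited",
    )
    effect = {
        "d_threshold_pct": paired.d_threshold_pct,
        "d_height_pct": paired.d_height_pct,
        "seed": paired.seed,
    }
    ctrl.meta["effect"] = effect
    test.meta["effect"] = effect
    return ctrl, test


def write_truth_sidecar(truth, path) -> None:
    """Echo a generator's ground truth next to its CSV output."""
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
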