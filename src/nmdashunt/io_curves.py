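"""Quantification of input-output curves: piecewise linear + logistic fits.

An I/O curve records the peak depolarization at a site as a function of a
graded excitatory stimulus (uncaging laser intensity, channel count, or
synapse count). NMDA-spiking dendrites produce a characteristic shape: a
shallow linear rise below threshold, an abrupt jump at the spike threshold,
and a saturating plateau. The analysis mirrors the standard slice protocol:

* the breakpoint (raw threshold) is the stimulus level with the maximum
  first difference in the responses;
* levels below the breakpoint are fitted with a line through the origin;
* levels at and above the breakpoint are fitted with a three-parameter
  logistic ``v_max / (1 + exp(-(s - s_half) / k))``.

The fitted spike threshold is ``s_half`` (the stimulus at the steepest slope
of the sigmoid, exactly its midpoint for this parameterization) and the spike
height is the asymptote ``v_max``. Inhibition conditions are compared to a
no-inhibition control via % changes of threshold, height, and subthreshold
slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "IOCurve",
    "PiecewiseSigmoidFit",
    "EffectSummary",
    "DegenerateCurveError",
    "detect_breakpoint",
    "is_degenerate",
    "fit_io",
    "compare",
]

#: A curve counts as spike-free when the largest response jump is below this
#: multiple of the median jump.
DEGENERATE_JUMP_FACTOR = 2.0
MIN_POINTS = 5


class DegenerateCurveError(ValueError):
    """The curve has no detectable spike jump (or a degenerate control fit)."""


@dataclass(frozen=True)
class IOCurve:
    """Stimulus levels vs. peak depolarization (mV above rest)."""

    stimulus: np.ndarray
    response: np.ndarray
    condition: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.stimulus, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if s.ndim != 1 or s.shape != r.shape:
            raise ValueError("stimulus and response must be matching 1-D arrays")
        if not np.all(np.diff(s) > 0):
            raise ValueError("stimulus levels must be strictly increasing")
        object.__setattr__(self, "stimulus", s)
        object.__setattr__(self, "response", r)

    def __len__(self) -> int:
        return len(self.stimulus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus": self.stimulus,
                "response_mV": self.response,
                "condition": self.condition,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "IOCurve":
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df.sort_values("stimulus")
        return cls(
            stimulus=df["stimulus"].to_numpy(float),
            response=df["response_mV"].to_numpy(float),
            condition=condition or str(df["condition"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "IOCurve":
        return cls.from_frame(pd.read_csv(path), condition=condition)


@dataclass(frozen=True)
class PiecewiseSigmoidFit:
    """Result of the piecewise linear + logistic fit.

    ``threshold`` is ``s_half`` and ``height`` is ``v_max``. ``flags`` lists
    caveats (``"degenerate"``: no spike jump; ``"fixed_k"``: too few
    suprathreshold points so the width was pinned; ``"no_convergence"``).
    """

    sub_slope: float
    v_max: float
    s_half: float
    k: float
    rss: float
    breakpoint_index: int
    break_stimulus: float = float("nan")
    flags: tuple[str, ...] = ()

    @property
    def threshold(self) -> float:
        return self.s_half

    @property
    def height(self) -> float:
        return self.v_max

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    @property
    def converged(self) -> bool:
        return "no_convergence" not in self.flags and not self.degenerate

    def predict(self, stimulus) -> np.ndarray:
        """Fitted piecewise curve: line below the breakpoint, logistic above."""
        s = np.asarray(stimulus, dtype=float)
        sigmoid = self.v_max / (1.0 + np.exp(-(s - self.s_half) / self.k))
        if not np.isfinite(self.break_stimulus):
            return self.sub_slope * s
        return np.where(s < self.break_stimulus, self.sub_slope * s, sigmoid)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class EffectSummary:
    """% changes of an inhibited fit relative to a control fit."""

    d_threshold_pct: float
    d_height_pct: float
    d_subslope_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def _first_differences(curve: IOCurve) -> np.ndarray:
    return np.diff(curve.response)


def is_degenerate(curve: IOCurve, factor: float = DEGENERATE_JUMP_FACTOR) -> bool:
    """True when no response jump stands out: the curve looks spike-free.

    A spike registers as an *interior* first difference that dwarfs the
    typical level-to-level increment. Purely linear curves (all increments
    equal) and concave saturating curves (largest increment first, as when
    NMDA conductances are blocked) both count as spike-free.
    """
    d = _first_differences(curve)
    if int(np.argmax(d)) == 0:
        return True
    med = float(np.median(d))
    return not np.max(d) > factor * max(med, 0.0)


def detect_breakpoint(curve: IOCurve, factor: float = DEGENERATE_JUMP_FACTOR) -> int:
    """Index of the first suprathreshold level (maximum raw response jump).

    Ties are broken toward the lower stimulus. Raises
    :class:`DegenerateCurveError` when no jump stands out against the typical
    level-to-level increment (e.g. a perfectly linear, spike-free curve).
    """
    if len(curve) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(curve)}")
    if is_degenerate(curve, factor):
        raise DegenerateCurveError("no spike jump detected in the i/o curve")
    return int(np.argmax(_first_differences(curve))) + 1


def _logistic_resid(theta, s, r):
    v_max, s_half, k = theta
    return v_max / (1.0 + np.exp(-(s - s_half) / k)) - r


def _fit_logistic(s: np.ndarray, r: np.ndarray, n_starts: int = 5, s_half_lo: float | None = None):
    """Bounded multi-start least squares for the 3-parameter logistic.

    ``s_half`` is constrained to [``s_half_lo``, max stimulus]: the spike
    threshold cannot lie below the last subthreshold level, which keeps the
    midpoint identified even for jump-shaped curves whose suprathreshold
    points are all near saturation. Starts are seeded from data quantiles, so
    repeated fits of the same data are bit-for-bit identical.
    """
    spacing = float(np.median(np.diff(s))) if len(s) > 1 else 1.0
    if s_half_lo is None:
        s_half_lo = s[0] - 2 * (s[-1] - s[0] + spacing)
    # the sigmoid width is bounded by the level spacing: the spike transition
    # is at most a couple of levels wide, and an unbounded width lets the fit
    # chase slow post-spike creep with an inflated asymptote
    lo = [1e-9, s_half_lo, 1e-6 * spacing]
    hi = [10.0 * max(r.max(), 1e-9), s[-1], 2.0 * spacing]
    hi = [max(h, l + 1e-9) for h, l in zip(hi, lo)]
    qs = np.linspace(0.05, 0.75, n_starts)
    best = None
    for q in qs:
        x0 = np.clip(
            [max(r.max(), 1e-6), float(np.quantile(s, q)), max(spacing, 1e-3)],
            np.asarray(lo) + 1e-12,
            hi,
        )
        try:
            res = least_squares(
                _logistic_resid, x0, args=(s, r), bounds=(lo, hi), method="trf"
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    return best


def fit_io(curve: IOCurve, n_starts: int = 5) -> PiecewiseSigmoidFit:
    """Piecewise linear + logistic fit of an I/O curve.

    Subthreshold levels get a least-squares line through the origin;
    suprathreshold levels (breakpoint included) get the logistic. With fewer
    than 3 suprathreshold points the logistic width ``k`` is fixed to half
    the level spacing and the fit is flagged ``"fixed_k"``.
    """
    flags: list[str] = []
    try:
        bp = detect_breakpoint(curve)
    except DegenerateCurveError:
        s, r = curve.stimulus, curve.response
        slope = float(np.dot(s, r) / np.dot(s, s))
        return PiecewiseSigmoidFit(
            sub_slope=slope,
            v_max=float("nan"),
            s_half=float("nan"),
            k=float("nan"),
            rss=float("inf"),
            breakpoint_index=-1,
            flags=("degenerate",),
        )
    s_sub, r_sub = curve.stimulus[:bp], curve.response[:bp]
    s_sup, r_sup = curve.stimulus[bp:], curve.response[bp:]
    denom = float(np.dot(s_sub, s_sub))
    if denom > 0:
        sub_slope = float(np.dot(s_sub, r_sub) / denom)
    else:
        sub_slope = float("nan")
        flags.append("no_subthreshold")
    spacing = float(np.median(np.diff(curve.stimulus)))
    if len(s_sup) < 3:
        flags.append("fixed_k")
        k_fixed = 0.5 * spacing

        def resid(theta, s, r):
            v_max, s_half = theta
            return v_max / (1.0 + np.exp(-(s - s_half) / k_fixed)) - r

        x0 = [max(r_sup.max(), 1e-6), float(s_sup[0])]
        res = least_squares(
            resid,
            x0,
            args=(s_sup, r_sup),
            bounds=([1e-9, float(curve.stimulus[bp - 1])], [np.inf, float(curve.stimulus[-1])]),
        )
        v_max, s_half = res.x
        k = k_fixed
        rss = float(np.sum(res.fun**2))
        if not res.success:
            flags.append("no_convergence")
            rss = float("inf")
    else:
        best = _fit_logistic(
            s_sup, r_sup, n_starts=n_starts, s_half_lo=float(curve.stimulus[bp - 1])
        )
        if best is None:
            flags.append("no_convergence")
            v_max = s_half = k = float("nan")
            rss = float("inf")
        else:
            rss, res = best
            v_max, s_half, k = (float(x) for x in res.x)
            if not res.success:
                flags.append("no_convergence")
                rss = float("inf")
    return PiecewiseSigmoidFit(
        sub_slope=sub_slope,
        v_max=float(v_max),
        s_half=float(s_half),
        k=float(k),
        rss=rss,
        breakpoint_index=bp,
        break_stimulus=float(curve.stimulus[bp]),
        flags=tuple(flags),
    )


def compare(control: PiecewiseSigmoidFit, test: PiecewiseSigmoidFit) -> EffectSummary:
    """% changes of threshold, height and subthreshold slope vs. control."""
    if control.degenerate or not np.isfinite(control.s_half):
        raise DegenerateCurveError("control fit is degenerate")
    return EffectSummary(
        d_threshold_pct=100.0 * (test.s_half / control.s_half - 1.0),
        d_height_pct=100.0 * (test.v_max / control.v_max - 1.0),
        d_subslope_pct=100.0 * (test.sub_slope / control.sub_slope - 1.0),
    )
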