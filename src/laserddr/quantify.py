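"""Quantification of recruitment from fluorescence time-lapse stacks.

The normalization follows the standard damage-site ratio: the mean
intensity over the damage ROI is divided by the mean over a nucleoplasmic
background ROI in the same nucleus, minus one, so 0 means no enrichment
and 1 means a two-fold signal at the stripe.  Recruitment is called when
the normalized trace exceeds a detection level on a minimum number of
consecutive frames inside the factor-specific monitoring window (15 min
for 53BP1-type reporters, 6 min for TRF2-type).  The per-power detection
threshold is the lowest power at which strictly more than half the cells
are called recruited.

Kinetic fits use two fixed model classes:

* ``saturating_rise``:   y(t) = A (1 - exp(-t/tau_on)) + b
* ``transient_pulse``:   y(t) = A (exp(-t/tau_off) - exp(-t/tau_on)) + b,
  with tau_off > tau_on; its peak sits at the closed-form
  t* = tau_on tau_off ln(tau_off/tau_on) / (tau_off - tau_on).

Group comparison is a seeded two-sided permutation test on the difference
of means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InvalidArgumentError,
)

__all__ = [
    "RoiSpec",
    "IntensityTrace",
    "RecruitmentCall",
    "KineticsFit",
    "extract_trace",
    "relative_increase",
    "call_recruitment",
    "threshold_power",
    "fit_kinetics",
    "transient_peak_time",
    "compare_groups",
]

Rect = tuple[int, int, int, int]  # (row0, row1, col0, col1), 0-based half-open


@dataclass(frozen=True)
class RoiSpec:
    """Damage-site and nucleoplasmic background regions.

    Rectangles are 0-based, row-major, half-open ``(row0, row1, col0,
    col1)``.  Boolean masks, when given, take precedence over rectangles.
    The two regions must be non-empty and disjoint; the background ROI is
    user-supplied (no auto-segmentation).
    """

    damage_rect: Rect | None = None
    background_rect: Rect | None = None
    damage_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None
    pre_damage_frames: int = 0

    def __post_init__(self) -> None:
        if self.pre_damage_frames < 0:
            raise InvalidArgumentError("pre_damage_frames must be >= 0")
        if self.damage_rect is None and self.damage_mask is None:
            raise InvalidArgumentError("damage ROI missing (rect or mask)")
        if self.background_rect is None and self.background_mask is None:
            raise InvalidArgumentError("background ROI missing (rect or mask)")

    def resolve(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (damage_mask, background_mask) as boolean arrays of
        ``shape``, validating bounds, non-emptiness and disjointness."""
        dmg = self._as_mask(self.damage_mask, self.damage_rect, shape, "damage")
        bkg = self._as_mask(self.background_mask, self.background_rect, shape, "background")
        if np.any(dmg & bkg):
            raise InvalidArgumentError("damage and background ROIs overlap")
        return dmg, bkg

    @staticmethod
    def _as_mask(
        mask: np.ndarray | None, rect: Rect | None, shape: tuple[int, int], label: str
    ) -> np.ndarray:
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise InvalidArgumentError(f"{label} mask shape {mask.shape} != image {shape}")
        else:
            r0, r1, c0, c1 = rect
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise InvalidArgumentError(f"{label} rect {rect} out of bounds for {shape}")
            mask = np.zeros(shape, dtype=bool)
            mask[r0:r1, c0:c1] = True
        if not mask.any():
            raise InvalidArgumentError(f"{label} ROI is empty")
        return mask


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame ROI means and the normalized damage-site contrast."""

    times_min: np.ndarray
    damage_mean: np.ndarray
    background_mean: np.ndarray
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        d = np.asarray(self.damage_mean, dtype=float)
        b = np.asarray(self.background_mean, dtype=float)
        if not (len(t) == len(d) == len(b)):
            raise InvalidArgumentError("trace arrays must have equal length")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(b <= 0):
            raise DegenerateInputError("background mean must be > 0 on every frame")
        norm = d / b - 1.0 if self.normalized is None else np.asarray(self.normalized, float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "damage_mean", d)
        object.__setattr__(self, "background_mean", b)
        object.__setattr__(self, "normalized", norm)

    def __len__(self) -> int:
        return len(self.times_min)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "damage_mean": self.damage_mean,
                "background_mean": self.background_mean,
                "normalized": self.normalized,
            }
        )


@dataclass(frozen=True)
class RecruitmentCall:
    recruited: bool
    onset_time_min: float | None
    peak_time_min: float
    peak_value: float
    window_min: float

    def __post_init__(self) -> None:
        if self.window_min <= 0:
            raise InvalidArgumentError("window must be > 0")
        if self.onset_time_min is not None and self.onset_time_min > self.peak_time_min:
            raise InvalidArgumentError("onset cannot be after the peak")


@dataclass(frozen=True)
class KineticsFit:
    model: str
    amplitude: float
    tau_on_min: float
    baseline: float
    rss: float
    tau_off_min: float | None = None

    @property
    def peak_time_min(self) -> float | None:
        """Analytic peak time for the transient pulse; None for the rise."""
        if self.model != "transient_pulse":
            return None
        return transient_peak_time(self.tau_on_min, self.tau_off_min)


def extract_trace(
    stack: np.ndarray,
    roi: RoiSpec,
    times_min: Sequence[float] | None = None,
) -> IntensityTrace:
    """Per-frame arithmetic ROI means and the ratio-minus-one contrast.

    ``stack`` is (T, H, W); ``times_min`` defaults to the frame index.
    The normalized trace is invariant under any global multiplicative
    rescaling of the stack (camera gain, photobleaching applied uniformly).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise InvalidArgumentError("stack must be (T, H, W) with >= 2 frames")
    dmg, bkg = roi.resolve(stack.shape[1:])
    times = np.arange(stack.shape[0], dtype=float) if times_min is None else np.asarray(times_min, float)
    if len(times) != stack.shape[0]:
        raise InvalidArgumentError("times length must match frame count")
    damage_mean = stack[:, dmg].mean(axis=1)
    background_mean = stack[:, bkg].mean(axis=1)
    return IntensityTrace(times, damage_mean, background_mean)


def relative_increase(trace: IntensityTrace, pre_damage_frames: int) -> float:
    """(peak post-damage signal - pre-damage signal) / pre-damage signal,
    computed on the raw damage-ROI mean."""
    if pre_damage_frames < 1:
        raise InvalidArgumentError("need at least one pre-damage frame")
    if pre_damage_frames >= len(trace):
        raise InvalidArgumentError("need at least one post-damage frame")
    before = trace.damage_mean[:pre_damage_frames].mean()
    if before <= 0:
        raise DegenerateInputError("pre-damage mean is not positive")
    peak = trace.damage_mean[pre_damage_frames:].max()
    return float((peak - before) / before)


def call_recruitment(
    trace: IntensityTrace,
    window_min: float,
    detection_level: float = 0.1,
    min_consecutive: int = 2,
) -> RecruitmentCall:
    """Score one cell as recruited or not inside the monitoring window.

    Recruited means the normalized contrast strictly exceeds
    ``detection_level`` on at least ``min_consecutive`` consecutive frames
    with 0 <= t <= window; the onset is the first frame of the first such
    run.  Raising the detection level can only flip recruited -> not.
    """
    if window_min <= 0:
        raise InvalidArgumentError("window must be > 0")
    in_window = (trace.times_min >= 0) & (trace.times_min <= window_min)
    if not in_window.any():
        raise InvalidArgumentError("trace does not cover the detection window")
    t = trace.times_min[in_window]
    y = trace.normalized[in_window]
    above = y > detection_level
    onset: float | None = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            onset = float(t[i - min_consecutive + 1])
            break
    i_peak = int(np.argmax(y))
    return RecruitmentCall(
        recruited=onset is not None,
        onset_time_min=onset,
        peak_time_min=float(t[i_peak]),
        peak_value=float(y[i_peak]),
        window_min=float(window_min),
    )


def threshold_power(
    per_power_calls: Mapping[float, Sequence[RecruitmentCall | bool]],
    majority_rule: float = 0.5,
) -> float | None:
    """Lowest tabulated power whose recruited fraction strictly exceeds
    ``majority_rule``; None when no power qualifies."""
    if not per_power_calls:
        raise InvalidArgumentError("no powers given")
    for power in sorted(per_power_calls):
        calls = per_power_calls[power]
        if len(calls) == 0:
            raise InvalidArgumentError(f"no cells at power {power}")
        frac = np.mean([c.recruited if isinstance(c, RecruitmentCall) else bool(c) for c in calls])
        if frac > majority_rule:
            return power
    return None


def _saturating_rise(t, a, tau_on, b):
    return a * (1.0 - np.exp(-t / tau_on)) + b


def _transient_pulse(t, a, tau_on, dtau, b):
    tau_off = tau_on + dtau
    return a * (np.exp(-t / tau_off) - np.exp(-t / tau_on)) + b


def transient_peak_time(tau_on: float, tau_off: float) -> float:
    """Closed-form peak time of the difference-of-exponentials pulse."""
    if not 0 < tau_on < tau_off:
        raise InvalidArgumentError("need 0 < tau_on < tau_off")
    return tau_on * tau_off * math.log(tau_off / tau_on) / (tau_off - tau_on)


def fit_kinetics(
    trace: IntensityTrace,
    model: str = "saturating_rise",
    t_start: float = 0.0,
) -> KineticsFit:
    """Least-squares fit of the normalized trace to one kinetic model.

    Frames with t >= ``t_start`` are used with time re-zeroed at
    ``t_start`` (pass the known irradiation/onset delay to fit the
    post-onset response).  Initialization is deterministic: amplitude from
    the data range, tau from time-to-half-max, baseline from the first
    frame; no random restarts.
    """
    if model not in ("saturating_rise", "transient_pulse"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    sel = trace.times_min >= t_start
    t = trace.times_min[sel] - t_start
    y = trace.normalized[sel]
    if len(t) < 5:
        raise InvalidArgumentError("need >= 5 frames at t >= t_start")

    span = float(y.max() - y.min())
    a0 = max(span, 1e-6)
    b0 = float(y[0])
    # time at which the trace first reaches half its range above baseline
    half = b0 + 0.5 * span
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if len(above) and t[above[0]] > 0 else float(t[-1]) / 4
    tau0 = max(t_half / math.log(2.0), 1e-3)

    try:
        if model == "saturating_rise":
            popt, _ = curve_fit(
                _saturating_rise,
                t,
                y,
                p0=(a0, tau0, b0),
                bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            a, tau_on, b = popt
            resid = y - _saturating_rise(t, *popt)
            return KineticsFit(
                model=model,
                amplitude=float(a),
                tau_on_min=float(tau_on),
                baseline=float(b),
                rss=float(resid @ resid),
            )
        # transient pulse: parametrize tau_off = tau_on + dtau to keep
        # tau_off > tau_on without a nonlinear constraint
        popt, _ = curve_fit(
            _transient_pulse,
            t,
            y,
            p0=(2.0 * a0, tau0 / 2, 2.0 * tau0, b0),
            bounds=([0, 1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, tau_on, dtau, b = popt
        resid = y - _transient_pulse(t, *popt)
        return KineticsFit(
            model=model,
            amplitude=float(a),
            tau_on_min=float(tau_on),
            tau_off_min=float(tau_on + dtau),
            baseline=float(b),
            rss=float(resid @ resid),
        )
    except RuntimeError as exc:  # scipy signals non-convergence this way
        raise FitFailureError(f"{model} fit did not converge: {exc}") from exc


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided permutation p-value on the difference of group means.

    Uses the add-one estimator (obs counts as one permutation), so the
    p-value is in (0, 1] and identical groups give exactly 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("need >= 2 values per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    if np.all(pool == pool[0]):
        return 1.0
    n_a = len(a)
    # vectorized permutations: argsort of uniforms gives random orderings
    order = np.argsort(rng.random((n_permutations, len(pool))), axis=1)
    shuffled = pool[order]
    diffs = np.abs(shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1))
    return float((np.sum(diffs >= obs - 1e-12) + 1) / (n_permutations + 1))
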