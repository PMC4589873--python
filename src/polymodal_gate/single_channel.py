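"""Single-channel idealization, open probability and unitary conductance.

Records are idealized by half-amplitude threshold crossing against a
baseline estimated from the all-points histogram; events shorter than a
configurable dead time are merged into their neighbours.  The unitary
amplitude may be supplied or estimated ("auto") from a two-Gaussian fit of
the all-points histogram.  Open probability is NPo/N with NPo the
level-weighted open time; unitary conductance is the slope of the i-V
relationship, fitted separately for inward and outward limbs because
permeation effects can be side-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from polymodal_gate.dose_response import welch_t_test, SIGNIFICANCE_LEVEL

__all__ = [
    "SingleChannelRecord",
    "Idealization",
    "Dwell",
    "SingleChannelError",
    "idealize",
    "open_probability_sc",
    "fit_unitary_iv",
]


class SingleChannelError(ValueError):
    """Raised on invalid single-channel inputs."""


@dataclass(frozen=True)
class SingleChannelRecord:
    """Raw single-channel current samples at a fixed holding voltage."""

    current: np.ndarray  # pA
    sampling_rate: float  # Hz
    voltage: float = 80.0  # mV
    condition: str = "capsaicin"
    channel_count: int = 1

    def __post_init__(self) -> None:
        cur = np.asarray(self.current, float)
        if cur.ndim != 1 or cur.size == 0 or not np.isfinite(cur).all():
            raise SingleChannelError("current must be a finite 1-D array")
        if not (self.sampling_rate > 0):
            raise SingleChannelError("sampling rate must be > 0")
        if self.channel_count < 1:
            raise SingleChannelError("channel count must be >= 1")
        object.__setattr__(self, "current", cur)

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate


@dataclass(frozen=True)
class Dwell:
    state: str  # "closed" | "open"
    duration: float  # s


@dataclass(frozen=True)
class Idealization:
    """Open/closed dwell sequence derived from a record."""

    dwells: tuple[Dwell, ...]
    unitary_amplitude: float  # pA
    baseline: float  # pA
    po: float
    event_count: int  # number of opening events (open dwells)
    open_time: float  # s
    total_time: float  # s

    def __post_init__(self) -> None:
        if any(d.duration <= 0 for d in self.dwells):
            raise SingleChannelError("dwell durations must be > 0")
        if not (0.0 <= self.po <= 1.0):
            raise SingleChannelError("Po must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(d) for d in self.dwells])


def _two_gaussians(x, a1, mu1, s1, a2, mu2, s2):
    g = lambda a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2)
    return g(a1, mu1, s1) + g(a2, mu2, s2)


def _auto_levels(current: np.ndarray) -> tuple[float, float]:
    """Baseline and unitary amplitude from a two-Gaussian histogram fit."""
    counts, edges = np.histogram(current, bins=200)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    min_sep = max(int(round(0.2 * (current.max() - current.min()) / width)), 1)
    # pad so level spikes in the first/last bin register as peaks, and
    # require real prominence so noise wiggles do not mimic a second level
    padded = np.r_[0, counts, 0]
    peaks, _ = find_peaks(
        padded,
        height=0.02 * counts.max(),
        prominence=0.02 * counts.max(),
        distance=min_sep,
    )
    peaks = peaks - 1
    if peaks.size < 2:
        raise SingleChannelError(
            "all-points histogram looks unimodal; pass an explicit unitary amplitude"
        )
    # two most populated peaks
    top2 = peaks[np.argsort(counts[peaks])[-2:]]
    mu_init = np.sort(centers[top2])
    if mu_init[1] - mu_init[0] < 0.1 * (current.max() - current.min()):
        raise SingleChannelError(
            "all-points histogram looks unimodal; pass an explicit unitary amplitude"
        )
    s_init = max(current.std() / 10, width)
    p0 = [
        counts[top2].max(), mu_init[0], s_init,
        counts[top2].max(), mu_init[1], s_init,
    ]
    try:
        popt, _ = curve_fit(_two_gaussians, centers, counts, p0=p0, maxfev=5000)
        mu = np.sort([popt[1], popt[4]])
        # genuinely bimodal only when the levels are resolved: the means
        # must be separated by several component widths
        if mu[1] - mu[0] < 3.0 * (abs(popt[2]) + abs(popt[5])):
            raise SingleChannelError(
                "all-points histogram looks unimodal; "
                "pass an explicit unitary amplitude"
            )
    except RuntimeError:
        mu = mu_init
    # closed level is the one nearer zero current
    if abs(mu[0]) <= abs(mu[1]):
        baseline, open_level = mu[0], mu[1]
    else:
        baseline, open_level = mu[1], mu[0]
    return float(baseline), float(open_level - baseline)


def _merge_short_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Merge runs shorter than ``min_len`` samples into their neighbours."""
    if min_len <= 1:
        return states
    states = states.copy()
    while True:
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [states.size]])
        lengths = ends - starts
        if lengths.size <= 1:
            return states
        short = np.flatnonzero(lengths < min_len)
        short = short[(short > 0) & (short < lengths.size - 1)]
        if short.size == 0:
            return states
        k = short[np.argmin(lengths[short])]
        states[starts[k] : ends[k]] = states[starts[k] - 1]


def idealize(
    record: SingleChannelRecord,
    unitary_amplitude: float | str = "auto",
    dead_time_samples: int = 2,
) -> Idealization:
    """Half-amplitude threshold idealization of a single-channel record.

    The baseline is estimated from the all-points histogram.  With
    ``unitary_amplitude="auto"`` both levels come from a two-Gaussian
    histogram fit (raising an error when the histogram is unimodal).  Events
    shorter than ``dead_time_samples`` are merged, which never increases the
    event count.
    """
    cur = record.current
    fs = record.sampling_rate
    if unitary_amplitude == "auto":
        baseline, amp = _auto_levels(cur)
    else:
        amp = float(unitary_amplitude)
        if amp == 0:
            raise SingleChannelError("unitary amplitude must be non-zero")
        counts, edges = np.histogram(cur, bins=200)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mode = centers[counts.argmax()]
        # the histogram mode is whichever level dominates; it is the closed
        # level when nearer 0 than one amplitude away, else the open level
        baseline = mode if abs(mode) < abs(mode - amp) else mode - amp
    threshold = baseline + amp / 2.0
    is_open = cur > threshold if amp > 0 else cur < threshold
    states = _merge_short_runs(is_open.astype(np.int8), dead_time_samples)

    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    dwells = tuple(
        Dwell(state="open" if states[s] else "closed", duration=(e - s) / fs)
        for s, e in zip(starts, ends)
    )
    open_time = float(states.sum() / fs)
    total = float(states.size / fs)
    return Idealization(
        dwells=dwells,
        unitary_amplitude=amp,
        baseline=float(baseline),
        po=open_time / total,
        event_count=sum(1 for d in dwells if d.state == "open"),
        open_time=open_time,
        total_time=total,
    )


def open_probability_sc(ideal: Idealization, channel_count: int = 1) -> float:
    """Per-channel open probability NPo/N from an idealization."""
    if channel_count < 1:
        raise SingleChannelError("channel count must be >= 1")
    npo = ideal.open_time / ideal.total_time
    return npo / channel_count


def fit_unitary_iv(
    points: pd.DataFrame,
    split_sides: bool = True,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> dict:
    """Unitary conductance per condition from i-V points, with comparison.

    ``points`` needs columns ``condition``, ``patch``, ``voltage_mV``,
    ``amplitude_pA``.  Conductance (pS) is the slope of an ordinary linear
    regression of unitary current on voltage, fitted separately for inward
    (V < 0) and outward (V > 0) limbs when ``split_sides``.  Per-patch
    slopes feed a Welch t-test between exactly two conditions.
    """
    required = {"condition", "patch", "voltage_mV", "amplitude_pA"}
    if not required <= set(points.columns):
        raise SingleChannelError(f"points table needs columns {sorted(required)}")
    sides = (
        {"inward": points["voltage_mV"] < 0, "outward": points["voltage_mV"] > 0}
        if split_sides
        else {"all": np.ones(len(points), dtype=bool)}
    )
    results: dict[str, dict] = {}
    per_patch: dict[str, dict[str, list[float]]] = {s: {} for s in sides}
    for side, mask in sides.items():
        sub = points[mask]
        results[side] = {}
        for cond, grp in sub.groupby("condition"):
            slopes = []
            for _, patch_grp in grp.groupby("patch"):
                v = patch_grp["voltage_mV"].to_numpy(float)
                i = patch_grp["amplitude_pA"].to_numpy(float)
                if np.unique(v).size < 3:
                    raise SingleChannelError(
                        f"condition {cond!r}: need >= 3 voltages per patch"
                    )
                slope = np.polyfit(v, i, 1)[0]  # pA/mV = nS
                slopes.append(1000.0 * slope)  # pS
            per_patch[side][str(cond)] = slopes
            results[side][str(cond)] = {
                "conductance_pS": float(np.mean(slopes)),
                "conductance_sem_pS": (
                    float(np.std(slopes, ddof=1) / math.sqrt(len(slopes)))
                    if len(slopes) > 1
                    else None
                ),
                "n_patches": len(slopes),
            }
        conds = sorted(per_patch[side])
        if len(conds) == 2:
            results[side]["comparison"] = welch_t_test(
                per_patch[side][conds[0]], per_patch[side][conds[1]], alpha=alpha
            )
            results[side]["comparison"]["conditions"] = conds
    return results
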