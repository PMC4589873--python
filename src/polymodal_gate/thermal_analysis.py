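"""Heat-activation threshold detection and heat-desensitization analysis.

Current-vs-temperature families from heat ramps are analysed on Arrhenius
axes (log10 current against reciprocal absolute temperature), where both the
leak current and the steeply temperature-dependent channel current are well
approximated by straight lines.  The activation threshold is the temperature
at which the two lines intersect, found by a continuous two-segment
piecewise-linear fit with the breakpoint chosen by exhaustive search over
interior data points (minimum SSE).  A fixed-current criterion and plain
linear axes are provided as alternatives.

Heat desensitization is quantified per patch as the ratio of the current
evoked by a 55 C temperature step to the same patch's saturating-capsaicin
current, compared between groups with the pipeline's Welch t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from polymodal_gate.dose_response import welch_t_test, SIGNIFICANCE_LEVEL

__all__ = [
    "TemperatureRampRecord",
    "ThresholdFit",
    "ThermalAnalysisError",
    "detect_threshold",
    "threshold_fixed_current",
    "normalize_heat_response",
    "desensitization_ratio",
    "read_ramp_csv",
    "write_ramp_csv",
]

KELVIN = 273.15


class ThermalAnalysisError(ValueError):
    """Raised on invalid ramp records or analysis inputs."""


@dataclass(frozen=True)
class TemperatureRampRecord:
    """Aligned time/temperature/current arrays from one heat ramp."""

    time: np.ndarray  # s
    temperature: np.ndarray  # C
    current: np.ndarray  # pA
    condition: str = "control"
    capsaicin_reference: float | None = None  # pA, saturating-capsaicin current

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        temp = np.asarray(self.temperature, float)
        cur = np.asarray(self.current, float)
        if not (t.shape == temp.shape == cur.shape) or t.ndim != 1:
            raise ThermalAnalysisError("time, temperature, current must align")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temperature", temp)
        object.__setattr__(self, "current", cur)


@dataclass(frozen=True)
class ThresholdFit:
    """Two-segment Arrhenius fit of one ramp.

    Slopes/intercepts are on the fit axes: x = 1/T_K, y = log10(I_pA) for
    ``axes="arrhenius"`` (the default), x = T_C, y = I_pA for ``"linear"``.
    ``found=False`` marks a leak-only record (no slope increase detected).
    """

    found: bool
    threshold: float | None  # C
    leak_slope: float
    leak_intercept: float
    channel_slope: float | None
    channel_intercept: float | None
    sse: float
    sse_single: float
    n_points: int
    axes: str
    breakpoint_candidates: int

    def to_dict(self) -> dict:
        return asdict(self)

    def leak_current(self, temperature) -> np.ndarray:
        """Leak current (pA) extrapolated from the leak segment."""
        temperature = np.asarray(temperature, float)
        if self.axes == "arrhenius":
            x = 1.0 / (temperature + KELVIN)
            return 10.0 ** (self.leak_intercept + self.leak_slope * x)
        return self.leak_intercept + self.leak_slope * temperature


def _segment_fit(x, y, w, b):
    """Continuous two-segment weighted LS with breakpoint at x=b.

    y = a + m_leak*(x-b) + dm*min(x-b, 0); on Arrhenius axes the channel
    segment is the small-x (hot) side, so dm is the extra (more negative)
    channel slope.
    """
    X = np.column_stack([np.ones_like(x), x - b, np.minimum(x - b, 0.0)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    return coef, float(np.sum(w * resid**2))


def detect_threshold(
    record: TemperatureRampRecord,
    axes: str = "arrhenius",
    floor_eps: float = 1e-3,
    floor_weight: float = 0.1,
    min_sse_ratio: float = 0.5,
    min_slope_ratio: float = 1.0,
    edge_points: int = 3,
    t_window: tuple[float, float] | None = None,
    refine: bool = True,
    refine_window: tuple[float, float] = (12.0, 7.0),
) -> ThresholdFit:
    """Two-segment piecewise-linear threshold fit of one ramp.

    The breakpoint is searched exhaustively over interior data points
    (``edge_points`` reserved at each end); segments are constrained to meet
    at the breakpoint so the threshold is unique.  The fit is accepted only
    when it beats a single straight line by at least ``min_sse_ratio`` in
    SSE and the channel segment is steeper than the leak segment; otherwise
    a "no-threshold" result is returned (pure-leak guard).  Non-positive
    currents are floored at ``floor_eps`` pA before the log transform and
    down-weighted by ``floor_weight``.

    With ``refine`` (default), a second fitting pass restricts the data to
    ``refine_window`` degrees below/above the first-pass threshold.  Real
    channel activation curves bend back into a plateau as open probability
    saturates, which drags a single-pass breakpoint off the leak/rise
    intersection; the refit window excludes the plateau while keeping
    enough leak on the cold side.
    """
    temp = record.temperature
    cur = record.current
    if t_window is not None:
        # restrict to the two-line regime (e.g. below Po saturation)
        keep = (temp >= t_window[0]) & (temp <= t_window[1])
        temp, cur = temp[keep], cur[keep]
    if temp.size < 20:
        raise ThermalAnalysisError("need >= 20 points")
    if temp.max() - temp.min() < 10.0:
        raise ThermalAnalysisError("ramp must span >= 10 C")
    d = np.diff(temp)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ThermalAnalysisError("temperature must be monotone in the window")
    order = np.argsort(temp)
    temp, cur = temp[order], cur[order]

    if axes == "arrhenius":
        x = 1.0 / (temp + KELVIN)
        floored = cur < floor_eps
        y = np.log10(np.maximum(cur, floor_eps))
        w = np.where(floored, floor_weight, 1.0)
        channel_steeper = lambda dm: dm < 0  # hotter = smaller x, steeper fall
    elif axes == "linear":
        x = temp.astype(float)
        y = cur.astype(float)
        w = np.ones_like(y)
        channel_steeper = lambda dm: dm < 0  # channel segment is x > b side
    else:
        raise ThermalAnalysisError(f"unknown axes {axes!r}")

    sw = np.sqrt(w)
    X1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(X1 * sw[:, None], y * sw, rcond=None)
    sse1 = float(np.sum(w * (y - X1 @ coef1) ** 2))

    candidates = np.unique(x)[edge_points:-edge_points]
    # search only breakpoints whose hot side comes out steeper: with a
    # saturating channel curve the globally best two-line split can land on
    # the rise/plateau corner, which is not an activation threshold
    best = None
    for b in candidates:
        coef, sse = _segment_fit(x, y, w, b)
        if coef[2] >= 0:
            continue
        if best is None or sse < best[2]:
            best = (b, coef, sse)
    if best is None:
        b, (a, m_leak, dm), sse2 = candidates[0], (0.0, 0.0, 0.0), sse1
        return ThresholdFit(
            found=False,
            threshold=None,
            leak_slope=float(coef1[1]),
            leak_intercept=float(coef1[0]),
            channel_slope=None,
            channel_intercept=None,
            sse=float(sse1),
            sse_single=float(sse1),
            n_points=int(x.size),
            axes=axes,
            breakpoint_candidates=int(candidates.size),
        )
    b, (a, m_leak, dm), sse2 = best

    # channel segment slope on the fit axes
    if axes == "linear":
        # channel on the hot side: refit with channel = x > b branch
        best = None
        for bb in candidates:
            X = np.column_stack(
                [np.ones_like(x), x - bb, np.maximum(x - bb, 0.0)]
            )
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            sse = float(np.sum(w * (y - X @ coef) ** 2))
            if best is None or sse < best[2]:
                best = (bb, coef, sse)
        b, (a, m_leak, dm), sse2 = best
        channel_steeper = lambda dm: dm > 0

    # a channel segment must be much steeper than the leak trend: mild leak
    # curvature alone (e.g. exponential leak on Arrhenius axes) can halve the
    # SSE without any activation being present
    accepted = (
        sse1 > 1e-12
        and sse2 < min_sse_ratio * sse1
        and channel_steeper(dm)
        and abs(dm) > min_slope_ratio * abs(m_leak)
    )
    if axes == "arrhenius":
        threshold = 1.0 / b - KELVIN
        leak_intercept = float(a - m_leak * b)  # y at x=0 for extrapolation
        channel_slope = float(m_leak + dm)
        channel_intercept = float(a - channel_slope * b)
    else:
        threshold = float(b)
        leak_intercept = float(a - m_leak * b)
        channel_slope = float(m_leak + dm)
        channel_intercept = float(a - channel_slope * b)
    fit = ThresholdFit(
        found=bool(accepted),
        threshold=float(threshold) if accepted else None,
        leak_slope=float(m_leak),
        leak_intercept=leak_intercept,
        channel_slope=channel_slope if accepted else None,
        channel_intercept=channel_intercept if accepted else None,
        sse=float(sse2),
        sse_single=float(sse1),
        n_points=int(x.size),
        axes=axes,
        breakpoint_candidates=int(candidates.size),
    )
    if refine and fit.found:
        lo, hi = fit.threshold - refine_window[0], fit.threshold + refine_window[1]
        if t_window is not None:
            lo, hi = max(lo, t_window[0]), min(hi, t_window[1])
        try:
            refit = detect_threshold(
                record,
                axes=axes,
                floor_eps=floor_eps,
                floor_weight=floor_weight,
                min_sse_ratio=min_sse_ratio,
                min_slope_ratio=min_slope_ratio,
                edge_points=edge_points,
                t_window=(lo, hi),
                refine=False,
            )
        except ThermalAnalysisError:
            refit = None
        if refit is not None and refit.found:
            return refit
    return fit


def threshold_fixed_current(
    record: TemperatureRampRecord, criterion_pA: float
) -> float | None:
    """Alternative threshold: first ramp temperature where current exceeds a
    fixed criterion.  Returns None when never crossed."""
    order = np.argsort(record.temperature)
    temp, cur = record.temperature[order], record.current[order]
    idx = np.flatnonzero(cur >= criterion_pA)
    return float(temp[idx[0]]) if idx.size else None


def normalize_heat_response(
    record: TemperatureRampRecord, threshold_fit: ThresholdFit | None = None
) -> np.ndarray:
    """Leak-corrected currents normalized by the capsaicin reference.

    The fitted leak segment (from ``detect_threshold`` unless supplied) is
    subtracted before dividing by the patch's saturating-capsaicin current.
    """
    if record.capsaicin_reference is None or not record.capsaicin_reference > 0:
        raise ThermalAnalysisError("capsaicin reference current missing or <= 0")
    if threshold_fit is None:
        threshold_fit = detect_threshold(record)
    leak = threshold_fit.leak_current(record.temperature)
    return (record.current - leak) / record.capsaicin_reference


def desensitization_ratio(
    patches: pd.DataFrame, alpha: float = SIGNIFICANCE_LEVEL
) -> dict:
    """Per-patch heat(55 C)/capsaicin current ratios and group comparison.

    ``patches`` needs columns ``patch``, ``group``, ``heat_current_pA``,
    ``capsaicin_current_pA``.  Patches with non-positive capsaicin current
    are excluded with a note.  With exactly two groups a Welch t-test on the
    ratios is reported (** at P < 0.001).
    """
    required = {"patch", "group", "heat_current_pA", "capsaicin_current_pA"}
    if not required <= set(patches.columns):
        raise ThermalAnalysisError(f"patches table needs columns {sorted(required)}")
    excluded = patches[patches["capsaicin_current_pA"] <= 0]
    kept = patches[patches["capsaicin_current_pA"] > 0].copy()
    kept["ratio"] = kept["heat_current_pA"] / kept["capsaicin_current_pA"]
    notes = [
        f"patch {p!r} excluded: non-positive capsaicin current"
        for p in excluded["patch"]
    ]
    groups = list(kept["group"].unique())
    comparison = None
    if len(groups) == 2:
        a = kept.loc[kept["group"] == groups[0], "ratio"]
        b = kept.loc[kept["group"] == groups[1], "ratio"]
        comparison = welch_t_test(a, b, alpha=alpha)
        comparison["groups"] = groups
    return {
        "ratios": kept[["patch", "group", "ratio"]].reset_index(drop=True),
        "group_means": kept.groupby("group")["ratio"].mean().to_dict(),
        "comparison": comparison,
        "notes": notes,
    }


# --- IO ---------------------------------------------------------------------


def write_ramp_csv(path, records) -> None:
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": rec.time,
                    "temp_C": rec.temperature,
                    "current_pA": rec.current,
                    "condition": rec.condition,
                    "capsaicin_reference_pA": (
                        rec.capsaicin_reference
                        if rec.capsaicin_reference is not None
                        else np.nan
                    ),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.6g")


def read_ramp_csv(path) -> list[TemperatureRampRecord]:
    df = pd.read_csv(path)
    records = []
    for cond, grp in df.groupby("condition", sort=False):
        ref = None
        if "capsaicin_reference_pA" in grp.columns:
            val = grp["capsaicin_reference_pA"].iloc[0]
            ref = float(val) if math.isfinite(val) else None
        records.append(
            TemperatureRampRecord(
                time=grp["time_s"].to_numpy(float),
                temperature=grp["temp_C"].to_numpy(float),
                current=grp["current_pA"].to_numpy(float),
                condition=str(cond),
                capsaicin_reference=ref,
            )
        )
    return records
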