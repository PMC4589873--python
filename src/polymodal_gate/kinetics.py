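"""Mono-exponential relaxation analysis and two-state binding kinetics.

Agonist wash-in and wash-out produce current relaxations

    I(t) = offset + amplitude * exp(-(t - t0) / tau)

whose time constants report on the binding scheme: for pseudo-first-order
two-state binding, 1/tau_on = kon * [L] + koff and 1/tau_off = koff, so a
weighted linear regression of 1/tau_on on concentration yields kon (slope)
and koff (intercept), and Kd = koff / kon.  The wash-out koff is the more
directly measured quantity and is the one used for Kd; the regression
intercept is retained in the report for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CurrentTrace",
    "ProtocolInterval",
    "RelaxationFit",
    "BindingKinetics",
    "KineticsError",
    "fit_relaxation",
    "estimate_rates",
    "read_trace_csv",
    "write_trace_csv",
]


class KineticsError(ValueError):
    """Raised on invalid traces, intervals or rate inputs."""


@dataclass(frozen=True)
class ProtocolInterval:
    """Annotated solution-exchange interval of a recording."""

    start: float  # s
    end: float  # s
    label: str
    concentration: float = 0.0  # molar agonist concentration during interval

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise KineticsError(f"interval {self.label!r}: end must exceed start")
        if self.concentration < 0:
            raise KineticsError(f"interval {self.label!r}: concentration must be >= 0")


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current time series with protocol annotations."""

    time: np.ndarray  # s
    current: np.ndarray  # pA
    annotations: tuple[ProtocolInterval, ...] = ()
    holding_voltage: float = 0.0  # mV
    test_voltage: float = 80.0  # mV

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        i = np.asarray(self.current, float)
        if t.ndim != 1 or t.shape != i.shape:
            raise KineticsError("time and current must be 1-D arrays of equal length")
        dt = np.diff(t)
        if t.size < 2 or not np.all(dt > 0):
            raise KineticsError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise KineticsError("sampling must be uniform")
        intervals = tuple(self.annotations)
        for iv in intervals:
            if iv.start < t[0] - 1e-9 or iv.end > t[-1] + 1e-9:
                raise KineticsError(f"interval {iv.label!r} outside the record")
        for a, b in zip(intervals, intervals[1:]):
            if b.start < a.end - 1e-9:
                raise KineticsError("annotated intervals must not overlap")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        object.__setattr__(self, "annotations", intervals)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def interval(self, label: str) -> ProtocolInterval:
        for iv in self.annotations:
            if iv.label == label:
                return iv
        raise KineticsError(f"no interval labelled {label!r}")


@dataclass(frozen=True)
class RelaxationFit:
    """Single-exponential fit of one relaxation."""

    tau: float  # s
    amplitude: float  # pA
    offset: float  # pA
    tau_stderr: float | None
    window: tuple[float, float]
    residual_rms: float
    direction: str  # "onset" | "offset"
    converged: bool
    identifiable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def fit_relaxation(
    trace: CurrentTrace,
    interval: ProtocolInterval | str,
    skip_samples: int = 2,
) -> RelaxationFit:
    """Least-squares mono-exponential fit within one annotated interval.

    The fit window starts ``skip_samples`` samples after the solution-switch
    annotation to skip exchange artifacts.  A flat trace yields an
    ``identifiable=False`` flag (tau means nothing when the amplitude is
    indistinguishable from zero).
    """
    if isinstance(interval, str):
        interval = trace.interval(interval)
    mask = (trace.time >= interval.start) & (trace.time <= interval.end)
    idx = np.flatnonzero(mask)[skip_samples:]
    if idx.size < 20:
        raise KineticsError(
            f"interval {interval.label!r} too short: {idx.size} samples after skip"
        )
    t = trace.time[idx]
    y = trace.current[idx]
    t0 = t[0]

    params = lmfit.Parameters()
    params.add("offset", value=float(y[-5:].mean()))
    params.add("amplitude", value=float(y[0] - y[-5:].mean()))
    params.add("tau", value=max((t[-1] - t0) / 5.0, trace.dt), min=trace.dt * 1e-3)

    def residual(p):
        return y - (
            p["offset"].value
            + p["amplitude"].value * np.exp(-(t - t0) / p["tau"].value)
        )

    res = lmfit.minimize(residual, params, method="leastsq")
    amp = float(res.params["amplitude"].value)
    tau = float(res.params["tau"].value)
    tau_err = res.params["tau"].stderr
    rms = float(np.sqrt(res.chisqr / t.size))
    # unidentifiable when the amplitude is lost in the noise or the fitted
    # tau is far longer than the window (a flat trace fits tau -> infinity
    # with a compensating amplitude/offset pair)
    span = float(t[-1] - t0)
    identifiable = (
        abs(amp) > max(3.0 * rms, 1e-9 * max(1.0, abs(float(y.mean()))))
        and tau < 10.0 * span
        and (tau_err is None or tau_err < tau)
    )
    return RelaxationFit(
        tau=tau,
        amplitude=amp,
        offset=float(res.params["offset"].value),
        tau_stderr=float(tau_err) if tau_err is not None else None,
        window=(float(t0), float(t[-1])),
        residual_rms=rms,
        direction="onset" if amp < 0 else "offset",
        converged=bool(res.success),
        identifiable=bool(identifiable),
    )


@dataclass(frozen=True)
class BindingKinetics:
    """Association/dissociation rate constants and affinity.

    ``koff`` is the wash-out estimate used for Kd; ``koff_intercept`` is the
    regression intercept retained for comparison.  The consistency identity
    Kd = koff / kon holds exactly by construction.
    """

    kon: float | None  # M^-1 s^-1
    koff: float | None  # s^-1 (wash-out estimate)
    kd: float | None  # M
    kon_stderr: float | None = None
    koff_stderr: float | None = None
    kd_stderr: float | None = None
    koff_intercept: float | None = None
    koff_intercept_stderr: float | None = None
    method: str = "regression"
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["notes"] = list(self.notes)
        return d


def estimate_rates(
    tau_on: Sequence[tuple[float, float]] | None,
    tau_off: Sequence[float] | None,
    weights: Sequence[float] | None = None,
) -> BindingKinetics:
    """Convert relaxation time constants into kon, koff and Kd.

    ``tau_on`` is a sequence of (concentration_M, tau_s) pairs; ``tau_off``
    a sequence of wash-out time constants.  With >= 2 distinct on-step
    concentrations, 1/tau_on is regressed on concentration (weighted linear
    regression; unit weights by default); with a single concentration, kon
    falls back to (1/tau_on - koff) / [L] using the wash-out koff, with a
    warning-level note in the report.
    """
    notes: list[str] = []
    koff_off = koff_off_err = None
    if tau_off:
        rates = 1.0 / np.asarray(list(tau_off), float)
        koff_off = float(rates.mean())
        if rates.size > 1:
            koff_off_err = float(rates.std(ddof=1) / math.sqrt(rates.size))

    if not tau_on:
        if koff_off is None:
            raise KineticsError("need tau_on and/or tau_off measurements")
        return BindingKinetics(
            kon=None, koff=koff_off, kd=None, koff_stderr=koff_off_err,
            method="tau_off_only", notes=("no on-step data: kon/Kd unavailable",),
        )

    conc = np.array([c for c, _ in tau_on], float)
    rate_on = 1.0 / np.array([t for _, t in tau_on], float)
    if np.any(conc <= 0):
        raise KineticsError("on-step concentrations must be > 0")

    kon_err = intercept = intercept_err = None
    if np.unique(conc).size >= 2:
        w = np.ones_like(rate_on) if weights is None else np.asarray(weights, float)
        X = sm.add_constant(conc)
        fit = sm.WLS(rate_on, X, weights=w).fit()
        intercept, kon = (float(v) for v in fit.params)
        intercept_err, kon_err = (float(v) for v in fit.bse)
        if kon <= 0:
            notes.append("regression slope non-positive: check concentration range")
        koff = koff_off if koff_off is not None else intercept
        koff_err = koff_off_err if koff_off is not None else intercept_err
        if koff_off is None:
            notes.append("no wash-out data: koff taken from regression intercept")
        method = "regression"
    else:
        if koff_off is None:
            raise KineticsError("single on-step concentration requires tau_off for koff")
        notes.append("single on-step concentration: kon from (1/tau_on - koff)/[L]")
        kon_each = (rate_on - koff_off) / conc
        kon = float(kon_each.mean())
        if kon_each.size > 1:
            kon_err = float(kon_each.std(ddof=1) / math.sqrt(kon_each.size))
        koff, koff_err = koff_off, koff_off_err
        method = "single_concentration"
        if kon <= 0:
            notes.append("apparent kon non-positive: 1/tau_on below koff")

    kd = koff / kon if (kon is not None and kon > 0 and koff is not None) else None
    kd_err = None
    if kd is not None and kon_err is not None and koff_err is not None:
        kd_err = kd * math.sqrt((kon_err / kon) ** 2 + (koff_err / koff) ** 2)
    return BindingKinetics(
        kon=kon,
        koff=koff,
        kd=kd,
        kon_stderr=kon_err,
        koff_stderr=koff_err,
        kd_stderr=kd_err,
        koff_intercept=intercept,
        koff_intercept_stderr=intercept_err,
        method=method,
        notes=tuple(notes),
    )


# --- IO ---------------------------------------------------------------------


def write_trace_csv(path, trace: CurrentTrace, protocol_path=None) -> None:
    pd.DataFrame({"time_s": trace.time, "current_pA": trace.current}).to_csv(
        path, index=False, float_format="%.6g"
    )
    if protocol_path is not None:
        protocol = {
            "holding_voltage_mV": trace.holding_voltage,
            "test_voltage_mV": trace.test_voltage,
            "intervals": [
                {
                    "start_s": iv.start,
                    "end_s": iv.end,
                    "label": iv.label,
                    "concentration_M": iv.concentration,
                }
                for iv in trace.annotations
            ],
        }
        with open(protocol_path, "w") as fh:
            json.dump(protocol, fh, indent=1, sort_keys=True)


def read_trace_csv(path, protocol_path=None) -> CurrentTrace:
    df = pd.read_csv(path)
    annotations: tuple[ProtocolInterval, ...] = ()
    holding, test = 0.0, 80.0
    if protocol_path is not None:
        with open(protocol_path) as fh:
            protocol = json.load(fh)
        holding = protocol.get("holding_voltage_mV", 0.0)
        test = protocol.get("test_voltage_mV", 80.0)
        annotations = tuple(
            ProtocolInterval(
                start=iv["start_s"],
                end=iv["end_s"],
                label=iv["label"],
                concentration=iv.get("concentration_M", 0.0),
            )
            for iv in protocol["intervals"]
        )
    return CurrentTrace(
        time=df["time_s"].to_numpy(float),
        current=df["current_pA"].to_numpy(float),
        annotations=annotations,
        holding_voltage=holding,
        test_voltage=test,
    )
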