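"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its config (master seed included): the
pseudo-random stream for the i-th output is derived from ``(seed, i)`` so
adding scenarios never perturbs existing outputs, and re-running with the
same config yields identical bytes.  Every generator returns its outputs
together with a manifest recording all ground-truth parameters, which the
round-trip test suite feeds back through the corresponding analysis
operation.

Default noise levels emulate good patch-clamp data: 5% multiplicative
Gaussian noise on macroscopic responses, 0.2 pA RMS additive noise on
single-channel records.  Solution exchange is simulated as a 10 ms linear
concentration ramp, which is why kinetics fits skip the first two samples
after a switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from polymodal_gate import gating_model as gm
from polymodal_gate.dose_response import DoseResponseDataset, hill
from polymodal_gate.kinetics import CurrentTrace, ProtocolInterval
from polymodal_gate.single_channel import SingleChannelRecord
from polymodal_gate.thermal_analysis import TemperatureRampRecord

__all__ = [
    "GeneratorError",
    "DoseResponseConfig",
    "WashTraceConfig",
    "TemperatureRampConfig",
    "SingleChannelConfig",
    "DesensitizationConfig",
    "gen_dose_response",
    "gen_wash_trace",
    "gen_temperature_ramp",
    "gen_single_channel",
    "gen_desensitization_patches",
]


class GeneratorError(ValueError):
    """Raised on invalid generator configuration."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one pseudo-random stream per output, derived from the master seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# --- dose-response ----------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseConfig:
    """Ground truth and sampling plan for Hill-curve datasets.

    Defaults generate the toxin agonist's macroscopic dose-response over
    8 log-spaced concentrations (10 nM - 10 uM) with 5% multiplicative
    Gaussian noise and 3 replicates per concentration.
    """

    seed: int = 0
    agonist: str = "RhTx"
    ec50: float = 521.5e-9  # M
    hill_slope: float = 1.17
    top: float = 1.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] = tuple(np.geomspace(1e-8, 1e-5, 8))
    noise_sigma: float = 0.05  # multiplicative Gaussian, fraction of signal
    n_replicates: int = 3
    n_datasets: int = 1

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, float)
        if conc.size < 4 or np.unique(conc).size < 4:
            raise GeneratorError("need >= 4 distinct concentrations")
        if conc.max() / conc.min() < 100.0:
            raise GeneratorError("concentration grid must span >= 2 decades")
        if self.noise_sigma < 0:
            raise GeneratorError("noise sigma must be >= 0")


def gen_dose_response(
    config: DoseResponseConfig,
) -> tuple[list[DoseResponseDataset], dict]:
    """Hill-curve datasets: response = Hill(truth) * (1 + noise), clipped at 0."""
    conc = np.asarray(config.concentrations, float)
    truth = hill(conc, config.ec50, config.hill_slope, config.top, config.bottom)
    datasets = []
    for d in range(config.n_datasets):
        rng = _rng(config.seed, d)
        rows = []
        for rep in range(config.n_replicates):
            noisy = truth * (1.0 + config.noise_sigma * rng.standard_normal(conc.size))
            noisy = np.clip(noisy, 0.0, None)
            for c, r in zip(conc, noisy):
                rows.append({"replicate": f"rep{rep}", "concentration_M": c, "response": r})
        datasets.append(
            DoseResponseDataset(agonist=config.agonist, data=pd.DataFrame(rows))
        )
    manifest = {"generator": "gen_dose_response", **asdict(config)}
    return datasets, manifest


# --- wash-in / wash-out traces ---------------------------------------------


@dataclass(frozen=True)
class WashTraceConfig:
    """Two-state binding relaxation protocol.

    The on-step drives occupancy toward c/(c+Kd) at rate kon*c + koff, the
    off-step decays at koff; current is occupancy scaled to ``i_max``.
    Defaults: kon/koff give Kd = 0.52 uM, on-step at 1 uM (the concentration
    used for the on-relaxation measurements), 10 ms linear exchange ramp,
    additive Gaussian noise at 5% of the steady-state amplitude.
    """

    seed: int = 0
    kon: float = 0.5 / 0.52e-6  # M^-1 s^-1; with koff gives Kd = 0.52 uM
    koff: float = 0.5  # s^-1
    concentration: float = 1e-6  # M during the on-step
    i_max: float = 500.0  # pA at full occupancy
    sampling_rate: float = 1000.0  # Hz
    baseline_s: float = 1.0
    on_s: float = 6.0
    off_s: float = 12.0
    exchange_ramp_s: float = 0.010
    noise_sigma: float = 0.05  # fraction of steady-state amplitude
    test_voltage: float = 80.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise GeneratorError("concentration must be >= 0")
        if self.kon <= 0 or self.koff <= 0:
            raise GeneratorError("kon and koff must be > 0")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def gen_wash_trace(
    config: WashTraceConfig, stream: int = 0
) -> tuple[CurrentTrace, dict]:
    """One wash-in/wash-out trace with annotated intervals and manifest."""
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round((config.baseline_s + config.on_s + config.off_s) * fs))
    t = np.arange(n) * dt
    t_on = config.baseline_s
    t_off = config.baseline_s + config.on_s
    # concentration profile with linear exchange ramps
    conc = np.zeros(n)
    ramp = max(config.exchange_ramp_s, dt)
    rising = (t >= t_on) & (t < t_on + ramp)
    conc[rising] = config.concentration * (t[rising] - t_on) / ramp
    conc[(t >= t_on + ramp) & (t < t_off)] = config.concentration
    falling = (t >= t_off) & (t < t_off + ramp)
    conc[falling] = config.concentration * (1.0 - (t[falling] - t_off) / ramp)
    # exact stepwise relaxation of occupancy at piecewise-constant concentration
    occ = np.zeros(n)
    p = 0.0
    for k in range(1, n):
        c = conc[k - 1]
        rate = config.kon * c + config.koff
        p_inf = config.kon * c / rate if rate > 0 else 0.0
        p = p_inf + (p - p_inf) * math.exp(-rate * dt)
        occ[k] = p
    ss_amp = config.i_max * config.concentration / (config.concentration + config.kd)
    rng = _rng(config.seed, stream)
    current = config.i_max * occ + config.noise_sigma * ss_amp * rng.standard_normal(n)
    trace = CurrentTrace(
        time=t,
        current=current,
        annotations=(
            ProtocolInterval(0.0, t_on, "baseline", 0.0),
            ProtocolInterval(t_on, t_off, "on", config.concentration),
            ProtocolInterval(t_off, t[-1], "off", 0.0),
        ),
        holding_voltage=0.0,
        test_voltage=config.test_voltage,
    )
    manifest = {
        "generator": "gen_wash_trace",
        "kd": config.kd,
        "tau_on_true": 1.0 / (config.kon * config.concentration + config.koff),
        "tau_off_true": 1.0 / config.koff,
        **asdict(config),
    }
    return trace, manifest


# --- temperature ramps ------------------------------------------------------


@dataclass(frozen=True)
class TemperatureRampConfig:
    """Heat-ramp families with a programmed activation-threshold shift.

    Currents are leak(T) + channel(T): the leak is a shallow exponential in
    temperature, the channel follows the gating model's heat-evoked Po(T)
    scaled by ``channel_scale``.  For the toxin condition the channel curve
    is translated along the temperature axis by ``threshold_shift`` degrees
    (so the programmed control-minus-toxin shift is exact by construction
    and recorded in the manifest).  ``channel_scale = 0`` produces leak-only
    families.
    """

    seed: int = 0
    model_spec: gm.GatingModelSpec = field(default_factory=gm.ramp_model_spec)
    t_start: float = 16.0  # cold enough for a leak segment under the toxin
    t_end: float = 40.0  # before deep Po saturation of the shifted curve
    n_points: int = 140
    ramp_duration_s: float = 14.0
    channel_scale: float = 10000.0  # pA at Po = 1
    leak_at_25C: float = 15.0  # pA
    leak_per_C: float = 0.02  # exponential coefficient
    threshold_shift: float = 6.0  # C, control minus toxin threshold
    toxin_condition: str = "RhTx_100nM"
    noise_sigma: float = 0.05  # multiplicative, fraction of signal
    noise_floor_pA: float = 0.5
    capsaicin_reference: float = 1000.0  # pA
    voltage: float = 80.0

    def __post_init__(self) -> None:
        if self.t_end - self.t_start < 15.0:
            raise GeneratorError("ramp must cover both leak and channel segments")
        gm.build_model(self.model_spec)  # propagate validation errors


def gen_temperature_ramp(
    config: TemperatureRampConfig, stream: int = 0
) -> tuple[list[TemperatureRampRecord], dict]:
    """Paired control / toxin ramp records with ground-truth manifest."""
    model = gm.build_model(config.model_spec)
    t = np.linspace(0.0, config.ramp_duration_s, config.n_points)
    temp = np.linspace(config.t_start, config.t_end, config.n_points)
    leak = config.leak_at_25C * np.exp(config.leak_per_C * (temp - 25.0))

    def channel(shift: float) -> np.ndarray:
        po = np.array(
            [
                model.open_probability(
                    gm.StimulusCondition(
                        voltage=config.voltage,
                        temperature=min(float(T + shift), 80.0),
                    )
                )
                for T in temp
            ]
        )
        return config.channel_scale * po

    records = []
    for j, (condition, shift) in enumerate(
        [("control", 0.0), (config.toxin_condition, config.threshold_shift)]
    ):
        rng = _rng(config.seed, 2 * stream + j)
        signal = leak + channel(shift)
        noisy = signal * (
            1.0 + config.noise_sigma * rng.standard_normal(config.n_points)
        ) + config.noise_floor_pA * rng.standard_normal(config.n_points)
        records.append(
            TemperatureRampRecord(
                time=t,
                temperature=temp,
                current=noisy,
                condition=condition,
                capsaicin_reference=config.capsaicin_reference,
            )
        )
    manifest = {
        "generator": "gen_temperature_ramp",
        "programmed_shift_C": config.threshold_shift,
        "channel_max_fraction_of_reference": float(
            channel(0.0).max() / config.capsaicin_reference
        ),
        **{k: v for k, v in asdict(config).items() if k != "model_spec"},
        "model_spec": config.model_spec.to_dict(),
    }
    return records, manifest


# --- single-channel records -------------------------------------------------


@dataclass(frozen=True)
class SingleChannelConfig:
    """Two-state Markov gating rendered as a noisy current record.

    Dwells are sampled exactly from exponential distributions (rates
    ``k_open``: closed->open, ``k_close``: open->closed); the stationary
    open probability k_open/(k_open+k_close) goes into the manifest.
    Unitary current is conductance * voltage, with the toxin condition's
    inward amplitudes scaled by ``inward_scale`` (permeation effect).
    """

    seed: int = 0
    k_open: float = 1900.0  # s^-1, closed -> open
    k_close: float = 100.0  # s^-1, open -> closed
    duration_s: float = 5.0
    sampling_rate: float = 5000.0  # Hz
    voltage: float = 80.0  # mV
    condition: str = "RhTx"
    conductance_pS: float = 100.0
    inward_scale: float = 0.7  # toxin-condition inward amplitude factor
    noise_rms: float = 0.2  # pA additive Gaussian
    filter_cutoff_hz: float | None = None  # optional Gaussian smoothing

    def __post_init__(self) -> None:
        if self.k_open <= 0 or self.k_close < 0:
            raise GeneratorError("need k_open > 0 and k_close >= 0")
        mean_dwell = 1.0 / max(self.k_open, self.k_close or self.k_open)
        if mean_dwell < 1e-3 / self.sampling_rate:
            raise GeneratorError(
                "mean dwell below 1e-3 sampling intervals: aliasing guard"
            )

    @property
    def stationary_po(self) -> float:
        return self.k_open / (self.k_open + self.k_close)

    @property
    def unitary_amplitude(self) -> float:
        amp = self.conductance_pS * 1e-3 * self.voltage  # pA
        if self.voltage < 0 and self.condition == "RhTx":
            amp *= self.inward_scale
        return amp


def gen_single_channel(
    config: SingleChannelConfig, stream: int = 0
) -> tuple[SingleChannelRecord, dict]:
    """Continuous-time two-state trajectory sampled at the recording rate."""
    rng = _rng(config.seed, stream)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    # exact exponential dwell sampling
    state = 1 if rng.random() < config.stationary_po else 0
    states = np.empty(n, dtype=np.int8)
    t_edge = 0.0
    i = 0
    while i < n:
        rate = config.k_close if state else config.k_open
        if rate == 0.0:  # absorbing state (e.g. k_close = 0: stays open)
            states[i:] = state
            break
        t_edge += rng.exponential(1.0 / rate)
        j = min(int(t_edge * fs), n)
        states[i:j] = state
        i = j
        state = 1 - state
    amp = config.unitary_amplitude
    current = amp * states + config.noise_rms * rng.standard_normal(n)
    if config.filter_cutoff_hz:
        from scipy.ndimage import gaussian_filter1d

        sigma = fs / (2.0 * math.pi * config.filter_cutoff_hz)
        current = gaussian_filter1d(current, sigma)
    record = SingleChannelRecord(
        current=current,
        sampling_rate=fs,
        voltage=config.voltage,
        condition=config.condition,
    )
    manifest = {
        "generator": "gen_single_channel",
        "stationary_po": config.stationary_po,
        "unitary_amplitude_pA": amp,
        "empirical_open_fraction": float(states.mean()),
        **asdict(config),
    }
    return record, manifest


# --- desensitization patches ------------------------------------------------


@dataclass(frozen=True)
class DesensitizationConfig:
    """Paired heat(55 C)/capsaicin currents for two incubation groups.

    The control group's heat/capsaicin ratio scatters log-normally around
    ``control_ratio``; the toxin-incubated group's heat responses are
    multiplied by ``ablation`` (0 = heat pathway fully desensitized) on top
    of the same scatter, while capsaicin responses are preserved.
    """

    seed: int = 0
    n_per_group: int = 8
    control_ratio: float = 1.0
    ablation: float = 0.0
    scatter_sigma: float = 0.25  # lognormal sigma of patch-to-patch ratios
    capsaicin_mean_pA: float = 1500.0
    capsaicin_scatter_sigma: float = 0.3
    heat_noise_floor_pA: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise GeneratorError("need >= 2 patches per group")
        if not (0.0 <= self.ablation):
            raise GeneratorError("ablation factor must be >= 0")


def gen_desensitization_patches(
    config: DesensitizationConfig,
) -> tuple[pd.DataFrame, dict]:
    rows = []
    for j, (group, factor) in enumerate(
        [("control", 1.0), ("RhTx_incubated", config.ablation)]
    ):
        rng = _rng(config.seed, j)
        for p in range(config.n_per_group):
            cap = config.capsaicin_mean_pA * rng.lognormal(
                0.0, config.capsaicin_scatter_sigma
            )
            ratio = config.control_ratio * rng.lognormal(0.0, config.scatter_sigma)
            heat = factor * ratio * cap + config.heat_noise_floor_pA * abs(
                rng.standard_normal()
            )
            rows.append(
                {
                    "patch": f"{group}_{p}",
                    "group": group,
                    "heat_current_pA": heat,
                    "capsaicin_current_pA": cap,
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.assign(ratio=table["heat_current_pA"] / table["capsaicin_current_pA"])
        .groupby("group")["ratio"]
        .mean()
        .to_dict()
    )
    manifest = {
        "generator": "gen_desensitization_patches",
        "group_mean_ratios": means,
        **asdict(config),
    }
    return table, manifest
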