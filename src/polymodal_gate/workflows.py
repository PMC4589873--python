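"""End-to-end scenario orchestration on synthetic data.

Each scenario generates its inputs, runs the relevant analysis chain and
returns a :class:`ScenarioReport` whose checks compare recovered quantities
against the generator's ground truth at declared tolerances.  A failed
tolerance marks the report failed; it never raises.  Reports are plain
JSON-serializable dictionaries that fully reconstruct the run (scenario
name, config, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from polymodal_gate import __version__
from polymodal_gate import dose_response as dr
from polymodal_gate import gating_model as gm
from polymodal_gate import kinetics as kin
from polymodal_gate import single_channel as sc
from polymodal_gate import synthetic_data as syn
from polymodal_gate import thermal_analysis as th

__all__ = ["ScenarioReport", "WorkflowError", "run_scenario", "SCENARIOS"]

log = logging.getLogger(__name__)


class WorkflowError(ValueError):
    """Raised for unknown scenarios or invalid configs."""


@dataclass
class ScenarioReport:
    scenario: str
    seed: int
    config: dict
    config_hash: str
    results: dict = field(default_factory=dict)
    checks: list = field(default_factory=list)
    passed: bool = True
    version: str = __version__

    def check(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append({"name": name, "passed": bool(ok), "detail": detail})
        if not ok:
            self.passed = False
            log.warning("scenario %s: check %s failed (%s)", self.scenario, name, detail)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True, default=str)


def _report(name: str, seed: int, config: dict) -> ScenarioReport:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return ScenarioReport(
        scenario=name,
        seed=seed,
        config=config,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
    )


# --- scenarios --------------------------------------------------------------


def _fig1h_dose_response(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Recover the two agonists' Hill parameters from synthetic datasets."""
    n_datasets = cfg.get("n_datasets", 10)
    noise = cfg.get("noise_sigma", 0.05)
    truths = cfg.get(
        "agonists",
        {
            "RhTx": {"ec50": 521.5e-9, "hill_slope": 1.17},
            "capsaicin": {"ec50": 213.8e-9, "hill_slope": 1.36},
        },
    )
    for i, (agonist, truth) in enumerate(sorted(truths.items())):
        config = syn.DoseResponseConfig(
            seed=seed + 1000 * i,
            agonist=agonist,
            ec50=truth["ec50"],
            hill_slope=truth["hill_slope"],
            noise_sigma=noise,
            n_datasets=n_datasets,
        )
        datasets, manifest = syn.gen_dose_response(config)
        fits, summary = dr.fit_hill_many(datasets)
        report.results[agonist] = {"summary": summary, "truth": truth}
        if noise == 0.0:
            ok = abs(summary["ec50_mean"] / truth["ec50"] - 1.0) < 1e-6
        else:
            tol = max(3.0 * summary["ec50_sem"], 0.15 * truth["ec50"])
            ok = abs(summary["ec50_mean"] - truth["ec50"]) < tol
        report.check(
            f"{agonist}_ec50_recovered",
            ok,
            f"mean {summary['ec50_mean']:.3g} vs truth {truth['ec50']:.3g}",
        )


def _fig1i_kinetics(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Recover kon/koff/Kd from wash-in/wash-out relaxations."""
    n_sets = cfg.get("n_trace_sets", 10)
    config = syn.WashTraceConfig(seed=seed, noise_sigma=cfg.get("noise_sigma", 0.05))
    kds, taus_on, taus_off = [], [], []
    for s in range(n_sets):
        trace, manifest = syn.gen_wash_trace(config, stream=s)
        fit_on = kin.fit_relaxation(trace, "on")
        fit_off = kin.fit_relaxation(trace, "off")
        taus_on.append(fit_on.tau)
        taus_off.append(fit_off.tau)
        rates = kin.estimate_rates(
            [(config.concentration, fit_on.tau)], [fit_off.tau]
        )
        if rates.kd is not None:
            kds.append(rates.kd)
    kd_mean = float(np.mean(kds))
    report.results["kinetics"] = {
        "kd_mean_M": kd_mean,
        "kd_true_M": config.kd,
        "tau_on_mean_s": float(np.mean(taus_on)),
        "tau_off_mean_s": float(np.mean(taus_off)),
        "n_trace_sets": n_sets,
    }
    report.check(
        "kd_recovered",
        abs(kd_mean / config.kd - 1.0) < cfg.get("kd_tolerance", 0.2),
        f"mean Kd {kd_mean:.3g} M vs truth {config.kd:.3g} M",
    )


def _fig1jl_single_channel(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Idealize saturating-agonist records and compare i-V conductances."""
    config = syn.SingleChannelConfig(seed=seed)
    record, manifest = syn.gen_single_channel(config)
    ideal = sc.idealize(record, unitary_amplitude=manifest["unitary_amplitude_pA"])
    po = sc.open_probability_sc(ideal)
    report.results["open_probability"] = {
        "po": po,
        "stationary_po": manifest["stationary_po"],
    }
    report.check("near_unity_po", po > 0.9, f"Po = {po:.3f}")
    # i-V points per condition/patch
    rows = []
    voltages = cfg.get("voltages", (-100, -80, -60, 60, 80, 100))
    for ci, cond in enumerate(("RhTx", "capsaicin")):
        for p in range(cfg.get("n_patches", 5)):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, p]))
            for v in voltages:
                c = syn.SingleChannelConfig(seed=seed, voltage=v, condition=cond)
                amp = c.unitary_amplitude * (1.0 + 0.03 * rng.standard_normal())
                rows.append(
                    {
                        "condition": cond,
                        "patch": f"{cond}_{p}",
                        "voltage_mV": v,
                        "amplitude_pA": amp,
                    }
                )
    import pandas as pd

    iv = sc.fit_unitary_iv(pd.DataFrame(rows))
    report.results["iv"] = iv
    report.check(
        "inward_conductance_reduced",
        iv["inward"]["comparison"]["significant"]
        and iv["inward"]["RhTx"]["conductance_pS"]
        < iv["inward"]["capsaicin"]["conductance_pS"],
        f"inward comparison p = {iv['inward']['comparison']['p']:.2g}",
    )


def _fig3ab_threshold(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Recover the programmed heat-activation threshold shift."""
    n_pairs = cfg.get("n_pairs", 20)
    config = syn.TemperatureRampConfig(
        seed=seed, threshold_shift=cfg.get("threshold_shift", 6.0)
    )
    shifts = []
    for s in range(n_pairs):
        records, manifest = syn.gen_temperature_ramp(config, stream=s)
        fits = {r.condition: th.detect_threshold(r) for r in records}
        if all(f.found for f in fits.values()):
            shifts.append(
                fits["control"].threshold - fits[config.toxin_condition].threshold
            )
    mean_shift = float(np.mean(shifts))
    report.results["threshold"] = {
        "mean_shift_C": mean_shift,
        "programmed_shift_C": config.threshold_shift,
        "n_pairs_detected": len(shifts),
    }
    report.check(
        "shift_recovered",
        abs(mean_shift - config.threshold_shift) < 1.0,
        f"recovered {mean_shift:.2f} C vs programmed {config.threshold_shift} C",
    )


def _fig3d_cooling_prediction(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Cooling-selectivity prediction under the four attachment hypotheses."""
    hypothesis = cfg.get("hypothesis", "heat_branch")
    base = gm.build_model(gm.default_model_spec())
    verdicts = {}
    for hyp in gm.ToxinHypothesis:
        rep = gm.predict_cooling_selectivity(gm.attach_toxin(base, hyp))
        verdicts[hyp.value] = {
            "selective_cooling_inhibition": rep.selective_cooling_inhibition,
            "toxin_cold_fraction": rep.toxin_cold_fraction,
            "capsaicin_cold_fraction": rep.capsaicin_cold_fraction,
            "max_toxin_excess": rep.max_toxin_excess,
        }
    report.results["hypotheses"] = verdicts
    report.check(
        "selected_hypothesis_selective",
        verdicts[hypothesis]["selective_cooling_inhibition"],
        hypothesis,
    )
    report.check(
        "unique_among_hypotheses",
        sum(v["selective_cooling_inhibition"] for v in verdicts.values()) == 1,
        str({k: v["selective_cooling_inhibition"] for k, v in verdicts.items()}),
    )


def _fig3ef_desensitization(report: ScenarioReport, seed: int, cfg: dict) -> None:
    """Toxin-incubation ablates heat responses: group contrast at P<0.001."""
    config = syn.DesensitizationConfig(
        seed=seed,
        n_per_group=cfg.get("n_per_group", 8),
        ablation=cfg.get("ablation", 0.0),
    )
    table, manifest = syn.gen_desensitization_patches(config)
    result = th.desensitization_ratio(table)
    report.results["desensitization"] = {
        "group_means": result["group_means"],
        "comparison": result["comparison"],
    }
    report.check(
        "groups_significantly_different",
        result["comparison"]["significant"],
        f"p = {result['comparison']['p']:.2g}",
    )


SCENARIOS: dict[str, Callable] = {
    "fig1h_dose_response": _fig1h_dose_response,
    "fig1i_kinetics": _fig1i_kinetics,
    "fig1jl_single_channel": _fig1jl_single_channel,
    "fig3ab_threshold": _fig3ab_threshold,
    "fig3d_cooling_prediction": _fig3d_cooling_prediction,
    "fig3ef_desensitization": _fig3ef_desensitization,
}


def run_scenario(
    name: str,
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> ScenarioReport:
    """Run one named scenario end to end and return its report.

    Unknown names raise with the list of valid scenarios.  When ``out_dir``
    is given the report (and optional plots) are written there.
    """
    if name not in SCENARIOS:
        raise WorkflowError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(SCENARIOS)}"
        )
    cfg = dict(config or {})
    report = _report(name, seed, cfg)
    SCENARIOS[name](report, seed, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / f"{name}_report.json")
        if make_plots:
            _plot_scenario(report, out)
    return report


def _plot_scenario(report: ScenarioReport, out: Path) -> None:
    """Convenience plots; all assertions operate on numbers, never images."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.scenario == "fig3d_cooling_prediction":
        base = gm.build_model(gm.default_model_spec())
        model = gm.attach_toxin(base, "heat_branch")
        rep = gm.predict_cooling_selectivity(model)
        fig, ax = plt.subplots()
        ax.plot(rep.temperatures, rep.toxin_response, label="toxin (saturating)")
        ax.plot(rep.temperatures, rep.capsaicin_response, label="capsaicin (saturating)")
        ax.plot(rep.temperatures, rep.baseline, "--", label="no agonist")
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("open probability")
        ax.legend()
        fig.savefig(out / "cooling_selectivity.png", dpi=120)
        plt.close(fig)
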