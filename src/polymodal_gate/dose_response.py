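"""Hill-equation fitting of normalized concentration-response data.

Responses are fractional currents normalized within each replicate to a
reference measurement (e.g. the current evoked by a saturating dose of a
standard agonist).  The Hill model fitted is

    response = bottom + (top - bottom) / (1 + (EC50 / c) ** n_H)

with ``bottom`` fixed at 0 by default (responses are baseline-subtracted
normalized currents) and ``top`` free.  EC50 comparisons between conditions
are Welch t-tests on log10(EC50), since EC50 estimates are approximately
log-normal across patches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseDataset",
    "HillFit",
    "DoseResponseError",
    "normalize_to_reference",
    "fit_hill",
    "fit_hill_many",
    "summarize_fits",
    "compare_ec50",
    "welch_t_test",
    "hill",
    "read_dose_response_csv",
]

SIGNIFICANCE_LEVEL = 0.001  # flagged ** when P < 0.001


class DoseResponseError(ValueError):
    """Raised on invalid dose-response inputs."""


def hill(c, ec50, n_h, top=1.0, bottom=0.0):
    """Hill equation; ``c`` and ``ec50`` in the same (molar) units."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** n_h)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Concentration-response table for one agonist.

    ``data`` holds columns ``replicate``, ``concentration_M``, ``response``
    (normalized fractional responses).  Replicates may be ragged.
    """

    agonist: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"replicate", "concentration_M", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise DoseResponseError(f"dataset missing columns {sorted(missing)}")
        if (self.data["concentration_M"] <= 0).any():
            raise DoseResponseError("concentrations must be strictly positive")
        if not np.isfinite(self.data["response"]).all():
            raise DoseResponseError("responses must be finite")
        df = self.data.sort_values(["replicate", "concentration_M"]).reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_M"].unique())

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with standard errors from the fit covariance."""

    ec50: float
    hill_slope: float
    top: float
    bottom: float
    ec50_stderr: float | None
    hill_slope_stderr: float | None
    top_stderr: float | None
    bottom_stderr: float | None
    n_points: int
    converged: bool
    extrapolated: bool
    residual_rms: float

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_to_reference(
    currents: pd.DataFrame, reference_label: str = "reference"
) -> dict[str, DoseResponseDataset]:
    """Normalize per-replicate currents to each replicate's reference row.

    ``currents`` needs columns ``replicate``, ``agonist``,
    ``concentration_M``, ``current_pA`` and a boolean ``is_reference`` (or
    rows whose ``agonist`` equals ``reference_label``).  Every response is
    divided by its replicate's reference current; reference rows are removed.
    Returns one dataset per remaining agonist.
    """
    df = currents.copy()
    if "is_reference" in df.columns:
        ref_mask = df["is_reference"].astype(bool)
    else:
        ref_mask = df["agonist"] == reference_label
    refs = df[ref_mask].groupby("replicate")["current_pA"].mean()
    out: dict[str, DoseResponseDataset] = {}
    body = df[~ref_mask]
    for rep in body["replicate"].unique():
        if rep not in refs.index:
            raise DoseResponseError(f"replicate {rep!r} has no reference measurement")
        if not refs.loc[rep] > 0:
            raise DoseResponseError(f"replicate {rep!r} reference is non-positive")
    for agonist, grp in body.groupby("agonist"):
        data = pd.DataFrame(
            {
                "replicate": grp["replicate"].values,
                "concentration_M": grp["concentration_M"].values,
                "response": grp["current_pA"].values
                / refs.loc[grp["replicate"]].values,
            }
        )
        out[str(agonist)] = DoseResponseDataset(agonist=str(agonist), data=data)
    return out


def _multistart_params(conc: np.ndarray, fix_bottom, fix_top):
    c_lo, c_hi = conc.min(), conc.max()
    for ec50_0 in np.geomspace(c_lo, c_hi, 5):
        for n0 in (0.5, 1.0, 2.0):
            p = lmfit.Parameters()
            p.add("ec50", value=ec50_0, min=c_lo * 1e-6, max=c_hi * 1e6)
            p.add("n_h", value=n0, min=0.05, max=10.0)
            if fix_top is None:
                p.add("top", value=1.0, min=1e-6)
            else:
                p.add("top", value=fix_top, vary=False)
            if fix_bottom is None:
                p.add("bottom", value=0.0)
            else:
                p.add("bottom", value=fix_bottom, vary=False)
            yield p


def fit_hill(
    dataset: DoseResponseDataset,
    fix_bottom: float | None = 0.0,
    fix_top: float | None = None,
) -> HillFit:
    """Multi-start nonlinear least-squares Hill fit of one dataset.

    EC50 starts span the tested concentration decades and the slope starts
    are {0.5, 1, 2}; the best (lowest chi-square) solution wins.  Poor
    convergence yields a flagged fit rather than an exception.
    """
    conc = dataset.data["concentration_M"].to_numpy(float)
    resp = dataset.data["response"].to_numpy(float)
    if dataset.concentrations.size < 4:
        raise DoseResponseError("need >= 4 distinct concentrations to fit")

    def residual(params):
        return resp - hill(
            conc,
            params["ec50"].value,
            params["n_h"].value,
            params["top"].value,
            params["bottom"].value,
        )

    best = None
    for params in _multistart_params(conc, fix_bottom, fix_top):
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # pragma: no cover - pathological data
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise DoseResponseError("all fit starts failed")

    def err(name):
        p = best.params[name]
        return float(p.stderr) if (p.vary and p.stderr is not None) else None

    ec50 = float(best.params["ec50"].value)
    converged = bool(best.success) and best.params["ec50"].stderr is not None
    return HillFit(
        ec50=ec50,
        hill_slope=float(best.params["n_h"].value),
        top=float(best.params["top"].value),
        bottom=float(best.params["bottom"].value),
        ec50_stderr=err("ec50"),
        hill_slope_stderr=err("n_h"),
        top_stderr=err("top"),
        bottom_stderr=err("bottom"),
        n_points=int(conc.size),
        converged=converged,
        extrapolated=not (conc.min() <= ec50 <= conc.max()),
        residual_rms=float(np.sqrt(best.chisqr / conc.size)),
    )


def fit_hill_many(
    datasets: Sequence[DoseResponseDataset], **kwargs
) -> tuple[list[HillFit], dict]:
    """Fit each dataset, then average parameters as mean +/- s.e.m."""
    fits = [fit_hill(d, **kwargs) for d in datasets]
    return fits, summarize_fits(fits)


def summarize_fits(fits: Sequence[HillFit]) -> dict:
    """Across-dataset mean +/- s.e.m. of EC50 and Hill slope."""
    ec50 = np.array([f.ec50 for f in fits])
    slope = np.array([f.hill_slope for f in fits])
    n = len(fits)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return {
        "n": n,
        "ec50_mean": float(ec50.mean()),
        "ec50_sem": sem(ec50),
        "hill_slope_mean": float(slope.mean()),
        "hill_slope_sem": sem(slope),
        "all_converged": all(f.converged for f in fits),
    }


def welch_t_test(a: Sequence[float], b: Sequence[float], alpha: float = SIGNIFICANCE_LEVEL) -> dict:
    """Two-sample Welch t-test with the pipeline's significance flag."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "difference": float(a.mean() - b.mean()),
        "statistic": float(t),
        "p": float(p),
        "significant": bool(p < alpha),
        "alpha": alpha,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def compare_ec50(
    fits_a: Sequence[HillFit], fits_b: Sequence[HillFit], alpha: float = SIGNIFICANCE_LEVEL
) -> dict:
    """Welch t-test on log10(EC50) between two groups of fits (>= 3 each)."""
    if len(fits_a) < 3 or len(fits_b) < 3:
        raise DoseResponseError("need >= 3 fits per group to compare EC50s")
    la = [math.log10(f.ec50) for f in fits_a]
    lb = [math.log10(f.ec50) for f in fits_b]
    out = welch_t_test(la, lb, alpha=alpha)
    out["scale"] = "log10(EC50)"
    out["fold_change"] = float(10 ** out["difference"])
    return out


def read_dose_response_csv(path, agonist: str | None = None) -> dict[str, DoseResponseDataset]:
    """Read a raw-currents CSV (replicate, agonist, concentration_M,
    current_pA, is_reference) and return normalized datasets."""
    df = pd.read_csv(path)
    datasets = normalize_to_reference(df)
    if agonist is not None:
        if agonist not in datasets:
            raise DoseResponseError(
                f"agonist {agonist!r} not in file (found {sorted(datasets)})"
            )
        return {agonist: datasets[agonist]}
    return datasets


def write_fit_report(path, fits: Sequence[HillFit], summary: dict | None = None) -> None:
    payload = {"fits": [f.to_dict() for f in fits]}
    if summary is not None:
        payload["summary"] = summary
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
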