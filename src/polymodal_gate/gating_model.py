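"""Multi-allosteric gating pyramid for a polymodal ion channel.

The channel pore has a single closed<->open (C<->O) transition with intrinsic
equilibrium constant ``L0``.  Each stimulus pathway (capsaicin, voltage, heat,
toxin) is a channel-level two-state sensor (resting<->active) whose activation
equilibrium depends on its stimulus:

* ligand sensor:   K = (c / Kd) ** n_sites
* voltage sensor:  K = exp(z * F * (V - V_half) / (R * T))
* thermal sensor:  K = exp(-(dH - T * dS) / (R * T))

A sensor's active state is favoured by a factor ``J`` (its pore coupling)
when the pore is open, and pairs of simultaneously active sensors may be
coupled by cross-coupling factors.  The open probability is

    Po = Z_open / (Z_closed + Z_open)

where Z sums Boltzmann weights over all sensor-configuration x pore-state
combinations.  When all cross-couplings equal 1 the partition function
factorizes and

    Z_closed / Z_open = (1 / L0) * prod_p (1 + K_p) / (1 + J_p * K_p)

which is the fast path used here; otherwise the 2**P sensor configurations
are enumerated in log space.

A toxin may be attached under four alternative hypotheses: it either
modulates the heat, capsaicin or voltage sensor (multiplying that sensor's
activation factor by an occupancy-dependent factor that saturates at the
toxin's efficacy) or forms an independent branch with its own pore coupling.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "R_KCAL",
    "F_KCAL_PER_VOLT",
    "CELSIUS_OFFSET",
    "Mechanism",
    "ToxinHypothesis",
    "PathwaySpec",
    "ToxinAttachment",
    "GatingModelSpec",
    "StimulusCondition",
    "GatingModel",
    "GatingModelError",
    "build_model",
    "default_model_spec",
    "ramp_model_spec",
    "open_probability",
    "po_surface",
    "attach_toxin",
    "predict_cooling_selectivity",
    "half_activation_temperature",
    "CoolingSelectivityReport",
    "HalfActivationResult",
]

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
F_KCAL_PER_VOLT = 23.060547  # Faraday constant, kcal mol^-1 V^-1
CELSIUS_OFFSET = 273.15

#: stimulus field of StimulusCondition driving each named pathway
_STIMULUS_FIELD = {
    "capsaicin": "capsaicin_conc",
    "toxin": "toxin_conc",
    "voltage": "voltage",
    "heat": "temperature",
}


class GatingModelError(ValueError):
    """Raised when a gating-model spec or stimulus is invalid."""


class Mechanism(str, Enum):
    LIGAND = "ligand"
    VOLTAGE = "voltage"
    THERMAL = "thermal"


class ToxinHypothesis(str, Enum):
    HEAT_BRANCH = "heat_branch"
    CAPSAICIN_BRANCH = "capsaicin_branch"
    VOLTAGE_BRANCH = "voltage_branch"
    INDEPENDENT_BRANCH = "independent_branch"


_BRANCH_TARGET = {
    ToxinHypothesis.HEAT_BRANCH: "heat",
    ToxinHypothesis.CAPSAICIN_BRANCH: "capsaicin",
    ToxinHypothesis.VOLTAGE_BRANCH: "voltage",
}


@dataclass(frozen=True)
class StimulusCondition:
    """One point in stimulus space.

    Concentrations are molar, voltage is mV, temperature is degrees Celsius
    (converted to Kelvin internally).  The temperature is validated against
    -10..80 C to guard against Kelvin/Celsius unit mistakes.
    """

    capsaicin_conc: float = 0.0
    toxin_conc: float = 0.0
    voltage: float = 0.0
    temperature: float = 23.0

    def __post_init__(self) -> None:
        if self.capsaicin_conc < 0 or self.toxin_conc < 0:
            raise GatingModelError("concentrations must be >= 0")
        if not (-10.0 <= self.temperature <= 80.0):
            raise GatingModelError(
                f"temperature {self.temperature} C outside the validated "
                "range -10..80 C (did you pass Kelvin?)"
            )
        for name in ("capsaicin_conc", "toxin_conc", "voltage", "temperature"):
            if not math.isfinite(getattr(self, name)):
                raise GatingModelError(f"{name} must be finite")

    @property
    def kelvin(self) -> float:
        return self.temperature + CELSIUS_OFFSET

    def evolve(self, **changes) -> "StimulusCondition":
        return replace(self, **changes)


@dataclass(frozen=True)
class PathwaySpec:
    """One stimulus-driven sensor of the gating pyramid.

    Parameters depend on the mechanism: ligand sensors need ``kd`` (molar)
    and ``n_sites``; voltage sensors need gating charge ``z`` (elementary
    charges) and ``v_half`` (mV); thermal sensors need ``dh`` (kcal/mol) and
    ``ds`` (kcal/mol/K) for the resting->active transition.
    """

    name: str
    mechanism: Mechanism
    kd: float | None = None
    n_sites: int = 1
    z: float | None = None
    v_half: float | None = None
    dh: float | None = None
    ds: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if self.name not in _STIMULUS_FIELD:
            raise GatingModelError(
                f"unknown pathway name {self.name!r}; expected one of "
                f"{sorted(_STIMULUS_FIELD)}"
            )
        if self.mechanism is Mechanism.LIGAND:
            if self.kd is None or not (self.kd > 0):
                raise GatingModelError(f"pathway {self.name}: Kd must be > 0")
            if self.n_sites < 1 or self.n_sites != int(self.n_sites):
                raise GatingModelError(f"pathway {self.name}: n_sites must be an integer >= 1")
        elif self.mechanism is Mechanism.VOLTAGE:
            if self.z is None or self.v_half is None:
                raise GatingModelError(f"pathway {self.name}: z and v_half required")
        elif self.mechanism is Mechanism.THERMAL:
            if self.dh is None or self.ds is None:
                raise GatingModelError(f"pathway {self.name}: dh and ds required")
            if not (math.isfinite(self.dh) and math.isfinite(self.ds)):
                raise GatingModelError(f"pathway {self.name}: dh, ds must be finite")

    def activation(self, condition: StimulusCondition) -> float:
        """Equilibrium constant of the resting->active sensor transition."""
        if self.mechanism is Mechanism.LIGAND:
            conc = getattr(condition, _STIMULUS_FIELD[self.name])
            if conc == 0.0:
                return 0.0
            return (conc / self.kd) ** self.n_sites
        T = condition.kelvin
        if self.mechanism is Mechanism.VOLTAGE:
            dv_volt = (condition.voltage - self.v_half) * 1e-3
            return math.exp(self.z * F_KCAL_PER_VOLT * dv_volt / (R_KCAL * T))
        # thermal
        return math.exp(-(self.dh - T * self.ds) / (R_KCAL * T))


@dataclass(frozen=True)
class ToxinAttachment:
    """Where and how strongly the toxin couples into the pyramid.

    For the three branch hypotheses, bound toxin multiplies the target
    sensor's activation factor by ``(1 + efficacy * x) / (1 + x)`` with
    ``x = (c / kd) ** n_sites`` — unity at zero toxin, ``efficacy`` at
    saturation.  For ``independent_branch`` the toxin is its own ligand
    sensor with pore coupling ``pore_coupling``.
    """

    hypothesis: ToxinHypothesis
    kd: float = 6.164e-6
    efficacy: float = 2.0e4
    n_sites: int = 1
    pore_coupling: float = 800.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hypothesis", ToxinHypothesis(self.hypothesis))
        if not (self.kd > 0):
            raise GatingModelError("toxin kd must be > 0")
        if not (self.efficacy > 0):
            raise GatingModelError("toxin efficacy must be > 0")
        if not (self.pore_coupling > 0):
            raise GatingModelError("toxin pore_coupling must be > 0")

    def occupancy_factor(self, toxin_conc: float) -> float:
        if toxin_conc == 0.0:
            return 1.0
        x = (toxin_conc / self.kd) ** self.n_sites
        if x > 1e15:
            return self.efficacy
        return (1.0 + self.efficacy * x) / (1.0 + x)


def _pair_key(a: str, b: str) -> frozenset:
    return frozenset((a, b))


@dataclass(frozen=True)
class GatingModelSpec:
    """Full parameterization of the allosteric pyramid."""

    l0: float
    pathways: tuple[PathwaySpec, ...]
    pore_couplings: Mapping[str, float]
    cross_couplings: Mapping[frozenset, float] = field(default_factory=dict)
    toxin: ToxinAttachment | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple(self.pathways))
        if not (self.l0 > 0) or not math.isfinite(self.l0):
            raise GatingModelError("L0 must be positive and finite")
        names = [p.name for p in self.pathways]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GatingModelError(f"duplicate pathway: {sorted(dupes)}")
        pore = dict(self.pore_couplings)
        for name in names:
            pore.setdefault(name, 1.0)
        for name, j in pore.items():
            if name not in names:
                raise GatingModelError(f"pore coupling for unknown pathway {name!r}")
            if not (j > 0):
                raise GatingModelError(f"pore coupling J[{name}] = {j} must be > 0")
        object.__setattr__(self, "pore_couplings", pore)
        cross: dict[frozenset, float] = {}
        for key, j in dict(self.cross_couplings).items():
            pair = frozenset(key)
            if len(pair) != 2 or not pair <= set(names):
                raise GatingModelError(f"bad cross-coupling key {set(key)}")
            if not (j > 0):
                raise GatingModelError(f"cross coupling J[{set(key)}] = {j} must be > 0")
            cross[pair] = j
        object.__setattr__(self, "cross_couplings", cross)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def decoupled(self) -> bool:
        """True when every coupling is 1 (Po is stimulus-independent)."""
        return all(j == 1.0 for j in self.pore_couplings.values()) and all(
            j == 1.0 for j in self.cross_couplings.values()
        )

    def to_dict(self) -> dict:
        d = {
            "l0": self.l0,
            "units": {
                "kd": "M",
                "v_half": "mV",
                "dh": "kcal/mol",
                "ds": "kcal/mol/K",
                "temperature": "C",
            },
            "pathways": [
                {
                    k: (v.value if isinstance(v, Enum) else v)
                    for k, v in vars(p).items()
                    if v is not None
                }
                for p in self.pathways
            ],
            "pore_couplings": dict(self.pore_couplings),
            "cross_couplings": [
                {"pair": sorted(k), "j": v} for k, v in self.cross_couplings.items()
            ],
            "metadata": dict(self.metadata),
        }
        if self.toxin is not None:
            d["toxin"] = {
                "hypothesis": self.toxin.hypothesis.value,
                "kd": self.toxin.kd,
                "efficacy": self.toxin.efficacy,
                "n_sites": self.toxin.n_sites,
                "pore_coupling": self.toxin.pore_coupling,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GatingModelSpec":
        toxin = None
        if d.get("toxin"):
            toxin = ToxinAttachment(**d["toxin"])
        return cls(
            l0=d["l0"],
            pathways=tuple(PathwaySpec(**p) for p in d["pathways"]),
            pore_couplings=d.get("pore_couplings", {}),
            cross_couplings={
                frozenset(c["pair"]): c["j"] for c in d.get("cross_couplings", [])
            },
            toxin=toxin,
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GatingModelSpec":
        path = str(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(d)


# --- calibrated defaults -----------------------------------------------------
#
# The pyramid's numeric parameters are calibrated, not experimentally
# measured: couplings J_capsaicin = J_heat = 800 with all cross-couplings 1;
# the heat sensor's dH = 100 kcal/mol with dS chosen so K_heat = 1 at 41 C
# (the heat-activation threshold of the channel); the capsaicin Kd and the
# toxin's apparent Kd/efficacy are tuned so the decorated model's room-
# temperature EC50s land near the measured macroscopic values (~214 nM for
# capsaicin, ~520 nM for the toxin).  L0 = 1e-2 keeps the saturating-agonist
# ceiling J*L0/(1+J*L0) ~ 0.89 at every temperature, so agonist responses are
# not swamped by direct heat activation at the top of the 10-50 C scan.

DEFAULT_DH = 100.0  # kcal/mol
DEFAULT_DS = DEFAULT_DH / (41.0 + CELSIUS_OFFSET)  # K_heat = 1 at 41 C
DEFAULT_L0 = 1e-2
DEFAULT_J = 800.0
DEFAULT_CAPSAICIN_KD = 2.031e-6  # M, calibrated: EC50 = 213.8 nM at 23 C, +80 mV
DEFAULT_TOXIN_KD = 6.164e-6  # M, calibrated apparent Kd: EC50 = 521.5 nM at 23 C
DEFAULT_TOXIN_EFFICACY = 2.0e4


def default_model_spec(
    l0: float = DEFAULT_L0,
    j_capsaicin: float = DEFAULT_J,
    j_heat: float = DEFAULT_J,
    j_voltage: float = 1.0,
    capsaicin_kd: float = DEFAULT_CAPSAICIN_KD,
    n_sites: int = 1,
) -> GatingModelSpec:
    """Calibrated default pyramid: capsaicin, voltage and heat sensors."""
    return GatingModelSpec(
        l0=l0,
        pathways=(
            PathwaySpec("capsaicin", Mechanism.LIGAND, kd=capsaicin_kd, n_sites=n_sites),
            PathwaySpec("voltage", Mechanism.VOLTAGE, z=0.6, v_half=120.0),
            PathwaySpec("heat", Mechanism.THERMAL, dh=DEFAULT_DH, ds=DEFAULT_DS),
        ),
        pore_couplings={"capsaicin": j_capsaicin, "voltage": j_voltage, "heat": j_heat},
        metadata={"provenance": "calibrated, not experimentally measured"},
    )


def ramp_model_spec() -> GatingModelSpec:
    """Heat-pathway spec used by the temperature-ramp generator.

    L0 = 1e-4 keeps spontaneous openings negligible so the heat-evoked
    current emerges from the leak near 40 C, as in inside-out patches.
    """
    return default_model_spec(l0=1e-4)


# --- model evaluation --------------------------------------------------------


def _log_sensor_term(k: float, j: float) -> float:
    """log((1 + K) / (1 + J*K)), stable for very large K."""
    if k > 1e12:
        return -math.log(j)
    return math.log1p(k) - math.log1p(j * k)


@dataclass(frozen=True)
class GatingModel:
    """Validated, immutable gating model.  Build with :func:`build_model`."""

    spec: GatingModelSpec

    # -- internals
    def _activation_factors(self, condition: StimulusCondition) -> dict[str, float]:
        ks = {p.name: p.activation(condition) for p in self.spec.pathways}
        tox = self.spec.toxin
        if tox is not None and tox.hypothesis is not ToxinHypothesis.INDEPENDENT_BRANCH:
            target = _BRANCH_TARGET[tox.hypothesis]
            if target in ks:
                ks[target] *= tox.occupancy_factor(condition.toxin_conc)
        return ks

    def open_probability(self, condition: StimulusCondition) -> float:
        """Open probability Po in (0, 1) at one stimulus condition."""
        ks = self._activation_factors(condition)
        js = self.spec.pore_couplings
        cross = self.spec.cross_couplings
        if not cross or all(j == 1.0 for j in cross.values()):
            # factorized partition function
            log_ratio = -math.log(self.spec.l0)
            for name, k in ks.items():
                log_ratio += _log_sensor_term(k, js[name])
            return 1.0 / (1.0 + math.exp(log_ratio))
        return self._po_enumerated(ks)

    def _po_enumerated(self, ks: dict[str, float]) -> float:
        names = list(ks)
        log_k = {n: (math.log(ks[n]) if ks[n] > 0 else -math.inf) for n in names}
        log_l0 = math.log(self.spec.l0)
        closed_terms: list[float] = []
        open_terms: list[float] = []
        for states in itertools.product((0, 1), repeat=len(names)):
            active = [n for n, s in zip(names, states) if s]
            if any(log_k[n] == -math.inf for n in active):
                continue
            w = sum(log_k[n] for n in active)
            for a, b in itertools.combinations(active, 2):
                w += math.log(self.spec.cross_couplings.get(_pair_key(a, b), 1.0))
            closed_terms.append(w)
            w_open = w + log_l0 + sum(
                math.log(self.spec.pore_couplings[n]) for n in active
            )
            open_terms.append(w_open)
        from scipy.special import logsumexp

        log_zc = logsumexp(closed_terms)
        log_zo = logsumexp(open_terms)
        return float(1.0 / (1.0 + math.exp(log_zc - log_zo)))

    # -- surfaces and derived quantities
    def po_surface(
        self,
        axis1: tuple[str, Sequence[float]],
        axis2: tuple[str, Sequence[float]],
        fixed: StimulusCondition,
    ) -> np.ndarray:
        """Po matrix over two stimulus grids.

        Rows follow ``axis1``, columns ``axis2``; entry (i, j) is the open
        probability with axis1's stimulus set to grid1[i] and axis2's to
        grid2[j], all other stimuli taken from ``fixed``.
        """
        for name, grid in (axis1, axis2):
            if name not in _STIMULUS_FIELD.values():
                raise GatingModelError(
                    f"axis {name!r} is not a stimulus; expected one of "
                    f"{sorted(_STIMULUS_FIELD.values())}"
                )
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise GatingModelError("axis grids must be non-empty")
            if grid.size > 1 and not (
                np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)
            ):
                raise GatingModelError(f"axis {name!r} grid must be monotone")
        (n1, g1), (n2, g2) = axis1, axis2
        out = np.empty((len(g1), len(g2)))
        for i, v1 in enumerate(g1):
            for j, v2 in enumerate(g2):
                cond = fixed.evolve(**{n1: float(v1), n2: float(v2)})
                out[i, j] = self.open_probability(cond)
        return out

    def saturating_condition(
        self, agonist: str, base: StimulusCondition, factor: float = 1e4
    ) -> StimulusCondition:
        """Condition with one agonist at ``factor`` times its Kd."""
        if agonist == "toxin":
            if self.spec.toxin is not None:
                kd = self.spec.toxin.kd
            else:
                ligands = [p for p in self.spec.pathways if p.name == "toxin"]
                if not ligands:
                    raise GatingModelError("model has no toxin attached")
                kd = ligands[0].kd
            return base.evolve(toxin_conc=factor * kd)
        if agonist == "capsaicin":
            ligands = [p for p in self.spec.pathways if p.name == "capsaicin"]
            if not ligands:
                raise GatingModelError("model has no capsaicin pathway")
            return base.evolve(capsaicin_conc=factor * ligands[0].kd)
        raise GatingModelError(f"unknown agonist {agonist!r}")


def build_model(spec: GatingModelSpec) -> GatingModel:
    """Validate a spec and return an immutable model object."""
    if not isinstance(spec, GatingModelSpec):
        raise GatingModelError("build_model expects a GatingModelSpec")
    return GatingModel(spec=spec)


def open_probability(model: GatingModel, condition: StimulusCondition) -> float:
    return model.open_probability(condition)


def po_surface(model, axis1, axis2, fixed) -> np.ndarray:
    return model.po_surface(axis1, axis2, fixed)


def attach_toxin(
    model: GatingModel,
    hypothesis: ToxinHypothesis | str,
    kd: float = DEFAULT_TOXIN_KD,
    efficacy: float = DEFAULT_TOXIN_EFFICACY,
    n_sites: int = 1,
    pore_coupling: float = DEFAULT_J,
    cross_couplings: Mapping | None = None,
) -> GatingModel:
    """Return a new model with the toxin coupled in; the original is unchanged.

    ``heat_branch``/``capsaicin_branch``/``voltage_branch`` multiply the
    corresponding sensor's activation factor by the toxin occupancy factor;
    ``independent_branch`` adds a toxin ligand sensor with its own pore
    coupling (toxin cross-couplings default to 1).
    """
    try:
        hypothesis = ToxinHypothesis(hypothesis)
    except ValueError as exc:
        raise GatingModelError(
            f"unknown toxin hypothesis {hypothesis!r}; expected one of "
            f"{[h.value for h in ToxinHypothesis]}"
        ) from exc
    attachment = ToxinAttachment(
        hypothesis=hypothesis,
        kd=kd,
        efficacy=efficacy,
        n_sites=n_sites,
        pore_coupling=pore_coupling,
    )
    spec = model.spec
    if hypothesis is ToxinHypothesis.INDEPENDENT_BRANCH:
        if any(p.name == "toxin" for p in spec.pathways):
            raise GatingModelError("model already has a toxin pathway")
        pathways = spec.pathways + (
            PathwaySpec("toxin", Mechanism.LIGAND, kd=kd, n_sites=n_sites),
        )
        pore = dict(spec.pore_couplings)
        pore["toxin"] = pore_coupling
        cross = dict(spec.cross_couplings)
        if cross_couplings:
            for key, j in dict(cross_couplings).items():
                cross[frozenset(key)] = j
        new_spec = replace(
            spec, pathways=pathways, pore_couplings=pore, cross_couplings=cross,
            toxin=attachment,
        )
    else:
        target = _BRANCH_TARGET[hypothesis]
        if target not in {p.name for p in spec.pathways}:
            raise GatingModelError(
                f"hypothesis {hypothesis.value} requires a {target!r} pathway"
            )
        new_spec = replace(spec, toxin=attachment)
    return build_model(new_spec)


@dataclass(frozen=True)
class HalfActivationResult:
    """Temperature at which Po first reaches a fraction of its scan maximum."""

    temperature: float
    found: bool
    max_po: float
    criterion: float


def half_activation_temperature(
    model: GatingModel,
    condition: StimulusCondition,
    criterion: float = 0.5,
    t_range: tuple[float, float] = (10.0, 50.0),
    grid_step: float = 0.25,
    tol: float = 0.01,
) -> HalfActivationResult:
    """First temperature where Po reaches ``criterion`` x the scan maximum.

    Scans ``t_range`` on a coarse grid, then bisects the first bracketing
    interval to ``tol`` (degrees C).  If Po never crosses the target the
    scan-range maximum temperature is returned flagged ``found=False``.
    """
    lo, hi = t_range
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    po = np.array(
        [model.open_probability(condition.evolve(temperature=float(t))) for t in grid]
    )
    max_po = float(po.max())
    target = criterion * max_po
    idx = np.flatnonzero(po >= target) if criterion < 1.0 else np.array([], dtype=int)
    if criterion >= 1.0 or idx.size == 0 or idx[0] == 0:
        if criterion < 1.0 and idx.size and idx[0] == 0:
            # already above target at the scan start: threshold at/below range
            return HalfActivationResult(float(grid[0]), True, max_po, criterion)
        return HalfActivationResult(float(grid[po.argmax()]), False, max_po, criterion)
    i = idx[0]
    t_lo, t_hi = float(grid[i - 1]), float(grid[i])
    f = lambda t: model.open_probability(condition.evolve(temperature=t)) - target
    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if f(mid) >= 0:
            t_hi = mid
        else:
            t_lo = mid
    return HalfActivationResult(0.5 * (t_lo + t_hi), True, max_po, criterion)


@dataclass(frozen=True)
class CoolingSelectivityReport:
    """Saturating-agonist Po vs temperature for toxin-only and capsaicin-only
    stimulation, with the selective-cooling-inhibition verdict."""

    temperatures: np.ndarray
    toxin_response: np.ndarray
    capsaicin_response: np.ndarray
    baseline: np.ndarray
    selective_cooling_inhibition: bool
    toxin_cold_fraction: float
    capsaicin_cold_fraction: float
    max_toxin_excess: float


def predict_cooling_selectivity(
    model: GatingModel,
    temperatures: Sequence[float] | None = None,
    voltage: float = 80.0,
    toxin_collapse_threshold: float = 0.10,
    capsaicin_preserved_threshold: float = 0.50,
    agonism_margin: float = 0.10,
) -> CoolingSelectivityReport:
    """Does cooling selectively abolish the toxin response?

    Selective cooling inhibition requires all of:

    1. toxin-evoked Po at the coldest scan temperature is below
       ``toxin_collapse_threshold`` times its value at the warmest;
    2. capsaicin-evoked Po at the coldest temperature exceeds
       ``capsaicin_preserved_threshold`` times its warmest value;
    3. the toxin is actually an agonist somewhere in the scan: its maximal
       excess Po over the unstimulated baseline exceeds ``agonism_margin``
       (this rules out attachments that leave the toxin inert, whose
       "response" would otherwise collapse trivially with the baseline).
    """
    spec = model.spec
    has_toxin = spec.toxin is not None or any(p.name == "toxin" for p in spec.pathways)
    if not has_toxin:
        raise GatingModelError("toxin not attached; call attach_toxin first")
    if temperatures is None:
        temperatures = np.arange(10.0, 50.0 + 0.5, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)
    base = StimulusCondition(voltage=voltage, temperature=float(temperatures[0]))
    tox_cond = model.saturating_condition("toxin", base)
    cap_cond = model.saturating_condition("capsaicin", base)
    tox = np.array(
        [model.open_probability(tox_cond.evolve(temperature=float(t))) for t in temperatures]
    )
    cap = np.array(
        [model.open_probability(cap_cond.evolve(temperature=float(t))) for t in temperatures]
    )
    baseline = np.array(
        [model.open_probability(base.evolve(temperature=float(t))) for t in temperatures]
    )
    tox_frac = float(tox[0] / tox[-1]) if tox[-1] > 0 else 1.0
    cap_frac = float(cap[0] / cap[-1]) if cap[-1] > 0 else 1.0
    excess = float(np.max(tox - baseline))
    selective = (
        tox_frac < toxin_collapse_threshold
        and cap_frac > capsaicin_preserved_threshold
        and excess > agonism_margin
    )
    return CoolingSelectivityReport(
        temperatures=temperatures,
        toxin_response=tox,
        capsaicin_response=cap,
        baseline=baseline,
        selective_cooling_inhibition=selective,
        toxin_cold_fraction=tox_frac,
        capsaicin_cold_fraction=cap_frac,
        max_toxin_excess=excess,
    )


def surface_to_frame(
    surface: np.ndarray,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
):
    """Long-format (stimulus1, stimulus2, Po) table for CSV export."""
    import pandas as pd

    (n1, g1), (n2, g2) = axis1, axis2
    rows = [
        {n1: float(v1), n2: float(v2), "po": float(surface[i, j])}
        for i, v1 in enumerate(g1)
        for j, v2 in enumerate(g2)
    ]
    return pd.DataFrame(rows)
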