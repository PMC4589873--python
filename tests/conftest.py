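import numpy as np
import pytest

from polymodal_gate import gating_model as gm


@pytest.fixture
def default_model():
    return gm.build_model(gm.default_model_spec())


@pytest.fixture
def room_condition():
    """Standard recording condition: +80 mV test pulse, room temperature."""
    return gm.StimulusCondition(voltage=80.0, temperature=23.0)


def random_spec_and_condition(rng: np.random.Generator):
    """Random small pyramid + condition for oracle-based property tests."""
    pathway_pool = [
        gm.PathwaySpec("capsaicin", "ligand", kd=10 ** rng.uniform(-8, -5)),
        gm.PathwaySpec("voltage", "voltage", z=rng.uniform(0.2, 2.0),
                       v_half=rng.uniform(-50, 150)),
        gm.PathwaySpec("heat", "thermal", dh=rng.uniform(20, 120),
                       ds=rng.uniform(0.05, 0.4)),
        gm.PathwaySpec("toxin", "ligand", kd=10 ** rng.uniform(-8, -5),
                       n_sites=int(rng.integers(1, 4))),
    ]
    k = int(rng.integers(1, len(pathway_pool) + 1))
    idx = rng.choice(len(pathway_pool), size=k, replace=False)
    pathways = tuple(pathway_pool[i] for i in sorted(idx))
    names = [p.name for p in pathways]
    pore = {n: 10 ** rng.uniform(-1, 3) for n in names}
    cross = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if rng.random() < 0.5:
                cross[frozenset((names[i], names[j]))] = 10 ** rng.uniform(-1, 1.5)
    spec = gm.GatingModelSpec(
        l0=10 ** rng.uniform(-5, 1),
        pathways=pathways,
        pore_couplings=pore,
        cross_couplings=cross,
    )
    condition = gm.StimulusCondition(
        capsaicin_conc=float(rng.uniform(0, 1e-5)),
        toxin_conc=float(rng.uniform(0, 1e-5)),
        voltage=float(rng.uniform(-100, 100)),
        temperature=float(rng.uniform(5, 55)),
    )
    return spec, condition


def enumerate_po(spec: gm.GatingModelSpec, condition: gm.StimulusCondition) -> float:
    """Brute-force oracle: explicit sum over all 2^(P+1) states.

    Independent of the package's factorized/log-space evaluation: plain
    products of Boltzmann weights over every sensor configuration and both
    pore states.
    """
    import itertools

    ks = {p.name: p.activation(condition) for p in spec.pathways}
    if spec.toxin is not None and spec.toxin.hypothesis.value != "independent_branch":
        target = {"heat_branch": "heat", "capsaicin_branch": "capsaicin",
                  "voltage_branch": "voltage"}[spec.toxin.hypothesis.value]
        if target in ks:
            ks[target] *= spec.toxin.occupancy_factor(condition.toxin_conc)
    names = list(ks)
    z_closed = 0.0
    z_open = 0.0
    for states in itertools.product((0, 1), repeat=len(names)):
        w = 1.0
        for n, s in zip(names, states):
            if s:
                w *= ks[n]
        active = [n for n, s in zip(names, states) if s]
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                w *= spec.cross_couplings.get(frozenset((active[i], active[j])), 1.0)
        z_closed += w
        w_open = w * spec.l0
        for n in active:
            w_open *= spec.pore_couplings[n]
        z_open += w_open
    return z_open / (z_closed + z_open)
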