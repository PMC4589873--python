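"""Gating-pyramid evaluation: closed forms, enumeration oracle, toxin
attachment hypotheses and derived temperature predictions."""

import numpy as np
import pytest

from polymodal_gate import gating_model as gm

from conftest import enumerate_po, random_spec_and_condition


class TestValidation:
    def test_non_positive_pore_coupling_rejected_by_name(self):
        with pytest.raises(gm.GatingModelError, match="heat"):
            gm.GatingModelSpec(
                l0=1.0,
                pathways=(gm.PathwaySpec("heat", "thermal", dh=100.0, ds=0.3),),
                pore_couplings={"heat": 0.0},
            )

    def test_duplicate_pathway_rejected(self):
        p = gm.PathwaySpec("capsaicin", "ligand", kd=1e-6)
        with pytest.raises(gm.GatingModelError, match="duplicate"):
            gm.GatingModelSpec(l0=1.0, pathways=(p, p), pore_couplings={})

    def test_unknown_pathway_name_rejected(self):
        with pytest.raises(gm.GatingModelError, match="unknown pathway"):
            gm.PathwaySpec("magnetism", "ligand", kd=1e-6)

    def test_default_spec_accepted_and_coupled(self):
        spec = gm.default_model_spec()
        model = gm.build_model(spec)
        assert spec.pore_couplings["capsaicin"] == 800.0
        assert spec.pore_couplings["heat"] == 800.0
        assert not spec.decoupled
        assert isinstance(model, gm.GatingModel)

    def test_all_couplings_one_flagged_decoupled(self):
        spec = gm.default_model_spec(j_capsaicin=1.0, j_heat=1.0, j_voltage=1.0)
        assert spec.decoupled

    def test_condition_guards(self):
        with pytest.raises(gm.GatingModelError):
            gm.StimulusCondition(capsaicin_conc=-1e-9)
        with pytest.raises(gm.GatingModelError, match="Kelvin"):
            gm.StimulusCondition(temperature=296.15)

    def test_spec_roundtrip_json_yaml(self, tmp_path):
        spec = gm.default_model_spec()
        for name in ("spec.json", "spec.yaml"):
            spec.save(tmp_path / name)
            loaded = gm.GatingModelSpec.load(tmp_path / name)
            cond = gm.StimulusCondition(capsaicin_conc=3e-7, voltage=80.0)
            assert gm.build_model(loaded).open_probability(cond) == pytest.approx(
                gm.build_model(spec).open_probability(cond), rel=1e-12
            )


class TestClosedForms:
    def test_decoupled_identity_po_is_l0_over_1_plus_l0(self):
        for l0 in (1e-4, 1e-2, 1.0, 10.0):
            spec = gm.default_model_spec(
                l0=l0, j_capsaicin=1.0, j_heat=1.0, j_voltage=1.0
            )
            model = gm.build_model(spec)
            for cond in (
                gm.StimulusCondition(),
                gm.StimulusCondition(capsaicin_conc=1e-3, voltage=100, temperature=50),
                gm.StimulusCondition(temperature=5.0, voltage=-80),
            ):
                assert model.open_probability(cond) == pytest.approx(
                    l0 / (1 + l0), rel=1e-12
                )

    def test_unity_l0_decoupled_gives_half(self):
        spec = gm.default_model_spec(l0=1.0, j_capsaicin=1.0, j_heat=1.0)
        model = gm.build_model(spec)
        assert model.open_probability(
            gm.StimulusCondition(capsaicin_conc=5e-6)
        ) == pytest.approx(0.5, rel=1e-12)

    def test_single_pathway_saturation_closed_form(self):
        # one saturated pathway with J=800, L0=0.01, others decoupled -> 8/9
        spec = gm.default_model_spec(l0=0.01, j_capsaicin=800.0, j_heat=1.0)
        model = gm.build_model(spec)
        cond = gm.StimulusCondition(capsaicin_conc=1e6, temperature=23.0)  # K -> inf limit
        assert model.open_probability(cond) == pytest.approx(8.0 / 9.0, rel=1e-6)
        # and the generic J*L0/(1+J*L0) law for other couplings
        for j in (2.0, 50.0, 1e4):
            spec_j = gm.default_model_spec(l0=0.01, j_capsaicin=j, j_heat=1.0)
            po = gm.build_model(spec_j).open_probability(cond)
            assert po == pytest.approx(j * 0.01 / (1 + j * 0.01), rel=1e-6)


class TestEnumerationOracle:
    def test_po_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(20150930)
        for _ in range(200):
            spec, cond = random_spec_and_condition(rng)
            model = gm.build_model(spec)
            expected = enumerate_po(spec, cond)
            got = model.open_probability(cond)
            assert got == pytest.approx(expected, rel=1e-12)
            assert 0.0 < got < 1.0

    def test_oracle_covers_attached_toxin(self):
        rng = np.random.default_rng(7)
        base = gm.build_model(gm.default_model_spec())
        for hyp in gm.ToxinHypothesis:
            model = gm.attach_toxin(base, hyp)
            for _ in range(20):
                cond = gm.StimulusCondition(
                    capsaicin_conc=float(rng.uniform(0, 1e-5)),
                    toxin_conc=float(rng.uniform(0, 1e-5)),
                    voltage=float(rng.uniform(-100, 100)),
                    temperature=float(rng.uniform(5, 55)),
                )
                assert model.open_probability(cond) == pytest.approx(
                    enumerate_po(model.spec, cond), rel=1e-12
                )


class TestPoSurface:
    def test_entries_equal_pointwise_calls(self, default_model, room_condition):
        caps = np.geomspace(1e-8, 1e-5, 5)
        temps = np.linspace(10, 50, 5)
        surface = default_model.po_surface(
            ("capsaicin_conc", caps), ("temperature", temps), room_condition
        )
        for i, c in enumerate(caps):
            for j, t in enumerate(temps):
                cond = room_condition.evolve(capsaicin_conc=float(c), temperature=float(t))
                assert surface[i, j] == default_model.open_probability(cond)

    def test_monotone_in_capsaicin_and_temperature(self, default_model, room_condition):
        caps = np.geomspace(1e-8, 1e-4, 8)
        temps = np.linspace(10, 50, 9)
        surface = default_model.po_surface(
            ("capsaicin_conc", caps), ("temperature", temps), room_condition
        )
        assert np.all(np.diff(surface, axis=0) > 0)
        assert np.all(np.diff(surface, axis=1) > 0)

    def test_constant_along_decoupled_toxin_axis(self, room_condition):
        base = gm.build_model(gm.default_model_spec())
        model = gm.attach_toxin(
            base, "independent_branch", pore_coupling=1.0
        )  # toxin couplings all 1
        tox = np.geomspace(1e-9, 1e-4, 6)
        temps = np.linspace(20, 40, 3)
        surface = model.po_surface(
            ("toxin_conc", tox), ("temperature", temps), room_condition
        )
        assert np.allclose(surface, surface[0, :], rtol=1e-12)

    def test_bad_axis_name_rejected(self, default_model, room_condition):
        with pytest.raises(gm.GatingModelError, match="not a stimulus"):
            default_model.po_surface(
                ("pressure", [1, 2]), ("temperature", [10, 20]), room_condition
            )

    def test_surface_long_format_export(self, default_model, room_condition):
        caps = np.geomspace(1e-8, 1e-6, 3)
        temps = np.linspace(20, 40, 3)
        surface = default_model.po_surface(
            ("capsaicin_conc", caps), ("temperature", temps), room_condition
        )
        frame = gm.surface_to_frame(surface, ("capsaicin_conc", caps), ("temperature", temps))
        assert list(frame.columns) == ["capsaicin_conc", "temperature", "po"]
        assert len(frame) == 9


class TestToxinAttachment:
    def test_zero_toxin_is_identity_under_every_hypothesis(self, default_model):
        conds = [
            gm.StimulusCondition(voltage=80, temperature=t, capsaicin_conc=c)
            for t in (15.0, 30.0, 45.0)
            for c in (0.0, 3e-7)
        ]
        for hyp in gm.ToxinHypothesis:
            attached = gm.attach_toxin(default_model, hyp)
            for cond in conds:
                assert attached.open_probability(cond) == pytest.approx(
                    default_model.open_probability(cond), rel=1e-12
                )

    def test_original_model_unchanged(self, default_model):
        gm.attach_toxin(default_model, "heat_branch")
        assert default_model.spec.toxin is None
        assert len(default_model.spec.pathways) == 3

    def test_unknown_hypothesis_rejected(self, default_model):
        with pytest.raises(gm.GatingModelError, match="unknown toxin hypothesis"):
            gm.attach_toxin(default_model, "outer_pore_branch")

    def test_heat_branch_downshifts_half_activation_temperature(self, default_model):
        model = gm.attach_toxin(default_model, "heat_branch")
        base = gm.StimulusCondition(voltage=80.0)
        without = gm.half_activation_temperature(model, base.evolve(toxin_conc=0.0))
        with_toxin = gm.half_activation_temperature(model, base.evolve(toxin_conc=100e-9))
        assert without.found and with_toxin.found
        assert with_toxin.temperature < without.temperature

    def test_heat_and_independent_branches_shape_po_temperature_differently(
        self, default_model
    ):
        temps = np.linspace(10, 50, 21)
        sat = 1e-3  # saturating toxin
        shapes = {}
        for hyp in ("heat_branch", "independent_branch"):
            model = gm.attach_toxin(default_model, hyp)
            po = np.array(
                [
                    model.open_probability(
                        gm.StimulusCondition(voltage=80, toxin_conc=sat, temperature=t)
                    )
                    for t in temps
                ]
            )
            shapes[hyp] = po / po.max()
        assert np.max(np.abs(shapes["heat_branch"] - shapes["independent_branch"])) > 0.3


class TestCoolingSelectivity:
    def test_heat_branch_is_uniquely_selective(self, default_model):
        verdicts = {}
        for hyp in gm.ToxinHypothesis:
            report = gm.predict_cooling_selectivity(gm.attach_toxin(default_model, hyp))
            verdicts[hyp.value] = report.selective_cooling_inhibition
        assert verdicts == {
            "heat_branch": True,
            "capsaicin_branch": False,
            "voltage_branch": False,
            "independent_branch": False,
        }

    def test_capsaicin_response_changes_less_than_toxin_response(self, default_model):
        report = gm.predict_cooling_selectivity(
            gm.attach_toxin(default_model, "heat_branch")
        )
        tox_change = report.toxin_response[-1] - report.toxin_response[0]
        cap_change = report.capsaicin_response[-1] - report.capsaicin_response[0]
        assert abs(cap_change) < abs(tox_change)

    def test_requires_attached_toxin(self, default_model):
        with pytest.raises(gm.GatingModelError, match="toxin not attached"):
            gm.predict_cooling_selectivity(default_model)

    def test_independent_branch_with_unit_couplings_not_selective(self, default_model):
        model = gm.attach_toxin(default_model, "independent_branch", pore_coupling=1.0)
        report = gm.predict_cooling_selectivity(model)
        assert not report.selective_cooling_inhibition


class TestHalfActivationTemperature:
    def test_criterion_one_flags_no_threshold_at_scan_maximum(self, default_model):
        res = gm.half_activation_temperature(
            default_model, gm.StimulusCondition(voltage=80.0), criterion=1.0
        )
        assert not res.found
        assert res.temperature == pytest.approx(50.0, abs=0.3)

    def test_bisection_matches_dense_grid(self, default_model):
        cond = gm.StimulusCondition(voltage=80.0)
        res = gm.half_activation_temperature(default_model, cond, criterion=0.5)
        temps = np.arange(10.0, 50.0001, 0.005)
        po = np.array(
            [default_model.open_probability(cond.evolve(temperature=float(t))) for t in temps]
        )
        target = 0.5 * po.max()
        grid_t = temps[np.flatnonzero(po >= target)[0]]
        assert res.found
        assert res.temperature == pytest.approx(grid_t, abs=0.02)


def test_thermal_sensor_equilibrium_increases_with_temperature():
    p = gm.PathwaySpec("heat", "thermal", dh=100.0, ds=gm.DEFAULT_DS)
    temps = np.linspace(0.0, 60.0, 25)
    ks = [p.activation(gm.StimulusCondition(temperature=float(t))) for t in temps]
    assert all(k > 0 for k in ks)
    assert np.all(np.diff(ks) > 0)
    # K = 1 at the calibrated half-activation temperature
    assert p.activation(gm.StimulusCondition(temperature=41.0)) == pytest.approx(1.0, rel=1e-9)
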