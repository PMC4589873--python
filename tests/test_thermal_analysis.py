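"""Arrhenius threshold detection, leak correction and heat-desensitization
quantification."""

import numpy as np
import pandas as pd
import pytest

from polymodal_gate import synthetic_data as syn
from polymodal_gate import thermal_analysis as th

KEL = 273.15


def piecewise_record(
    breakpoint_c=40.0,
    leak_slope=-2000.0,
    channel_slope=-22000.0,
    t_range=(25.0, 50.0),
    n=126,
    noise=0.0,
    seed=0,
    scale=1.0,
):
    """Exactly two-segment record on Arrhenius axes (generator ground truth)."""
    temp = np.linspace(*t_range, n)
    x = 1.0 / (temp + KEL)
    b = 1.0 / (breakpoint_c + KEL)
    y = 1.2 + leak_slope * (x - b) + np.where(x < b, (channel_slope - leak_slope) * (x - b), 0.0)
    cur = scale * 10.0**y
    rng = np.random.default_rng(seed)
    cur = cur * (1.0 + noise * rng.standard_normal(n))
    return th.TemperatureRampRecord(
        time=np.arange(n) * 0.1, temperature=temp, current=cur, condition="test"
    )


class TestDetectThreshold:
    def test_noiseless_breakpoint_recovered_exactly(self):
        fit = th.detect_threshold(piecewise_record(breakpoint_c=40.0))
        assert fit.found
        assert fit.threshold == pytest.approx(40.0, abs=0.1)
        assert fit.channel_slope < fit.leak_slope  # steeper fall on 1/T axis

    def test_single_slope_yields_no_threshold(self):
        temp = np.linspace(25, 50, 60)
        cur = 20.0 * np.exp(0.02 * (temp - 25.0))
        rec = th.TemperatureRampRecord(
            time=np.arange(60.0), temperature=temp, current=cur
        )
        fit = th.detect_threshold(rec)
        assert not fit.found and fit.threshold is None

    def test_scale_invariance_of_threshold(self):
        f1 = th.detect_threshold(piecewise_record(noise=0.05, seed=5))
        f2 = th.detect_threshold(piecewise_record(noise=0.05, seed=5, scale=50.0))
        assert f1.threshold == pytest.approx(f2.threshold, abs=1e-9)

    def test_bias_below_half_degree_at_five_percent_noise(self):
        errs = [
            th.detect_threshold(piecewise_record(noise=0.05, seed=s)).threshold - 40.0
            for s in range(100)
        ]
        assert abs(np.mean(errs)) < 0.5

    def test_leak_only_families_never_cross(self):
        # false-positive guard: noisy leak-only records yield no threshold
        temp = np.linspace(20, 50, 80)
        leak = 15.0 * np.exp(0.02 * (temp - 25.0))
        found = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            rec = th.TemperatureRampRecord(
                time=np.arange(80.0),
                temperature=temp,
                current=leak * (1 + 0.05 * rng.standard_normal(80)),
            )
            found += th.detect_threshold(rec).found
        assert found == 0

    def test_nonmonotone_temperature_rejected(self):
        temp = np.concatenate([np.linspace(25, 45, 30), np.linspace(44, 50, 10)])
        rec = th.TemperatureRampRecord(
            time=np.arange(40.0), temperature=temp, current=np.ones(40)
        )
        with pytest.raises(th.ThermalAnalysisError, match="monotone"):
            th.detect_threshold(rec)

    def test_generator_families_recover_programmed_shift(self):
        config = syn.TemperatureRampConfig(seed=9)
        shifts = []
        for s in range(8):
            records, manifest = syn.gen_temperature_ramp(config, stream=s)
            fits = {r.condition: th.detect_threshold(r) for r in records}
            assert all(f.found for f in fits.values())
            shifts.append(
                fits["control"].threshold - fits["RhTx_100nM"].threshold
            )
        assert np.mean(shifts) == pytest.approx(manifest["programmed_shift_C"], abs=1.0)

    def test_fixed_current_criterion_alternative(self):
        rec = piecewise_record()
        t = th.threshold_fixed_current(rec, criterion_pA=10 ** 1.2)
        assert t is not None and 38.0 < t < 42.0
        assert th.threshold_fixed_current(rec, criterion_pA=1e9) is None


class TestNormalizeHeatResponse:
    def test_zero_leak_correction_is_identity(self):
        rec = piecewise_record()
        fit = th.detect_threshold(rec)
        rec_ref = th.TemperatureRampRecord(
            time=rec.time,
            temperature=rec.temperature,
            current=rec.current,
            capsaicin_reference=1.0,
        )
        # with the leak segment removed the cold limb goes to ~0
        normalized = th.normalize_heat_response(rec_ref, fit)
        cold = normalized[rec.temperature < 35.0]
        assert np.all(np.abs(cold) < 0.05 * np.max(np.abs(normalized)))

    def test_reference_equal_current_gives_unity(self):
        # after leak correction the hot-end response equals the reference
        config = syn.TemperatureRampConfig(seed=3, noise_sigma=0.0, noise_floor_pA=0.0)
        records, manifest = syn.gen_temperature_ramp(config)
        rec = records[0]
        fit = th.detect_threshold(rec)
        normalized = th.normalize_heat_response(rec, fit)
        frac = manifest["channel_max_fraction_of_reference"]
        assert normalized.max() == pytest.approx(frac, rel=0.15)

    def test_known_fractional_amplitude_recovered(self):
        config = syn.TemperatureRampConfig(
            seed=12, channel_scale=5405.0, capsaicin_reference=1000.0
        )
        records, manifest = syn.gen_temperature_ramp(config)
        rec = records[0]
        normalized = th.normalize_heat_response(rec)
        assert normalized.max() == pytest.approx(
            manifest["channel_max_fraction_of_reference"], rel=0.2
        )

    def test_missing_reference_rejected(self):
        rec = piecewise_record()
        with pytest.raises(th.ThermalAnalysisError, match="reference"):
            th.normalize_heat_response(rec)


class TestDesensitizationRatio:
    def _table(self, heat, cap, groups=None):
        n = len(heat)
        return pd.DataFrame(
            {
                "patch": [f"p{i}" for i in range(n)],
                "group": groups or ["g"] * n,
                "heat_current_pA": heat,
                "capsaicin_current_pA": cap,
            }
        )

    def test_equal_currents_ratio_one(self):
        out = th.desensitization_ratio(self._table([500.0], [500.0]))
        assert out["ratios"]["ratio"].iloc[0] == pytest.approx(1.0)

    def test_ratios_invariant_to_common_rescaling(self):
        heat = [300.0, 800.0, 120.0]
        cap = [400.0, 900.0, 100.0]
        r1 = th.desensitization_ratio(self._table(heat, cap))["ratios"]["ratio"]
        r2 = th.desensitization_ratio(
            self._table([h * 7.5 for h in heat], [c * 7.5 for c in cap])
        )["ratios"]["ratio"]
        np.testing.assert_allclose(r1, r2)

    def test_non_positive_capsaicin_excluded_with_note(self):
        out = th.desensitization_ratio(self._table([100.0, 100.0], [500.0, 0.0]))
        assert len(out["ratios"]) == 1
        assert any("excluded" in n for n in out["notes"])

    def test_ablated_group_significant_at_hard_threshold(self):
        table, _ = syn.gen_desensitization_patches(
            syn.DesensitizationConfig(seed=21, n_per_group=8, ablation=0.0)
        )
        out = th.desensitization_ratio(table)
        assert out["comparison"]["significant"]
        assert out["comparison"]["p"] < 0.001

    def test_ramp_csv_roundtrip(self, tmp_path):
        records, _ = syn.gen_temperature_ramp(syn.TemperatureRampConfig(seed=2))
        th.write_ramp_csv(tmp_path / "ramps.csv", records)
        loaded = th.read_ramp_csv(tmp_path / "ramps.csv")
        assert [r.condition for r in loaded] == [r.condition for r in records]
        np.testing.assert_allclose(
            loaded[0].current, records[0].current, rtol=1e-4
        )
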