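"""FAIR quantification: T1app relation, kinetic model, dM, flow fit, masking."""

import numpy as np
import pytest

from tumorperf import (
    ASLConstants,
    ImageSeries,
    T1MapResult,
    apply_quality_mask,
    compute_delta_m,
    fair_delta_m_model,
    fit_perfusion,
    t1app_from_t1,
)
from tumorperf.asl_quant import DeltaMSeries

TIS = np.array([100.0, 350.0, 750.0, 1500.0, 2500.0, 4000.0])


class TestT1App:
    def test_zero_flow_limit(self):
        assert t1app_from_t1(1500.0, 0.0) == pytest.approx(1500.0)

    def test_arithmetic_example(self):
        # f=90 mL/100 g/min over lambda=0.9 mL/g is 0.016667 1/s
        assert t1app_from_t1(1500.0, 90.0, 0.9) == pytest.approx(1463.4, abs=0.1)

    def test_strictly_decreasing_in_flow(self):
        f = np.linspace(0, 300, 50)
        t1app = t1app_from_t1(1500.0, f)
        assert np.all(np.diff(t1app) < 0)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            t1app_from_t1(0.0, 90.0)


class TestKineticModel:
    def test_zero_flow_and_zero_ti(self):
        assert np.allclose(fair_delta_m_model(0.0, 1000.0, 1463.4, TIS), 0.0)
        assert fair_delta_m_model(90.0, 1000.0, 1463.4, 0.0) == 0.0

    def test_nonnegative_and_linear_in_flow(self):
        dm1 = fair_delta_m_model(45.0, 1000.0, 1463.4, TIS)
        dm2 = fair_delta_m_model(90.0, 1000.0, 1463.4, TIS)
        assert np.all(dm1 >= 0)
        assert np.allclose(dm2, 2.0 * dm1, rtol=1e-12)

    def test_removable_singularity_matches_limit(self):
        consts = ASLConstants()
        t1a = consts.t1a_ms
        limit = (
            2.0 * 1000.0 * consts.alpha
            * (60.0 / (100 * 60 * 1000 * consts.lambda_part))
            * TIS * np.exp(-TIS / t1a)
        )
        # exactly at the singularity and within a hair of it
        for eps in (0.0, 1e-6, -1e-6):
            got = fair_delta_m_model(60.0, 1000.0, t1a + eps, TIS, consts)
            assert np.allclose(got, limit, rtol=1e-9)
        # the general branch converges to the same limit
        got = fair_delta_m_model(60.0, 1000.0, t1a * (1 + 1e-4), TIS, consts)
        assert np.allclose(got, limit, rtol=1e-3)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            fair_delta_m_model(-1.0, 1000.0, 1463.4, TIS)

    def test_peak_ti_depends_on_t1app_not_flow(self):
        consts = ASLConstants()
        ti = np.linspace(1.0, 8000.0, 20000)
        t1app = 1400.0
        peaks = [ti[np.argmax(fair_delta_m_model(f, 1000.0, t1app, ti, consts))] for f in (30.0, 150.0)]
        assert peaks[0] == peaks[1]
        r_a, r_app = 1 / consts.t1a_ms, 1 / t1app
        analytic = np.log(r_app / r_a) / (r_app - r_a)
        assert peaks[0] == pytest.approx(analytic, rel=1e-3)


def _pair(ny=2, nx=3, repeats=40):
    base = np.zeros((ny, nx, TIS.size * repeats))
    control = ImageSeries(base.copy(), "ti_ms", TIS, repeats=repeats)
    label = ImageSeries(base.copy(), "ti_ms", TIS, repeats=repeats)
    return control, label


class TestDeltaM:
    def test_identical_series_give_zero(self):
        control, label = _pair()
        assert np.allclose(compute_delta_m(control, label).data, 0.0)

    def test_single_voxel_offset_hand_count(self):
        control, label = _pair()
        # +5 at voxel (1, 2), TI index 3, in every repeat
        for r in range(40):
            label.data[1, 2, r * TIS.size + 3] += 5.0
        dm = compute_delta_m(control, label)
        assert dm.data[1, 2, 3] == pytest.approx(5.0)
        dm.data[1, 2, 3] = 0.0
        assert np.allclose(dm.data, 0.0)

    def test_mismatched_inputs_rejected(self):
        control, _ = _pair()
        other = ImageSeries(np.zeros((2, 3, TIS.size)), "ti_ms", TIS, repeats=1)
        with pytest.raises(ValueError, match="repeat"):
            compute_delta_m(control, other)
        shifted = ImageSeries(np.zeros((2, 3, TIS.size * 40)), "ti_ms", TIS + 1.0, repeats=40)
        with pytest.raises(ValueError, match="TI list"):
            compute_delta_m(control, shifted)


def _t1fit(shape, t1=1463.4, m0=1000.0, r2=1.0):
    return T1MapResult(
        m0_map=np.full(shape, m0),
        t1_map=np.full(shape, t1),
        r2_map=np.full(shape, r2),
        converged_mask=np.ones(shape, bool),
    )


class TestFitPerfusion:
    def test_zero_delta_m_gives_zero_flow(self):
        dm = DeltaMSeries(np.zeros((2, 2, TIS.size)), TIS)
        pm = fit_perfusion(dm, _t1fit((2, 2)))
        assert np.allclose(pm.f_map, 0.0)

    def test_exact_model_curve_recovered(self):
        f_true = np.array([[10.0, 45.0], [90.0, 200.0]])
        curve = fair_delta_m_model(f_true[..., None], 1000.0, 1463.4, TIS[None, None, :])
        pm = fit_perfusion(DeltaMSeries(curve, TIS), _t1fit((2, 2)))
        assert np.allclose(pm.f_map, f_true, rtol=1e-10)

    def test_negative_signal_clamped_unless_diagnostic_mode(self):
        curve = -fair_delta_m_model(50.0, 1000.0, 1463.4, TIS)[None, None, :]
        dm = DeltaMSeries(curve, TIS)
        assert fit_perfusion(dm, _t1fit((1, 1))).f_map[0, 0] == 0.0
        assert fit_perfusion(dm, _t1fit((1, 1)), allow_negative=True).f_map[0, 0] == pytest.approx(-50.0)

    def test_roi_mean_is_arithmetic_mean_and_histogram_conserves(self):
        f_true = np.arange(1.0, 13.0).reshape(3, 4)
        curve = fair_delta_m_model(f_true[..., None], 1000.0, 1463.4, TIS[None, None, :])
        roi = np.zeros((3, 4), bool)
        roi[:2, :2] = True
        pm = fit_perfusion(DeltaMSeries(curve, TIS), _t1fit((3, 4)), roi_mask=roi)
        assert pm.roi_mean == pytest.approx(f_true[roi].mean())
        assert pm.hist_counts.sum() == int(pm.stats_mask.sum()) == 4

    def test_grid_mismatch_rejected(self):
        dm = DeltaMSeries(np.zeros((2, 2, TIS.size)), TIS)
        with pytest.raises(ValueError, match="mismatch"):
            fit_perfusion(dm, _t1fit((3, 3)))


class TestQualityMask:
    def test_all_good_is_identity(self):
        arr = np.arange(10.0).reshape(2, 5)
        out = apply_quality_mask(arr, np.ones((2, 5)))
        assert np.array_equal(out, arr)

    def test_counting_and_strict_boundary(self):
        arr = np.ones(10)
        r2 = np.ones(10)
        r2[:3] = 0.5
        assert np.isfinite(apply_quality_mask(arr, r2)).sum() == 7
        # R^2 exactly at the threshold is excluded (strict >)
        assert np.isnan(apply_quality_mask(np.array([1.0]), np.array([0.9]))[0])

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_quality_mask(np.ones(3), np.ones(3), threshold=1.5)
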