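"""Kill-model calibration and plate prediction/comparison."""

import math

import numpy as np
import pytest

from osadose.maps import FluenceMap
from osadose.scene import SceneConfig
from osadose.synth import SynthConfig, gen_analytic_fluence, gen_plate
from osadose.viability import (
    KillModel,
    PlateLayout,
    ViabilityMap,
    calibrate_kill_model,
    compare_plates,
    predict_plate,
)


def _uniform_map(value, shape=(120, 85), spacing=1.0):
    return FluenceMap(
        np.full(shape, float(value)), plane_z_mm=0.0, spacing_mm=spacing, duration_s=278.0
    )


class TestKillModelCalibration:
    def test_closed_form_slope_and_dp50(self):
        """10 uM, EC50 at 5 J/cm2, full kill at 20 J/cm2, 1% floor:
        dp50 = 50 uM.J/cm2 and h_k = ln(99)/ln(4)."""
        m = calibrate_kill_model(10.0, 5.0, 20.0, kill_floor=0.01)
        assert m.dp50_um_j_cm2 == pytest.approx(50.0)
        assert m.hill_slope == pytest.approx(math.log(99.0) / math.log(4.0))
        assert m.hill_slope == pytest.approx(3.31, abs=0.01)

    def test_pinned_thresholds(self):
        m = calibrate_kill_model(10.0, 5.0, 20.0, kill_floor=0.01)
        assert m.viability(5.0) == pytest.approx(0.5)
        assert m.viability(20.0) == pytest.approx(0.01)
        assert m.viability(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "args",
        [
            (10.0, 20.0, 5.0, 0.01),  # f50 >= f_kill
            (10.0, 5.0, 20.0, 0.6),  # infeasible floor
            (0.0, 5.0, 20.0, 0.01),  # no photosensitizer
        ],
    )
    def test_infeasible_calibrations_rejected(self, args):
        with pytest.raises(ValueError):
            calibrate_kill_model(*args)

    def test_monotone_in_fluence_and_concentration(self):
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        f = np.linspace(0, 50, 200)
        v = m.viability(f)
        assert np.all(np.diff(v) <= 1e-12)
        # at fixed dp50 and slope, more photosensitizer kills more
        m_hi = KillModel(
            dp50_um_j_cm2=m.dp50_um_j_cm2,
            hill_slope=m.hill_slope,
            concentration_um=20.0,
        )
        assert m_hi.viability(5.0) < m.viability(5.0)


class TestPredictPlate:
    def _layout(self, fmap):
        ex, ey = fmap.extent_mm
        return PlateLayout(origin_mm=(ex / 2 - 49.5, ey / 2 - 31.5))

    def test_zero_fluence_fully_viable(self):
        fmap = _uniform_map(0.0)
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        plate = predict_plate(fmap, self._layout(fmap), m)
        assert plate.values.shape == (8, 12)
        assert np.all(plate.values == 1.0)

    def test_full_kill_threshold_everywhere(self):
        fmap = _uniform_map(20.0)
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        plate = predict_plate(fmap, self._layout(fmap), m)
        assert np.all(plate.values <= 0.01 + 1e-12)

    def test_well_outside_map_rejected(self):
        fmap = _uniform_map(1.0, shape=(40, 40))
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        with pytest.raises(ValueError, match="beyond the map"):
            predict_plate(fmap, PlateLayout(origin_mm=(0.0, 0.0)), m)

    def test_translation_equivariance(self):
        """Shifting plate and fluence field together leaves predictions unchanged."""
        fmap = gen_analytic_fluence("two-line", shape=(140, 100), peak_j_cm2=25.0)
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        layout = PlateLayout(origin_mm=(12.0, 8.0))
        base = predict_plate(fmap, layout, m)
        shift = 7  # pixels == mm at 1-mm spacing
        rolled = FluenceMap(
            np.roll(fmap.values, shift, axis=0),
            plane_z_mm=fmap.plane_z_mm,
            spacing_mm=fmap.spacing_mm,
            duration_s=fmap.duration_s,
        )
        moved = predict_plate(rolled, layout.translated(shift, 0.0), m)
        assert np.allclose(base.values, moved.values)

    def test_layout_pitch_must_exceed_diameter(self):
        with pytest.raises(ValueError, match="pitch"):
            PlateLayout(pitch_mm=6.0)


class TestComparePlates:
    def test_identical_plates(self):
        v = ViabilityMap(np.linspace(0, 1, 96).reshape(8, 12), provenance="predicted")
        out = compare_plates(v, v)
        assert out["rmse"] == 0.0
        assert out["spearman"] == pytest.approx(1.0)
        assert out["confusion_at_50pct"]["predicted_only"] == 0

    def test_noise_floor_rmse(self):
        """Synthetic measured plate from the same truth with sigma=0.05 noise
        stays within RMSE 0.08 of the prediction."""
        fmap = gen_analytic_fluence("two-line", peak_j_cm2=25.0)
        ex, ey = fmap.extent_mm
        layout = PlateLayout(origin_mm=(ex / 2 - 49.5, ey / 2 - 31.5))
        m = calibrate_kill_model(10.0, 5.0, 20.0)
        predicted = predict_plate(fmap, layout, m)
        measured = gen_plate(fmap, layout, m, SynthConfig(seed=17, noise_sd=0.05))
        out = compare_plates(predicted, measured)
        assert out["rmse"] <= 0.08

    def test_unrelated_plates_uncorrelated(self):
        rng = np.random.default_rng(3)
        a = ViabilityMap(rng.random((8, 12)), provenance="predicted")
        b = ViabilityMap(rng.random((8, 12)), provenance="predicted")
        out = compare_plates(a, b)
        assert abs(out["spearman"]) < 0.3  # ~3 standard errors at n=96

    def test_mismatched_layouts_rejected(self):
        a = ViabilityMap(np.ones((8, 12)), provenance="predicted")
        b = ViabilityMap(np.ones((4, 6)), provenance="predicted")
        with pytest.raises(ValueError, match="layout"):
            compare_plates(a, b)


class TestPlateForScene:
    def test_overhang_places_last_column_beyond_applicator(self):
        cfg = SceneConfig(top_phantom_mm=3.0, backscatter_mm=15.0, voxel_size_mm=1.0)
        layout = PlateLayout.for_scene(cfg, overhang_cols=1)
        centers = layout.well_centers_mm()
        x0, x1, y0, y1 = cfg.osa_rect_mm
        assert centers[:, -1, 0].min() > x1  # last column beyond the right edge
        assert centers[:, -2, 0].max() < x1  # penultimate column still inside
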