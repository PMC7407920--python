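"""Score-to-dose conversion: normalization, units, arithmetic, comparisons."""

import numpy as np
import pytest

from osadose.maps import (
    FluenceMap,
    IrradianceMap,
    absorption_self_check,
    compare_configs,
    irradiance_to_fluence,
    linear_exposure,
    score_to_irradiance,
    source_roi,
)
from osadose.optics import phantom_properties
from osadose.scene import slab_scene
from osadose.transport import (
    LineDiffuserSource,
    RawScoreGrid,
    TransportSettings,
    run_transport,
)


def _raw_from_score(score, spacing=1.0, n_packets=1, plane=None):
    src = LineDiffuserSource(start_mm=(0, 0, 0), end_mm=(1, 0, 0))
    return RawScoreGrid(
        score=score,
        spacing_mm=spacing,
        n_packets=n_packets,
        seed=0,
        ledger={},
        scoring_plane_z_mm=plane if plane is not None else score.shape[2] * spacing,
        wavelength=532,
        sources=(src,),
    )


class TestScoreToIrradiance:
    def test_single_track_hand_computed(self):
        """One packet of weight 1 crossing one 1-mm voxel at 1 mW total power:
        fluence rate = 0.1 cm / 0.001 cm^3 x 1 mW = 100 mW/cm^2."""
        score = np.zeros((3, 3, 3))
        score[1, 1, 0] = 1.0  # weight.mm
        raw = _raw_from_score(score)
        imap = score_to_irradiance(raw, total_power_mw=1.0, plane_z_mm=0.5)
        assert imap.values[1, 1] == pytest.approx(100.0)
        assert imap.values.sum() == pytest.approx(100.0)

    def test_zero_score_gives_zero_map(self):
        raw = _raw_from_score(np.zeros((4, 4, 4)))
        imap = score_to_irradiance(raw, total_power_mw=5.0)
        assert np.all(imap.values == 0.0)

    def test_power_linearity_exact(self):
        rng = np.random.default_rng(0)
        raw = _raw_from_score(rng.random((5, 5, 5)))
        a = score_to_irradiance(raw, total_power_mw=10.0)
        b = score_to_irradiance(raw, total_power_mw=20.0)
        assert np.array_equal(b.values, 2.0 * a.values)

    def test_boundary_plane_uses_layer_below(self):
        score = np.zeros((2, 2, 4))
        score[:, :, 3] = 1.0
        raw = _raw_from_score(score)
        top = score_to_irradiance(raw, total_power_mw=1.0, plane_z_mm=4.0)
        assert np.all(top.values > 0)
        below = score_to_irradiance(raw, total_power_mw=1.0, plane_z_mm=3.0)
        assert np.all(below.values == 0.0)

    def test_plane_outside_grid_rejected(self):
        raw = _raw_from_score(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="outside"):
            score_to_irradiance(raw, total_power_mw=1.0, plane_z_mm=5.0)


class TestFluenceArithmetic:
    @pytest.mark.parametrize(
        "irr, t, fluence",
        [
            (28.0, 714.3, 20.0),  # green-light delivery
            (65.0, 3538.5, 230.0),  # red-light delivery
        ],
    )
    def test_delivery_schedules(self, irr, t, fluence):
        imap = IrradianceMap(np.full((3, 3), irr), plane_z_mm=0.5, spacing_mm=1.0, wavelength=532)
        fmap = irradiance_to_fluence(imap, t)
        assert fmap.values == pytest.approx(fluence, abs=0.01)

    def test_zero_irradiance_zero_fluence(self):
        imap = IrradianceMap(np.zeros((3, 3)), 0.5, 1.0, 532)
        assert np.all(irradiance_to_fluence(imap, 100.0).values == 0.0)

    def test_nonpositive_duration_rejected(self):
        imap = IrradianceMap(np.ones((3, 3)), 0.5, 1.0, 532)
        with pytest.raises(ValueError):
            irradiance_to_fluence(imap, 0.0)


class TestLinearExposure:
    def test_total_delivery(self):
        assert linear_exposure(200.0, 278.0) == pytest.approx(55.6)

    def test_per_fiber_delivery(self):
        assert linear_exposure(50.0, 278.0) == pytest.approx(13.9)

    @pytest.mark.parametrize("p, t", [(0.0, 278.0), (200.0, 0.0), (-1.0, 10.0)])
    def test_nonpositive_inputs_rejected(self, p, t):
        with pytest.raises(ValueError):
            linear_exposure(p, t)


class TestCompareConfigs:
    def _fmap(self, values):
        return FluenceMap(values, plane_z_mm=1.0, spacing_mm=1.0, duration_s=1.0)

    def test_identical_maps_ratio_one(self):
        f = self._fmap(np.full((4, 4), 2.0))
        out = compare_configs(f, f)
        assert np.all(out["ratio"] == 1.0)
        assert out["mean_ratio"] == 1.0

    def test_zero_denominator_masked(self):
        a = self._fmap(np.ones((2, 2)))
        b = self._fmap(np.array([[1.0, 0.0], [1.0, 1.0]]))
        out = compare_configs(a, b)
        assert np.isnan(out["ratio"][0, 1])
        assert out["mean_ratio"] == 1.0

    def test_mismatched_grids_rejected(self):
        a = self._fmap(np.ones((3, 3)))
        b = self._fmap(np.ones((4, 4)))
        with pytest.raises(ValueError, match="identical pixel grid"):
            compare_configs(a, b)


class TestConfigurationPhysics:
    def test_backscatter_increases_plate_fluence(self, osa_full_run, osa_no_backscatter_run):
        """The thick phantom below the applicator reflects light upward."""
        _, _, raw_bs = osa_full_run
        _, _, raw_no = osa_no_backscatter_run
        roi = source_roi(raw_bs)
        f_bs = irradiance_to_fluence(score_to_irradiance(raw_bs), 278.0)
        f_no = irradiance_to_fluence(score_to_irradiance(raw_no), 278.0)
        out = compare_configs(f_bs, f_no, roi=roi)
        assert out["mean_a"] > out["mean_b"]
        assert out["mean_ratio"] > 1.0

    def test_top_phantom_attenuates(self, osa_full_run, osa_no_phantom_run):
        """Light transmitted past a 3-mm top phantom is strictly less than
        past the bare applicator.

        Compared in the air layer just above the stack in both
        configurations: inside a turbid layer the local fluence is inflated
        by diffusive buildup, so the transmitted light above the surface is
        the like-for-like attenuation measure.
        """
        _, _, raw_top = osa_full_run
        _, _, raw_bare = osa_no_phantom_run
        roi = source_roi(raw_top)
        h = raw_top.spacing_mm
        f_top = irradiance_to_fluence(
            score_to_irradiance(raw_top, plane_z_mm=raw_top.scoring_plane_z_mm + h / 2),
            278.0,
        )
        f_bare = irradiance_to_fluence(
            score_to_irradiance(raw_bare, plane_z_mm=raw_bare.scoring_plane_z_mm + h / 2),
            278.0,
        )
        assert f_top.values[roi].mean() < f_bare.values[roi].mean()

    def test_absorption_estimators_agree(self):
        """Track-length and collision absorption estimates agree within 0.5%."""
        scene = slab_scene(20.0, phantom_properties(532), lateral_mm=(60, 60))
        src = LineDiffuserSource(start_mm=(20, 30, 10), end_mm=(40, 30, 10))
        raw = run_transport(scene, [src], TransportSettings(n_packets=50_000, seed=0))
        check = absorption_self_check(raw, scene)
        assert check["relative_difference"] < 0.005


class TestPersistence:
    def test_map_regenerated_from_saved_score_is_identical(self, tmp_path, osa_full_run):
        _, _, raw = osa_full_run
        path = tmp_path / "score.h5"
        raw.save(path)
        again = RawScoreGrid.load(path)
        a = score_to_irradiance(raw)
        b = score_to_irradiance(again)
        assert np.array_equal(a.values, b.values)
        assert a.plane_z_mm == b.plane_z_mm

    def test_csv_export_with_sidecar(self, tmp_path):
        from osadose.maps import save_map_csv

        fmap = FluenceMap(np.ones((3, 4)), plane_z_mm=2.0, spacing_mm=1.0, duration_s=278.0)
        out = tmp_path / "fluence.csv"
        save_map_csv(fmap, out)
        assert np.allclose(np.loadtxt(out, delimiter=","), 1.0)
        sidecar = out.with_suffix(".csv.json").read_text()
        assert "J/cm^2" in sidecar and "278" in sidecar
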