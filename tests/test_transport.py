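"""Monte Carlo engine: emission sampling, physics limits, conservation,
determinism, and the diffusion-theory oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from osadose import _kernel
from osadose.optics import OpticalProperties, phantom_properties
from osadose.scene import SceneConfig, build_scene, slab_scene
from osadose.transport import (
    LineDiffuserSource,
    PhotonPacket,
    TransportSettings,
    make_osa_sources,
    propagate,
    run_transport,
    sample_emission,
)


class TestEmission:
    def test_positions_uniform_on_segment(self, rng):
        src = LineDiffuserSource(start_mm=(10, 20, 5), end_mm=(30, 20, 5))
        pos = np.array([sample_emission(src, rng).position_mm for _ in range(100_000)])
        # mean -> midpoint within 3 standard errors (sd of U(10,30) = 20/sqrt(12))
        se = 20.0 / math.sqrt(12.0) / math.sqrt(len(pos))
        assert abs(pos[:, 0].mean() - 20.0) < 3 * se
        assert np.all(pos[:, 1] == 20.0) and np.all(pos[:, 2] == 5.0)

    def test_directions_isotropic(self, rng):
        src = LineDiffuserSource(start_mm=(0, 0, 0), end_mm=(1, 0, 0))
        d = np.array([sample_emission(src, rng).direction for _ in range(100_000)])
        se = 1.0 / math.sqrt(3.0) / math.sqrt(len(d))  # sd of each component
        assert np.all(np.abs(d.mean(axis=0)) < 3 * se)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)

    def test_zero_length_source_rejected(self):
        with pytest.raises(ValueError, match="length"):
            LineDiffuserSource(start_mm=(1, 1, 1), end_mm=(1, 1, 1))


class TestPhaseFunction:
    def test_isotropic_limit_uniform_cosine(self, rng):
        """At g = 0 the scattering cosine is uniform on [-1, 1] (KS, alpha=0.01)."""
        u = rng.random(100_000)
        cos = np.array([_kernel._hg_cos(0.0, ui) for ui in u])
        res = stats.kstest(cos, stats.uniform(loc=-1, scale=2).cdf)
        assert res.pvalue > 0.01

    def test_anisotropic_mean_cosine_equals_g(self, rng):
        g = 0.9
        u = rng.random(100_000)
        cos = np.array([_kernel._hg_cos(g, ui) for ui in u])
        se = cos.std() / math.sqrt(len(cos))
        assert abs(cos.mean() - g) < 3 * se
        assert np.all((cos >= -1) & (cos <= 1))


class TestPropagation:
    def test_beer_lambert_pure_absorber(self):
        """Pencil beam through a pure absorber: transmission exp(-mu_a d)."""
        props = OpticalProperties(mu_a=2.0, mu_s_prime=0.0, g=0.0, n=1.0)
        scene = slab_scene(10.0, props, lateral_mm=(20, 20), voxel_size_mm=1.0)
        settings = TransportSettings(n_packets=1, seed=0)
        n, transmitted = 20_000, 0.0
        score = np.zeros(scene.shape)
        for i in range(n):
            p = PhotonPacket(position_mm=(10.0, 10.0, 0.0), direction=(0.0, 0.0, 1.0))
            rec = propagate(p, scene, settings, score=score, packet_id=i)
            if rec["status"] == "escaped" and rec["exit_position_mm"][2] >= 10.0 - 1e-9:
                transmitted += rec["escaped_weight"]
        p_true = math.exp(-0.2 * 10.0)  # mu_a = 2/cm = 0.2/mm over 10 mm
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(transmitted / n - p_true) < 4 * se

    def test_straight_track_deposits_length_per_voxel(self):
        """In vacuum each traversed voxel accumulates weight x voxel edge."""
        props = OpticalProperties(mu_a=0.0, mu_s_prime=0.0, g=0.0, n=1.0)
        scene = slab_scene(5.0, props, lateral_mm=(5, 5), voxel_size_mm=1.0)
        p = PhotonPacket(position_mm=(2.5, 2.5, 0.0), direction=(0.0, 0.0, 1.0))
        rec = propagate(p, scene, TransportSettings(n_packets=1, seed=0))
        col = rec["score"][2, 2, :]
        assert np.allclose(col, 1.0)
        assert rec["score"].sum() == pytest.approx(5.0)

    def test_packet_starting_outside_rejected(self):
        scene = slab_scene(5.0, phantom_properties(532), lateral_mm=(5, 5))
        p = PhotonPacket(position_mm=(10.0, 1.0, 1.0), direction=(0.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            propagate(p, scene, TransportSettings(n_packets=1, seed=0))


class TestRunTransport:
    def test_transparent_scene_conserves_all_weight(self):
        props = OpticalProperties(mu_a=0.0, mu_s_prime=0.0, g=0.0, n=1.0)
        scene = slab_scene(10.0, props, lateral_mm=(20, 20))
        src = LineDiffuserSource(start_mm=(5, 10, 5), end_mm=(15, 10, 5))
        raw = run_transport(scene, [src], TransportSettings(n_packets=5_000, seed=3))
        assert raw.ledger["absorbed"] == 0.0
        assert raw.ledger["escaped"] == pytest.approx(raw.ledger["launched"])

    def test_same_seed_bit_identical(self):
        scene = slab_scene(10.0, phantom_properties(532), lateral_mm=(30, 30))
        src = LineDiffuserSource(start_mm=(10, 15, 5), end_mm=(20, 15, 5))
        settings = TransportSettings(n_packets=5_000, seed=7)
        a = run_transport(scene, [src], settings)
        b = run_transport(scene, [src], settings)
        assert np.array_equal(a.score, b.score)
        assert a.ledger == b.ledger
        c = run_transport(scene, [src], TransportSettings(n_packets=5_000, seed=8))
        assert not np.array_equal(a.score, c.score)

    def test_source_outside_scene_rejected(self):
        scene = slab_scene(10.0, phantom_properties(532), lateral_mm=(30, 30))
        src = LineDiffuserSource(start_mm=(10, 15, 5), end_mm=(20, 15, 50))
        with pytest.raises(ValueError, match="outside"):
            run_transport(scene, [src], TransportSettings(n_packets=10, seed=0))

    def test_no_sources_rejected(self):
        scene = slab_scene(10.0, phantom_properties(532), lateral_mm=(30, 30))
        with pytest.raises(ValueError, match="at least one"):
            run_transport(scene, [], TransportSettings(n_packets=10, seed=0))

    def test_mirror_symmetric_sources_give_mirror_symmetric_score(self):
        """Two sources mirrored about the y mid-plane produce a score grid
        symmetric under the same reflection, up to Monte Carlo noise."""
        scene = slab_scene(20.0, phantom_properties(532), lateral_mm=(60, 60))
        srcs = [
            LineDiffuserSource(start_mm=(20, 20, 10), end_mm=(40, 20, 10)),
            LineDiffuserSource(start_mm=(20, 40, 10), end_mm=(40, 40, 10)),
        ]
        raw = run_transport(scene, srcs, TransportSettings(n_packets=100_000, seed=5))
        a = raw.score
        b = raw.score[:, ::-1, :]
        # coarse-bin to suppress per-voxel noise, compare where signal exists
        blocks_a = a.reshape(15, 4, 15, 4, 20).sum(axis=(1, 3))
        blocks_b = b.reshape(15, 4, 15, 4, 20).sum(axis=(1, 3))
        mask = blocks_a + blocks_b > 0.01 * blocks_a.max()
        rel = np.abs(blocks_a - blocks_b)[mask] / (blocks_a + blocks_b)[mask]
        assert np.quantile(rel, 0.95) < 0.1

    def test_energy_ledger_closure(self, ledger_report):
        """Roulette bookkeeping closes exactly; expectation closes < 1e-3."""
        assert ledger_report["exact_closure"] < 1e-9
        assert ledger_report["statistical_closure"] < 1e-3
        assert ledger_report["passed"]


class TestDiffusionOracle:
    @pytest.mark.parametrize("wavelength", [532, 630])
    def test_point_source_matches_diffusion_theory(self, oracle_reports, wavelength):
        """Shell-averaged MC fluence within 5% of exp(-mu_eff r)/(4 pi D r)
        over 1 <= mu_eff r <= 4 for both phantom characterizations."""
        report = oracle_reports[wavelength]
        assert report["max_relative_deviation"] < 0.05

    def test_similarity_relation_g09_vs_isotropic(self):
        """g=0.9 and reduced g=0 runs agree on layer fluence beyond one
        transport mean free path (within 10%)."""
        full = phantom_properties(532)
        layer_means = {}
        for tag, props in (("hg", full), ("iso", full.reduced())):
            scene = slab_scene(20.0, props, lateral_mm=(50, 50), voxel_size_mm=1.0)
            src = LineDiffuserSource(start_mm=(24.5, 25, 10), end_mm=(25.5, 25, 10))
            raw = run_transport(scene, [src], TransportSettings(n_packets=60_000, seed=9))
            layer_means[tag] = raw.score.mean(axis=(0, 1))
        mfp_t = 10.0 / (full.mu_a + full.mu_s_prime)  # transport mfp, mm
        z = np.arange(20) + 0.5
        sel = np.abs(z - 10.0) > mfp_t
        ratio = layer_means["hg"][sel] / layer_means["iso"][sel]
        assert np.all(np.abs(ratio - 1.0) < 0.1)


class TestOsaSources:
    def test_two_fibers_share_total_power(self):
        cfg = SceneConfig(top_phantom_mm=3.0, backscatter_mm=15.0, voxel_size_mm=1.0)
        srcs = make_osa_sources(cfg, total_linear_power_mw_per_cm=200.0)
        assert len(srcs) == 2
        # 100 mW/cm per 2-cm fiber -> 200 mW each, 400 mW total
        assert sum(s.total_power_mw for s in srcs) == pytest.approx(400.0)
        assert srcs[0].length_mm == pytest.approx(20.0)
        ys = sorted(s.start_mm[1] for s in srcs)
        assert ys[1] - ys[0] == pytest.approx(30.0)
        assert all(s.start_mm[2] == cfg.fiber_z_mm for s in srcs)

    def test_per_fiber_power_reading(self):
        cfg = SceneConfig(top_phantom_mm=0.0, backscatter_mm=0.0, voxel_size_mm=1.0)
        srcs = make_osa_sources(cfg, total_linear_power_mw_per_cm=50.0, per_fiber=True)
        assert sum(s.total_power_mw for s in srcs) == pytest.approx(200.0)
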