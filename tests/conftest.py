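"""Shared fixtures: small Monte Carlo runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from osadose.maps import irradiance_to_fluence, score_to_irradiance
from osadose.pipeline import conservation_report, diffusion_oracle_report
from osadose.scene import SceneConfig, build_scene
from osadose.transport import TransportSettings, make_osa_sources, run_transport

DURATION_S = 278.0
TOTAL_LINEAR_POWER = 200.0  # mW/cm across both fibers


def _osa_run(top_mm: float, backscatter_mm: float, n_packets: int, seed: int):
    cfg = SceneConfig(
        wavelength=532,
        top_phantom_mm=top_mm,
        backscatter_mm=backscatter_mm,
        voxel_size_mm=1.0,
    )
    scene = build_scene(cfg)
    sources = make_osa_sources(
        cfg, total_linear_power_mw_per_cm=TOTAL_LINEAR_POWER, duration_s=DURATION_S
    )
    raw = run_transport(scene, sources, TransportSettings(n_packets=n_packets, seed=seed))
    return cfg, scene, raw


@pytest.fixture(scope="session")
def osa_full_run():
    """Phantom-above + backscatter-below configuration (the end-to-end geometry)."""
    return _osa_run(top_mm=3.0, backscatter_mm=15.0, n_packets=200_000, seed=1)


@pytest.fixture(scope="session")
def osa_full_fluence(osa_full_run):
    _, _, raw = osa_full_run
    return irradiance_to_fluence(score_to_irradiance(raw), DURATION_S)


@pytest.fixture(scope="session")
def osa_no_backscatter_run():
    return _osa_run(top_mm=3.0, backscatter_mm=0.0, n_packets=100_000, seed=1)


@pytest.fixture(scope="session")
def osa_no_phantom_run():
    return _osa_run(top_mm=0.0, backscatter_mm=15.0, n_packets=100_000, seed=1)


@pytest.fixture(scope="session")
def oracle_reports():
    """Diffusion-approximation comparison at both wavelengths."""
    return {wl: diffusion_oracle_report(wavelength=wl) for wl in (532, 630)}


@pytest.fixture(scope="session")
def ledger_report():
    return conservation_report()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
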