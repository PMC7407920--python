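"""Synthetic data generators.

No raw viability data accompanies the experiments this package models, so
every pipeline stage is exercised against synthetic inputs built here:
triplicate Hill-shaped concentration-viability datasets on the
experimental concentration grids, measured-style 96-well plates derived
from a ground-truth fluence field, and closed-form fluence patterns that
let the plate-prediction stages run without a Monte Carlo simulation.

All generators are pure functions of (truth, config): the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import k0

from .dose_response import DoseResponseDataset, hill
from .maps import FluenceMap
from .viability import KillModel, PlateLayout, ViabilityMap, predict_plate

__all__ = [
    "SynthConfig",
    "HillTruth",
    "GREEN_GRID_UM",
    "RED_GRID_UM",
    "DARK_GRID_UM",
    "GREEN_TRUTH",
    "RED_TRUTH",
    "gen_dose_response",
    "gen_plate",
    "gen_analytic_fluence",
]

#: Concentration grids (uM) used in the light / dark viability experiments.
GREEN_GRID_UM = (0.01, 0.05, 0.1, 0.3, 0.5)
RED_GRID_UM = (2.0, 10.0, 20.0, 40.0)
DARK_GRID_UM = (0.1, 0.3, 0.5, 1.0, 5.0, 10.0, 30.0, 60.0)


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    noise_sd: float = 0.03
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class HillTruth:
    ec50_um: float
    hill_slope: float = 2.0
    top: float = 1.0
    bottom: float = 0.0


#: Ground truths anchored to the measured light-condition potencies.
GREEN_TRUTH = HillTruth(ec50_um=0.099)
RED_TRUTH = HillTruth(ec50_um=20.9)


def gen_dose_response(
    truth: HillTruth,
    grid_um,
    config: SynthConfig,
    condition: str = "synthetic",
) -> DoseResponseDataset:
    """Replicate viability observations: Hill curve + Gaussian noise, clipped at 0."""
    grid = np.asarray(grid_um, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("concentration grid must be non-empty and positive")
    rng = np.random.default_rng(config.seed)
    conc = np.tile(grid, config.n_replicates)
    rep = np.repeat(np.arange(config.n_replicates), grid.size)
    clean = hill(conc, truth.ec50_um, truth.hill_slope, truth.top, truth.bottom)
    v = clean + rng.normal(0.0, config.noise_sd, size=conc.shape)
    v = np.clip(v, 0.0, None)
    return DoseResponseDataset(
        concentration_um=conc, viability=v, condition=condition, replicate=rep
    )


def gen_plate(
    fluence_truth: FluenceMap,
    layout: PlateLayout,
    kill: KillModel,
    config: SynthConfig,
) -> ViabilityMap:
    """Measured-style plate: model prediction + per-well noise, clipped to [0, 1]."""
    pred = predict_plate(fluence_truth, layout, kill)
    rng = np.random.default_rng(config.seed)
    noisy = pred.values + rng.normal(0.0, config.noise_sd, size=pred.values.shape)
    return ViabilityMap(
        values=np.clip(noisy, 0.0, 1.0),
        provenance="measured-synthetic",
        layout=layout,
    )


def clipping_fraction(values: np.ndarray) -> float:
    """Fraction of entries sitting exactly on a clip boundary."""
    v = np.asarray(values)
    return float(np.mean((v == 0.0) | (v == 1.0)))


def gen_analytic_fluence(
    pattern: str,
    *,
    shape: tuple[int, int] = (120, 85),
    spacing_mm: float = 1.0,
    peak_j_cm2: float = 30.0,
    duration_s: float = 278.0,
    mu_eff_cm: float = 2.29,
    source_separation_mm: float = 30.0,
    source_length_mm: float = 20.0,
) -> FluenceMap:
    """Closed-form fluence fields for exercising the plate stages.

    ``uniform``: constant map at ``peak_j_cm2``. ``two-line``: superposition
    of two parallel line-diffusion kernels, each the modified Bessel profile
    K0(mu_eff r) of an infinite line source in a diffusive medium, truncated
    to the finite source length and normalized so the map maximum equals
    ``peak_j_cm2``.
    """
    if peak_j_cm2 < 0:
        raise ValueError("peak fluence must be >= 0")
    nx, ny = shape
    if pattern == "uniform":
        values = np.full((nx, ny), peak_j_cm2, dtype=float)
    elif pattern == "two-line":
        xc = (np.arange(nx) + 0.5) * spacing_mm
        yc = (np.arange(ny) + 0.5) * spacing_mm
        x_mid = nx * spacing_mm / 2.0
        y_mid = ny * spacing_mm / 2.0
        mu_eff_mm = mu_eff_cm / 10.0
        values = np.zeros((nx, ny))
        for dy in (-source_separation_mm / 2.0, source_separation_mm / 2.0):
            # perpendicular distance to the finite segment along x
            ax = np.clip(np.abs(xc - x_mid) - source_length_mm / 2.0, 0.0, None)
            ry = yc - (y_mid + dy)
            r = np.sqrt(ax[:, None] ** 2 + ry[None, :] ** 2)
            r = np.maximum(r, spacing_mm / 2.0)
            values += k0(mu_eff_mm * r)
        if values.max() > 0:
            values *= peak_j_cm2 / values.max()
    else:
        raise ValueError(f"unknown pattern {pattern!r}; use 'uniform' or 'two-line'")
    return FluenceMap(
        values=values,
        plane_z_mm=0.0,
        spacing_mm=spacing_mm,
        duration_s=duration_s,
    )
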