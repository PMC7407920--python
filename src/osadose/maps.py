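"""Irradiance and fluence maps at the plate interface.

A raw track-length score S (weight.mm summed per voxel) becomes a fluence
rate by normalizing per launched packet and per voxel volume and scaling by
the total source power:

    E [mW/cm^2] = S / V_voxel * P_total / N_packets

and fluence is fluence rate integrated over the delivery time,
F [J/cm^2] = E x t / 1000. The map plane is the single voxel layer
containing the requested z (no interpolation), matching a plate resting on
the surface of the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .transport import RawScoreGrid

__all__ = [
    "IrradianceMap",
    "FluenceMap",
    "score_to_irradiance",
    "irradiance_to_fluence",
    "linear_exposure",
    "compare_configs",
    "source_roi",
    "absorption_self_check",
    "save_map_csv",
    "save_map_tiff",
]


@dataclass
class IrradianceMap:
    """Planar fluence-rate grid, mW/cm^2."""

    values: np.ndarray  # (nx, ny)
    plane_z_mm: float
    spacing_mm: float
    wavelength: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("irradiance values must be finite and non-negative")


@dataclass
class FluenceMap:
    """Planar fluence grid, J/cm^2."""

    values: np.ndarray
    plane_z_mm: float
    spacing_mm: float
    duration_s: float
    wavelength: int = 532

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("fluence values must be finite and non-negative")

    @property
    def extent_mm(self) -> tuple[float, float]:
        nx, ny = self.values.shape
        return (nx * self.spacing_mm, ny * self.spacing_mm)


def _plane_layer(raw: RawScoreGrid, plane_z_mm: float) -> int:
    nz = raw.score.shape[2]
    h = raw.spacing_mm
    if not 0.0 <= plane_z_mm <= nz * h:
        raise ValueError(f"plane z={plane_z_mm} mm lies outside the grid [0, {nz * h}]")
    # a plane coinciding with a layer boundary belongs to the layer below it,
    # matching a plate resting on the surface of the stack
    k = int(np.ceil(plane_z_mm / h)) - 1
    return max(0, min(k, nz - 1))


def score_to_irradiance(
    raw: RawScoreGrid,
    total_power_mw: float | None = None,
    plane_z_mm: float | None = None,
) -> IrradianceMap:
    """Normalize the score layer at ``plane_z_mm`` to physical fluence rate.

    Defaults: the run's scoring plane and the summed source power. Output
    scales linearly in ``total_power_mw``, so re-scaling never requires
    re-simulation.
    """
    if total_power_mw is None:
        total_power_mw = raw.total_source_power_mw
    if total_power_mw <= 0:
        raise ValueError("total_power_mw must be > 0")
    if plane_z_mm is None:
        plane_z_mm = raw.scoring_plane_z_mm
    k = _plane_layer(raw, plane_z_mm)
    h = raw.spacing_mm
    # (weight.mm / mm^3) = mm^-2; x100 converts to cm^-2
    values = raw.score[:, :, k] / (h**3) * (total_power_mw / raw.n_packets) * 100.0
    return IrradianceMap(
        values=values, plane_z_mm=plane_z_mm, spacing_mm=h, wavelength=raw.wavelength
    )


def irradiance_to_fluence(imap: IrradianceMap, duration_s: float) -> FluenceMap:
    """Fluence = fluence rate x delivery time (mW -> W conversion)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return FluenceMap(
        values=imap.values * duration_s / 1000.0,
        plane_z_mm=imap.plane_z_mm,
        spacing_mm=imap.spacing_mm,
        duration_s=duration_s,
        wavelength=imap.wavelength,
    )


def linear_exposure(linear_power_mw_per_cm: float, duration_s: float) -> float:
    """Linear radiant exposure in J/cm: linear power density x time."""
    if linear_power_mw_per_cm <= 0:
        raise ValueError("linear power must be > 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return linear_power_mw_per_cm * duration_s / 1000.0


def compare_configs(
    map_a: FluenceMap,
    map_b: FluenceMap,
    roi: tuple[slice, slice] | None = None,
) -> dict:
    """Elementwise ratio a/b with zero-denominator pixels masked.

    Returns the masked ratio array plus the mean ratio and mean fluences
    over the region of interest (the whole map when ``roi`` is omitted).
    """
    if map_a.values.shape != map_b.values.shape or map_a.spacing_mm != map_b.spacing_mm:
        raise ValueError("maps must share an identical pixel grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(map_b.values > 0, map_a.values / map_b.values, np.nan)
    if roi is None:
        roi = (slice(None), slice(None))
    ra = map_a.values[roi]
    rb = map_b.values[roi]
    rr = ratio[roi]
    return {
        "ratio": ratio,
        "mean_ratio": float(np.nanmean(rr)),
        "mean_a": float(ra.mean()),
        "mean_b": float(rb.mean()),
        "roi": roi,
    }


def source_roi(raw: RawScoreGrid, margin_mm: float = 5.0) -> tuple[slice, slice]:
    """Rectangle spanned by the source footprints plus a margin, as index slices."""
    if not raw.sources:
        raise ValueError("run has no recorded sources")
    pts = np.array(
        [list(s.start_mm) for s in raw.sources] + [list(s.end_mm) for s in raw.sources]
    )
    h = raw.spacing_mm
    nx, ny = raw.score.shape[:2]
    x0 = max(0, int((pts[:, 0].min() - margin_mm) / h))
    x1 = min(nx, int(np.ceil((pts[:, 0].max() + margin_mm) / h)))
    y0 = max(0, int((pts[:, 1].min() - margin_mm) / h))
    y1 = min(ny, int(np.ceil((pts[:, 1].max() + margin_mm) / h)))
    return (slice(x0, x1), slice(y0, y1))


def absorption_self_check(raw: RawScoreGrid, scene) -> dict:
    """Cross-check the two absorption estimators.

    The track-length estimate integrates score x mu_a per voxel; the
    collision estimate is the ledger's absorbed weight. Both equal the
    absorbed fraction of launched weight in expectation.
    """
    mu_a_mm = np.array([m.mu_a / 10.0 for m in scene.materials])
    track = float(np.sum(raw.score * mu_a_mm[scene.labels]))
    collision = raw.ledger["absorbed"]
    rel = abs(track - collision) / collision if collision > 0 else 0.0
    return {"track_length": track, "collision": collision, "relative_difference": rel}


def _sidecar(map_obj, extra: dict) -> dict:
    meta = {
        "plane_z_mm": map_obj.plane_z_mm,
        "spacing_mm": map_obj.spacing_mm,
        "wavelength_nm": map_obj.wavelength,
    }
    meta.update(extra)
    return meta


def save_map_csv(map_obj: IrradianceMap | FluenceMap, path: str | Path) -> None:
    """Write the grid as CSV plus a JSON sidecar with units and plane metadata."""
    path = Path(path)
    np.savetxt(path, map_obj.values, delimiter=",")
    units = "J/cm^2" if isinstance(map_obj, FluenceMap) else "mW/cm^2"
    extra = {"units": units}
    if isinstance(map_obj, FluenceMap):
        extra["duration_s"] = map_obj.duration_s
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_sidecar(map_obj, extra), indent=2)
    )


def save_map_tiff(map_obj: IrradianceMap | FluenceMap, path: str | Path) -> None:
    """Write the grid as 32-bit TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, map_obj.values.astype(np.float32))
    units = "J/cm^2" if isinstance(map_obj, FluenceMap) else "mW/cm^2"
    extra = {"units": units}
    if isinstance(map_obj, FluenceMap):
        extra["duration_s"] = map_obj.duration_s
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_sidecar(map_obj, extra), indent=2)
    )
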