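"""Fluence -> predicted 96-well viability maps.

The kill model treats the dose product concentration x fluence as the dose
metric, consistent with the uM.(J/cm^2) potency summaries of the
dose-response layer:

    v(F) = 1 / (1 + (c F / dp50)^h_k)

Calibration pins the curve to two fluence thresholds at a working
concentration: the fluence producing 50% viability (f50, so
dp50 = c x f50) and the fluence producing "complete" kill, operationalized
as a small residual viability floor (default 1%, since an exact zero is
unreachable under a Hill form). A 96-well plate is predicted by averaging
the fluence map over each well's disc footprint and pushing the mean
through the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .maps import FluenceMap

__all__ = [
    "PlateLayout",
    "KillModel",
    "ViabilityMap",
    "calibrate_kill_model",
    "predict_plate",
    "compare_plates",
]


@dataclass(frozen=True)
class PlateLayout:
    """Standard 96-well geometry positioned in scene coordinates.

    ``origin_mm`` is the center of well (row 0, column 0); rows advance
    along y, columns along x, at the standard 9-mm pitch.
    """

    rows: int = 8
    cols: int = 12
    pitch_mm: float = 9.0
    well_diameter_mm: float = 6.4
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pitch_mm <= self.well_diameter_mm:
            raise ValueError("well pitch must exceed well diameter")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("plate must have at least one well")

    def well_centers_mm(self) -> np.ndarray:
        """(rows, cols, 2) array of (x, y) well-center coordinates."""
        x0, y0 = self.origin_mm
        cx = x0 + np.arange(self.cols) * self.pitch_mm
        cy = y0 + np.arange(self.rows) * self.pitch_mm
        out = np.empty((self.rows, self.cols, 2))
        out[..., 0] = cx[None, :]
        out[..., 1] = cy[:, None]
        return out

    def translated(self, dx_mm: float, dy_mm: float) -> "PlateLayout":
        x0, y0 = self.origin_mm
        return PlateLayout(
            rows=self.rows,
            cols=self.cols,
            pitch_mm=self.pitch_mm,
            well_diameter_mm=self.well_diameter_mm,
            origin_mm=(x0 + dx_mm, y0 + dy_mm),
        )

    @classmethod
    def for_scene(cls, config, overhang_cols: int = 1) -> "PlateLayout":
        """Plate centered on the applicator, overhanging its right edge.

        With ``overhang_cols`` = 1 the rightmost well column sits beyond the
        applicator footprint, reproducing the edge-of-field arrangement used
        to probe viability just outside the treated region.
        """
        x0, x1, y0, y1 = config.osa_rect_mm
        layout = cls()
        span_x = (layout.cols - 1) * layout.pitch_mm
        span_y = (layout.rows - 1) * layout.pitch_mm
        # place so that `overhang_cols` columns lie beyond x1
        ox = x1 + (overhang_cols - 0.5) * layout.pitch_mm - span_x
        oy = 0.5 * (y0 + y1) - span_y / 2.0
        return cls(origin_mm=(ox, oy))


@dataclass(frozen=True)
class KillModel:
    """Hill kill curve in the dose product c x F."""

    dp50_um_j_cm2: float
    hill_slope: float
    concentration_um: float

    def __post_init__(self) -> None:
        if self.dp50_um_j_cm2 <= 0:
            raise ValueError("dp50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill slope must be > 0")
        if self.concentration_um <= 0:
            raise ValueError("concentration must be > 0")

    def viability(self, fluence_j_cm2):
        """Predicted surviving fraction at the model's working concentration."""
        f = np.asarray(fluence_j_cm2, dtype=float)
        dp = self.concentration_um * f
        return 1.0 / (1.0 + (dp / self.dp50_um_j_cm2) ** self.hill_slope)


def calibrate_kill_model(
    concentration_um: float,
    f50_j_cm2: float,
    f_kill_j_cm2: float,
    kill_floor: float = 0.01,
) -> KillModel:
    """Solve the Hill slope from the two fluence thresholds.

    ``f50`` is the fluence inducing 50% viability; ``f_kill`` the fluence
    treated as complete kill, i.e. viability equal to ``kill_floor``.
    Closed form: dp50 = c x f50 and
    h_k = ln(1/kill_floor - 1) / ln(f_kill / f50).
    """
    if concentration_um <= 0:
        raise ValueError("concentration must be > 0")
    if not 0 < f50_j_cm2 < f_kill_j_cm2:
        raise ValueError("require 0 < f50 < f_kill")
    if not 0 < kill_floor < 0.5:
        raise ValueError("kill_floor must be in (0, 0.5)")
    h_k = math.log(1.0 / kill_floor - 1.0) / math.log(f_kill_j_cm2 / f50_j_cm2)
    return KillModel(
        dp50_um_j_cm2=concentration_um * f50_j_cm2,
        hill_slope=h_k,
        concentration_um=concentration_um,
    )


@dataclass
class ViabilityMap:
    """Per-well viability fractions with provenance."""

    values: np.ndarray  # (rows, cols) in [0, 1]
    provenance: str  # "predicted" | "measured-synthetic"
    layout: PlateLayout | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("viability values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [chr(ord("A") + i) for i in range(self.values.shape[0])]
        return pd.DataFrame(
            self.values, index=rows, columns=np.arange(1, self.values.shape[1] + 1)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def well_fluence(fluence: FluenceMap, layout: PlateLayout) -> np.ndarray:
    """Footprint-mean fluence per well (rows x cols), J/cm^2.

    Averages over all map pixels whose centers fall inside the well disc;
    raises if any well footprint extends beyond the map.
    """
    h = fluence.spacing_mm
    nx, ny = fluence.values.shape
    centers = layout.well_centers_mm()
    r = layout.well_diameter_mm / 2.0
    ex, ey = fluence.extent_mm
    out = np.empty((layout.rows, layout.cols))
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    for i in range(layout.rows):
        for j in range(layout.cols):
            wx, wy = centers[i, j]
            if wx - r < 0 or wx + r > ex or wy - r < 0 or wy + r > ey:
                raise ValueError(
                    f"well ({i}, {j}) at ({wx:.1f}, {wy:.1f}) mm extends beyond the map"
                )
            mx = np.abs(xc - wx) <= r
            my = np.abs(yc - wy) <= r
            sub = fluence.values[np.ix_(mx, my)]
            dx = xc[mx] - wx
            dy = yc[my] - wy
            disc = dx[:, None] ** 2 + dy[None, :] ** 2 <= r * r
            if not disc.any():
                raise ValueError(f"map too coarse: no pixels inside well ({i}, {j})")
            out[i, j] = float(sub[disc].mean())
    return out


def predict_plate(
    fluence: FluenceMap, layout: PlateLayout, model: KillModel
) -> ViabilityMap:
    """Predict per-well viability from a fluence map via the kill model."""
    wf = well_fluence(fluence, layout)
    return ViabilityMap(
        values=model.viability(wf), provenance="predicted", layout=layout
    )


def compare_plates(predicted: ViabilityMap, measured: ViabilityMap) -> dict:
    """Agreement summaries: RMSE, Spearman correlation, confusion at 50%.

    Descriptive statistics only; no significance claims.
    """
    if predicted.values.shape != measured.values.shape:
        raise ValueError("plates must share a layout")
    p = predicted.values.ravel()
    m = measured.values.ravel()
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        rho = 1.0 if np.allclose(p, m) else float("nan")
    else:
        rho = float(spearmanr(p, m).statistic)
    pk = p < 0.5
    mk = m < 0.5
    confusion = {
        "both_killed": int(np.sum(pk & mk)),
        "predicted_only": int(np.sum(pk & ~mk)),
        "measured_only": int(np.sum(~pk & mk)),
        "both_viable": int(np.sum(~pk & ~mk)),
    }
    return {"rmse": rmse, "spearman": rho, "confusion_at_50pct": confusion}
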