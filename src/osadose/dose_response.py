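"""Concentration-viability dose-response modelling.

Viability v as a function of photosensitizer concentration C is described by
a four-parameter Hill (log-logistic) curve

    v(C) = bottom + (top - bottom) / (1 + (C / EC50)^h),

fitted by multi-start least squares on log10 concentration to all replicate
points jointly. Derived potency summaries: the phototherapeutic index
(dark EC50 / light EC50, reported as a lower bound when the dark curve is
censored), the EC50 dose product (EC50 x delivered fluence, uM.J/cm^2),
and fold differences between light conditions.

A curve whose fitted EC50 exceeds the highest tested concentration is
flagged *censored* and its EC50 reported as that lower bound — the standard
situation for a dark-toxicity curve that never reaches 50% kill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseDataset",
    "DoseResponseModel",
    "hill",
    "fit_dose_response",
    "phototherapeutic_index",
    "dose_product",
    "fold_difference",
    "round_to_sig",
]


def hill(conc, ec50: float, hill_slope: float, top: float = 1.0, bottom: float = 0.0):
    """Four-parameter Hill viability curve (decreasing in concentration)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill_slope)


@dataclass
class DoseResponseDataset:
    """Tidy replicate-level viability observations for one condition."""

    concentration_um: np.ndarray
    viability: np.ndarray
    condition: str = "unspecified"
    irradiance_mw_cm2: float | None = None
    fluence_j_cm2: float | None = None
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration_um = np.asarray(self.concentration_um, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentration_um.shape != self.viability.shape:
            raise ValueError("concentration and viability must have equal length")
        if np.any(self.concentration_um <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(self.viability < 0):
            raise ValueError("viability must be >= 0")

    @property
    def n_concentrations(self) -> int:
        return len(np.unique(self.concentration_um))

    @property
    def max_concentration_um(self) -> float:
        return float(self.concentration_um.max())

    def to_frame(self) -> pd.DataFrame:
        rep = (
            self.replicate
            if self.replicate is not None
            else np.zeros(len(self.viability), dtype=int)
        )
        return pd.DataFrame(
            {
                "condition": self.condition,
                "concentration_uM": self.concentration_um,
                "replicate": rep,
                "viability": self.viability,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, condition: str | None = None) -> "DoseResponseDataset":
        """Read the tidy CSV schema (condition, concentration_uM, replicate, viability)."""
        df = pd.read_csv(path)
        required = {"condition", "concentration_uM", "replicate", "viability"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        if condition is not None:
            df = df[df["condition"] == condition]
            if df.empty:
                raise ValueError(f"{path}: no rows for condition {condition!r}")
        else:
            conds = df["condition"].unique()
            if len(conds) > 1:
                raise ValueError(f"{path}: multiple conditions {list(conds)}; pick one")
            condition = conds[0]
        return cls(
            concentration_um=df["concentration_uM"].to_numpy(),
            viability=df["viability"].to_numpy(),
            condition=str(condition),
            replicate=df["replicate"].to_numpy(),
        )


@dataclass
class DoseResponseModel:
    """Fitted Hill parameters with standard errors.

    When ``censored`` is true, ``ec50_um`` is a lower bound (the highest
    tested concentration), not a point estimate.
    """

    ec50_um: float
    hill_slope: float
    top: float
    bottom: float
    se: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    censored: bool = False
    condition: str = "unspecified"

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("ec50 must be > 0")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")
        if self.top > 1.2:
            raise ValueError("top exceeds the assay ceiling of 1.2")

    def predict(self, conc):
        return hill(conc, self.ec50_um, self.hill_slope, self.top, self.bottom)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "ec50_um": self.ec50_um,
            "hill_slope": self.hill_slope,
            "top": self.top,
            "bottom": self.bottom,
            "censored": self.censored,
            "se": self.se,
        }


def _hill_logx(logc, log_ec50, h, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - log_ec50) * h))


def fit_dose_response(data: DoseResponseDataset) -> DoseResponseModel:
    """Multi-start least-squares fit of the 4-parameter Hill model.

    Fits on log10 concentration to all replicate points jointly. Raises if
    fewer than 4 distinct concentrations are available or no start
    converges. Flat curves (no detectable kill over the tested range) are
    returned censored at the highest tested concentration.
    """
    if data.n_concentrations < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations to fit, got {data.n_concentrations}"
        )
    logc = np.log10(data.concentration_um)
    v = data.viability
    cmax = data.max_concentration_um

    # flat-curve handling: no fit is identifiable without a response
    per_conc = pd.Series(v).groupby(logc).mean()
    drop = float(per_conc.max() - per_conc.min())
    if drop < 0.05:
        return DoseResponseModel(
            ec50_um=cmax,
            hill_slope=1.0,
            top=min(float(per_conc.mean()), 1.2),
            bottom=0.0,
            censored=True,
            condition=data.condition,
        )

    lo = [logc.min() - 3.0, 0.05, 0.0, 0.0]
    hi = [logc.max() + 3.0, 20.0, 1.2, 1.2]
    best = None
    top0 = min(float(per_conc.iloc[0]), 1.2)
    bot0 = max(float(per_conc.iloc[-1]), 0.0)
    for le0 in np.linspace(logc.min() - 1.0, logc.max() + 1.0, 7):
        for h0 in (0.5, 1.0, 2.0, 4.0):
            p0 = [le0, h0, top0, min(bot0, top0)]
            try:
                popt, pcov = curve_fit(
                    _hill_logx,
                    logc,
                    v,
                    p0=p0,
                    bounds=(lo, hi),
                    maxfev=20000,
                    xtol=1e-13,
                    ftol=1e-13,
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((_hill_logx(logc, *popt) - v) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(
            "dose-response fit did not converge from any start "
            f"(condition {data.condition!r}, {len(v)} points)"
        )
    _, popt, pcov = best
    log_ec50, h, top, bottom = popt
    ec50 = 10.0**log_ec50
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se = {
        "ec50_um": math.log(10.0) * ec50 * perr[0],  # delta method
        "hill_slope": perr[1],
        "top": perr[2],
        "bottom": perr[3],
    }
    if ec50 > cmax:
        return DoseResponseModel(
            ec50_um=cmax,
            hill_slope=h,
            top=top,
            bottom=min(bottom, top),
            se=se,
            covariance=pcov,
            censored=True,
            condition=data.condition,
        )
    return DoseResponseModel(
        ec50_um=ec50,
        hill_slope=h,
        top=top,
        bottom=min(bottom, top),
        se=se,
        covariance=pcov,
        censored=False,
        condition=data.condition,
    )


def phototherapeutic_index(
    dark: DoseResponseModel, light: DoseResponseModel
) -> tuple[float, bool]:
    """Dark EC50 over light EC50; ``(value, is_lower_bound)``.

    The ratio is a lower bound whenever the dark curve is censored (its
    EC50 is itself only a lower bound). A censored light curve admits no
    index at all.
    """
    if light.censored:
        raise ValueError("light-condition EC50 is censored; index undefined")
    return dark.ec50_um / light.ec50_um, dark.censored


def dose_product(ec50_um: float, fluence_j_cm2: float) -> float:
    """EC50 dose product, uM.(J/cm^2)."""
    if ec50_um <= 0 or fluence_j_cm2 <= 0:
        raise ValueError("ec50 and fluence must both be > 0")
    return ec50_um * fluence_j_cm2


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fold_difference(dp_a: float, dp_b: float) -> float:
    """Ratio of two dose products, rounded to 2 significant figures."""
    if dp_a <= 0 or dp_b <= 0:
        raise ValueError("dose products must both be > 0")
    return round_to_sig(dp_a / dp_b, 2)
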