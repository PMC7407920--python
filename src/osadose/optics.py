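"""Optical properties of turbid media.

Absorption (``mu_a``) and reduced scattering (``mu_s_prime``) coefficients
are stored in cm^-1, the unit in which tissue-phantom recipes are quoted;
the transport kernel converts to mm^-1 at a single, documented boundary
(:func:`osadose.scene.VoxelScene.kernel_tables`).

The built-in material table covers the three media of the surface-applicator
experiments: an agar/intralipid/India-ink tissue phantom (at 532 and 630 nm),
the silicone of the applicator beads, and air.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "OpticalProperties",
    "phantom_properties",
    "builtin_materials",
    "load_material_table",
    "SILICONE",
    "AIR",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-medium optical constants.

    Parameters
    ----------
    mu_a:
        Absorption coefficient, cm^-1.
    mu_s_prime:
        Reduced scattering coefficient ``mu_s * (1 - g)``, cm^-1.
    g:
        Henyey-Greenstein scattering anisotropy, dimensionless, in [0, 1).
    n:
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    n: float = 1.37

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime < 0:
            raise ValueError(f"mu_s_prime must be >= 0, got {self.mu_s_prime}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient ``mu_s_prime / (1 - g)``, cm^-1."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient ``mu_a + mu_s``, cm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo ``mu_s / mu_t`` (0 for vacuum)."""
        mt = self.mu_t
        return self.mu_s / mt if mt > 0 else 0.0

    @property
    def mu_eff(self) -> float:
        """Effective attenuation ``sqrt(3 mu_a (mu_a + mu_s_prime))``, cm^-1."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))

    @property
    def penetration_depth_mm(self) -> float:
        """Diffusion 1/e penetration depth ``1 / mu_eff`` in mm (inf if mu_eff == 0)."""
        me = self.mu_eff
        return math.inf if me == 0 else 10.0 / me

    @property
    def diffusion_constant(self) -> float:
        """Diffusion constant ``D = 1 / (3 (mu_a + mu_s_prime))``, cm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    def reduced(self) -> "OpticalProperties":
        """Isotropic-scattering equivalent (g = 0, mu_s = mu_s_prime).

        By the similarity relation this medium has the same diffusive
        behaviour but far fewer scattering events per unit path, which makes
        it the cheap choice for diffusion-regime validation runs.
        """
        return replace(self, g=0.0)

    def index_matched(self, n: float = 1.0) -> "OpticalProperties":
        """Copy with the refractive index replaced (for boundary-free oracles)."""
        return replace(self, n=n)


#: Applicator silicone: effectively transparent, slightly absorbing.
SILICONE = OpticalProperties(mu_a=0.01, mu_s_prime=0.0, g=0.0, n=1.41)

#: Air treated as vacuum for transport purposes.
AIR = OpticalProperties(mu_a=0.0, mu_s_prime=0.0, g=0.0, n=1.0)

_PHANTOM = {
    532: OpticalProperties(mu_a=0.24, mu_s_prime=7.05, g=0.9, n=1.37),
    630: OpticalProperties(mu_a=0.26, mu_s_prime=7.00, g=0.9, n=1.37),
}


def phantom_properties(wavelength: int) -> OpticalProperties:
    """Tissue-mimicking phantom constants at 532 or 630 nm."""
    try:
        return _PHANTOM[int(wavelength)]
    except KeyError:
        raise ValueError(
            f"no phantom characterization at {wavelength} nm; known: {sorted(_PHANTOM)}"
        ) from None


def builtin_materials(wavelength: int) -> dict[str, OpticalProperties]:
    """Default material table for a scene at the given wavelength."""
    return {
        "air": AIR,
        "phantom": phantom_properties(wavelength),
        "silicone": SILICONE,
    }


def load_material_table(path: str | Path) -> dict[tuple[str, int], OpticalProperties]:
    """Read a YAML material table.

    The file holds a top-level ``materials`` list of mappings with keys
    ``name, wavelength, mu_a, mu_s_prime`` and optional ``g, n``. Entries are
    keyed by ``(name, wavelength)`` in the returned dict.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "materials" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'materials' list")
    table: dict[tuple[str, int], OpticalProperties] = {}
    for entry in doc["materials"]:
        missing = {"name", "wavelength", "mu_a", "mu_s_prime"} - set(entry)
        if missing:
            raise ValueError(f"{path}: material entry missing keys {sorted(missing)}")
        props = OpticalProperties(
            mu_a=float(entry["mu_a"]),
            mu_s_prime=float(entry["mu_s_prime"]),
            g=float(entry.get("g", 0.9)),
            n=float(entry.get("n", 1.37)),
        )
        table[(str(entry["name"]), int(entry["wavelength"]))] = props
    return table
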