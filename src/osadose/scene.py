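"""Voxelized scene geometry for surface-applicator dosimetry.

The physical stack, bottom to top, is: an optional thick "backscatter"
phantom slab, the optical surface applicator (OSA) — a layer of 10-mm
silicone spheres on a square lattice with embedded line-diffuser channels —
and an optional thin phantom slab that stands in for overlying tissue. The
scoring plane (where a 96-well plate would rest) is the top surface of the
stack.

Conventions: z increases from the backscatter bottom to the plate top; all
lengths are stored in mm; voxels own the half-open cube
``[i*h, (i+1)*h)`` on each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalProperties, builtin_materials

__all__ = [
    "LABEL_AIR",
    "LABEL_PHANTOM",
    "LABEL_SILICONE",
    "SceneConfig",
    "VoxelScene",
    "build_scene",
    "material_at",
    "slab_scene",
]

LABEL_AIR = 0
LABEL_PHANTOM = 1
LABEL_SILICONE = 2


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of one experimental configuration.

    ``top_phantom_mm`` in {0, 3, 5} and ``backscatter_mm`` in {0, 15}
    reproduce the three applicator set-ups (applicator alone, phantom on
    top, backscatter below); other values are allowed for exploration.
    """

    wavelength: int = 532
    top_phantom_mm: float = 0.0
    backscatter_mm: float = 0.0
    osa_bead_diameter_mm: float = 10.0
    fiber_depth_mm: float = 5.0  # below the OSA top surface
    source_separation_cm: float = 3.0
    source_length_cm: float = 2.0
    lateral_extent_cm: tuple[float, float] = (12.0, 8.5)  # full grid (x, y)
    osa_extent_cm: tuple[float, float] = (10.0, 7.0)  # applicator footprint
    voxel_size_mm: float = 0.5
    #: air above the stack so the top surface is a real refractive boundary
    #: (internal reflection there matters at the scoring plane)
    air_headspace_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.top_phantom_mm < 0 or self.backscatter_mm < 0:
            raise ValueError("slab thicknesses must be non-negative")
        if self.air_headspace_mm < 0:
            raise ValueError("air headspace must be non-negative")
        if self.source_separation_cm <= 0:
            raise ValueError("source_separation_cm must be > 0")
        if self.source_length_cm <= 0:
            raise ValueError("source_length_cm must be > 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.voxel_size_mm > self.osa_bead_diameter_mm / 4.0:
            raise ValueError(
                f"voxel_size_mm={self.voxel_size_mm} too coarse: must be <= "
                f"bead diameter / 4 = {self.osa_bead_diameter_mm / 4.0} mm"
            )
        if self.voxel_size_mm > self.fiber_depth_mm:
            raise ValueError(
                f"voxel_size_mm={self.voxel_size_mm} cannot resolve the "
                f"{self.fiber_depth_mm} mm fiber depth"
            )
        if not 0 < self.fiber_depth_mm <= self.osa_bead_diameter_mm:
            raise ValueError("fiber depth must lie within the OSA layer")
        ox, oy = self.osa_extent_cm
        lx, ly = self.lateral_extent_cm
        if ox > lx or oy > ly:
            raise ValueError("OSA footprint must fit inside the lateral extent")

    # -- derived geometry (mm) ------------------------------------------
    @property
    def grid_lx_mm(self) -> float:
        return self.lateral_extent_cm[0] * 10.0

    @property
    def grid_ly_mm(self) -> float:
        return self.lateral_extent_cm[1] * 10.0

    @property
    def osa_rect_mm(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the applicator footprint, centered in the grid."""
        ox = self.osa_extent_cm[0] * 10.0
        oy = self.osa_extent_cm[1] * 10.0
        x0 = 0.5 * (self.grid_lx_mm - ox)
        y0 = 0.5 * (self.grid_ly_mm - oy)
        return (x0, x0 + ox, y0, y0 + oy)

    @property
    def z_osa_bottom_mm(self) -> float:
        return self.backscatter_mm

    @property
    def z_osa_top_mm(self) -> float:
        return self.backscatter_mm + self.osa_bead_diameter_mm

    @property
    def z_top_mm(self) -> float:
        return self.z_osa_top_mm + self.top_phantom_mm

    @property
    def z_grid_top_mm(self) -> float:
        return self.z_top_mm + self.air_headspace_mm

    @property
    def fiber_z_mm(self) -> float:
        return self.z_osa_top_mm - self.fiber_depth_mm


@dataclass
class VoxelScene:
    """Labeled regular voxel grid plus its material table.

    ``labels[i, j, k]`` indexes ``materials``; the grid origin is (0, 0, 0)
    and spacing is isotropic.
    """

    labels: np.ndarray  # (nx, ny, nz) uint8
    spacing_mm: float
    materials: tuple[OpticalProperties, ...]
    material_names: tuple[str, ...]
    scoring_plane_z_mm: float
    config: SceneConfig | None = None
    wavelength: int = 532

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.labels.max(initial=0) >= len(self.materials):
            raise ValueError("label grid references an undefined material")
        if not 0.0 <= self.scoring_plane_z_mm <= self.shape[2] * self.spacing_mm:
            raise ValueError("scoring plane lies outside the grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        h = self.spacing_mm
        return (nx * h, ny * h, nz * h)

    def contains(self, point) -> bool:
        x, y, z = point
        ex, ey, ez = self.extent_mm
        return 0 <= x < ex and 0 <= y < ey and 0 <= z < ez

    def voxel_index(self, point) -> tuple[int, int, int]:
        if not self.contains(point):
            raise ValueError(f"point {tuple(point)} lies outside the grid")
        h = self.spacing_mm
        return (int(point[0] // h), int(point[1] // h), int(point[2] // h))

    def material_volumes_mm3(self) -> dict[str, float]:
        """Total voxel volume per material, in mm^3."""
        v = self.spacing_mm**3
        counts = np.bincount(self.labels.ravel(), minlength=len(self.materials))
        return {name: float(c) * v for name, c in zip(self.material_names, counts)}

    def save(self, path) -> None:
        """Write the label grid (.npy) plus a JSON sidecar of spacing/materials."""
        import json
        from pathlib import Path

        path = Path(path)
        np.save(path, self.labels)
        sidecar = {
            "spacing_mm": self.spacing_mm,
            "scoring_plane_z_mm": self.scoring_plane_z_mm,
            "wavelength": self.wavelength,
            "materials": [
                {"name": name, "mu_a": m.mu_a, "mu_s_prime": m.mu_s_prime, "g": m.g, "n": m.n}
                for name, m in zip(self.material_names, self.materials)
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "VoxelScene":
        import json
        from pathlib import Path

        path = Path(path)
        labels = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        materials = tuple(
            OpticalProperties(
                mu_a=m["mu_a"], mu_s_prime=m["mu_s_prime"], g=m["g"], n=m["n"]
            )
            for m in meta["materials"]
        )
        return cls(
            labels=labels,
            spacing_mm=meta["spacing_mm"],
            materials=materials,
            material_names=tuple(m["name"] for m in meta["materials"]),
            scoring_plane_z_mm=meta["scoring_plane_z_mm"],
            wavelength=meta["wavelength"],
        )

    def kernel_tables(self):
        """Per-material arrays for the transport kernel.

        This is the single cm -> mm unit boundary: interaction coefficients
        are returned in mm^-1.
        """
        mu_t = np.array([m.mu_t / 10.0 for m in self.materials])
        albedo = np.array([m.albedo for m in self.materials])
        g = np.array([m.g for m in self.materials])
        n = np.array([m.n for m in self.materials])
        return mu_t, albedo, g, n


def build_scene(
    config: SceneConfig,
    materials: dict[str, OpticalProperties] | None = None,
) -> VoxelScene:
    """Voxelize one applicator configuration.

    ``materials`` must provide entries for ``air``, ``phantom`` (at the
    configured wavelength) and ``silicone``; the built-in table is used when
    omitted. Labeling is a pure function of the configuration: identical
    configs yield bit-identical grids.
    """
    if materials is None:
        materials = builtin_materials(config.wavelength)
    missing = {"air", "phantom", "silicone"} - set(materials)
    if missing:
        raise ValueError(f"material table missing entries: {sorted(missing)}")

    h = config.voxel_size_mm
    nx = int(round(config.grid_lx_mm / h))
    ny = int(round(config.grid_ly_mm / h))
    nz = int(round(config.z_grid_top_mm / h))
    if nz == 0:
        raise ValueError("scene has zero height")
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h
    x0, x1, y0, y1 = config.osa_rect_mm
    in_osa_x = (xc >= x0) & (xc < x1)
    in_osa_y = (yc >= y0) & (yc < y1)
    footprint = np.outer(in_osa_x, in_osa_y)

    # phantom slabs (within the applicator footprint)
    bs = zc < config.z_osa_bottom_mm
    top = (zc >= config.z_osa_top_mm) & (zc < config.z_top_mm)
    labels[np.ix_(in_osa_x, in_osa_y, np.flatnonzero(bs | top))] = LABEL_PHANTOM

    # OSA bead lattice: square packing of touching spheres, one layer deep
    d = config.osa_bead_diameter_mm
    r = d / 2.0
    n_bx = int((x1 - x0) // d)
    n_by = int((y1 - y0) // d)
    if n_bx >= 1 and n_by >= 1:
        ib = np.clip(np.round((xc - x0 - r) / d), 0, n_bx - 1)
        jb = np.clip(np.round((yc - y0 - r) / d), 0, n_by - 1)
        dx = xc - (x0 + r + ib * d)
        dy = yc - (y0 + r + jb * d)
        zc_bead = config.z_osa_bottom_mm + r
        osa_k = np.flatnonzero((zc >= config.z_osa_bottom_mm) & (zc < config.z_osa_top_mm))
        lat2 = dx[:, None] ** 2 + dy[None, :] ** 2
        for k in osa_k:
            in_bead = (lat2 + (zc[k] - zc_bead) ** 2 <= r * r) & footprint
            labels[:, :, k][in_bead] = LABEL_SILICONE

    return VoxelScene(
        labels=labels,
        spacing_mm=h,
        materials=(materials["air"], materials["phantom"], materials["silicone"]),
        material_names=("air", "phantom", "silicone"),
        scoring_plane_z_mm=config.z_top_mm,
        config=config,
        wavelength=config.wavelength,
    )


def material_at(scene: VoxelScene, point) -> OpticalProperties:
    """Material of the voxel owning ``point`` (half-open voxel ownership)."""
    i, j, k = scene.voxel_index(point)
    return scene.materials[scene.labels[i, j, k]]


def slab_scene(
    thickness_mm: float,
    material: OpticalProperties,
    lateral_mm: tuple[float, float] = (60.0, 60.0),
    voxel_size_mm: float = 1.0,
    name: str = "slab",
) -> VoxelScene:
    """Homogeneous single-material slab, used as validation geometry."""
    if thickness_mm <= 0:
        raise ValueError("slab thickness must be > 0")
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be > 0")
    h = voxel_size_mm
    nx = max(1, int(round(lateral_mm[0] / h)))
    ny = max(1, int(round(lateral_mm[1] / h)))
    nz = max(1, int(round(thickness_mm / h)))
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    return VoxelScene(
        labels=labels,
        spacing_mm=h,
        materials=(material,),
        material_names=(name,),
        scoring_plane_z_mm=nz * h,
        wavelength=532,
    )
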