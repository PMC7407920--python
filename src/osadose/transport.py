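"""Monte Carlo photon-packet transport through a voxel scene.

The public surface wraps the jitted kernel in :mod:`osadose._kernel` with
physical source descriptions and an energy ledger. Scores are raw
track-length sums (weight x mm per voxel); conversion to irradiance and
fluence lives in :mod:`osadose.maps` so that a single simulation can be
re-scaled to any source power without re-running (transport is linear in
power).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import _kernel
from .scene import VoxelScene

__all__ = [
    "LineDiffuserSource",
    "TransportSettings",
    "PhotonPacket",
    "RawScoreGrid",
    "sample_emission",
    "propagate",
    "run_transport",
    "make_osa_sources",
]


@dataclass(frozen=True)
class LineDiffuserSource:
    """Isotropically emitting line segment (a cylindrical/radial diffuser).

    ``linear_power_mw_per_cm`` is the linear power density delivered along
    the diffuser; total power is linear power x length.
    """

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    linear_power_mw_per_cm: float = 100.0
    duration_s: float = 278.0
    wavelength: int = 532

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("source must have non-zero length")
        if self.linear_power_mw_per_cm <= 0:
            raise ValueError("linear power must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")

    @property
    def length_mm(self) -> float:
        a = np.asarray(self.start_mm, dtype=float)
        b = np.asarray(self.end_mm, dtype=float)
        return float(np.linalg.norm(b - a))

    @property
    def total_power_mw(self) -> float:
        return self.linear_power_mw_per_cm * self.length_mm / 10.0


@dataclass(frozen=True)
class TransportSettings:
    n_packets: int = 100_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 10.0
    max_interactions: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette_threshold must be in (0, 1)")
        if self.roulette_survival <= 1.0:
            raise ValueError("roulette_survival must be > 1")


@dataclass
class PhotonPacket:
    position_mm: np.ndarray
    direction: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must be in (0, 1]")


@dataclass
class RawScoreGrid:
    """Per-voxel accumulated weight x path-length (weight.mm) plus run metadata."""

    score: np.ndarray  # (nx, ny, nz) float64
    spacing_mm: float
    n_packets: int
    seed: int
    ledger: dict[str, float]
    scoring_plane_z_mm: float
    wavelength: int
    sources: tuple[LineDiffuserSource, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.score < 0) or not np.all(np.isfinite(self.score)):
            raise ValueError("score grid must be finite and non-negative")

    @property
    def total_source_power_mw(self) -> float:
        return sum(s.total_power_mw for s in self.sources)

    def save(self, path: str | Path) -> None:
        """Persist to HDF5 with a JSON metadata attribute."""
        meta = {
            "spacing_mm": self.spacing_mm,
            "n_packets": self.n_packets,
            "seed": self.seed,
            "ledger": self.ledger,
            "scoring_plane_z_mm": self.scoring_plane_z_mm,
            "wavelength": self.wavelength,
            "sources": [
                {
                    "start_mm": list(s.start_mm),
                    "end_mm": list(s.end_mm),
                    "linear_power_mw_per_cm": s.linear_power_mw_per_cm,
                    "duration_s": s.duration_s,
                    "wavelength": s.wavelength,
                }
                for s in self.sources
            ],
        }
        with h5py.File(path, "w") as fh:
            fh.create_dataset("score", data=self.score, compression="gzip", track_times=False)
            fh.attrs["meta"] = json.dumps(meta)

    @classmethod
    def load(cls, path: str | Path) -> "RawScoreGrid":
        with h5py.File(path, "r") as fh:
            score = fh["score"][...]
            meta = json.loads(fh.attrs["meta"])
        sources = tuple(
            LineDiffuserSource(
                start_mm=tuple(s["start_mm"]),
                end_mm=tuple(s["end_mm"]),
                linear_power_mw_per_cm=s["linear_power_mw_per_cm"],
                duration_s=s["duration_s"],
                wavelength=s["wavelength"],
            )
            for s in meta["sources"]
        )
        return cls(
            score=score,
            spacing_mm=meta["spacing_mm"],
            n_packets=meta["n_packets"],
            seed=meta["seed"],
            ledger=meta["ledger"],
            scoring_plane_z_mm=meta["scoring_plane_z_mm"],
            wavelength=meta["wavelength"],
            sources=sources,
        )


def sample_emission(source: LineDiffuserSource, rng: np.random.Generator) -> PhotonPacket:
    """Draw one packet: position uniform on the segment, direction isotropic.

    This is the numpy-level reference sampler; the jitted kernel implements
    the identical distribution with its own counter-based streams.
    """
    a = np.asarray(source.start_mm, dtype=float)
    b = np.asarray(source.end_mm, dtype=float)
    pos = a + (b - a) * rng.random()
    cost = 2.0 * rng.random() - 1.0
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * np.pi * rng.random()
    direction = np.array([sint * np.cos(phi), sint * np.sin(phi), cost])
    return PhotonPacket(position_mm=pos, direction=direction, weight=1.0)


def propagate(
    packet: PhotonPacket,
    scene: VoxelScene,
    settings: TransportSettings,
    score: np.ndarray | None = None,
    packet_id: int = 0,
) -> dict:
    """Transport a single packet to termination.

    Returns a record with the termination status (``escaped`` / ``rouletted``
    / ``forced``), exit position and weight, interaction count, and the
    per-termination weight ledger. Deposits track length into ``score`` when
    a grid is supplied.
    """
    if not scene.contains(packet.position_mm):
        raise ValueError("packet starts outside the scene")
    if score is None:
        score = np.zeros(scene.shape, dtype=np.float64)
    mu_t, albedo, g, n = scene.kernel_tables()
    state = np.uint64(_kernel._packet_state(settings.seed, packet_id))
    res = _kernel.trace_packet(
        scene.labels,
        mu_t,
        albedo,
        g,
        n,
        scene.spacing_mm,
        packet.position_mm[0],
        packet.position_mm[1],
        packet.position_mm[2],
        packet.direction[0],
        packet.direction[1],
        packet.direction[2],
        packet.weight,
        state,
        settings.roulette_threshold,
        settings.roulette_survival,
        settings.max_interactions,
        score,
    )
    status = {_kernel.ESCAPED: "escaped", _kernel.ROULETTED: "rouletted", _kernel.FORCED: "forced"}
    return {
        "absorbed": res[0],
        "escaped_weight": res[1],
        "roulette_loss": res[2],
        "roulette_gain": res[3],
        "forced_weight": res[4],
        "n_interactions": res[5],
        "status": status[res[6]],
        "exit_position_mm": np.array(res[7:10]),
        "score": score,
    }


def _allocate_packets(powers: np.ndarray, n_total: int) -> np.ndarray:
    """Largest-remainder allocation of packets proportional to source power."""
    share = powers / powers.sum() * n_total
    n = np.floor(share).astype(np.int64)
    rem = n_total - int(n.sum())
    if rem > 0:
        order = np.argsort(-(share - n))
        n[order[:rem]] += 1
    return n


def run_transport(
    scene: VoxelScene,
    sources: list[LineDiffuserSource] | tuple[LineDiffuserSource, ...],
    settings: TransportSettings,
) -> RawScoreGrid:
    """Run the full simulation; deterministic given ``settings.seed``.

    Packets are allocated to sources proportionally to their total power so
    that a single global ``total power / n_packets`` normalization applies.
    """
    if len(sources) == 0:
        raise ValueError("at least one source is required")
    for s in sources:
        if not (scene.contains(s.start_mm) and scene.contains(s.end_mm)):
            raise ValueError(f"source {s.start_mm}->{s.end_mm} lies outside the scene")

    src = np.array(
        [[*s.start_mm, *s.end_mm] for s in sources], dtype=np.float64
    ).reshape(len(sources), 6)
    powers = np.array([s.total_power_mw for s in sources])
    n_per = _allocate_packets(powers, settings.n_packets)

    score = np.zeros(scene.shape, dtype=np.float64)
    mu_t, albedo, g, n = scene.kernel_tables()
    led = _kernel.run_kernel(
        scene.labels,
        mu_t,
        albedo,
        g,
        n,
        scene.spacing_mm,
        src,
        n_per,
        settings.seed,
        settings.roulette_threshold,
        settings.roulette_survival,
        settings.max_interactions,
        score,
    )
    ledger = {
        "launched": led[0],
        "absorbed": led[1],
        "escaped": led[2],
        "roulette_loss": led[3],
        "roulette_gain": led[4],
        "forced": led[5],
        "n_forced_packets": led[6],
    }
    return RawScoreGrid(
        score=score,
        spacing_mm=scene.spacing_mm,
        n_packets=settings.n_packets,
        seed=settings.seed,
        ledger=ledger,
        scoring_plane_z_mm=scene.scoring_plane_z_mm,
        wavelength=scene.wavelength,
        sources=tuple(sources),
    )


def make_osa_sources(
    config,
    total_linear_power_mw_per_cm: float = 200.0,
    duration_s: float = 278.0,
    per_fiber: bool = False,
) -> list[LineDiffuserSource]:
    """The two parallel diffuser fibers of an applicator configuration.

    Fibers run along x (the applicator's long axis) at the configured
    separation, centered on the applicator footprint, at the fiber depth
    below the applicator's top surface. By default
    ``total_linear_power_mw_per_cm`` is the *total* across both fibers and
    is split equally; with ``per_fiber=True`` it is taken as the per-fiber
    value instead.
    """
    if total_linear_power_mw_per_cm <= 0:
        raise ValueError("linear power must be > 0")
    x0, x1, y0, y1 = config.osa_rect_mm
    xc = 0.5 * (x0 + x1)
    yc = 0.5 * (y0 + y1)
    half_len = config.source_length_cm * 10.0 / 2.0
    half_sep = config.source_separation_cm * 10.0 / 2.0
    z = config.fiber_z_mm
    per = (
        total_linear_power_mw_per_cm
        if per_fiber
        else total_linear_power_mw_per_cm / 2.0
    )
    return [
        LineDiffuserSource(
            start_mm=(xc - half_len, yc + dy, z),
            end_mm=(xc + half_len, yc + dy, z),
            linear_power_mw_per_cm=per,
            duration_s=duration_s,
            wavelength=config.wavelength,
        )
        for dy in (-half_sep, +half_sep)
    ]
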