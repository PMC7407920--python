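"""Pipeline orchestration and validation suites.

Runs the full dosimetry chain — scene voxelization, Monte Carlo transport,
irradiance/fluence maps, kill-model calibration, plate prediction, synthetic
measured plate, comparison — from a single YAML configuration, with content
digests recorded in a run manifest so that deterministic stages can be
skipped on re-runs and reproduced bit-for-bit.

All randomness derives from one root seed: stage seeds are split off with
``numpy.random.SeedSequence(root).spawn`` in a fixed order (transport,
plate noise).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dose_response import fit_dose_response
from .maps import (
    FluenceMap,
    absorption_self_check,
    irradiance_to_fluence,
    save_map_csv,
    save_map_tiff,
    score_to_irradiance,
)
from .optics import phantom_properties
from .scene import SceneConfig, build_scene, slab_scene
from .synth import GREEN_GRID_UM, GREEN_TRUTH, SynthConfig, gen_dose_response, gen_plate
from .transport import (
    LineDiffuserSource,
    RawScoreGrid,
    TransportSettings,
    make_osa_sources,
    run_transport,
)
from .viability import PlateLayout, calibrate_kill_model, compare_plates, predict_plate

__all__ = [
    "CONFIG_SCHEMA",
    "load_config",
    "validate_config",
    "demo_config",
    "RunManifest",
    "run_pipeline",
    "validate",
]

log = logging.getLogger("osadose")

#: section -> {key: (required, type)} — the published configuration schema.
CONFIG_SCHEMA: dict[str, dict[str, tuple[bool, type]]] = {
    "scene": {
        "wavelength": (True, int),
        "top_phantom_mm": (True, float),
        "backscatter_mm": (True, float),
        "voxel_size_mm": (False, float),
        "osa_bead_diameter_mm": (False, float),
        "fiber_depth_mm": (False, float),
        "source_separation_cm": (False, float),
        "source_length_cm": (False, float),
        "lateral_extent_cm": (False, list),
        "osa_extent_cm": (False, list),
    },
    "source": {
        "linear_power_mw_per_cm": (True, float),
        "duration_s": (True, float),
        "per_fiber": (False, bool),
    },
    "transport": {
        "n_packets": (True, int),
        "seed": (True, int),
        "roulette_threshold": (False, float),
        "roulette_survival": (False, float),
    },
    "kill_model": {
        "concentration_um": (True, float),
        "f50_j_cm2": (True, float),
        "f_kill_j_cm2": (True, float),
        "kill_floor": (False, float),
    },
    "plate": {
        "overhang_cols": (False, int),
        "noise_sd": (False, float),
    },
}


class ConfigError(ValueError):
    """Configuration does not conform to :data:`CONFIG_SCHEMA`."""


def validate_config(cfg: dict) -> None:
    """Raise :class:`ConfigError` listing every offending key."""
    problems: list[str] = []
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    for section, keys in CONFIG_SCHEMA.items():
        if section not in cfg:
            if any(req for req, _ in keys.values()):
                problems.append(f"missing section '{section}'")
            continue
        body = cfg[section]
        if not isinstance(body, dict):
            problems.append(f"section '{section}' must be a mapping")
            continue
        for key, (required, typ) in keys.items():
            if key not in body:
                if required:
                    problems.append(f"missing key '{section}.{key}'")
                continue
            val = body[key]
            if typ is float and isinstance(val, (int, float)) and not isinstance(val, bool):
                continue
            if typ is int and isinstance(val, int) and not isinstance(val, bool):
                continue
            if not isinstance(val, typ) or isinstance(val, bool) and typ is not bool:
                problems.append(
                    f"key '{section}.{key}' has type {type(val).__name__}, expected {typ.__name__}"
                )
        unknown = set(body) - set(keys)
        for key in sorted(unknown):
            problems.append(f"unknown key '{section}.{key}'")
    unknown_sections = set(cfg) - set(CONFIG_SCHEMA)
    for s in sorted(unknown_sections):
        problems.append(f"unknown section '{s}'")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def demo_config() -> dict:
    """The bundled demonstration configuration (phantom-above, backscatter-below)."""
    text = resources.files("osadose").joinpath("configs/osa_demo.yaml").read_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def _scene_config_from(cfg: dict) -> SceneConfig:
    s = cfg["scene"]
    kwargs = dict(
        wavelength=int(s["wavelength"]),
        top_phantom_mm=float(s["top_phantom_mm"]),
        backscatter_mm=float(s["backscatter_mm"]),
    )
    for key in (
        "voxel_size_mm",
        "osa_bead_diameter_mm",
        "fiber_depth_mm",
        "source_separation_cm",
        "source_length_cm",
    ):
        if key in s:
            kwargs[key] = float(s[key])
    for key in ("lateral_extent_cm", "osa_extent_cm"):
        if key in s:
            kwargs[key] = tuple(float(v) for v in s[key])
    return SceneConfig(**kwargs)


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    root_seed: int
    stage_seeds: dict[str, int]
    package_version: str
    stage_hashes: dict[str, str]
    files: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "root_seed": self.root_seed,
            "stage_seeds": self.stage_seeds,
            "package_version": self.package_version,
            "stage_hashes": self.stage_hashes,
            "files": self.files,
            "stages": self.stages,
            "skipped": self.skipped,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute all stages in dependency order; returns the run manifest.

    The expensive transport stage is skipped when the output of a previous
    run with an identical (scene, source, transport) configuration is found
    in ``outdir`` with a matching digest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # per-run log file alongside the console handler
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    run_log = logging.FileHandler(outdir / "run.log")
    run_log.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(run_log)
    log.setLevel(logging.INFO)

    root_seed = int(config["transport"]["seed"])
    ss = np.random.SeedSequence(root_seed)
    transport_seed, plate_seed = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)
    )
    stage_seeds = {"transport": transport_seed, "plate_noise": plate_seed}

    manifest = RunManifest(
        config_hash=_digest_obj(config),
        root_seed=root_seed,
        stage_seeds=stage_seeds,
        package_version=__version__,
        stage_hashes={},
    )
    prev = None
    prev_path = outdir / "manifest.json"
    if prev_path.exists():
        try:
            prev = json.loads(prev_path.read_text())
        except json.JSONDecodeError:
            prev = None

    # -- scene ----------------------------------------------------------
    scene_cfg = _scene_config_from(config)
    scene = build_scene(scene_cfg)
    log.info(
        "scene: %s voxels at %.2f mm, stack height %.1f mm",
        scene.shape,
        scene.spacing_mm,
        scene.extent_mm[2],
    )
    manifest.stages.append("scene")

    # -- transport ------------------------------------------------------
    src_cfg = config["source"]
    sources = make_osa_sources(
        scene_cfg,
        total_linear_power_mw_per_cm=float(src_cfg["linear_power_mw_per_cm"]),
        duration_s=float(src_cfg["duration_s"]),
        per_fiber=bool(src_cfg.get("per_fiber", False)),
    )
    t_cfg = config["transport"]
    settings = TransportSettings(
        n_packets=int(t_cfg["n_packets"]),
        seed=transport_seed,
        roulette_threshold=float(t_cfg.get("roulette_threshold", 1e-4)),
        roulette_survival=float(t_cfg.get("roulette_survival", 10.0)),
    )
    transport_hash = _digest_obj(
        {"scene": config["scene"], "source": config["source"], "transport": config["transport"]}
    )
    manifest.stage_hashes["transport"] = transport_hash
    score_path = outdir / "score.h5"
    raw = None
    if (
        prev is not None
        and prev.get("stage_hashes", {}).get("transport") == transport_hash
        and score_path.exists()
        and prev.get("files", {}).get("score.h5") == _digest_file(score_path)
    ):
        raw = RawScoreGrid.load(score_path)
        manifest.skipped.append("transport")
        log.info("transport: reusing %s (unchanged inputs)", score_path)
    if raw is None:
        log.info(
            "transport: %d packets, seed %d, total power %.1f mW",
            settings.n_packets,
            settings.seed,
            sum(s.total_power_mw for s in sources),
        )
        raw = run_transport(scene, sources, settings)
        raw.save(score_path)
    manifest.files["score.h5"] = _digest_file(score_path)
    manifest.stages.append("transport")

    # -- maps -----------------------------------------------------------
    duration = float(src_cfg["duration_s"])
    imap = score_to_irradiance(raw)
    fmap = irradiance_to_fluence(imap, duration)
    save_map_csv(imap, outdir / "irradiance.csv")
    save_map_csv(fmap, outdir / "fluence.csv")
    save_map_tiff(fmap, outdir / "fluence.tiff")
    for name in ("irradiance.csv", "fluence.csv", "fluence.tiff"):
        manifest.files[name] = _digest_file(outdir / name)
    manifest.stages.append("maps")
    log.info(
        "maps: peak irradiance %.2f mW/cm^2, peak fluence %.2f J/cm^2 at plane z=%.1f mm",
        imap.values.max(),
        fmap.values.max(),
        imap.plane_z_mm,
    )

    # -- kill model + plates -------------------------------------------
    k_cfg = config["kill_model"]
    kill = calibrate_kill_model(
        concentration_um=float(k_cfg["concentration_um"]),
        f50_j_cm2=float(k_cfg["f50_j_cm2"]),
        f_kill_j_cm2=float(k_cfg["f_kill_j_cm2"]),
        kill_floor=float(k_cfg.get("kill_floor", 0.01)),
    )
    p_cfg = config.get("plate", {})
    layout = PlateLayout.for_scene(scene_cfg, overhang_cols=int(p_cfg.get("overhang_cols", 1)))
    predicted = predict_plate(fmap, layout, kill)
    predicted.to_csv(outdir / "predicted_plate.csv")
    synth_cfg = SynthConfig(seed=plate_seed, noise_sd=float(p_cfg.get("noise_sd", 0.05)))
    measured = gen_plate(fmap, layout, kill, synth_cfg)
    measured.to_csv(outdir / "measured_synthetic_plate.csv")
    manifest.stages += ["kill_model", "predict", "synth_plate"]

    # -- comparison -----------------------------------------------------
    report = compare_plates(predicted, measured)
    report["energy_ledger"] = raw.ledger
    report["absorption_self_check"] = absorption_self_check(raw, scene)
    (outdir / "comparison.json").write_text(json.dumps(report, indent=2))
    for name in ("predicted_plate.csv", "measured_synthetic_plate.csv", "comparison.json"):
        manifest.files[name] = _digest_file(outdir / name)
    manifest.stages.append("compare")
    log.info("compare: RMSE %.3f, Spearman %.3f", report["rmse"], report["spearman"])

    manifest.save(prev_path)
    log.removeHandler(run_log)
    run_log.close()
    return manifest


# ---------------------------------------------------------------------------
# validation suites
# ---------------------------------------------------------------------------


def diffusion_oracle_report(
    wavelength: int = 532, n_packets: int = 150_000, seed: int = 0
) -> dict:
    """Monte Carlo vs diffusion theory for a point source in a turbid cube.

    An index-matched, isotropically scattering (reduced) phantom medium is
    simulated with a sub-voxel source at the cube center; the shell-averaged
    fluence per unit power is compared with
    ``phi(r) = exp(-mu_eff r) / (4 pi D r)`` over 1 <= mu_eff r <= 4.
    """
    props = phantom_properties(wavelength).reduced().index_matched(1.0)
    size = 70.0
    scene = slab_scene(size, props, lateral_mm=(size, size), voxel_size_mm=1.0)
    c = size / 2.0
    src = LineDiffuserSource(
        start_mm=(c, c, c - 0.25), end_mm=(c, c, c + 0.25), linear_power_mw_per_cm=100.0
    )
    raw = run_transport(scene, [src], TransportSettings(n_packets=n_packets, seed=seed))

    h = scene.spacing_mm
    centers = (np.arange(scene.shape[0]) + 0.5) * h
    X, Y, Z = np.meshgrid(centers, centers, centers, indexing="ij")
    r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)  # mm

    mu_eff_mm = props.mu_eff / 10.0
    d_mm = props.diffusion_constant * 10.0
    phi_mc = raw.score / (h**3) / raw.n_packets  # per packet, mm^-2
    phi_th = np.exp(-mu_eff_mm * r) / (4.0 * np.pi * d_mm * np.maximum(r, 1e-6))

    r_lo, r_hi = 1.0 / mu_eff_mm, 4.0 / mu_eff_mm
    edges = np.linspace(r_lo, r_hi, 11)
    devs = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (r >= a) & (r < b)
        mc = phi_mc[sel].mean()
        th = phi_th[sel].mean()
        devs.append(abs(mc - th) / th)
    max_dev = float(max(devs))
    return {
        "suite": "oracle",
        "wavelength": wavelength,
        "n_packets": n_packets,
        "max_relative_deviation": max_dev,
        "tolerance": 0.05,
        "passed": bool(max_dev < 0.05),
    }


def conservation_report(n_packets: int = 50_000, seed: int = 0) -> dict:
    """Energy-ledger closure in a phantom slab."""
    props = phantom_properties(532)
    scene = slab_scene(20.0, props, lateral_mm=(60.0, 60.0), voxel_size_mm=1.0)
    src = LineDiffuserSource(start_mm=(20.0, 30.0, 10.0), end_mm=(40.0, 30.0, 10.0))
    raw = run_transport(scene, [src], TransportSettings(n_packets=n_packets, seed=seed))
    led = raw.ledger
    exact = abs(
        led["launched"]
        - led["absorbed"]
        - led["escaped"]
        - led["forced"]
        - (led["roulette_loss"] - led["roulette_gain"])
    ) / led["launched"]
    statistical = abs(led["launched"] - led["absorbed"] - led["escaped"] - led["forced"]) / led[
        "launched"
    ]
    return {
        "suite": "conservation",
        "n_packets": n_packets,
        "exact_closure": float(exact),
        "statistical_closure": float(statistical),
        "tolerance": 1e-3,
        "passed": bool(exact < 1e-9 and statistical < 1e-3),
    }


def recovery_report(seed: int = 0) -> dict:
    """EC50 parameter recovery on synthetic triplicates."""
    data = gen_dose_response(
        GREEN_TRUTH, GREEN_GRID_UM, SynthConfig(seed=seed, noise_sd=0.03), condition="532 nm"
    )
    model = fit_dose_response(data)
    rel = abs(model.ec50_um - GREEN_TRUTH.ec50_um) / GREEN_TRUTH.ec50_um
    return {
        "suite": "recovery",
        "seed": seed,
        "true_ec50_um": GREEN_TRUTH.ec50_um,
        "fitted_ec50_um": model.ec50_um,
        "relative_error": float(rel),
        "tolerance": 0.15,
        "passed": bool(rel < 0.15),
    }


def validate(suite: str, seed: int = 0) -> dict:
    """Run one named validation suite: oracle | conservation | recovery."""
    if suite == "oracle":
        return diffusion_oracle_report(seed=seed)
    if suite == "conservation":
        return conservation_report(seed=seed)
    if suite == "recovery":
        return recovery_report(seed=seed)
    raise ValueError(f"unknown suite {suite!r}; use oracle, conservation or recovery")
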