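"""Configuration parsing, dose-raster I/O, and mask/report export.

Configs are YAML with a mandatory ``units`` section pinned to
``{length: mm, angle: deg, energy: MeV}``; a file without it (or with any
other units) is rejected outright, so unit drift cannot pass silently.

Dose grids are written as MetaImage (.mhd + .raw, 32-bit float, mm
spacing) through SimpleITK, with a JSON sidecar carrying the seed,
particle tallies, spacing, and the configuration hash; reading refuses a
raster whose sidecar (and hence spacing provenance) is missing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml
from PIL import Image

from .beam import Box, TreatmentPlan, build_plan, default_energy_layers, synthetic_beam_model
from .collimator import DualCollimatorSystem
from .transport import DoseGrid, Phantom, TransportSettings

__all__ = [
    "ConfigError",
    "RunConfig",
    "REQUIRED_UNITS",
    "load_config",
    "parse_config",
    "config_to_dict",
    "config_hash",
    "build_scene",
    "write_dose_grid",
    "read_dose_grid",
    "write_mask_image",
]

REQUIRED_UNITS = {"length": "mm", "angle": "deg", "energy": "MeV"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration (all lengths mm, angles deg, energy MeV)."""

    # dual collimator system; None -> open field
    dcs_period1: float = 2.0
    dcs_period2: float = 2.0
    dcs_throughput: float = 0.5
    dcs_thickness: float = 30.0
    dcs_angle: float = 30.0
    dcs_inter_gap: float = 5.0
    dcs_phantom_gap: float = 5.0
    dcs_enabled: bool = True
    # phantom
    wall_thickness: float = 10.0
    # synthetic beam model / plan
    n_layers: int = 8
    e_min: float = 84.7
    e_max: float = 107.6
    spot_sigma: tuple[float, float] = (5.0, 3.0)
    divergence: tuple[float, float] = (0.004, 0.002)
    rho: float = -0.3
    energy_spread: tuple[float, float] = (0.0121, 0.0109)
    spot_spacing: float = 5.0
    sad: float = 2000.0
    # transport / run
    step: float = 1.0
    protons_per_spot: int = 200
    seed: int = 1
    out_dir: str = "."


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "units": dict(REQUIRED_UNITS),
        "dcs": {
            "enabled": cfg.dcs_enabled,
            "period1_mm": cfg.dcs_period1,
            "period2_mm": cfg.dcs_period2,
            "throughput": cfg.dcs_throughput,
            "thickness_mm": cfg.dcs_thickness,
            "angle_deg": cfg.dcs_angle,
            "inter_collimator_gap_mm": cfg.dcs_inter_gap,
            "collimator_to_phantom_gap_mm": cfg.dcs_phantom_gap,
        },
        "phantom": {"wall_thickness_mm": cfg.wall_thickness},
        "beam_model": {
            "n_layers": cfg.n_layers,
            "e_min_mev": cfg.e_min,
            "e_max_mev": cfg.e_max,
            "spot_sigma_mm": list(cfg.spot_sigma),
            "divergence_rad": list(cfg.divergence),
            "rho": cfg.rho,
            "energy_spread": list(cfg.energy_spread),
        },
        "plan": {"spot_spacing_mm": cfg.spot_spacing, "sad_mm": cfg.sad},
        "transport": {"step_mm": cfg.step},
        "run": {
            "protons_per_spot": cfg.protons_per_spot,
            "seed": cfg.seed,
            "out_dir": cfg.out_dir,
        },
    }


def parse_config(data: dict) -> RunConfig:
    """Validate a config dict; error messages name the offending key."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    units = data.get("units")
    if units is None:
        raise ConfigError("missing mandatory 'units' section")
    for key, expect in REQUIRED_UNITS.items():
        if units.get(key) != expect:
            raise ConfigError(
                f"units.{key} must be '{expect}', got {units.get(key)!r}"
            )

    def get(section: str, key: str, default, cast):
        sec = data.get(section, {})
        if not isinstance(sec, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        try:
            return cast(sec.get(key, default))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{section}.{key}: {exc}") from exc

    pair = lambda v: (float(v[0]), float(v[1]))
    cfg = RunConfig(
        dcs_enabled=get("dcs", "enabled", True, bool),
        dcs_period1=get("dcs", "period1_mm", 2.0, float),
        dcs_period2=get("dcs", "period2_mm", 2.0, float),
        dcs_throughput=get("dcs", "throughput", 0.5, float),
        dcs_thickness=get("dcs", "thickness_mm", 30.0, float),
        dcs_angle=get("dcs", "angle_deg", 30.0, float),
        dcs_inter_gap=get("dcs", "inter_collimator_gap_mm", 5.0, float),
        dcs_phantom_gap=get("dcs", "collimator_to_phantom_gap_mm", 5.0, float),
        wall_thickness=get("phantom", "wall_thickness_mm", 10.0, float),
        n_layers=get("beam_model", "n_layers", 8, int),
        e_min=get("beam_model", "e_min_mev", 84.7, float),
        e_max=get("beam_model", "e_max_mev", 107.6, float),
        spot_sigma=get("beam_model", "spot_sigma_mm", (5.0, 3.0), pair),
        divergence=get("beam_model", "divergence_rad", (0.004, 0.002), pair),
        rho=get("beam_model", "rho", -0.3, float),
        energy_spread=get("beam_model", "energy_spread", (0.0121, 0.0109), pair),
        spot_spacing=get("plan", "spot_spacing_mm", 5.0, float),
        sad=get("plan", "sad_mm", 2000.0, float),
        step=get("transport", "step_mm", 1.0, float),
        protons_per_spot=get("run", "protons_per_spot", 200, int),
        seed=get("run", "seed", 1, int),
        out_dir=get("run", "out_dir", ".", str),
    )
    for key, val in (
        ("dcs.throughput", cfg.dcs_throughput),
        ("dcs.period1_mm", cfg.dcs_period1),
        ("dcs.period2_mm", cfg.dcs_period2),
    ):
        if val <= 0 or (key == "dcs.throughput" and val >= 1):
            raise ConfigError(f"{key}: value {val} outside the valid range")
    if cfg.protons_per_spot < 0:
        raise ConfigError("run.protons_per_spot must be >= 0")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_scene(
    cfg: RunConfig,
) -> tuple[TreatmentPlan, DualCollimatorSystem | None, Phantom, TransportSettings]:
    """Instantiate the simulation objects a config describes."""
    phantom = Phantom(wall_thickness=cfg.wall_thickness)
    dcs = None
    if cfg.dcs_enabled:
        dcs = DualCollimatorSystem.symmetric(
            period=cfg.dcs_period1,
            period2=cfg.dcs_period2,
            throughput=cfg.dcs_throughput,
            angle_deg=cfg.dcs_angle,
            thickness=cfg.dcs_thickness,
            inter_collimator_gap=cfg.dcs_inter_gap,
            collimator_to_phantom_gap=cfg.dcs_phantom_gap,
            phantom_face_z=phantom.entrance_z,
        )
    layers = synthetic_beam_model(
        default_energy_layers(cfg.n_layers, cfg.e_min, cfg.e_max),
        spot_sigma_range=cfg.spot_sigma,
        divergence_range=cfg.divergence,
        rho=cfg.rho,
        energy_spread_range=cfg.energy_spread,
    )
    plan = build_plan(
        Box.default_ptv(),
        layers,
        spot_spacing=cfg.spot_spacing,
        sad=cfg.sad,
        wet_offset=phantom.wet_offset(),
    )
    settings = TransportSettings(step=cfg.step, seed=cfg.seed)
    return plan, dcs, phantom, settings


def write_dose_grid(grid: DoseGrid, mhd_path: str | Path) -> Path:
    """Write a dose grid as MetaImage plus a JSON sidecar; returns the
    sidecar path."""
    mhd_path = Path(mhd_path)
    dose = grid.dose.astype(np.float32)
    img = sitk.GetImageFromArray(np.transpose(dose, (2, 1, 0)))  # itk order z,y,x
    img.SetSpacing((grid.dx, grid.dy, grid.dz))
    img.SetOrigin(
        (grid.x0 + 0.5 * grid.dx, grid.y0 + 0.5 * grid.dy, grid.z0 + 0.5 * grid.dz)
    )
    sitk.WriteImage(img, str(mhd_path))
    sidecar = mhd_path.with_suffix(".json")
    meta = dict(grid.meta)
    meta.update(
        {
            "spacing_mm": [grid.dx, grid.dy, grid.dz],
            "origin_mm": [grid.x0, grid.y0, grid.z0],
            "shape": [grid.nx, grid.ny, grid.nz],
            "primaries": grid.primaries,
        }
    )
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def read_dose_grid(mhd_path: str | Path, phantom: Phantom | None = None) -> DoseGrid:
    """Read a MetaImage dose raster back into a :class:`DoseGrid`.

    The JSON sidecar written alongside the raster is required: it is the
    provenance record of the voxel spacing and run metadata, and a raster
    without it is refused rather than read with assumed geometry.
    The grid's ``edep`` is repopulated from the stored dose so that
    profile extraction round-trips.
    """
    mhd_path = Path(mhd_path)
    sidecar = mhd_path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigError(
            f"missing sidecar {sidecar.name}: voxel spacing metadata is required"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("spacing_mm", "origin_mm", "shape"):
        if key not in meta:
            raise ConfigError(f"sidecar lacks '{key}' metadata")
    img = sitk.ReadImage(str(mhd_path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float64)
    dx, dy, dz = meta["spacing_mm"]
    x0, y0, z0 = meta["origin_mm"]
    nx, ny, nz = meta["shape"]
    if list(arr.shape) != [nx, ny, nz]:
        raise ConfigError("raster shape disagrees with sidecar metadata")
    grid = DoseGrid(
        nx=nx, ny=ny, nz=nz, dx=dx, dy=dy, dz=dz, x0=x0, y0=y0, z0=z0,
        phantom=phantom,
    )
    vol_cm3 = dx * dy * dz * 1e-3
    rho = grid.slab_density()[np.newaxis, np.newaxis, :]
    grid.edep = arr * rho * vol_cm3
    grid.meta = meta
    grid.primaries = int(meta.get("primaries", 0))
    return grid


def write_mask_image(mask: np.ndarray, path: str | Path) -> None:
    """Export a binary aperture mask as an 8-bit PNG or PGM raster."""
    img = Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255), mode="L")
    img.save(str(path))
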