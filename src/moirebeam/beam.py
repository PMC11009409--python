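"""Pencil-beam-scanning beam model, phase-space sampling, and plan building.

Each energy layer is described by per-axis second moments of the beam at
the isocenter plane: spot size ``sigma_u`` (mm), divergence ``sigma_u'``
(rad), and their covariance ``sigma_uu'`` (mm rad).  Per axis the joint
(position, angle) distribution is bivariate Gaussian with correlation

    rho = sigma_uu' / (sigma_u * sigma_u')

and is sampled with two independent standard normals per particle and axis:

    u  = sigma_u  * Z_u + mu_u
    u' = sigma_u' * (rho * Z_u + sqrt(1 - rho^2) * Z_u') + mu_u'

x and y are treated as independent bivariate Gaussians (no x-y coupling).
Spot deflection is modelled as a virtual point source a distance ``sad``
upstream of the isocenter, so off-axis spots carry a mean divergence
``mu_u' = iso_u / sad`` (a diverging scanned field, as delivered by
cyclotron-based PBS systems).

A synthetic beam-model generator provides machine-plausible layer moments
for studies where no measured machine model is available; it makes no
claim to match any specific machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyLayerModel",
    "Spot",
    "Box",
    "TreatmentPlan",
    "PhaseSpaceParticle",
    "ParticleBatch",
    "correlation",
    "sample_phase_space",
    "synthetic_beam_model",
    "default_energy_layers",
    "build_plan",
    "optimize_layer_weights",
]


def correlation(sigma_uuprime: float, sigma_u: float, sigma_uprime: float) -> float:
    """Correlation coefficient of the per-axis (position, angle) Gaussian.

    Raises a ``ValueError`` for ``|rho| >= 1`` (non-physical emittance).
    """
    if sigma_u <= 0 or sigma_uprime <= 0:
        raise ValueError("sigma_u and sigma_uprime must be positive")
    rho = sigma_uuprime / (sigma_u * sigma_uprime)
    if abs(rho) >= 1.0:
        raise ValueError(
            f"|rho| = {abs(rho):.6g} >= 1: covariance {sigma_uuprime} exceeds "
            f"the emittance bound sigma_u*sigma_uprime = {sigma_u * sigma_uprime:.6g}"
        )
    return rho


@dataclass(frozen=True)
class EnergyLayerModel:
    """Beam moments of one energy layer (defined at the isocenter plane)."""

    nominal_energy: float  # MeV
    actual_energy: float  # MeV
    sigma_u: float  # mm
    sigma_uprime: float  # rad
    sigma_uuprime: float  # mm rad
    energy_spread_fraction: float  # relative 1-sigma Gaussian energy smear

    def __post_init__(self) -> None:
        if self.actual_energy <= 0:
            raise ValueError("actual_energy must be positive")
        if not (0.0 <= self.energy_spread_fraction <= 0.05):
            raise ValueError(
                f"energy_spread_fraction must lie in [0, 0.05], got "
                f"{self.energy_spread_fraction}"
            )
        correlation(self.sigma_uuprime, self.sigma_u, self.sigma_uprime)

    @property
    def rho(self) -> float:
        return correlation(self.sigma_uuprime, self.sigma_u, self.sigma_uprime)


@dataclass(frozen=True)
class Spot:
    """One scanned spot: deflection at isocenter, layer index, weight
    (expected primary-proton count, dimensionless, >= 0)."""

    iso_x: float
    iso_y: float
    layer: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, mm: ((xmin, xmax), (ymin, ymax), (zmin, zmax))."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    @classmethod
    def default_ptv(cls) -> "Box":
        # 100 x 25 x 30 mm target, entrance face at the isocenter plane
        return cls(x=(-50.0, 50.0), y=(-12.5, 12.5), z=(55.0, 85.0))


@dataclass
class TreatmentPlan:
    layers: list[EnergyLayerModel]
    spots: list[Spot]
    ptv: Box
    sad: float = 2000.0  # virtual source-to-isocenter distance, mm

    def __post_init__(self) -> None:
        for s in self.spots:
            if not (0 <= s.layer < len(self.layers)):
                raise ValueError(f"spot references missing layer {s.layer}")


@dataclass(frozen=True)
class PhaseSpaceParticle:
    """One primary proton at a reference plane upstream of the collimators."""

    x: float
    y: float
    xp: float
    yp: float
    energy: float  # MeV kinetic
    weight: float = 1.0


class ParticleBatch:
    """Columnar container of phase-space particles (mm, rad, MeV).

    Iterating or indexing yields :class:`PhaseSpaceParticle`; the array
    attributes are what the transport code consumes.
    """

    __slots__ = ("x", "y", "xp", "yp", "energy", "weight", "z_ref")

    def __init__(self, x, y, xp, yp, energy, weight=None, z_ref: float = 0.0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.xp = np.asarray(xp, dtype=float)
        self.yp = np.asarray(yp, dtype=float)
        self.energy = np.asarray(energy, dtype=float)
        self.weight = (
            np.ones_like(self.x) if weight is None else np.asarray(weight, dtype=float)
        )
        self.z_ref = float(z_ref)
        if np.any(self.energy <= 0):
            raise ValueError("particle energies must be positive")

    def __len__(self) -> int:
        return self.x.size

    def __getitem__(self, i: int) -> PhaseSpaceParticle:
        return PhaseSpaceParticle(
            float(self.x[i]),
            float(self.y[i]),
            float(self.xp[i]),
            float(self.yp[i]),
            float(self.energy[i]),
            float(self.weight[i]),
        )

    def select(self, mask: np.ndarray) -> "ParticleBatch":
        return ParticleBatch(
            self.x[mask],
            self.y[mask],
            self.xp[mask],
            self.yp[mask],
            self.energy[mask],
            self.weight[mask],
            z_ref=self.z_ref,
        )

    def drifted(self, z_to: float) -> "ParticleBatch":
        """Straight-line drift of every particle to plane ``z_to``."""
        dz = z_to - self.z_ref
        return ParticleBatch(
            self.x + dz * self.xp,
            self.y + dz * self.yp,
            self.xp,
            self.yp,
            self.energy,
            self.weight,
            z_ref=z_to,
        )

    @classmethod
    def concatenate(cls, batches: list["ParticleBatch"]) -> "ParticleBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        z = batches[0].z_ref
        if any(abs(b.z_ref - z) > 1e-9 for b in batches):
            raise ValueError("batches must share a reference plane")
        return cls(
            np.concatenate([b.x for b in batches]),
            np.concatenate([b.y for b in batches]),
            np.concatenate([b.xp for b in batches]),
            np.concatenate([b.yp for b in batches]),
            np.concatenate([b.energy for b in batches]),
            np.concatenate([b.weight for b in batches]),
            z_ref=z,
        )


def sample_phase_space(
    plan: TreatmentPlan,
    spot: Spot,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    z_plane: float = -90.0,
) -> ParticleBatch:
    """Sample ``n`` primaries of one spot and drift them to ``z_plane``.

    Particles are generated at the isocenter plane (z = 0) from the layer's
    bivariate Gaussians, given the spot's mean deflection and the virtual
    point-source mean divergence ``iso / sad``; kinetic energies are
    Gaussian around the layer's actual energy with its relative spread.
    The whole batch is then drifted in a straight line to the
    pre-collimator plane ``z_plane`` (negative = upstream).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= spot.layer < len(plan.layers)):
        raise ValueError(f"spot references missing layer {spot.layer}")
    if rng is None:
        rng = np.random.default_rng(seed)
    layer = plan.layers[spot.layer]
    rho = layer.rho
    chol = math.sqrt(1.0 - rho * rho)

    def axis(mu_u: float) -> tuple[np.ndarray, np.ndarray]:
        z_u = rng.standard_normal(n)
        z_up = rng.standard_normal(n)
        u = layer.sigma_u * z_u + mu_u
        up = layer.sigma_uprime * (rho * z_u + chol * z_up) + mu_u / plan.sad
        return u, up

    x, xp = axis(spot.iso_x)
    y, yp = axis(spot.iso_y)
    energy = layer.actual_energy * (
        1.0 + layer.energy_spread_fraction * rng.standard_normal(n)
    )
    np.clip(energy, 1.0, None, out=energy)
    batch = ParticleBatch(x, y, xp, yp, energy, z_ref=0.0)
    return batch.drifted(z_plane)


def default_energy_layers(
    n_layers: int = 8, e_min: float = 84.7, e_max: float = 107.6
) -> np.ndarray:
    """Default layer energies: evenly spaced between the plan's endpoint
    energies (whose ranges bracket the 55-85 mm target depth window)."""
    return np.linspace(e_min, e_max, n_layers)


def synthetic_beam_model(
    energies,
    spot_sigma_range: tuple[float, float] = (5.0, 3.0),
    divergence_range: tuple[float, float] = (0.004, 0.002),
    rho: float = -0.3,
    energy_spread_range: tuple[float, float] = (0.0121, 0.0109),
) -> list[EnergyLayerModel]:
    """Synthetic per-layer beam model standing in for a measured machine model.

    Spot size and divergence fall smoothly (linearly) with energy across the
    given ranges, mirroring the qualitative behaviour of cyclotron PBS
    beamlines; the covariance follows from a fixed correlation ``rho``
    (negative = beam converging toward the isocenter); the relative energy
    spread falls linearly with energy across ``energy_spread_range``
    (degraded low-energy beams carry the larger momentum spread).

    The numbers are machine-plausible fixtures, not a fit to any published
    beam model.
    """
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    if energies.size == 0:
        raise ValueError("energy list must be non-empty")
    if energies.size > 1 and np.any(np.diff(energies) <= 0):
        raise ValueError("energies must be strictly ascending")
    e0, e1 = energies[0], energies[-1]
    frac = np.zeros_like(energies) if e1 == e0 else (energies - e0) / (e1 - e0)
    sig_u = spot_sigma_range[0] + frac * (spot_sigma_range[1] - spot_sigma_range[0])
    sig_up = divergence_range[0] + frac * (divergence_range[1] - divergence_range[0])
    spread = energy_spread_range[0] + frac * (
        energy_spread_range[1] - energy_spread_range[0]
    )
    return [
        EnergyLayerModel(
            nominal_energy=float(e),
            actual_energy=float(e),
            sigma_u=float(su),
            sigma_uprime=float(sp),
            sigma_uuprime=float(rho * su * sp),
            energy_spread_fraction=float(es),
        )
        for e, su, sp, es in zip(energies, sig_u, sig_up, spread)
    ]


def optimize_layer_weights(
    layer_models: list[EnergyLayerModel],
    ptv_z_range: tuple[float, float],
    depth_dose_oracle,
    wet_offset: float = 1.6,
    n_depth: int = 151,
) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares layer weights for a flat SOBP.

    Minimizes the deviation of the weighted sum of per-layer depth-dose
    curves from a flat unit plateau across the geometric depth window
    ``ptv_z_range``; ``wet_offset`` converts geometric depth to
    water-equivalent depth (entrance-wall excess WET).  Returns
    ``(weights, max_relative_deviation)``.

    ``depth_dose_oracle(energy, spread, depth_wet_mm)`` must accept a depth
    array and return relative dose.
    """
    from scipy.optimize import nnls

    if not layer_models:
        raise ValueError("need at least one layer")
    z = np.linspace(ptv_z_range[0], ptv_z_range[1], n_depth) + wet_offset
    a = np.column_stack(
        [
            np.asarray(depth_dose_oracle(m.actual_energy, m.energy_spread_fraction, z))
            for m in layer_models
        ]
    )
    if not np.all(np.isfinite(a)) or np.linalg.matrix_rank(a) < min(a.shape):
        cond = np.linalg.cond(a)
        raise ValueError(
            f"singular depth-dose system (condition number {cond:.3g}); "
            "layers may be degenerate or outside the depth window"
        )
    w, _ = nnls(a, np.ones(n_depth))
    sobp = a @ w
    mean = sobp.mean()
    max_dev = float(np.max(np.abs(sobp - mean)) / mean)
    return w, max_dev


def build_plan(
    ptv: Box,
    layer_models: list[EnergyLayerModel],
    spot_spacing: float = 5.0,
    sad: float = 2000.0,
    depth_dose_oracle=None,
    wet_offset: float = 1.6,
    scoring_half_extent: tuple[float, float] = (75.0, 50.0),
) -> TreatmentPlan:
    """Rectangular-grid treatment plan covering the PTV lateral extent.

    Spots are placed on a regular grid from the PTV edges inward at
    ``spot_spacing``; lateral weights are uniform within a layer, and layer
    weights come from :func:`optimize_layer_weights` (normalized to mean 1)
    so the summed central-axis depth dose is flat across the PTV depth.
    """
    if spot_spacing <= 0:
        raise ValueError("spot_spacing must be positive")
    if (
        ptv.x[0] < -scoring_half_extent[0]
        or ptv.x[1] > scoring_half_extent[0]
        or ptv.y[0] < -scoring_half_extent[1]
        or ptv.y[1] > scoring_half_extent[1]
    ):
        raise ValueError("PTV extends outside the lateral scoring field")
    if depth_dose_oracle is None:
        from .transport import depth_dose as depth_dose_oracle  # lazy, avoids cycle

    weights, _ = optimize_layer_weights(
        layer_models, ptv.z, depth_dose_oracle, wet_offset=wet_offset
    )
    weights = weights / weights.mean() if weights.mean() > 0 else weights

    nx = int(math.floor((ptv.x[1] - ptv.x[0]) / spot_spacing + 1e-9)) + 1
    ny = int(math.floor((ptv.y[1] - ptv.y[0]) / spot_spacing + 1e-9)) + 1
    xs = ptv.x[0] + spot_spacing * np.arange(nx)
    ys = ptv.y[0] + spot_spacing * np.arange(ny)
    spots = [
        Spot(iso_x=float(sx), iso_y=float(sy), layer=li, weight=float(weights[li]))
        for li in range(len(layer_models))
        for sx in xs
        for sy in ys
    ]
    return TreatmentPlan(layers=list(layer_models), spots=spots, ptv=ptv, sad=sad)
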