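"""Geometric model of multi-slit collimators and the rotated dual system.

A multi-slit collimator (MSC) is a thick slab of tungsten with parallel
slit apertures at a fixed period.  A ray is transmitted iff its straight
chord through the slab stays inside a single aperture; the slab is treated
as a perfect binary absorber (30 mm of tungsten stops the simulated proton
energies outright, and septal/edge scatter is outside this model).

Rotation convention: slits run nominally along x (grating wavevector along
y); in a symmetric dual system the upstream collimator is rotated by
``+theta/2`` and the downstream one by ``-theta/2`` about the beam axis, so
the moire fringes align with the x-direction.  Aperture centers pass
through the rotation axis (the beam axis).

The beam travels along +z.  All lengths are mm, angles degrees, ray slopes
are small-angle (rad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MultiSlitCollimator",
    "DualCollimatorSystem",
    "Ray",
    "transmits",
    "transmits_dcs",
    "transmits_mask",
    "transmits_dcs_mask",
    "aperture_map",
    "mask_dominant_period",
]


@dataclass(frozen=True)
class MultiSlitCollimator:
    """One periodic slit grating.

    Parameters
    ----------
    period:
        Slit period in mm (equal to the geometric CTC of a single MSC).
    throughput:
        Open fraction in (0, 1); aperture width = period * throughput.
    thickness:
        Slab thickness along the beam, mm.
    rotation_deg:
        Rotation about the beam axis; at 0 the slits run along x.
    z_upstream_face:
        z of the upstream face, mm (beam travels toward +z).
    lateral_half_extent:
        Half-size of the physical slab; rays outside are absorbed.
    """

    period: float
    throughput: float
    thickness: float = 30.0
    rotation_deg: float = 0.0
    z_upstream_face: float = 0.0
    lateral_half_extent: float = 75.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if not (0.0 < self.throughput < 1.0):
            raise ValueError(
                f"throughput must lie strictly in (0, 1), got {self.throughput}"
            )
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        if self.lateral_half_extent <= 0:
            raise ValueError("lateral_half_extent must be positive")

    @property
    def aperture_width(self) -> float:
        return self.period * self.throughput

    @property
    def septal_width(self) -> float:
        return self.period * (1.0 - self.throughput)

    @property
    def z_downstream_face(self) -> float:
        return self.z_upstream_face + self.thickness


@dataclass(frozen=True)
class Ray:
    """Straight ray: lateral position (mm) and slopes (rad) at plane ``z``."""

    x: float
    y: float
    xp: float = 0.0
    yp: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.xp) >= 0.1 or abs(self.yp) >= 0.1:
            raise ValueError("ray slopes must satisfy |slope| < 0.1 rad")


@dataclass(frozen=True)
class DualCollimatorSystem:
    """Two multi-slit collimators in series, upstream of a phantom.

    z-ordering is validated: msc1 slab, inter-collimator gap, msc2 slab,
    collimator-to-phantom gap, phantom entrance face.
    """

    msc1: MultiSlitCollimator
    msc2: MultiSlitCollimator
    inter_collimator_gap: float = 5.0
    collimator_to_phantom_gap: float = 5.0

    def __post_init__(self) -> None:
        if self.inter_collimator_gap < 0 or self.collimator_to_phantom_gap < 0:
            raise ValueError("gaps must be non-negative")
        gap = self.msc2.z_upstream_face - self.msc1.z_downstream_face
        if abs(gap - self.inter_collimator_gap) > 1e-9:
            raise ValueError(
                f"collimator z positions imply a {gap} mm gap, inconsistent "
                f"with inter_collimator_gap={self.inter_collimator_gap}"
            )

    @property
    def relative_angle_deg(self) -> float:
        """Angle between the two slit orientations, folded into [0, 90]."""
        a = abs(self.msc2.rotation_deg - self.msc1.rotation_deg) % 180.0
        return min(a, 180.0 - a)

    @property
    def phantom_face_z(self) -> float:
        return self.msc2.z_downstream_face + self.collimator_to_phantom_gap

    @classmethod
    def symmetric(
        cls,
        period: float,
        throughput: float,
        angle_deg: float,
        period2: float | None = None,
        thickness: float = 30.0,
        inter_collimator_gap: float = 5.0,
        collimator_to_phantom_gap: float = 5.0,
        phantom_face_z: float = 0.0,
        lateral_half_extent: float = 75.0,
    ) -> "DualCollimatorSystem":
        """Build the standard setup: collimators rotated by ±angle/2, the
        downstream face of msc2 a fixed gap upstream of the phantom face."""
        z2 = phantom_face_z - collimator_to_phantom_gap - thickness
        z1 = z2 - inter_collimator_gap - thickness
        msc1 = MultiSlitCollimator(
            period=period,
            throughput=throughput,
            thickness=thickness,
            rotation_deg=+angle_deg / 2.0,
            z_upstream_face=z1,
            lateral_half_extent=lateral_half_extent,
        )
        msc2 = MultiSlitCollimator(
            period=period2 if period2 is not None else period,
            throughput=throughput,
            thickness=thickness,
            rotation_deg=-angle_deg / 2.0,
            z_upstream_face=z2,
            lateral_half_extent=lateral_half_extent,
        )
        return cls(
            msc1=msc1,
            msc2=msc2,
            inter_collimator_gap=inter_collimator_gap,
            collimator_to_phantom_gap=collimator_to_phantom_gap,
        )


def transmits_mask(
    msc: MultiSlitCollimator,
    x: np.ndarray,
    y: np.ndarray,
    xp: np.ndarray,
    yp: np.ndarray,
    z_ref: float,
) -> np.ndarray:
    """Vectorized binary transmission through one collimator.

    A ray is transmitted iff both its entry and exit points lie inside the
    *same* aperture interval (straight chords through planar-walled slits
    are convex, so endpoint membership implies whole-chord membership) and
    the entry point is within the slab's lateral extent.
    """
    x = np.asarray(x, dtype=float)
    dz_in = msc.z_upstream_face - z_ref
    x_in = x + xp * dz_in
    y_in = y + yp * dz_in
    inside_slab = (np.abs(x_in) <= msc.lateral_half_extent) & (
        np.abs(y_in) <= msc.lateral_half_extent
    )

    phi = math.radians(msc.rotation_deg)
    s, c = math.sin(phi), math.cos(phi)
    # coordinate along the grating wavevector (local y) and its slope
    v_in = -x_in * s + y_in * c
    vp = -xp * s + yp * c
    v_out = v_in + vp * msc.thickness

    half_ap = 0.5 * msc.aperture_width
    k_in = np.round(v_in / msc.period)
    k_out = np.round(v_out / msc.period)
    open_in = np.abs(v_in - k_in * msc.period) <= half_ap
    open_out = np.abs(v_out - k_out * msc.period) <= half_ap
    return inside_slab & open_in & open_out & (k_in == k_out)


def transmits(ray: Ray, msc: MultiSlitCollimator) -> bool:
    """Scalar binary transmission of one ray through one collimator."""
    return bool(
        transmits_mask(
            msc,
            np.array([ray.x]),
            np.array([ray.y]),
            np.array([ray.xp]),
            np.array([ray.yp]),
            ray.z,
        )[0]
    )


def transmits_dcs_mask(
    dcs: DualCollimatorSystem,
    x: np.ndarray,
    y: np.ndarray,
    xp: np.ndarray,
    yp: np.ndarray,
    z_ref: float,
) -> np.ndarray:
    """Transmission through both collimators (straight-line propagation
    across the inter-collimator gap; logical AND)."""
    m1 = transmits_mask(dcs.msc1, x, y, xp, yp, z_ref)
    m2 = transmits_mask(dcs.msc2, x, y, xp, yp, z_ref)
    return m1 & m2


def transmits_dcs(ray: Ray, dcs: DualCollimatorSystem) -> bool:
    return bool(
        transmits_dcs_mask(
            dcs,
            np.array([ray.x]),
            np.array([ray.y]),
            np.array([ray.xp]),
            np.array([ray.yp]),
            ray.z,
        )[0]
    )


def aperture_map(
    dcs: DualCollimatorSystem,
    grid_spacing: float,
    half_extent_x: float = 40.0,
    half_extent_y: float = 20.0,
    plane_z: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static binary openness mask of the dual system for a parallel beam.

    Evaluates :func:`transmits_dcs_mask` for normally incident rays on a
    regular lateral grid.  Returns ``(mask, xs, ys)`` with ``mask`` indexed
    ``[iy, ix]``.  The mask is periodic; its dominant period along the
    moire axis matches the closed-form moire period.
    """
    min_ap = min(dcs.msc1.aperture_width, dcs.msc2.aperture_width)
    if grid_spacing <= 0 or grid_spacing > min_ap / 5.0:
        raise ValueError(
            f"grid_spacing must be in (0, {min_ap / 5.0:.4g}] mm "
            f"(a fifth of the smallest aperture width)"
        )
    if plane_z is None:
        plane_z = dcs.msc1.z_upstream_face - 1.0
    xs = np.arange(-half_extent_x, half_extent_x + 0.5 * grid_spacing, grid_spacing)
    ys = np.arange(-half_extent_y, half_extent_y + 0.5 * grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    zeros = np.zeros_like(gx)
    mask = transmits_dcs_mask(
        dcs, gx.ravel(), gy.ravel(), zeros.ravel(), zeros.ravel(), plane_z
    ).reshape(gx.shape)
    return mask, xs, ys


def mask_dominant_period(
    mask: np.ndarray, xs: np.ndarray, prominence_fraction: float = 0.2
) -> float:
    """Dominant spatial period (mm) of an openness mask along x.

    Column-averages the mask into an openness profile and measures the mean
    spacing of its prominent peaks (the same estimator used for dose CTC).
    """
    from .metrics import LateralProfile, ctc, find_peaks_valleys

    profile = LateralProfile(
        axis="x",
        positions=np.asarray(xs, dtype=float),
        values=mask.mean(axis=0).astype(float),
        depth_window=(0.0, 0.0),
        band_halfwidth=float(xs[-1]),
    )
    pv = find_peaks_valleys(profile, prominence_fraction=prominence_fraction)
    return ctc(pv)
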