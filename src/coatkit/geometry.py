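"""Spherical-cap model of the clathrin coat.

A curved clathrin-coated structure is idealised as a spherical cap of tip
radius ``R`` (nm) and contact angle ``theta`` (radians, measured at the tip:
``theta = 0`` is a point, ``pi/2`` a hemisphere, ``pi`` a complete sphere).
The module converts between the coat surface area (what fluorescence
reports), the projected area (what transmission EM of a metal replica
reports: the silhouette on the membrane plane), contact angle and tip
radius, and provides the curvature correction factor — the
surface-to-projected ratio used to map curved structures onto a flat-coat
intensity calibration.

All lengths are nm, areas nm², angles radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CapShape",
    "FlatDisc",
    "cap_surface_area",
    "cap_projected_area",
    "correction_factor",
    "shape_from_surface",
    "cap_from_surface_and_angle",
    "bend_flat_disc",
]


@dataclass(frozen=True)
class CapShape:
    """Spherical cap: tip radius (nm, > 0) and contact angle (rad, [0, pi])."""

    tip_radius: float
    contact_angle: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.tip_radius) or self.tip_radius <= 0:
            raise ValueError(f"tip_radius must be positive, got {self.tip_radius}")
        if not np.isfinite(self.contact_angle) or not (0.0 <= self.contact_angle <= np.pi):
            raise ValueError(
                f"contact_angle must be in [0, pi], got {self.contact_angle}"
            )

    @property
    def surface_area(self) -> float:
        return cap_surface_area(self)

    @property
    def projected_area(self) -> float:
        return cap_projected_area(self)


@dataclass(frozen=True)
class FlatDisc:
    """Flat circular clathrin patch of a given area (nm², >= 0)."""

    area: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.area) or self.area < 0:
            raise ValueError(f"area must be nonnegative, got {self.area}")

    @property
    def edge_length(self) -> float:
        """Circumference of the disc, the only place new triskelia can add."""
        return 2.0 * np.sqrt(np.pi * self.area)


def cap_surface_area(shape: CapShape) -> float:
    """Surface area of a spherical cap, ``2 pi R^2 (1 - cos theta)``.

    Equals ``4 pi R^2`` for a complete sphere (theta = pi) and
    ``2 pi R^2`` for a hemisphere (theta = pi/2).
    """
    r, theta = shape.tip_radius, shape.contact_angle
    return 2.0 * np.pi * r * r * (1.0 - np.cos(theta))


def cap_projected_area(shape: CapShape) -> float:
    """Area of the cap's silhouette on the membrane plane.

    For ``theta <= pi/2`` the silhouette is the rim disc,
    ``pi R^2 sin^2 theta``; past the hemisphere the equator is the widest
    circle, so the silhouette saturates at ``pi R^2``.  This is what the
    outline of a structure in a TEM replica measures.
    """
    r, theta = shape.tip_radius, shape.contact_angle
    if theta <= np.pi / 2:
        s = np.sin(theta)
        return np.pi * r * r * s * s
    return np.pi * r * r


def correction_factor(theta: float) -> float:
    """Surface-to-projected-area ratio of a cap at contact angle ``theta``.

    ``2 / (1 + cos theta)`` up to the hemisphere, ``2 (1 - cos theta)``
    beyond it.  Monotone nondecreasing from 1 (flat limit) to 2 at the
    hemisphere and 4 at the complete sphere; this is the factor by which a
    curved structure's fluorescence exceeds what its TEM footprint would
    suggest under a flat-coat calibration.

    Raises
    ------
    ValueError
        If ``theta`` is outside ``(0, pi]`` (at 0 the projected area
        vanishes and the ratio degenerates).
    """
    if not np.isfinite(theta) or not (0.0 < theta <= np.pi):
        raise ValueError(f"theta must be in (0, pi], got {theta}")
    if theta <= np.pi / 2:
        return 2.0 / (1.0 + np.cos(theta))
    return 2.0 * (1.0 - np.cos(theta))


def shape_from_surface(surface: float, tip_radius: float) -> CapShape:
    """Cap of given surface area on a sphere of given tip radius.

    Inverts ``S = 2 pi R^2 (1 - cos theta)``; used to compute the predicted
    contact angle of a coat from its (fluorescence-derived) surface area.

    Raises
    ------
    ValueError
        If ``surface`` is negative or exceeds the full-sphere area
        ``4 pi R^2``.
    """
    if tip_radius <= 0:
        raise ValueError(f"tip_radius must be positive, got {tip_radius}")
    full = 4.0 * np.pi * tip_radius * tip_radius
    if not np.isfinite(surface) or surface < 0 or surface > full * (1 + 1e-12):
        raise ValueError(
            f"surface must be in [0, 4*pi*R^2] = [0, {full:.6g}], got {surface}"
        )
    cos_theta = 1.0 - surface / (2.0 * np.pi * tip_radius * tip_radius)
    theta = float(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    return CapShape(tip_radius=tip_radius, contact_angle=theta)


def cap_from_surface_and_angle(surface: float, theta: float) -> CapShape:
    """Cap with a given surface area and contact angle.

    Solves ``S = 2 pi R^2 (1 - cos theta)`` for the tip radius; this is the
    geometry of constant-surface bending, where the lattice keeps its area
    while the angle grows and the sphere it sits on shrinks.
    """
    if surface <= 0:
        raise ValueError(f"surface must be positive, got {surface}")
    if not (0.0 < theta <= np.pi):
        raise ValueError(f"theta must be in (0, pi], got {theta}")
    r = np.sqrt(surface / (2.0 * np.pi * (1.0 - np.cos(theta))))
    return CapShape(tip_radius=float(r), contact_angle=float(theta))


def bend_flat_disc(disc: FlatDisc, tip_radius: float) -> CapShape:
    """Bend a flat patch into a cap of equal surface area.

    Constant-surface bending: the lattice rearranges without adding
    material, so ``cap_surface_area(result) == disc.area``.
    """
    return shape_from_surface(disc.area, tip_radius)
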