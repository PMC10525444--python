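"""Biconic surface geometry.

The biconic is the standard average description of a corneal surface: two
independent radii of curvature ``Rx``, ``Ry`` along the horizontal and
vertical meridians and two asphericities (q-values) ``Qx``, ``Qy``.  Its sag
(elevation along the optical axis, zero at the apex, increasing posteriorly)
is

    z(x, y) = (x^2/Rx + y^2/Ry) /
              (1 + sqrt(1 - (1+Qx) x^2/Rx^2 - (1+Qy) y^2/Ry^2))

A sphere of radius R is the special case Rx = Ry = R, Qx = Qy = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BiconicParams:
    """Average-curvature description of one corneal surface.

    Radii in mm, q-values dimensionless.  ``rms_residual`` (mm) is filled in
    by the least-squares fitter; for exact constructions it is zero.
    """

    Rx: float
    Ry: float
    Qx: float
    Qy: float
    rms_residual: float = 0.0
    #: free apex offset z0 (mm) recovered when fitting deformed surfaces
    apex_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.Rx <= 0 or self.Ry <= 0:
            raise ValueError(f"radii must be positive, got Rx={self.Rx}, Ry={self.Ry}")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


class BiconicDomainError(ValueError):
    """Raised when the biconic radicand becomes non-positive inside the zone."""


def biconic_radicand(x, y, params: BiconicParams):
    """Radicand of the biconic sag expression; must stay positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (
        1.0
        - (1.0 + params.Qx) * x**2 / params.Rx**2
        - (1.0 + params.Qy) * y**2 / params.Ry**2
    )


def biconic_sag(x, y, params: BiconicParams, *, check: bool = True):
    """Sag z(x, y) of a biconic surface (mm, apex at the origin).

    With ``check`` enabled a non-positive radicand anywhere raises
    :class:`BiconicDomainError` naming the offending radius/Q pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rad = biconic_radicand(x, y, params)
    if check and np.any(rad <= 0):
        r_bad = float(np.hypot(x, y).flat[int(np.argmin(rad))])
        raise BiconicDomainError(
            f"biconic radicand <= 0 at radius {r_bad:.3f} mm for "
            f"(Rx={params.Rx}, Qx={params.Qx}) / (Ry={params.Ry}, Qy={params.Qy})"
        )
    num = x**2 / params.Rx + y**2 / params.Ry
    return num / (1.0 + np.sqrt(np.clip(rad, 0.0, None)))


def sphere_sag(r, radius: float):
    """Sag of a sphere: R - sqrt(R^2 - r^2)."""
    r = np.asarray(r, dtype=float)
    return radius - np.sqrt(radius**2 - r**2)


def disk_grid(zone_diameter: float, grid_spacing: float):
    """Regular square grid clipped to the zone disk; returns (x, y) 1-D arrays."""
    if zone_diameter <= 0 or grid_spacing <= 0:
        raise ValueError("zone_diameter and grid_spacing must be positive")
    half = zone_diameter / 2.0
    n = int(np.floor(half / grid_spacing))
    axis = np.arange(-n, n + 1) * grid_spacing
    xg, yg = np.meshgrid(axis, axis)
    mask = np.hypot(xg, yg) <= half + 1e-12
    return xg[mask].ravel(), yg[mask].ravel()
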