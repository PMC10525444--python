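"""Curvature analysis of corneal surface samplings.

Two complementary descriptions:

* the *average* curvature via a biconic least-squares fit (radii Rx, Ry and
  q-values Qx, Qy over a central optical zone), and
* *local* sagittal (axial) curvature maps — the clinical topographer
  quantity: at each point the radius is the distance along the local surface
  normal to the reference axis, converted to diopters with the appropriate
  refractive-index step (0.375 for the anterior surface, -0.042 for the
  posterior).

For keratoconic surfaces the reference axis is re-centred on the most
elevated point of the cornea before the map is computed (``re_origin``),
mirroring standard topographer practice for decentred cones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import BiconicParams, biconic_radicand, biconic_sag
from .surfaces import SurfaceSampling

__all__ = [
    "CurvatureMap",
    "fit_biconic",
    "sagittal_map",
    "difference_map",
    "extract_extrema",
    "delta_axial_length",
    "INDEX_STEP",
]

#: Refractive-index step (n1 - n0) across each surface, used to convert a
#: radius of curvature in meters to diopters.
INDEX_STEP = {"anterior": 1.375 - 1.0, "posterior": 1.333 - 1.375}


@dataclass
class CurvatureMap:
    """Sagittal curvature in diopters on a polar grid around ``origin``.

    ``values`` has shape (n_meridians, n_radii); ``thetas`` are meridian
    angles in radians, ``rs`` radial distances in mm from the origin.
    """

    values: np.ndarray
    thetas: np.ndarray
    rs: np.ndarray
    origin: tuple[float, float]
    zone_diameter: float
    surface_side: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.rs = np.asarray(self.rs, dtype=float)
        if self.values.shape != (self.thetas.size, self.rs.size):
            raise ValueError("values shape must be (n_meridians, n_radii)")
        if np.hypot(*self.origin) > self.zone_diameter / 2 + 1e-9:
            raise ValueError("origin outside the zone")

    def same_grid(self, other: "CurvatureMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.thetas, other.thetas)
            and np.allclose(self.rs, other.rs)
        )


class FitError(RuntimeError):
    """Biconic fit failed (non-convergence or degenerate data)."""


def _select_zone(surface: SurfaceSampling, zone_diameter: float):
    r = np.hypot(surface.x, surface.y)
    m = r <= zone_diameter / 2 + 1e-12
    return surface.x[m], surface.y[m], surface.z[m]


def fit_biconic(
    surface: SurfaceSampling,
    zone_diameter: float = 5.0,
    *,
    fit_offset: bool = True,
) -> BiconicParams:
    """Nonlinear least-squares biconic fit over the central zone.

    The model is the biconic sag plus (by default) a free apex offset z0,
    needed because deformed surfaces no longer pass through the coordinate
    origin; for an exact biconic input z0 converges to zero and the four
    shape parameters are recovered to machine precision.  Deterministic:
    the initial guess is a paraxial (linear) fit with Qx = Qy = 0.
    """
    x, y, z = _select_zone(surface, zone_diameter)
    if x.size < 6:
        raise FitError(f"need >= 6 points in the {zone_diameter} mm zone, got {x.size}")

    # paraxial initialisation: z ~ z0 + x^2/(2 Rx) + y^2/(2 Ry)
    A = np.column_stack([x**2 / 2, y**2 / 2, np.ones_like(x)])
    if np.linalg.matrix_rank(A) < 3:
        raise FitError("degenerate point set: paraxial design matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    cx = coef[0] if coef[0] > 1e-4 else 1.0 / 7.8
    cy = coef[1] if coef[1] > 1e-4 else 1.0 / 7.8
    p0 = [1.0 / cx, 1.0 / cy, 0.0, 0.0, coef[2] if fit_offset else 0.0]

    def residuals(p):
        Rx, Ry, Qx, Qy, z0 = p
        if Rx <= 0.05 or Ry <= 0.05:
            return 1e3 * np.ones_like(z)
        params = BiconicParams(Rx, Ry, Qx, Qy)
        rad = biconic_radicand(x, y, params)
        if np.any(rad <= 1e-9):
            return 1e3 * np.ones_like(z)
        model = biconic_sag(x, y, params, check=False)
        if not fit_offset:
            z0 = 0.0
        return model + z0 - z

    sol = least_squares(residuals, p0, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=5000)
    if not sol.success:
        raise FitError(f"biconic fit did not converge: {sol.message}; "
                       f"final cost {sol.cost:.3e}")
    Rx, Ry, Qx, Qy, z0 = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return BiconicParams(float(Rx), float(Ry), float(Qx), float(Qy),
                         rms_residual=rms, apex_offset=float(z0))


def _patch_derivatives(surface: SurfaceSampling, px: np.ndarray, py: np.ndarray,
                       k: int = 16):
    """Weighted local quadric-patch fit at each evaluation point.

    Fits z = a + b u + c v + d u^2 + e u v + f v^2 to the k nearest surface
    samples (u, v relative to the evaluation point, inverse-distance
    weighted), returning the gradient (b, c) and the Hessian entries
    (2d, e, 2f).  Exact for any quadratic surface; for smooth corneal
    surfaces the patch bias is far below clinical map resolution.
    """
    tree = cKDTree(np.column_stack([surface.x, surface.y]))
    k = min(k, surface.n_points)
    dist, idx = tree.query(np.column_stack([px, py]), k=k)
    u = surface.x[idx] - px[:, None]
    v = surface.y[idx] - py[:, None]
    z = surface.z[idx]
    dmax = dist[:, -1][:, None] * 1.05 + 1e-12
    w = (1.0 - (dist / dmax) ** 2) ** 2
    Phi = np.stack([np.ones_like(u), u, v, u**2, u * v, v**2], axis=2)  # (M,k,6)
    Pw = Phi * w[:, :, None]
    AtA = np.einsum("mki,mkj->mij", Pw, Phi)
    Atz = np.einsum("mki,mk->mi", Pw, z)
    beta = np.linalg.solve(AtA, Atz[:, :, None])[:, :, 0]
    grad = beta[:, 1:3]
    hess = np.stack([2 * beta[:, 3], beta[:, 4], 2 * beta[:, 5]], axis=1)
    return grad, hess


def sagittal_map(
    surface: SurfaceSampling,
    zone_diameter: float = 8.0,
    re_origin: bool = False,
    *,
    n_meridians: int = 64,
    dr: float = 0.05,
    mode: str = "axial",
    r_max: float | None = None,
) -> CurvatureMap:
    """Sagittal curvature map on a polar grid.

    ``re_origin`` moves the map origin (and the curvature reference axis) to
    the most elevated point of the surface, as done for keratoconic corneas;
    otherwise the origin is the coordinate apex.  ``mode`` selects the
    clinical axial definition (default) or the meridional (tangential)
    curvature.
    """
    if mode not in ("axial", "tangential"):
        raise ValueError("mode must be 'axial' or 'tangential'")
    origin = surface.most_elevated_point() if re_origin else (0.0, 0.0)
    dn = INDEX_STEP[surface.surface_side]

    off = float(np.hypot(*origin))
    if r_max is None:
        r_max = min(zone_diameter / 2, surface.zone_diameter / 2 - off - 2 * dr)
    if r_max <= 3 * dr:
        raise ValueError("map zone too small after origin shift")
    rs = np.arange(0.0, r_max + dr / 2, dr)
    thetas = 2 * np.pi * np.arange(n_meridians) / n_meridians

    ct, st = np.cos(thetas)[:, None], np.sin(thetas)[:, None]
    rr = rs[None, :]
    px = (origin[0] + rr * ct).ravel()
    py = (origin[1] + rr * st).ravel()
    grad, hess = _patch_derivatives(surface, px, py)

    shape = (n_meridians, rs.size)
    # meridional slope and second derivative along each ray
    cdir = np.broadcast_to(ct, shape).ravel()
    sdir = np.broadcast_to(st, shape).ravel()
    dzdr = (grad[:, 0] * cdir + grad[:, 1] * sdir).reshape(shape)
    d2z = (hess[:, 0] * cdir**2 + 2 * hess[:, 1] * cdir * sdir
           + hess[:, 2] * sdir**2).reshape(shape)

    values = np.empty(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "axial":
            sinphi = dzdr / np.sqrt(1.0 + dzdr**2)
            values[:, 1:] = 1000.0 * dn * sinphi[:, 1:] / rr[:, 1:]
        else:
            values[:, 1:] = (
                1000.0 * dn * d2z[:, 1:] / (1.0 + dzdr[:, 1:] ** 2) ** 1.5
            )
    # r = 0: meridional limit (axial and tangential curvature coincide)
    values[:, 0] = 1000.0 * dn * d2z[:, 0]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite curvature values inside the zone")
    return CurvatureMap(values, thetas, rs, origin, 2 * r_max, surface.surface_side)


def difference_map(post: CurvatureMap, pre: CurvatureMap) -> CurvatureMap:
    """Pointwise post - pre map; origin metadata carried from the post map."""
    if not post.same_grid(pre):
        raise ValueError("curvature maps are on different grids")
    return CurvatureMap(post.values - pre.values, post.thetas.copy(),
                        post.rs.copy(), post.origin, post.zone_diameter,
                        post.surface_side)


def extract_extrema(cmap: CurvatureMap):
    """(Kmax, location) and (Kmin, location) of a map.

    Ties are broken by smallest radius, then smallest meridian angle.
    Locations are absolute (x, y) in mm.
    """
    vals = cmap.values
    tt, rr = np.meshgrid(cmap.thetas, cmap.rs, indexing="ij")

    def pick(target):
        hit = np.isclose(vals, target, rtol=0.0, atol=0.0)
        cand = np.argwhere(hit)
        keys = [(rr[i, j], tt[i, j]) for i, j in cand]
        i, j = cand[int(np.lexsort(np.array(keys).T[::-1])[0])]
        x = cmap.origin[0] + rr[i, j] * np.cos(tt[i, j])
        y = cmap.origin[1] + rr[i, j] * np.sin(tt[i, j])
        return float(vals[i, j]), (float(x), float(y))

    kmax, loc_max = pick(vals.max())
    kmin, loc_min = pick(vals.min())
    return (kmax, loc_max), (kmin, loc_min)


def delta_axial_length(post: SurfaceSampling, pre: SurfaceSampling) -> float:
    """Signed maximal-magnitude axial displacement in mm, anterior-positive.

    A posterior recession of the anterior surface (sag increase) shortens
    the globe and is reported negative, matching the sign convention of the
    axial-length column in the reference assessment.
    """
    if post.n_points != pre.n_points or not (
        np.allclose(post.x, pre.x) and np.allclose(post.y, pre.y)
    ):
        raise ValueError("surfaces are sampled at different (x, y) points")
    d = -(post.z - pre.z)  # anterior-positive displacement
    i = int(np.argmax(np.abs(d)))
    return float(d[i])
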