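"""Zernike decomposition of corneal elevation over a circular pupil.

Orthonormal Zernike polynomials with OSA/ANSI single indexing,
j = (n(n+2) + m) / 2, up to radial order six (28 terms).  Coefficients are
in micrometers of surface elevation.  Clinically named low-order terms
(tilt, defocus, astigmatism) and high-order terms (coma, trefoil, spherical
aberration, ...) follow the standard single-index ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np

from .surfaces import SurfaceSampling

__all__ = [
    "ZernikeSpectrum",
    "zernike_value",
    "zernike_nm",
    "fit_zernike",
    "aberration_table",
    "OSA_DESCRIPTIONS",
    "N_TERMS",
]

MAX_ORDER = 6
N_TERMS = (MAX_ORDER + 1) * (MAX_ORDER + 2) // 2  # 28

#: Clinical names of the OSA single-index terms through fourth order.
OSA_DESCRIPTIONS = {
    0: "piston",
    1: "vertical tilt",
    2: "horizontal tilt",
    3: "oblique primary astigmatism",
    4: "defocus",
    5: "vertical/horizontal primary astigmatism",
    6: "vertical trefoil",
    7: "vertical coma",
    8: "horizontal coma",
    9: "oblique trefoil",
    10: "oblique quadrafoil",
    11: "oblique secondary astigmatism",
    12: "primary spherical",
    13: "vertical secondary astigmatism",
    14: "vertical quadrafoil",
}


def zernike_nm(j: int) -> tuple[int, int]:
    """OSA single index -> (radial order n, azimuthal frequency m)."""
    if not 0 <= j < N_TERMS:
        raise IndexError(f"OSA index must be in 0..{N_TERMS - 1}, got {j}")
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def describe(j: int) -> str:
    n, m = zernike_nm(j)
    if j in OSA_DESCRIPTIONS:
        return OSA_DESCRIPTIONS[j]
    return f"order-{n} term (m={m:+d})"


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + m_abs) // 2 - k)
                * factorial((n - m_abs) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_value(j: int, rho, theta):
    """Orthonormal Zernike polynomial with OSA index j at (rho, theta).

    rho in [0, 1]; normalisation sqrt(2(n+1)/(1+delta_m0)) so the discrete
    inner product over the unit disk (area-weighted) is the identity.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1 + 1e-12):
        raise ValueError("rho must lie in [0, 1]")
    n, m = zernike_nm(j)
    norm = np.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))
    rad = _radial(n, abs(m), rho)
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(theta)
    return norm * rad * ang


@dataclass
class ZernikeSpectrum:
    """OSA-indexed coefficients (um) of an elevation fit over a pupil."""

    coefficients: np.ndarray
    pupil_radius: float  # mm
    normalization: str = "orthonormal"
    rms_fit_residual: float = 0.0  # um

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if self.coefficients.size != N_TERMS:
            raise ValueError(f"need exactly {N_TERMS} coefficients")
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be positive")

    def __getitem__(self, j: int) -> float:
        return float(self.coefficients[j])

    def summary(self, *, kind: str = "signed", split_order: int = 3) -> dict:
        """Low/high-order summaries of the coefficients (piston excluded).

        ``kind`` 'signed' sums the raw coefficients; 'rms' takes the root
        sum of squares.  Terms of radial order < ``split_order`` count as
        low order.
        """
        orders = np.array([zernike_nm(j)[0] for j in range(N_TERMS)])
        lo = (orders > 0) & (orders < split_order)
        hi = orders >= split_order
        if kind == "signed":
            agg = lambda c: float(np.sum(c))
        elif kind == "rms":
            agg = lambda c: float(np.sqrt(np.sum(c**2)))
        else:
            raise ValueError("kind must be 'signed' or 'rms'")
        return {"low_order": agg(self.coefficients[lo]),
                "high_order": agg(self.coefficients[hi])}


def _design_matrix(x, y, pupil_radius: float, n_terms: int) -> np.ndarray:
    rho = np.hypot(x, y) / pupil_radius
    theta = np.arctan2(y, x)
    return np.column_stack([zernike_value(j, rho, theta) for j in range(n_terms)])


def fit_zernike(
    surface: SurfaceSampling,
    pupil_diameter: float = 5.0,
    max_order: int = MAX_ORDER,
    *,
    max_cond: float = 1e8,
) -> ZernikeSpectrum:
    """Least-squares Zernike fit of elevation (um) over the pupil.

    Plain linear least squares on the orthonormal basis functions through
    radial order ``max_order`` at the pupil-scaled sample coordinates (the
    returned spectrum always carries 28 slots; orders above ``max_order``
    are zero).  If the design matrix is ill-conditioned (condition number
    above ``max_cond``) a warning is issued and a small ridge penalty
    stabilises the solve.
    """
    if not 0 <= max_order <= MAX_ORDER:
        raise ValueError(f"max_order must be in 0..{MAX_ORDER}")
    n_terms = (max_order + 1) * (max_order + 2) // 2
    R = pupil_diameter / 2.0
    m = np.hypot(surface.x, surface.y) <= R + 1e-12
    x, y, z = surface.x[m], surface.y[m], surface.z[m]
    if x.size < n_terms:
        raise ValueError(
            f"need >= {n_terms} points inside the {pupil_diameter} mm pupil, got {x.size}"
        )
    A = _design_matrix(x, y, R, n_terms)
    z_um = z * 1000.0
    cond = np.linalg.cond(A)
    if cond > max_cond:
        warnings.warn(
            f"Zernike design matrix ill-conditioned (cond={cond:.2e}); "
            "applying ridge regularisation", RuntimeWarning, stacklevel=2)
        coef = np.linalg.solve(A.T @ A + 1e-8 * np.eye(n_terms), A.T @ z_um)
    else:
        coef, *_ = np.linalg.lstsq(A, z_um, rcond=None)
    resid = A @ coef - z_um
    full = np.zeros(N_TERMS)
    full[:n_terms] = coef
    return ZernikeSpectrum(full, R, rms_fit_residual=float(np.sqrt(np.mean(resid**2))))


def aberration_table(spectra: dict, baseline: str):
    """Per-index coefficient changes of each scenario against a baseline.

    ``spectra`` maps scenario name -> ZernikeSpectrum (all with the same
    pupil radius and normalisation).  Returns a DataFrame with one row per
    OSA index (with its clinical description) and one column per non-baseline
    scenario, plus signed low/high-order summary rows.
    """
    import pandas as pd

    if baseline not in spectra:
        raise KeyError(f"baseline scenario {baseline!r} missing from spectra")
    ref = spectra[baseline]
    for name, sp in spectra.items():
        if not np.isclose(sp.pupil_radius, ref.pupil_radius) or (
            sp.normalization != ref.normalization
        ):
            raise ValueError(
                f"spectrum {name!r} has a different pupil or normalisation "
                "and cannot be compared")
    scenarios = [s for s in spectra if s != baseline]
    rows = {}
    for j in range(N_TERMS):
        rows[j] = [spectra[s][j] - ref[j] for s in scenarios]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=scenarios)
    df.insert(0, "description", [describe(j) for j in df.index])
    df.index.name = "osa_index"
    lo = {s: (spectra[s].summary()["low_order"] - ref.summary()["low_order"])
          for s in scenarios}
    hi = {s: (spectra[s].summary()["high_order"] - ref.summary()["high_order"])
          for s in scenarios}
    df.loc["sum_low_order"] = ["signed sum, orders 1-2"] + [lo[s] for s in scenarios]
    df.loc["sum_high_order"] = ["signed sum, orders 3-6"] + [hi[s] for s in scenarios]
    return df
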