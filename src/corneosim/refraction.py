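"""Refraction arithmetic for ring-segment scenarios.

Converts radii of curvature to surface powers ((n1 - n0)/R, anterior index
step +0.375, posterior -0.042), averages the two meridional powers of a
biconic surface, converts an axial-length change to a myopic shift
(D_total^2 x |dAL|, so 36 um at 60 dpt gives 0.13 dpt), and aggregates
anterior, posterior and axial contributions into the effective refractive
change of one scenario:

    effective = d_anterior + d_posterior - myopic_shift

with flattening negative, steepening positive, and an axial-length
*reduction* contributing a myopic (negative) correction term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem_reference import KC_STEEPENING_DPT, TOTAL_POWER_HEALTHY_DPT
from .geometry import BiconicParams

__all__ = [
    "RefractionSummary",
    "radius_to_power",
    "mean_meridional_power",
    "myopic_shift",
    "effective_change",
    "build_summary_table",
    "total_power",
]

_INDEX_STEP = {"anterior": 1.375 - 1.0, "posterior": 1.333 - 1.375}


def total_power(cornea: str) -> float:
    """Assumed total ocular power: 60 dpt healthy, 60 + 4.7 dpt keratoconic."""
    if cornea == "healthy":
        return TOTAL_POWER_HEALTHY_DPT
    if cornea == "KC":
        return TOTAL_POWER_HEALTHY_DPT + KC_STEEPENING_DPT
    raise ValueError("cornea must be 'healthy' or 'KC'")


def radius_to_power(R_mm: float, side: str) -> float:
    """Surface power in diopters from a radius of curvature in mm."""
    if side not in _INDEX_STEP:
        raise ValueError(f"side must be one of {tuple(_INDEX_STEP)}")
    R_mm = float(R_mm)
    if R_mm <= 0:
        raise ValueError(f"radius must be positive, got {R_mm}")
    return _INDEX_STEP[side] / (R_mm * 1e-3)


def mean_meridional_power(params: BiconicParams, side: str, *, rule: str = "mean_power") -> float:
    """Average power of a biconic surface in diopters.

    The default rule is the arithmetic mean of the two meridional powers;
    'mean_radius' (power of the mean radius) and 'geometric' (geometric mean
    of the powers) are retained as alternatives.
    """
    if rule == "mean_power":
        return 0.5 * (radius_to_power(params.Rx, side) + radius_to_power(params.Ry, side))
    if rule == "mean_radius":
        return radius_to_power(0.5 * (params.Rx + params.Ry), side)
    if rule == "geometric":
        px, py = radius_to_power(params.Rx, side), radius_to_power(params.Ry, side)
        return float(np.sign(px) * np.sqrt(px * py))
    raise ValueError(f"unknown averaging rule {rule!r}")


def myopic_shift(delta_AL_mm: float, total_power_dpt: float) -> float:
    """Myopic shift (dpt) induced by an axial-length change.

    D_total^2 x |dAL| with dAL in meters: at the model eye's 60 dpt a 36 um
    shortening gives 0.1296 ~ 0.13 dpt.
    """
    if total_power_dpt <= 0:
        raise ValueError("total power must be positive")
    return total_power_dpt**2 * abs(delta_AL_mm) * 1e-3


def effective_change(
    anterior_delta_dpt: float,
    posterior_delta_dpt: float,
    delta_AL_mm: float,
    total_power_dpt: float,
) -> float:
    """Effective refractive change of one scenario (dpt, unrounded).

    Anterior plus posterior surface-power change minus the myopic shift of
    the (magnitude of the) axial-length change.
    """
    return (anterior_delta_dpt + posterior_delta_dpt
            - myopic_shift(delta_AL_mm, total_power_dpt))


@dataclass(frozen=True)
class RefractionSummary:
    """Aggregated refractive outcome of one ring-segment scenario."""

    scenario: str
    anterior_delta_dpt: float
    posterior_delta_dpt: float
    delta_AL: float  # mm
    total_power: float  # dpt
    myopic_shift: float  # dpt
    effective_change: float  # dpt (unrounded)

    @classmethod
    def from_inputs(cls, scenario, anterior_delta_dpt, posterior_delta_dpt,
                    delta_AL_mm, total_power_dpt) -> "RefractionSummary":
        shift = myopic_shift(delta_AL_mm, total_power_dpt)
        eff = anterior_delta_dpt + posterior_delta_dpt - shift
        return cls(scenario, float(anterior_delta_dpt), float(posterior_delta_dpt),
                   float(delta_AL_mm), float(total_power_dpt), shift, eff)

    @property
    def effective_change_reported(self) -> float:
        """Effective change rounded to one decimal for reporting."""
        return float(np.round(self.effective_change, 1))


def build_summary_table(scenarios: dict) -> pd.DataFrame:
    """Biconic assessment table (one row per scenario and surface).

    ``scenarios`` maps scenario name -> dict with keys 'anterior' and
    'posterior', each holding {'pre': BiconicParams, 'post': BiconicParams},
    plus 'delta_AL' (mm) and 'cornea' ('healthy' or 'KC').  Columns follow
    the reference layout: Rx, Ry, dRx, dRy, dAL, Qx, Qy, ddpt; the
    per-surface ddpt is the mean-meridional-power change, and a separate
    'effective_dpt' column aggregates both surfaces and the axial term.
    """
    missing = []
    for name, s in scenarios.items():
        for key in ("anterior", "posterior", "delta_AL", "cornea"):
            if key not in s:
                missing.append(f"{name}:{key}")
    if missing:
        raise ValueError("incomplete scenario data: " + ", ".join(missing))

    rows = []
    for name, s in scenarios.items():
        D = total_power(s["cornea"])
        deltas = {}
        for side in ("anterior", "posterior"):
            pre, post = s[side]["pre"], s[side]["post"]
            deltas[side] = (mean_meridional_power(post, side)
                            - mean_meridional_power(pre, side))
            rows.append({
                "scenario": name, "side": side,
                "Rx": round(post.Rx, 2), "Ry": round(post.Ry, 2),
                "dRx": round(post.Rx - pre.Rx, 2),
                "dRy": round(post.Ry - pre.Ry, 2),
                "dAL": round(s["delta_AL"], 2) if side == "anterior" else np.nan,
                "Qx": round(post.Qx, 2), "Qy": round(post.Qy, 2),
                "ddpt": round(deltas[side], 2),
                "effective_dpt": np.nan,
            })
        eff = effective_change(deltas["anterior"], deltas["posterior"],
                               s["delta_AL"], D)
        rows[-2]["effective_dpt"] = round(eff, 1)  # on the anterior row
    return pd.DataFrame(rows)
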