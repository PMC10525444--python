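"""Reference data of the finite-element ICRS study this analysis builds on.

Two small tables are shipped as code so the downstream arithmetic has its
printed inputs available without any external files:

* the material table (Yeoh constants and thicknesses of the stromal layers,
  the regionally weakened keratoconic zones, the sclera, and the elastic
  constants of the PMMA ring segment), and
* the biconic curvature assessment of the six ring-segment designs in the
  generic healthy and keratoconic cornea (radii, asphericities, axial-length
  changes, and per-surface dioptric changes for the anterior and posterior
  surface).

All radii in mm, Yeoh constants in kPa, thicknesses in um, dAL in mm,
dioptric changes in dpt.  Missing entries (pre-op rows have no deltas) are
``None``.
"""

from __future__ import annotations

import pandas as pd

# --- material table ---------------------------------------------------------

#: Yeoh constants (kPa) and thickness (um) per tissue layer.
MATERIALS = {
    "healthy_anterior": {"C1": 35.5, "C2": 3.2, "C3": 1.9, "th": 385.0},
    "healthy_posterior": {"C1": 32.0, "C2": 2.9, "C3": 1.7, "th": 165.0},
    "kc_region1_anterior": {"C1": 24.9, "C2": 2.2, "C3": 1.3, "th": 270.0},
    "kc_region1_posterior": {"C1": 22.4, "C2": 2.0, "C3": 1.2, "th": 116.0},
    "kc_region2_anterior": {"C1": 10.7, "C2": 1.0, "C3": 0.57, "th": 193.0},
    "kc_region2_posterior": {"C1": 9.6, "C2": 0.86, "C3": 0.51, "th": 83.0},
    "sclera": {"C1": 800.0, "C2": 56100.0, "C3": 2332000.0, "th": 1000.0},
}

#: PMMA ring-segment elastic constants.
ICRS_MATERIAL = {"E_MPa": 3300.0, "nu": 0.40, "rho_kg_m3": 1062.0}

#: Stiffness multipliers of the two weakened keratoconic zones relative to
#: healthy tissue (region1 = 0.70x, region2 = 0.30x; verified against the
#: material table at <= 0.25 kPa on every Yeoh constant).
WEAKENING_FRACTIONS = {"region1": 0.70, "region2": 0.30}

#: Joint corneal thickness (um) and intraocular pressure (mmHg) of the model.
JOINT_THICKNESS_UM = 550.0
IOP_MMHG = 15.0
MMHG_TO_PA = 133.322

#: Assumed total ocular refractive power (cornea + lens) and the average
#: steepening induced by the keratoconus simulation.
TOTAL_POWER_HEALTHY_DPT = 60.0
KC_STEEPENING_DPT = 4.7

# --- biconic curvature assessment -------------------------------------------

_COLS = ("cornea", "scenario", "side", "Rx", "Ry", "dRx", "dRy", "dAL", "Qx", "Qy", "ddpt")

_ROWS = [
    # anterior block
    ("healthy", "pre", "anterior", 7.37, 7.62, None, None, None, -0.25, -0.10, None),
    ("healthy", "asym", "anterior", 8.05, 7.95, 0.68, 0.33, -0.04, 1.21, -2.07, -3.17),
    ("healthy", "sym", "anterior", 7.96, 8.14, 0.59, 0.52, -0.04, -0.13, -0.22, -3.44),
    ("healthy", "symMax", "anterior", 8.36, 8.35, 0.99, 0.73, -0.04, 0.98, -1.40, -5.14),
    ("healthy", "symMin", "anterior", 7.77, 7.87, 0.40, 0.25, -0.03, -0.18, -0.17, -2.09),
    ("healthy", "asymW", "anterior", 7.97, 8.14, 0.60, 0.52, -0.04, -0.15, -0.21, -3.47),
    ("healthy", "asymTH", "anterior", 7.96, 8.13, 0.59, 0.50, -0.04, 0.65, -0.94, -3.40),
    ("KC", "pre", "anterior", 6.15, 7.24, None, None, 0.11, -1.55, 1.33, None),
    ("KC", "asym", "anterior", 5.88, 7.72, -0.26, 0.48, -0.04, -3.83, 2.19, -0.89),
    ("KC", "sym", "anterior", 6.34, 7.61, 0.19, 0.36, -0.04, -2.17, 1.76, -2.23),
    ("KC", "symMax", "anterior", 6.89, 7.61, 0.75, 0.36, -0.05, -0.19, -0.18, -4.29),
    ("KC", "symMin", "anterior", 6.20, 6.61, 0.05, -0.63, -0.04, -1.76, -2.54, 2.52),
    ("KC", "asymW", "anterior", 6.44, 7.57, 0.29, 0.33, -0.04, -1.63, 1.53, -2.49),
    ("KC", "asymTH", "anterior", 6.44, 6.79, 0.30, -0.46, -0.04, -0.01, -3.77, 0.68),
    # posterior block
    ("healthy", "pre", "posterior", 7.91, 7.97, None, None, None, 0.63, 0.37, None),
    ("healthy", "asym", "posterior", 8.35, 8.70, 0.99, 1.08, None, 5.18, 7.85, 0.39),
    ("healthy", "sym", "posterior", 7.17, 7.40, -0.20, -0.22, None, -1.39, 1.03, -0.51),
    ("healthy", "symMax", "posterior", 8.74, 8.69, 1.37, 1.07, None, 8.16, 9.08, 0.50),
    ("healthy", "symMin", "posterior", 7.51, 7.45, 0.14, -0.17, None, -0.19, -0.20, -0.35),
    ("healthy", "asymW", "posterior", 7.18, 7.37, -0.19, -0.25, None, -1.48, 1.08, -0.52),
    ("healthy", "asymTH", "posterior", 7.10, 7.46, -0.26, -0.17, None, -1.53, 1.10, -0.52),
    ("KC", "pre", "posterior", 6.18, 6.81, None, None, None, -1.13, -1.02, None),
    ("KC", "asym", "posterior", 6.23, 7.55, 0.08, 0.31, None, 1.11, 7.05, 0.40),
    ("KC", "sym", "posterior", 6.34, 7.71, 0.19, 0.47, None, 0.66, 7.32, 0.52),
    ("KC", "symMax", "posterior", 6.54, 7.58, 0.40, 0.33, None, 2.88, 7.59, 0.56),
    ("KC", "symMin", "posterior", 5.86, 7.18, -0.28, -0.07, None, -2.37, 4.01, 0.03),
    ("KC", "asymW", "posterior", 6.48, 7.71, 0.34, 0.47, None, 1.42, 7.36, 0.59),
    ("KC", "asymTH", "posterior", 5.29, 6.35, -0.86, -0.89, None, -2.56, 2.42, -0.80),
]

SCENARIOS = ("asym", "sym", "symMax", "symMin", "asymW", "asymTH")


def biconic_assessment() -> pd.DataFrame:
    """The reference biconic curvature table as a DataFrame."""
    return pd.DataFrame.from_records(_ROWS, columns=_COLS)


def lookup(cornea: str, scenario: str, side: str) -> dict:
    """One row of the assessment table as a plain dict."""
    for row in _ROWS:
        if row[0] == cornea and row[1] == scenario and row[2] == side:
            return dict(zip(_COLS, row))
    raise KeyError(f"no reference row for ({cornea}, {scenario}, {side})")
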