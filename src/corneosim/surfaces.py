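"""Synthetic corneal surface generator.

Produces the surface samplings the analysis pipeline consumes, emulating the
outputs of a finite-element corneal model with three ingredients:

* healthy corneas as exact biconic surfaces,
* an asymmetric keratoconic cone: a Gaussian anterior protrusion over the
  inferior paracentral region (the clinically typical cone location), and
* a parametric emulation of ring-segment (ICRS) implantation: a smooth,
  compactly supported flattening of the optical zone plus a localized
  anterior lift along the ring track, with magnitude proportional to the
  local implant cross-section, and a smaller opposite-sign perturbation on
  the diametrically opposite corneal half.

Sag convention: z = 0 at the geometric apex of the pristine surface and
increases posteriorly.  An anterior protrusion (the cone, the tissue above
the ring) therefore *lowers* z; the "most elevated point" of a surface is
its sag minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BiconicParams, biconic_sag, disk_grid

__all__ = [
    "SurfaceSampling",
    "ConeSpec",
    "ICRSDesign",
    "DEFAULT_CONE",
    "DEFAULT_DESIGNS",
    "DEFAULT_ICRS_GAIN_UM_PER_MM2",
    "make_biconic_surface",
    "add_kc_cone",
    "apply_icrs_effect",
    "add_measurement_noise",
    "generate_scenario_surfaces",
    "write_fixture_set",
]

SIDES = ("anterior", "posterior")


@dataclass
class SurfaceSampling:
    """A labelled sampling of one corneal surface.

    ``x``, ``y`` are coordinates in mm perpendicular to the optical axis,
    ``z`` the sag in mm (posterior-positive, see module docstring).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    surface_side: str = "anterior"
    zone_diameter: float = 9.0
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("x, y, z must have equal length")
        if self.x.size < 3:
            raise ValueError("need at least 3 surface points")
        if self.surface_side not in SIDES:
            raise ValueError(f"surface_side must be one of {SIDES}")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.zone_diameter / 2 + 1e-9):
            raise ValueError("points outside the declared zone diameter")

    @property
    def n_points(self) -> int:
        return self.x.size

    def most_elevated_point(self) -> tuple[float, float]:
        """(x, y) of the most anterior point (sag minimum).

        Ties are broken by smallest radius, then smallest polar angle.
        """
        r = np.hypot(self.x, self.y)
        theta = np.mod(np.arctan2(self.y, self.x), 2 * np.pi)
        order = np.lexsort((theta, r, self.z))
        i = order[0]
        return float(self.x[i]), float(self.y[i])

    def copy(self, **updates) -> "SurfaceSampling":
        out = SurfaceSampling(
            self.x.copy(), self.y.copy(), self.z.copy(),
            surface_side=self.surface_side,
            zone_diameter=self.zone_diameter,
            label=self.label,
        )
        for k, v in updates.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class ConeSpec:
    """Keratoconic cone: geometry of the protrusion and the weakened zones.

    ``amplitude`` is the added anterior elevation (um) at the cone centre;
    ``width`` the Gaussian decay length (mm).  The weakening fractions are
    stiffness multipliers applied by the mechanics module: the core zone
    (radius ``core_radius`` around the centre) and the surrounding annulus
    (to ``outer_radius``).
    """

    center: tuple[float, float] = (0.0, -1.0)
    amplitude: float = 110.0
    width: float = 2.75
    inner_weaken_fraction: float = 0.30
    outer_weaken_fraction: float = 0.70
    core_radius: float = 1.5
    outer_radius: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_weaken_fraction <= self.outer_weaken_fraction <= 1):
            raise ValueError(
                "need 0 < inner_weaken_fraction <= outer_weaken_fraction <= 1"
            )
        if not self.core_radius < self.outer_radius:
            raise ValueError("core_radius must be smaller than outer_radius")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.width <= 0:
            raise ValueError("width must be positive")


DEFAULT_CONE = ConeSpec()


@dataclass(frozen=True)
class ICRSDesign:
    """One intracorneal ring-segment design.

    Thickness and base width (um) vary linearly along the arc from the
    ``start`` to the ``end`` values; ``orientation`` is the angular position
    (degrees, mathematical convention) of the thick end, the arc extending
    ``arc_length`` degrees clockwise from there.
    """

    name: str
    arc_length: float = 160.0
    start_thickness: float = 150.0
    end_thickness: float = 300.0
    start_width: float = 600.0
    end_width: float = 800.0
    optical_zone: float = 6.0
    orientation: float = -10.0
    material_E: float = 3300.0  # MPa
    material_nu: float = 0.4
    material_rho: float = 1062.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (0 < self.arc_length <= 360):
            raise ValueError("arc_length must be in (0, 360] degrees")
        for v in (self.start_thickness, self.end_thickness,
                  self.start_width, self.end_width):
            if v <= 0:
                raise ValueError("thickness and width profiles must be positive")
        if self.optical_zone <= 0:
            raise ValueError("optical_zone must be positive")

    def profile_at(self, frac: np.ndarray | float):
        """(thickness um, width um) at arc fraction 0 (thin end) .. 1 (thick end)."""
        frac = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)
        t = self.start_thickness + frac * (self.end_thickness - self.start_thickness)
        w = self.start_width + frac * (self.end_width - self.start_width)
        return t, w

    @property
    def mean_cross_section_mm2(self) -> float:
        """Arc-average of thickness x width in mm^2."""
        f = np.linspace(0.0, 1.0, 201)
        t, w = self.profile_at(f)
        return float(np.mean(t * w)) * 1e-6


#: The six designs compared in the study: the progressive asymmetric segment
#: (thickness 150->300 um, base width 600->800 um, arc 160 deg, optical zone
#: 6 mm), the average symmetric segment (225 x 700), the symmetric extremes
#: (symMax 300 x 800, symMin 150 x 600), and the two reduced asymmetric forms
#: varying only width (asymW) or only thickness (asymTH).
DEFAULT_DESIGNS: dict[str, ICRSDesign] = {
    "asym": ICRSDesign("asym"),
    "sym": ICRSDesign("sym", start_thickness=225, end_thickness=225,
                      start_width=700, end_width=700),
    "symMax": ICRSDesign("symMax", start_thickness=300, end_thickness=300,
                         start_width=800, end_width=800),
    "symMin": ICRSDesign("symMin", start_thickness=150, end_thickness=150,
                         start_width=600, end_width=600),
    "asymW": ICRSDesign("asymW", start_thickness=225, end_thickness=225,
                        start_width=600, end_width=800),
    "asymTH": ICRSDesign("asymTH", start_thickness=150, end_thickness=300,
                         start_width=700, end_width=700),
}


def make_biconic_surface(
    params: BiconicParams,
    zone_diameter: float = 9.0,
    grid_spacing: float = 0.1,
    *,
    surface_side: str = "anterior",
    label: str = "",
) -> SurfaceSampling:
    """Sample an exact biconic surface on a regular grid clipped to the zone disk.

    Raises :class:`~corneosim.geometry.BiconicDomainError` if the biconic
    radicand is non-positive anywhere in the zone.
    """
    x, y = disk_grid(zone_diameter, grid_spacing)
    z = biconic_sag(x, y, params, check=True)
    return SurfaceSampling(x, y, z, surface_side=surface_side,
                           zone_diameter=zone_diameter, label=label)


def add_kc_cone(surface: SurfaceSampling, cone: ConeSpec = DEFAULT_CONE) -> SurfaceSampling:
    """Add a keratoconic cone: a Gaussian anterior protrusion.

    The sag is lowered by ``amplitude * exp(-rho^2 / (2 width^2))`` where
    ``rho`` is the distance to the cone centre, so the added anterior
    elevation peaks at exactly ``amplitude`` um at the centre.
    """
    cx, cy = cone.center
    if np.hypot(cx, cy) > surface.zone_diameter / 2:
        raise ValueError("cone centre lies outside the surface zone")
    rho2 = (surface.x - cx) ** 2 + (surface.y - cy) ** 2
    bump_mm = (cone.amplitude * 1e-3) * np.exp(-rho2 / (2 * cone.width**2))
    out = surface.copy()
    out.z = surface.z - bump_mm
    out.label = (surface.label + " +cone").strip()
    return out


def _arc_window(rel_deg: np.ndarray, arc_length: float, shoulder: float) -> np.ndarray:
    """Angular window: exactly 1 on the arc [0, arc_length] (degrees of
    clockwise offset from the thick end), cos^2 shoulders *outside* the arc
    ends, exactly 0 beyond them.  Keeping the plateau over the full arc means
    the perturbation magnitude at each arc end reflects the local implant
    cross-section there."""
    w = np.zeros_like(rel_deg)
    w[rel_deg <= arc_length] = 1.0
    lead = (rel_deg > 360.0 - shoulder)  # just before the thick end
    w[lead] = np.cos(0.5 * np.pi * (360.0 - rel_deg[lead]) / shoulder) ** 2
    trail = (rel_deg > arc_length) & (rel_deg <= arc_length + shoulder)
    w[trail] = np.cos(0.5 * np.pi * (rel_deg[trail] - arc_length) / shoulder) ** 2
    return w


def _icrs_perturbation(
    x: np.ndarray,
    y: np.ndarray,
    design: ICRSDesign,
    gain_um_per_mm2: float,
    *,
    track_factor: float = 0.5,
    opposite_factor: float = 0.15,
    central_extent: float = 4.2,
    shoulder_deg: float = 15.0,
    components: tuple = ("central", "track", "opposite"),
) -> np.ndarray:
    """Sag change (mm) of the geometric ICRS emulation at the given points.

    Three smooth, compactly supported components (individually selectable
    for diagnostics via ``components``):

    * 'central': optical-zone flattening — a quartic posterior recession
      with apex magnitude gain x (mean cross-section) vanishing with zero
      slope at ``central_extent``; this drives the average (biconic)
      flattening and the axial-length reduction;
    * 'track': ring-track anterior lift of magnitude gain x track_factor x
      local thickness x width (linear along the arc), a radial cos^2 bump
      spanning exactly the local base width outward of the optical-zone
      radius;
    * 'opposite': a posterior bump of the same radial shape on the
      diametrically opposite arc, scaled by opposite_factor (the localized
      steepening seen on the half of the cornea away from the segment).
    """
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))
    r_in = design.optical_zone / 2.0
    shoulder = min(shoulder_deg, (360.0 - design.arc_length) / 2.0)

    # angular offset along the arc, 0 at the thick end increasing clockwise;
    # the thin end sits at rel = arc_length
    rel = np.mod(design.orientation - theta, 360.0)
    frac = 1.0 - rel / design.arc_length
    on_arc = _arc_window(rel, design.arc_length, shoulder)
    t_um, w_um = design.profile_at(frac)
    cross_mm2 = (t_um * 1e-3) * (w_um * 1e-3)

    dz = np.zeros_like(r)
    xbar = design.mean_cross_section_mm2

    if "central" in components:
        delta_mm = gain_um_per_mm2 * xbar * 1e-3
        central = np.clip(1.0 - (r / central_extent) ** 2, 0.0, None) ** 2
        dz = dz + delta_mm * central

    if "track" in components:
        w_mm = w_um * 1e-3
        rc = r_in + w_mm / 2.0
        track = np.zeros_like(r)
        in_track = np.abs(r - rc) <= w_mm / 2.0
        track[in_track] = np.cos(
            np.pi * (r[in_track] - rc[in_track]) / w_mm[in_track]
        ) ** 2
        dz = dz - (gain_um_per_mm2 * track_factor * cross_mm2 * 1e-3) * track * on_arc

    if "opposite" in components:
        rel_opp = np.mod(design.orientation + 180.0 - theta, 360.0)
        on_opp = _arc_window(rel_opp, design.arc_length, shoulder)
        w_bar = (design.start_width + design.end_width) / 2.0 * 1e-3
        rc_o = r_in + w_bar / 2.0
        track_o = np.zeros_like(r)
        in_o = np.abs(r - rc_o) <= w_bar / 2.0
        track_o[in_o] = np.cos(np.pi * (r[in_o] - rc_o) / w_bar) ** 2
        dz = dz + (gain_um_per_mm2 * opposite_factor * xbar * 1e-3) * track_o * on_opp

    return dz


#: Default emulation gain (um of apex recession per mm^2 of mean implant
#: cross-section), calibrated so the average symmetric design produces a mean
#: anterior flattening on the healthy cornea in the -3 to -4 dpt range.
DEFAULT_ICRS_GAIN_UM_PER_MM2 = 250.0


def apply_icrs_effect(
    surface: SurfaceSampling,
    design: ICRSDesign,
    gain: float = DEFAULT_ICRS_GAIN_UM_PER_MM2,
    **kwargs,
) -> SurfaceSampling:
    """Apply the geometric ICRS emulation to an anterior surface.

    ``gain`` is the emulation knob in um of flattening per mm^2 of implant
    cross-section; it is not a mechanical prediction.  Elevation outside the
    perturbation support is conserved to machine precision.
    """
    if surface.surface_side != "anterior":
        raise ValueError("ICRS effect is applied to the anterior surface")
    if gain < 0:
        raise ValueError("gain must be non-negative")
    dz = _icrs_perturbation(surface.x, surface.y, design, gain, **kwargs)
    out = surface.copy()
    out.z = surface.z + dz
    out.label = (surface.label + f" +ICRS:{design.name}").strip()
    return out


def add_measurement_noise(
    surface: SurfaceSampling, sigma_um: float, rng: np.random.Generator
) -> SurfaceSampling:
    """Add iid Gaussian elevation noise of the given standard deviation (um)."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be non-negative")
    out = surface.copy()
    if sigma_um > 0:
        out.z = surface.z + rng.normal(0.0, sigma_um * 1e-3, size=surface.z.shape)
    return out


def generate_scenario_surfaces(
    *,
    cone: ConeSpec = DEFAULT_CONE,
    designs: dict[str, ICRSDesign] | None = None,
    gain: float = DEFAULT_ICRS_GAIN_UM_PER_MM2,
    zone_diameter: float = 9.0,
    grid_spacing: float = 0.1,
    noise_sigma_um: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, str, str], SurfaceSampling]:
    """All study surfaces, keyed by (cornea, scenario, side).

    Corneas: 'healthy' (exact biconic with the reference pre-op parameters)
    and 'KC' (the healthy surface plus the cone; the posterior gets a
    half-amplitude cone).  Scenarios: 'pre' plus one per design; post-op
    anterior surfaces carry the full geometric ICRS emulation, posterior
    surfaces a quarter-gain copy (the posterior response of the reference
    model is much weaker than the anterior one).
    """
    from .fem_reference import lookup

    if designs is None:
        designs = DEFAULT_DESIGNS
    rng = np.random.default_rng(seed)
    pre: dict[tuple[str, str], SurfaceSampling] = {}
    for side in SIDES:
        row = lookup("healthy", "pre", side)
        params = BiconicParams(row["Rx"], row["Ry"], row["Qx"], row["Qy"])
        base = make_biconic_surface(params, zone_diameter, grid_spacing,
                                    surface_side=side, label=f"healthy pre {side}")
        pre[("healthy", side)] = base
        kc_cone = cone if side == "anterior" else ConeSpec(
            center=cone.center, amplitude=cone.amplitude * 0.5, width=cone.width,
            inner_weaken_fraction=cone.inner_weaken_fraction,
            outer_weaken_fraction=cone.outer_weaken_fraction,
            core_radius=cone.core_radius, outer_radius=cone.outer_radius)
        kc = add_kc_cone(base, kc_cone)
        kc.label = f"KC pre {side}"
        pre[("KC", side)] = kc

    out: dict[tuple[str, str, str], SurfaceSampling] = {}
    for cornea in ("healthy", "KC"):
        for side in SIDES:
            out[(cornea, "pre", side)] = pre[(cornea, side)]
        for name, design in designs.items():
            ant = apply_icrs_effect(pre[(cornea, "anterior")], design, gain)
            ant.label = f"{cornea} {name} anterior"
            post = pre[(cornea, "posterior")].copy()
            post.z = post.z + _icrs_perturbation(post.x, post.y, design, gain * 0.25)
            post.label = f"{cornea} {name} posterior"
            out[(cornea, name, "anterior")] = ant
            out[(cornea, name, "posterior")] = post
    if noise_sigma_um > 0:
        out = {k: add_measurement_noise(s, noise_sigma_um, rng)
               for k, s in out.items()}
    return out


def write_fixture_set(output_dir, seed: int, **kwargs) -> list[dict]:
    """Write the full deterministic scenario fixture set and its manifest.

    28 surface files (2 corneas x (1 pre + 6 post-op scenarios) x 2 sides)
    plus ``manifest.tsv`` listing scenario, cornea, side, file and the
    generation parameters.  Identical seeds yield byte-identical files.
    Returns the manifest entries.
    """
    from pathlib import Path

    from . import io as cio

    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    surfaces = generate_scenario_surfaces(seed=seed, **kwargs)
    gen_params = {"seed": seed}
    for k in ("gain", "noise_sigma_um", "zone_diameter", "grid_spacing"):
        if k in kwargs:
            gen_params[k] = kwargs[k]
    entries = []
    for (cornea, scenario, side), surf in sorted(surfaces.items()):
        fname = f"{cornea}_{scenario}_{side}.csv"
        cio.write_surface(surf, out_dir / fname)
        entries.append({"scenario": scenario, "cornea": cornea, "side": side,
                        "path": fname, "params": gen_params})
    import json

    lines = ["scenario\tcornea\tside\tpath\tparams"]
    for e in entries:
        lines.append("\t".join([e["scenario"], e["cornea"], e["side"], e["path"],
                                json.dumps(e["params"], sort_keys=True)]))
    (out_dir / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return entries
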