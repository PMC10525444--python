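# corneosim

Corneal optomechanics and ring-segment refraction analysis in Python.

Intracorneal ring segments (ICRS) are arc-shaped PMMA implants inserted
into the corneal stroma to flatten a keratoconic cornea and reduce its
irregular astigmatism. Comparing ring designs — symmetric rings against
progressive designs whose thickness and base width vary along the arc —
requires a chain of analyses that is usually spread across FEM software and
ad-hoc scripts: generate or load corneal surfaces, fit average curvature,
map local curvature, decompose optical aberrations, and convert geometry
changes into refractive changes. `corneosim` implements that chain as a
tested library with no external data dependencies.

## What is inside

* **Synthetic corneas** (`corneosim.surfaces`) — biconic surfaces
  `z(x,y) = (x²/Rx + y²/Ry) / (1 + √(1 − (1+Qx)x²/Rx² − (1+Qy)y²/Ry²))`,
  an asymmetric keratoconic cone (Gaussian anterior protrusion over the
  inferior paracentral zone), and a parametric, compactly supported
  emulation of ICRS-induced deformation for six ring designs
  (`asym`, `sym`, `symMax`, `symMin`, `asymW`, `asymTH`).
* **Membrane mechanics** (`corneosim.mechanics`) — a nonlinear
  membrane-inflation solver with incompressible Yeoh hyperelasticity
  `W = C1(I1−3) + C2(I1−3)² + C3(I1−3)³`, follower intraocular pressure,
  equatorial radial-sliding boundary, regional keratoconic weakening
  (0.30×/0.70× stiffness zones), and an inverse stress-free geometry solve.
* **Curvature analysis** (`corneosim.curvature`) — nonlinear least-squares
  biconic fits, clinical sagittal (axial) curvature maps in diopters with
  cone re-centring, difference maps, Kmax/Kmin extraction, and axial-length
  change ΔAL.
* **Aberrations** (`corneosim.aberrations`) — sixth-order orthonormal
  Zernike decomposition of elevation over a circular pupil with OSA/ANSI
  single indexing and clinical term names.
* **Refraction arithmetic** (`corneosim.refraction`) — surface power
  `(n1−n0)/R` (anterior 0.375/R, posterior −0.042/R), mean meridional
  power of a biconic, the myopic shift `D² · |ΔAL|` of an axial-length
  change, and the effective refractive change
  `Δant + Δpost − myopic_shift` per scenario.
* **Pipeline, I/O and CLI** (`corneosim.pipeline`, `corneosim.io`,
  `corneosim.cli`) — plain-text surface/map/mesh formats with metadata
  sidecars, a seeded end-to-end pipeline, and the `corneosim` command with
  `synth`, `inflate`, `analyze` and `compare` subcommands.

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/` (bulky surface and map files go to
`scratch/`).

## Worked example

```python
import corneosim as cs

# a healthy cornea: anterior radii 7.37/7.62 mm, prolate asphericity
pre = cs.make_biconic_surface(cs.BiconicParams(7.37, 7.62, -0.25, -0.10))

# implant the average symmetric ring (225 um x 700 um, 160 deg arc)
post = cs.apply_icrs_effect(pre, cs.DEFAULT_DESIGNS["sym"])

fit_pre = cs.fit_biconic(pre, 5.0)
fit_post = cs.fit_biconic(post, 5.0)
d_ant = (cs.mean_meridional_power(fit_post, "anterior")
         - cs.mean_meridional_power(fit_pre, "anterior"))
dal = cs.delta_axial_length(post, pre)
print(f"anterior change {d_ant:+.2f} dpt, dAL {dal:+.3f} mm")
print(f"myopic shift {cs.myopic_shift(dal, 60):.2f} dpt")
print(f"effective change {cs.effective_change(d_ant, 0.0, dal, 60):+.2f} dpt")
```

prints

```
anterior change -3.30 dpt, dAL -0.039 mm
myopic shift 0.14 dpt
effective change -3.44 dpt
```

— the ring flattens the central cornea by 3.3 dpt, recedes the apex by
39 µm (shortening the globe and adding a 0.14 dpt myopic counter-shift),
for a net refractive change of −3.4 dpt.

The same chain for all six designs on both corneas, including posterior
surfaces, curvature maps and Zernike change tables:

```sh
python analysis/03_scenario_pipeline.py
```

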