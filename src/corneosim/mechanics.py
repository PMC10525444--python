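"""Nonlinear membrane inflation with Yeoh hyperelasticity.

A simplified corneal mechanics model: the stroma is a single curved membrane
(no bending stiffness) of constant-strain triangles, loaded by intraocular
pressure acting as a follower load on the posterior face, with the rim
either fixed or sliding radially in its own plane (the equator boundary
condition).  The material is the incompressible isotropic Yeoh solid,

    W(I1) = C1 (I1 - 3) + C2 (I1 - 3)^2 + C3 (I1 - 3)^3,

with incompressibility enforced exactly through the plane-stress thickness
stretch (lambda_3 = 1/(lambda_1 lambda_2), det F = 1), so the volumetric
penalty parameter d never enters the discrete equations; it is carried for
completeness.  Regional keratoconic weakening scales C1..C3 per element.

The inverse stress-free problem (find the unloaded geometry that inflates
into a measured one) is solved by damped fixed-point (deflation) iteration.

Units at the interface: node coordinates in mm, thickness in um, pressure in
Pa, materials in Pa.  The z axis points posteriorly (sag convention of the
surface modules): inflation displaces the apex in -z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_reference import MATERIALS, MMHG_TO_PA
from .surfaces import ConeSpec, SurfaceSampling

__all__ = [
    "YeohMaterial",
    "MembraneMesh",
    "InflationResult",
    "NonConvergenceError",
    "yeoh_energy_and_stress",
    "inflate",
    "find_stress_free",
    "apply_weakening",
    "make_cap_mesh",
    "corneal_material",
    "surface_from_mesh",
    "MMHG_TO_PA",
]

_I1_TOL = 1e-9


@dataclass(frozen=True)
class YeohMaterial:
    """Yeoh constants in Pa; ``d`` is the (inverse) volumetric penalty
    parameter, immaterial under exact plane-stress incompressibility."""

    C1: float
    C2: float = 0.0
    C3: float = 0.0
    d: float = 1e-5

    def __post_init__(self) -> None:
        if self.C1 <= 0:
            raise ValueError("C1 must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")

    @property
    def initial_shear_modulus(self) -> float:
        """Small-strain shear modulus mu0 = 2 C1 (Pa)."""
        return 2.0 * self.C1

    def dW(self, I1):
        x = np.asarray(I1, dtype=float) - 3.0
        return self.C1 + 2.0 * self.C2 * x + 3.0 * self.C3 * x**2

    def W(self, I1):
        x = np.asarray(I1, dtype=float) - 3.0
        return self.C1 * x + self.C2 * x**2 + self.C3 * x**3


def corneal_material(kind: str = "healthy") -> YeohMaterial:
    """Thickness-weighted Yeoh constants of the merged stromal membrane.

    The anterior and posterior stromal layers of the reference material
    table are merged into one membrane with their thickness-weighted
    constants (the tunnel interface carries no load here).
    """
    ant = MATERIALS[f"{kind}_anterior"]
    post = MATERIALS[f"{kind}_posterior"]
    ta, tp = ant["th"], post["th"]
    merged = {
        c: (ant[c] * ta + post[c] * tp) / (ta + tp) * 1e3  # kPa -> Pa
        for c in ("C1", "C2", "C3")
    }
    return YeohMaterial(**merged)


def yeoh_energy_and_stress(I1: float, areal_stretch: float, material: YeohMaterial):
    """Energy density (Pa) and principal Cauchy stresses of a membrane state.

    The state is given by the first invariant I1 = l1^2 + l2^2 + l3^2 (with
    l3 = 1/(l1 l2) from incompressibility) and the areal stretch J = l1 l2.
    Plane stress (sigma_3 = 0) gives sigma_i = 2 W'(I1) (l_i^2 - l3^2).
    The stress is the exact derivative of the energy (finite-difference
    verified in the test suite).
    """
    I1 = float(I1)
    J = float(areal_stretch)
    if I1 < 3.0 - _I1_TOL:
        raise ValueError(f"non-physical stretch state: I1 = {I1} < 3")
    if J <= 0:
        raise ValueError("areal stretch must be positive")
    l3sq = 1.0 / J**2
    # l1^2, l2^2 are roots of s^2 - (I1 - l3^2) s + J^2 = 0
    s = I1 - l3sq
    disc = max(s**2 - 4.0 * J**2, 0.0)
    l1sq = 0.5 * (s + np.sqrt(disc))
    l2sq = 0.5 * (s - np.sqrt(disc))
    dW = material.dW(I1)
    sigma = (2.0 * dW * (l1sq - l3sq), 2.0 * dW * (l2sq - l3sq))
    return float(material.W(I1)), sigma


@dataclass
class MembraneMesh:
    """Triangulated membrane with per-element attributes.

    ``nodes`` (n, 3) in mm; ``triangles`` (m, 3) int, outward-oriented
    (area vectors point anteriorly, toward -z for a corneal cap);
    ``thickness_um`` and ``stiffness_scale`` per element; ``fixed_nodes``
    are clamped, ``sliding_nodes`` move only radially within their own
    horizontal plane (the equator ring condition).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    material: YeohMaterial
    thickness_um: np.ndarray
    stiffness_scale: np.ndarray = None
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sliding_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.thickness_um = np.broadcast_to(
            np.asarray(self.thickness_um, dtype=float), (self.n_elements,)
        ).copy()
        if self.stiffness_scale is None:
            self.stiffness_scale = np.ones(self.n_elements)
        self.stiffness_scale = np.broadcast_to(
            np.asarray(self.stiffness_scale, dtype=float), (self.n_elements,)
        ).copy()
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)
        self.sliding_nodes = np.asarray(self.sliding_nodes, dtype=int)
        if self.triangles.min(initial=0) < 0 or (
            self.triangles.max(initial=-1) >= len(self.nodes)
        ):
            raise ValueError("triangle indices out of range")
        if np.any(self.thickness_um <= 0):
            raise ValueError("thickness must be positive")
        if np.any((self.stiffness_scale <= 0) | (self.stiffness_scale > 1)):
            raise ValueError("stiffness_scale must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def with_nodes(self, nodes_mm: np.ndarray) -> "MembraneMesh":
        return MembraneMesh(
            np.asarray(nodes_mm, dtype=float).copy(), self.triangles.copy(),
            self.material, self.thickness_um.copy(), self.stiffness_scale.copy(),
            self.fixed_nodes.copy(), self.sliding_nodes.copy(),
        )


@dataclass
class InflationResult:
    """Equilibrium state of one inflation solve."""

    deformed_nodes: np.ndarray  # mm
    apex_axial_displacement: float  # um, anterior-positive
    residual_norm: float  # N (max nodal residual)
    iterations: int
    converged: bool
    residual_history: list = field(default_factory=list)


class NonConvergenceError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history or [])


class _Assembler:
    """Vectorised residual/Jacobian assembly in SI units (meters)."""

    def __init__(self, mesh: MembraneMesh):
        self.mesh = mesh
        self.X = mesh.nodes * 1e-3
        self.tris = mesh.triangles
        E1 = self.X[self.tris[:, 1]] - self.X[self.tris[:, 0]]
        E2 = self.X[self.tris[:, 2]] - self.X[self.tris[:, 0]]
        G11 = np.einsum("ij,ij->i", E1, E1)
        G12 = np.einsum("ij,ij->i", E1, E2)
        G22 = np.einsum("ij,ij->i", E2, E2)
        self.detG = G11 * G22 - G12**2
        if np.any(self.detG <= 0):
            raise ValueError("degenerate reference triangle")
        self.H11 = G22 / self.detG
        self.H12 = -G12 / self.detG
        self.H22 = G11 / self.detG
        self.A0 = 0.5 * np.sqrt(self.detG)
        self.t0 = mesh.thickness_um * 1e-6
        self.scale = mesh.stiffness_scale
        self.coefW = self.t0 * self.A0 * self.scale

        # reduced dof map: x = X + P q
        n = mesh.n_nodes
        fixed = set(mesh.fixed_nodes.tolist())
        sliding = set(mesh.sliding_nodes.tolist())
        cols, rows, vals = [], [], []
        nq = 0
        self.node_dof = {}
        for i in range(n):
            if i in fixed:
                continue
            if i in sliding:
                r = np.hypot(self.X[i, 0], self.X[i, 1])
                if r < 1e-12:
                    raise ValueError("sliding node on the axis has no radial direction")
                ux, uy = self.X[i, 0] / r, self.X[i, 1] / r
                rows += [3 * i, 3 * i + 1]
                cols += [nq, nq]
                vals += [ux, uy]
                nq += 1
            else:
                rows += [3 * i, 3 * i + 1, 3 * i + 2]
                cols += [nq, nq + 1, nq + 2]
                vals += [1.0, 1.0, 1.0]
                nq += 3
        self.P = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, nq))
        self.nq = nq
        self.A_mean = float(np.mean(self.A0))

        # global dof indices of the 9 local dofs per element, for assembly
        gdof = np.empty((mesh.n_elements, 9), dtype=int)
        for a in range(3):
            for c in range(3):
                gdof[:, 3 * a + c] = 3 * self.tris[:, a] + c
        self.gdof = gdof
        self.rows_K = np.repeat(gdof, 9, axis=1).ravel()
        self.cols_K = np.tile(gdof, (1, 9)).ravel()

    def positions(self, q: np.ndarray) -> np.ndarray:
        return (self.X.ravel() + self.P @ q).reshape(-1, 3)

    def element_state(self, x: np.ndarray):
        """Per-element (I1, areal stretch) at deformed positions x (m)."""
        d1 = x[self.tris[:, 1]] - x[self.tris[:, 0]]
        d2 = x[self.tris[:, 2]] - x[self.tris[:, 0]]
        g11 = np.einsum("ij,ij->i", d1, d1)
        g12 = np.einsum("ij,ij->i", d1, d2)
        g22 = np.einsum("ij,ij->i", d2, d2)
        detg = g11 * g22 - g12**2
        trC = self.H11 * g11 + 2 * self.H12 * g12 + self.H22 * g22
        detC = detg / self.detG
        I1 = trC + 1.0 / detC
        return I1, np.sqrt(detC)

    def _element_forces(self, x: np.ndarray, pressure: float) -> np.ndarray:
        """(m, 9) internal-minus-pressure force of each element's 3 nodes."""
        d1 = x[self.tris[:, 1]] - x[self.tris[:, 0]]
        d2 = x[self.tris[:, 2]] - x[self.tris[:, 0]]
        return self._forces_from_edges(d1, d2, pressure)

    def residual(self, q: np.ndarray, pressure: float) -> np.ndarray:
        x = self.positions(q)
        fe = self._element_forces(x, pressure)
        R = np.zeros(3 * self.mesh.n_nodes)
        np.add.at(R, self.gdof.ravel(), fe.ravel())
        return self.P.T @ R

    def jacobian(self, q: np.ndarray, pressure: float) -> sp.csr_matrix:
        x = self.positions(q)
        h = 1e-9  # m; central differences of the analytic element gradient
        cols = []
        for k in range(9):
            a, c = divmod(k, 3)
            fp = self._element_forces_local(x, a, c, +h, pressure)
            fm = self._element_forces_local(x, a, c, -h, pressure)
            cols.append((fp - fm) / (2 * h))
        Ke = np.stack(cols, axis=2)  # (m, 9, 9): dF_i/dx_k
        K = sp.coo_matrix(
            (Ke.ravel(), (self.rows_K, self.cols_K)),
            shape=(3 * self.mesh.n_nodes,) * 2,
        ).tocsr()
        return (self.P.T @ K @ self.P).tocsr()

    def _element_forces_local(self, x, a, c, h, pressure):
        """Element forces with local dof (node slot a, component c) perturbed
        element-wise (not globally), yielding true element stiffness columns."""
        t = self.tris
        d1 = x[t[:, 1]] - x[t[:, 0]]
        d2 = x[t[:, 2]] - x[t[:, 0]]
        if a == 0:
            d1 = d1.copy(); d2 = d2.copy()
            d1[:, c] -= h
            d2[:, c] -= h
        elif a == 1:
            d1 = d1.copy()
            d1[:, c] += h
        else:
            d2 = d2.copy()
            d2[:, c] += h
        return self._forces_from_edges(d1, d2, pressure)

    def _forces_from_edges(self, d1, d2, pressure, ref=None):
        """Element nodal forces from deformed edges; ``ref`` optionally
        overrides the precomputed reference quantities (H, detG, coefW)."""
        H11, H12, H22, detG, coefW = (
            (self.H11, self.H12, self.H22, self.detG, self.coefW)
            if ref is None else ref
        )
        g11 = np.einsum("ij,ij->i", d1, d1)
        g12 = np.einsum("ij,ij->i", d1, d2)
        g22 = np.einsum("ij,ij->i", d2, d2)
        detg = g11 * g22 - g12**2
        I1 = H11 * g11 + 2 * H12 * g12 + H22 * g22 + detG / detg
        dW = self.mesh.material.dW(I1) * coefW
        qq = detG / detg**2
        dI_dg11 = H11 - qq * g22
        dI_dg22 = H22 - qq * g11
        dI_dg12 = 2.0 * H12 + 2.0 * qq * g12
        f1 = ((2 * dI_dg11)[:, None] * d1 + dI_dg12[:, None] * d2) * dW[:, None]
        f2 = ((2 * dI_dg22)[:, None] * d2 + dI_dg12[:, None] * d1) * dW[:, None]
        f0 = -(f1 + f2)
        out = np.concatenate([f0, f1, f2], axis=1)
        if pressure != 0.0:
            S = 0.5 * np.cross(d1, d2)
            fp = (pressure / 3.0) * S
            out -= np.concatenate([fp, fp, fp], axis=1)
        return out

    def _ref_quantities(self, X):
        """Reference metric quantities (H, detG, coefW) for geometry X (m)."""
        E1 = X[self.tris[:, 1]] - X[self.tris[:, 0]]
        E2 = X[self.tris[:, 2]] - X[self.tris[:, 0]]
        G11 = np.einsum("ij,ij->i", E1, E1)
        G12 = np.einsum("ij,ij->i", E1, E2)
        G22 = np.einsum("ij,ij->i", E2, E2)
        detG = G11 * G22 - G12**2
        A0 = 0.5 * np.sqrt(detG)
        coefW = self.t0 * A0 * self.scale
        return (G22 / detG, -G12 / detG, G11 / detG, detG, coefW)

    def jacobian_ref(self, q: np.ndarray, pressure: float) -> sp.csr_matrix:
        """d(residual)/d(reference coordinates) at fixed deformed positions.

        Element-local central differences over the reference coordinate
        slots; the pressure load depends only on the deformed geometry, so
        only the internal force contributes.
        """
        x = self.positions(q)
        d1 = x[self.tris[:, 1]] - x[self.tris[:, 0]]
        d2 = x[self.tris[:, 2]] - x[self.tris[:, 0]]
        h = 1e-9
        cols = []
        for k in range(9):
            a, c = divmod(k, 3)
            out = []
            for sgn in (+h, -h):
                Xp = self.X.copy()
                E1 = Xp[self.tris[:, 1]] - Xp[self.tris[:, 0]]
                E2 = Xp[self.tris[:, 2]] - Xp[self.tris[:, 0]]
                if a == 0:
                    E1 = E1.copy(); E2 = E2.copy()
                    E1[:, c] -= sgn
                    E2[:, c] -= sgn
                elif a == 1:
                    E1 = E1.copy()
                    E1[:, c] += sgn
                else:
                    E2 = E2.copy()
                    E2[:, c] += sgn
                G11 = np.einsum("ij,ij->i", E1, E1)
                G12 = np.einsum("ij,ij->i", E1, E2)
                G22 = np.einsum("ij,ij->i", E2, E2)
                detG = G11 * G22 - G12**2
                A0 = 0.5 * np.sqrt(detG)
                ref = (G22 / detG, -G12 / detG, G11 / detG, detG,
                       self.t0 * A0 * self.scale)
                out.append(self._forces_from_edges(d1, d2, 0.0, ref=ref))
            cols.append((out[0] - out[1]) / (2 * h))
        Ke = np.stack(cols, axis=2)
        K = sp.coo_matrix(
            (Ke.ravel(), (self.rows_K, self.cols_K)),
            shape=(3 * self.mesh.n_nodes,) * 2,
        ).tocsr()
        return (self.P.T @ K @ self.P).tocsr()


def inflate(
    mesh: MembraneMesh,
    pressure: float,
    *,
    x0: np.ndarray | None = None,
    tol_factor: float = 1e-8,
    max_iter: int = 60,
    n_load_steps: int | None = None,
) -> InflationResult:
    """Static equilibrium of the membrane under follower pressure (Pa).

    Newton iteration with backtracking line search and incremental load
    ramping; converges on both the residual norm (max nodal residual below
    ``tol_factor`` x pressure x mean element area, with an absolute floor)
    and the step norm.  Raises :class:`NonConvergenceError` with the
    residual history if Newton diverges.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    asm = _Assembler(mesh)
    q = np.zeros(asm.nq)
    if x0 is not None:
        # project an initial deformed guess onto the reduced dofs
        dx = (np.asarray(x0, dtype=float) * 1e-3 - asm.X).ravel()
        q = asm.P.T @ dx
    history: list[float] = []
    tol = max(tol_factor * max(pressure, 1.0) * asm.A_mean, 1e-16)

    if pressure == 0.0 and x0 is None:
        r0 = float(np.max(np.abs(asm.residual(q, 0.0)))) if asm.nq else 0.0
        return InflationResult(mesh.nodes.copy(), 0.0, r0, 1, True, [r0])

    eye = sp.identity(asm.nq, format="csr")
    counters = {"newton": 0}

    def newton_solve(q_in, p, record):
        """Newton with line search at fixed pressure; returns q or None."""
        q = q_in.copy()
        for _ in range(max_iter):
            R = asm.residual(q, p)
            rnorm = float(np.max(np.abs(R))) if R.size else 0.0
            if record:
                history.append(rnorm)
            if rnorm <= tol:
                return q
            K = asm.jacobian(q, p)

            def try_step(mat):
                try:
                    dq = spla.spsolve(mat, -R)
                except RuntimeError:
                    return None
                if not np.all(np.isfinite(dq)):
                    return None
                alpha = 1.0
                for _ in range(12):
                    rn = float(np.max(np.abs(asm.residual(q + alpha * dq, p))))
                    if rn < rnorm:
                        return alpha * dq
                    alpha *= 0.5
                return None

            step = try_step(K)
            if step is None:
                # indefinite or near-singular tangent (local membrane
                # compression): Levenberg-style regularisation
                lam = abs(K.diagonal()).mean() * 1e-8 + 1e-30
                for _ in range(12):
                    step = try_step(K + lam * eye)
                    if step is not None:
                        break
                    lam *= 30.0
            if step is None:
                if rnorm <= 1e3 * tol:
                    # roundoff floor of the assembled residual; equilibrium
                    # is resolved to machine precision
                    return q
                return None
            q = q + step
            counters["newton"] += 1
            if np.max(np.abs(step)) < 1e-15:
                return q
        return None

    # adaptive incremental loading: bisect the load step on failure,
    # restarting from the last converged state
    if x0 is not None:
        dp0 = pressure  # a good warm start usually needs no ramping
    else:
        dp0 = pressure / max(1, int(np.ceil(pressure / 600.0)))
    if n_load_steps is not None:
        dp0 = pressure / n_load_steps
    p_cur, dp = 0.0, dp0
    bisections = 0
    while p_cur < pressure - 1e-12:
        p_try = min(p_cur + dp, pressure)
        q_new = newton_solve(q, p_try, record=(p_try >= pressure - 1e-12))
        if q_new is None:
            bisections += 1
            dp *= 0.5
            if bisections > 20:
                raise NonConvergenceError(
                    f"Newton failed to converge even with load substepping "
                    f"(stalled at p = {p_cur:.1f} Pa of {pressure:.1f} Pa)",
                    history)
            continue
        q = q_new
        p_cur = p_try
        dp = min(dp * 2.0, dp0)
    total_iters = counters["newton"]

    x = asm.positions(q)
    R = asm.residual(q, pressure)
    rnorm = float(np.max(np.abs(R))) if R.size else 0.0
    history.append(rnorm)
    nodes_mm = x * 1e3
    apex = int(np.argmin(np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])))
    # anterior-positive: the cap bulges toward -z when inflated
    apex_disp_um = float(-(nodes_mm[apex, 2] - mesh.nodes[apex, 2]) * 1e3)
    return InflationResult(nodes_mm, apex_disp_um, rnorm,
                           max(total_iters, 1), rnorm <= tol, history)


def membrane_stress(mesh: MembraneMesh, deformed_nodes_mm: np.ndarray):
    """Principal Cauchy stresses (Pa) per element at a deformed state."""
    asm = _Assembler(mesh)
    I1, J = asm.element_state(np.asarray(deformed_nodes_mm, dtype=float) * 1e-3)
    s1 = np.empty_like(I1)
    s2 = np.empty_like(I1)
    for e in range(len(I1)):
        mat = YeohMaterial(
            mesh.material.C1 * mesh.stiffness_scale[e],
            mesh.material.C2 * mesh.stiffness_scale[e],
            mesh.material.C3 * mesh.stiffness_scale[e],
            mesh.material.d,
        )
        _, (a, b) = yeoh_energy_and_stress(max(I1[e], 3.0), J[e], mat)
        s1[e], s2[e] = a, b
    return s1, s2


def find_stress_free(
    target_nodes: np.ndarray,
    mesh: MembraneMesh,
    pressure: float,
    *,
    tol_um: float = 0.1,
    damping: float = 0.5,
    max_iter: int = 100,
) -> MembraneMesh:
    """Unloaded geometry whose inflation reproduces ``target_nodes`` (mm).

    Deflation iteration on the shape mismatch, accelerated with the exact
    mismatch sensitivity (implicit-function-theorem Newton step with a
    Levenberg blend seeded by ``damping`` and a backtracking line search).
    Converges when inflating the returned mesh reproduces the target to
    ``tol_um`` at every node; raises :class:`NonConvergenceError` with the
    mismatch history when no descent direction exists — for a soft membrane
    this happens at loads where the target state has no stable unloaded
    configuration (the rest shape required crosses the ballooning limit
    point), so the failure report is meaningful output, not just a
    numerical breakdown.
    """
    target = np.asarray(target_nodes, dtype=float)
    if pressure == 0.0:
        return mesh.with_nodes(target)
    guess = mesh.with_nodes(target)
    res = inflate(guess, pressure)
    errs: list[float] = []
    lam = 0.0  # Levenberg blend toward the plain deflation direction

    for _ in range(max_iter):
        err = res.deformed_nodes - target  # mm
        err_um = float(np.max(np.linalg.norm(err, axis=1))) * 1e3
        err_2 = float(np.linalg.norm(err))
        errs.append(err_um)
        if err_um <= tol_um:
            guess.iterations = len(errs)  # type: ignore[attr-defined]
            return guess

        # Newton step on the shape mismatch via the exact sensitivity
        # dx/dX = -K^{-1} K_X (implicit function theorem); the classic
        # damped deflation update is the K_X = -K approximation of this
        # step.  The plain iteration is non-contractive for membranes
        # (their curvature sensitivity is large), so the exact step with a
        # Levenberg blend and a line search on the mismatch norm is used.
        asm = _Assembler(guess)
        q = asm.P.T @ ((res.deformed_nodes - guess.nodes) * 1e-3).ravel()
        K = asm.jacobian(q, pressure)
        KX = asm.jacobian_ref(q, pressure)
        rhs = K @ (asm.P.T @ (err * 1e-3).ravel())
        improved = False
        for _ in range(6):
            step_full = None
            try:
                A = (KX - lam * K).tocsr() if lam > 0 else KX
                dxi = spla.spsolve(A, rhs)
                if np.all(np.isfinite(dxi)):
                    step_full = (asm.P @ dxi).reshape(-1, 3) * 1e3  # mm
            except RuntimeError:
                step_full = None
            if step_full is not None:
                for alpha in (1.0, 0.7, 0.4, 0.2, 0.1, 0.05):
                    try:
                        trial = guess.with_nodes(guess.nodes + alpha * step_full)
                        res_t = inflate(trial, pressure, x0=res.deformed_nodes)
                    except NonConvergenceError:
                        continue
                    if np.linalg.norm(res_t.deformed_nodes - target) < err_2 * (1 - 1e-4):
                        guess, res = trial, res_t
                        improved = True
                        lam = lam / 5 if lam > 1e-4 else 0.0
                        break
            if improved:
                break
            lam = damping * 0.02 if lam == 0 else lam * 10
            if lam > 1e3:
                break
        if not improved:
            raise NonConvergenceError(
                f"stress-free iteration stalled at {err_um:.3f} um after "
                f"{len(errs)} iterations (no descent direction; the target "
                "state may have no stable unloaded configuration at this "
                "pressure)", errs)
    raise NonConvergenceError(
        f"stress-free iteration did not reach {tol_um} um in {max_iter} "
        f"iterations (last error {errs[-1]:.3f} um)", errs)


def apply_weakening(mesh: MembraneMesh, cone: ConeSpec) -> MembraneMesh:
    """Keratoconic weakening: scale element stiffness inside the cone zones.

    Elements whose centroid lies within ``core_radius`` of the cone centre
    get ``inner_weaken_fraction``; the annulus to ``outer_radius`` gets
    ``outer_weaken_fraction``; thickness is untouched.
    """
    cx, cy = cone.center
    cen = mesh.nodes[mesh.triangles].mean(axis=1)
    rho = np.hypot(cen[:, 0] - cx, cen[:, 1] - cy)
    extent = np.max(np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1]))
    if np.hypot(cx, cy) + cone.outer_radius > extent + 1e-9:
        raise ValueError("weakening zones extend beyond the mesh")
    scale = np.ones(mesh.n_elements)
    scale[rho <= cone.outer_radius] = cone.outer_weaken_fraction
    scale[rho <= cone.core_radius] = cone.inner_weaken_fraction
    out = mesh.with_nodes(mesh.nodes)
    out.stiffness_scale = scale
    return out


def make_cap_mesh(
    radius: float = 7.5,
    cap_diameter: float = 11.0,
    n_rings: int = 12,
    n_sectors: int = 24,
    *,
    thickness_um: float = 550.0,
    material: YeohMaterial | None = None,
    boundary: str = "radial",
) -> MembraneMesh:
    """Spherical-cap membrane mesh in sag convention (apex at origin, +z
    posterior), rim at ``cap_diameter``; ``boundary`` 'radial' (equatorial
    sliding) or 'fixed'."""
    if boundary not in ("radial", "fixed"):
        raise ValueError("boundary must be 'radial' or 'fixed'")
    if material is None:
        material = corneal_material("healthy")
    rim_r = cap_diameter / 2.0
    if rim_r > radius:
        raise ValueError("cap diameter exceeds the sphere diameter")
    phi_max = np.arcsin(rim_r / radius)
    nodes = [(0.0, 0.0, 0.0)]
    rings: list[list[int]] = []
    for i in range(1, n_rings + 1):
        phi = phi_max * i / n_rings
        r = radius * np.sin(phi)
        z = radius * (1 - np.cos(phi))
        ring = []
        for j in range(n_sectors):
            th = 2 * np.pi * j / n_sectors
            ring.append(len(nodes))
            nodes.append((r * np.cos(th), r * np.sin(th), z))
        rings.append(ring)
    tris = []
    for j in range(n_sectors):
        jn = (j + 1) % n_sectors
        tris.append((0, rings[0][jn], rings[0][j]))
    for i in range(len(rings) - 1):
        a, b = rings[i], rings[i + 1]
        for j in range(n_sectors):
            jn = (j + 1) % n_sectors
            tris.append((a[j], b[jn], b[j]))
            tris.append((a[j], a[jn], b[jn]))
    nodes = np.array(nodes)
    tris = np.array(tris, dtype=int)
    # orient area vectors anteriorly (-z): outward for a cap opening to +z
    d1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    d2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    flip = np.cross(d1, d2)[:, 2] > 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    rim = np.array(rings[-1], dtype=int)
    if boundary == "fixed":
        return MembraneMesh(nodes, tris, material, thickness_um,
                            fixed_nodes=rim)
    return MembraneMesh(nodes, tris, material, thickness_um,
                        sliding_nodes=rim)


def surface_from_mesh(nodes_mm: np.ndarray, *, surface_side: str = "anterior",
                      label: str = "") -> SurfaceSampling:
    """Wrap deformed membrane nodes as a scattered surface sampling.

    The mesh z coordinate is already the sag; downstream curvature analysis
    interpolates scattered points, so no gridding is needed.
    """
    nodes = np.asarray(nodes_mm, dtype=float)
    r = np.hypot(nodes[:, 0], nodes[:, 1])
    zone = 2 * float(r.max()) + 1e-6
    return SurfaceSampling(nodes[:, 0], nodes[:, 1], nodes[:, 2] - nodes[:, 2].min(),
                           surface_side=surface_side, zone_diameter=zone,
                           label=label)
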