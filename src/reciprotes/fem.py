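"""Complete-electrode-model finite-element forward solver.

The forward problem is the quasi-static Poisson equation ∇·(σ∇ψ) = 0 in the
head with complete-electrode-model (CEM) boundary conditions: electrodes of
finite contact area E_l with contact impedance per unit area z_l, measured
potentials V_l and injected currents I_l, and an insulating boundary
elsewhere.  First-order Galerkin discretization yields a symmetric
(N+L)×(N+L) system K v = f whose blocks are

* the volume stiffness  ∫ σ ∇φ_i·∇φ_j,
* facet mass terms (1/z_l) ∫_{E_l} φ_i φ_j coupling boundary nodes,
* couplings −(1/z_l) ∫_{E_l} φ_i between nodes and electrode unknowns,
* electrode diagonals (1/z_l)|E_l|,

all surface integrals evaluated in closed form on linear triangles.  K is
singular with a one-dimensional constant nullspace; uniqueness comes from
the grounding contract of zero-mean electrode potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import ElectrodeMontage, TetMesh

__all__ = [
    "StiffnessSystem",
    "FieldSolution",
    "assemble_cem_system",
    "solve_system",
    "element_fields",
    "electrode_rhs",
    "electrode_flux",
    "shape_gradients",
]

DEFAULT_TOL = 1e-11


@dataclass
class StiffnessSystem:
    """Assembled CEM system with its grounding contract.

    ``matrix`` is the symmetric (N+L)×(N+L) sparse matrix; the grounding
    contract is zero-mean electrode potentials (the constant vector spans
    the nullspace before grounding).  A sparse LU factorization of the
    one-node-grounded reduction is cached after the first solve so repeated
    right-hand sides (transfer-matrix builds) cost only triangular solves.
    """

    matrix: sp.csr_matrix
    mesh: TetMesh
    montage: ElectrodeMontage
    grounding: str = "zero-mean electrode potentials"
    _lu: object = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_electrodes(self) -> int:
        return self.montage.n_electrodes

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FieldSolution:
    """Potentials and derived per-element fields of one forward solve."""

    node_potentials: np.ndarray  # (N,) V
    electrode_potentials: np.ndarray  # (L,) V, zero mean
    E: np.ndarray  # (T, 3) V/m
    J: np.ndarray  # (T, 3) A/m²
    relative_residual: float
    iterations: int
    method: str

    @property
    def potentials(self) -> np.ndarray:
        return np.concatenate([self.node_potentials, self.electrode_potentials])


def shape_gradients(mesh: TetMesh) -> np.ndarray:
    """Constant gradients of the 4 linear shape functions per tet, (T,4,3)."""
    cached = getattr(mesh, "_shape_gradients", None)
    if cached is not None:
        return cached
    p = mesh.nodes[mesh.tets]
    e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
    einv = np.linalg.inv(e)  # (T,3,3); rows of einv^T are ∇λ_1..3
    g123 = np.transpose(einv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    g = np.concatenate([g0, g123], axis=1)
    mesh._shape_gradients = g
    return g


def _conductivity_per_element(mesh: TetMesh, cond: dict) -> np.ndarray:
    missing = sorted(set(mesh.tissue.tolist()) - set(cond))
    if missing:
        raise KeyError(f"no conductivity for tissue label(s) {missing}")
    bad = [k for k, v in cond.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive conductivity for {bad}")
    lut = {k: float(v) for k, v in cond.items()}
    return np.array([lut[t] for t in mesh.tissue])


def assemble_cem_system(
    mesh: TetMesh, cond: dict, montage: ElectrodeMontage
) -> StiffnessSystem:
    """Assemble the symmetric (N+L)×(N+L) CEM stiffness system."""
    if np.any(montage.z_contact <= 0):
        raise ValueError("contact impedances must be positive")
    sigma = _conductivity_per_element(mesh, cond)
    N, L = mesh.n_nodes, montage.n_electrodes
    g = shape_gradients(mesh)
    vol = np.abs(mesh.element_volumes)

    # volume stiffness: K_ij = σ V ∇φ_i·∇φ_j, 16 entries per tet
    kloc = np.einsum("t,tia,tja->tij", sigma * vol, g, g)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    data = [kloc.ravel()]
    rr = [rows]
    cc = [cols]

    # CEM surface terms per electrode
    for l in range(L):
        z = montage.z_contact[l]
        fac = mesh.boundary_facets[montage.facet_indices[l]]
        area = mesh.facet_areas(fac)
        # node-node facet mass, ∫ φ_i φ_j = (A/12)(1+δij)
        mloc = (area[:, None, None] / 12.0) * (np.ones((3, 3)) + np.eye(3))
        rr.append(np.repeat(fac, 3, axis=1).ravel())
        cc.append(np.tile(fac, (1, 3)).ravel())
        data.append(mloc.ravel() / z)
        # node-electrode coupling, −(1/z)∫ φ_i = −A/3 per facet node
        cpl = -np.repeat(area / 3.0, 3) / z
        frows = fac.ravel()
        rr.append(frows)
        cc.append(np.full(frows.shape, N + l, dtype=np.int64))
        data.append(cpl)
        rr.append(np.full(frows.shape, N + l, dtype=np.int64))
        cc.append(frows)
        data.append(cpl)
        # electrode diagonal, (1/z)|E_l|
        rr.append(np.array([N + l]))
        cc.append(np.array([N + l]))
        data.append(np.array([area.sum() / z]))

    K = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rr), np.concatenate(cc))),
        shape=(N + L, N + L),
    ).tocsr()
    return StiffnessSystem(matrix=K, mesh=mesh, montage=montage)


def electrode_rhs(system: StiffnessSystem, currents: np.ndarray) -> np.ndarray:
    """Right-hand side for scalp injection: f_l = I_l on electrode unknowns."""
    currents = np.asarray(currents, dtype=float)
    if currents.shape != (system.n_electrodes,):
        raise ValueError("currents must have one entry per electrode")
    f = np.zeros(system.size)
    f[system.n_nodes :] = currents
    return f


def _grounded_lu(system: StiffnessSystem):
    if system._lu is None:
        K = system.matrix.tocsc()
        n = system.size
        keep = np.arange(1, n)  # ground node 0, restore by nullspace shift
        system._lu = spla.splu(K[keep][:, keep])
    return system._lu


def _direct_solve(system: StiffnessSystem, f: np.ndarray, tol: float):
    """LU solve of the one-node-grounded reduction plus iterative refinement,
    then shift onto the zero-mean-electrode-potential gauge."""
    K = system.matrix
    lu = _grounded_lu(system)
    v = np.zeros_like(f)
    fnorm = np.linalg.norm(f)
    res = 1.0
    for it in range(1, 6):
        r = f - K @ v
        dv = np.zeros_like(f)
        dv[1:] = lu.solve(r[1:])
        v = v + dv
        res = np.linalg.norm(f - K @ v) / fnorm
        if res <= tol:
            break
    return v, res, it


def _ildlt_preconditioner(system: StiffnessSystem, drop_tol: float, fill_factor: float):
    """Symmetric incomplete LDLᵀ preconditioner built from an incomplete LU.

    With natural ordering and no pivoting on a symmetric matrix the
    incomplete factors satisfy K ≈ Uᵀ D⁻¹ U (D = diag U), so
    M⁻¹ = U⁻¹ D U⁻ᵀ is symmetric positive definite as CG requires.
    """
    cached = getattr(system, "_ildlt", None)
    if cached is not None:
        return cached
    ilu = spla.spilu(
        system.matrix.tocsc(),
        drop_tol=drop_tol,
        fill_factor=fill_factor,
        permc_spec="NATURAL",
        diag_pivot_thresh=0.0,
        options=dict(SymmetricMode=True),
    )
    U = ilu.U.tocsr()
    D = U.diagonal()
    Ut = U.T.tocsr()

    def minv(x):
        y = spla.spsolve_triangular(Ut, x, lower=True)
        return spla.spsolve_triangular(U, D * y, lower=False)

    system._ildlt = minv
    return minv


def _cg_solve(
    system: StiffnessSystem,
    f: np.ndarray,
    tol: float,
    maxiter: int,
    drop_tol: float = 1e-4,
    fill_factor: float = 15.0,
):
    """Preconditioned CG on the singular consistent system.

    K maps into the orthogonal complement of the constant vector, so with a
    zero initial guess the iterates never pick up a nullspace component; the
    gauge is fixed afterwards.
    """
    K = system.matrix
    minv = _ildlt_preconditioner(system, drop_tol, fill_factor)
    fnorm = np.linalg.norm(f)
    x = np.zeros_like(f)
    r = f.copy()
    z = minv(r)
    p = z.copy()
    rz = r @ z
    for it in range(1, maxiter + 1):
        Kp = K @ p
        x += (alpha := rz / (p @ Kp)) * p
        r -= alpha * Kp
        if np.linalg.norm(r) <= tol * fnorm:
            break
        z = minv(r)
        rz, rz_old = r @ z, rz
        p = z + (rz / rz_old) * p
    res = np.linalg.norm(f - K @ x) / fnorm
    if res > tol:
        raise RuntimeError(
            f"CG did not converge in {maxiter} iterations (residual {res:.3e})"
        )
    return x, res, it


def solve_system(
    system: StiffnessSystem,
    rhs: np.ndarray,
    cond: dict,
    tol: float = DEFAULT_TOL,
    method: str = "direct",
    maxiter: int = 5000,
) -> FieldSolution:
    """Solve K v = f under the zero-mean electrode-potential grounding.

    The right-hand side must be compatible (entries summing to zero —
    current conservation).  ``method`` is ``"direct"`` (cached sparse LU with
    iterative refinement, the default) or ``"cg"`` (ILU-preconditioned
    conjugate gradients); both report the true relative residual of the full
    singular system and must agree to ~1e-9.
    """
    f = np.asarray(rhs, dtype=float)
    if f.shape != (system.size,):
        raise ValueError(f"rhs must have length {system.size}")
    scale = np.abs(f).sum()
    if scale == 0.0:
        zeros = np.zeros(system.size)
        return _finalize(system, zeros, cond, 0.0, 0, method)
    if abs(f.sum()) > 1e-10 * scale:
        raise ValueError(
            f"incompatible rhs: entries sum to {f.sum():.3e} (current must be conserved)"
        )
    if method == "direct":
        v, res, its = _direct_solve(system, f, tol)
    elif method == "cg":
        v, res, its = _cg_solve(system, f, tol, maxiter)
    else:
        raise ValueError(f"unknown method {method!r}")
    if res > tol:
        raise RuntimeError(f"solver stalled at relative residual {res:.3e} > {tol:g}")
    return _finalize(system, v, cond, res, its, method)


def _finalize(system, v, cond, res, its, method) -> FieldSolution:
    N = system.n_nodes
    v = v - v[N:].mean()  # grounding gauge: zero-mean electrode potentials
    E, J = element_fields(system.mesh, v[:N], cond)
    return FieldSolution(
        node_potentials=v[:N],
        electrode_potentials=v[N:],
        E=E,
        J=J,
        relative_residual=float(res),
        iterations=int(its),
        method=method,
    )


def element_fields(mesh: TetMesh, node_potentials: np.ndarray, cond: dict):
    """Per-element E = −∇ψ (constant per tet) and J = σE."""
    sigma = _conductivity_per_element(mesh, cond)
    g = shape_gradients(mesh)
    psi = node_potentials[mesh.tets]  # (T,4)
    E = -np.einsum("ti,tia->ta", psi, g)
    J = sigma[:, None] * E
    return E, J


def electrode_flux(
    system: StiffnessSystem, solution: FieldSolution, method: str = "field"
) -> np.ndarray:
    """Injected current recovered from each electrode's contact surface:
    I_l = −∫_{E_l} J·n̂ dS with n̂ the outward normal (A).

    ``method="field"`` integrates the raw element current density over the
    contact facets; ``method="cem"`` uses the variationally consistent form
    (1/z_l)∫(V_l − ψ) dS, exact up to solver tolerance.
    """
    mesh, montage = system.mesh, system.montage
    out = np.empty(montage.n_electrodes)
    if method == "field":
        normals = mesh.boundary_facet_normals()
        owners = mesh.boundary_facet_tets
        areas = mesh.facet_areas(mesh.boundary_facets)
        for l, fi in enumerate(montage.facet_indices):
            Jn = np.einsum("ij,ij->i", solution.J[owners[fi]], normals[fi])
            out[l] = -(Jn * areas[fi]).sum()
    elif method == "cem":
        for l, fi in enumerate(montage.facet_indices):
            fac = mesh.boundary_facets[fi]
            areas = mesh.facet_areas(fac)
            psi_bar = solution.node_potentials[fac].mean(axis=1)
            out[l] = (
                (solution.electrode_potentials[l] - psi_bar)
                * areas
                / montage.z_contact[l]
            ).sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    return out
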