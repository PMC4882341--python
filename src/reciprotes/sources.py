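"""Injection patterns, transfer matrices, dipole sources and reciprocity.

The elementary injection basis follows the one-source convention: pattern i
puts +I_max on electrode i and −I_max/(L−1) on every other electrode.  The
first L−1 such patterns form a complete basis of the zero-sum current space;
solving each gives the 3T×(L−1) transfer matrix of per-element electric-field
responses (element-major, component-minor flattening: x, y, z per element).

EEG sources are current dipoles handled by the partial-integration method:
the load vector has exactly four nonzeros, f_n = d·∇φ_n in the tetrahedron
containing the dipole.  The reciprocity identity

    Φ(a) − Φ(b) = d·∇ψ_ab(r) / I_ab

couples the dipole topography Φ with the pair-injection potential ψ_ab and
holds exactly on the discretization because the stiffness matrix is
symmetric; :func:`verify_reciprocity` computes both sides independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import FieldSolution, StiffnessSystem, electrode_rhs, shape_gradients, solve_system
from .mesh import TetMesh

__all__ = [
    "InjectionPattern",
    "TransferMatrix",
    "DipoleSource",
    "LeadFieldTopography",
    "elementary_pattern",
    "pattern_from_coefficients",
    "coefficients_from_pattern",
    "build_transfer_matrix",
    "find_containing_element",
    "dipole_rhs",
    "eeg_topography",
    "verify_reciprocity",
    "lead_field_solve_counts",
]


@dataclass
class InjectionPattern:
    """Per-electrode injected currents (A) summing to zero."""

    currents: np.ndarray
    method: str
    i_max: float

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if abs(self.currents.sum()) > 1e-12 * max(self.i_max, 1e-300):
            raise ValueError("pattern currents must sum to zero")

    @property
    def n_electrodes(self) -> int:
        return len(self.currents)


@dataclass
class TransferMatrix:
    """Element electric-field responses to the elementary patterns.

    ``matrix`` is 3T×(L−1): column j is the solved E-field of elementary
    pattern j (source electrode j), flattened element-major/component-minor.
    The last electrode's elementary pattern is the omitted basis member.
    """

    matrix: np.ndarray
    i_max: float
    n_elements: int
    n_electrodes: int

    def rows_for_element(self, element: int) -> np.ndarray:
        """The 3×(L−1) block of responses at one element (T̃)."""
        return self.matrix[3 * element : 3 * element + 3]

    def field_for_coefficients(self, c: np.ndarray) -> np.ndarray:
        """Per-element E field (T,3) of the combination Σ c_i p_i."""
        return (self.matrix @ np.asarray(c, dtype=float)).reshape(-1, 3)


@dataclass
class DipoleSource:
    """Current dipole: position r (m) and moment d (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)


@dataclass
class LeadFieldTopography:
    """Average-referenced electrode potentials of one dipole (V)."""

    potentials: np.ndarray
    dipole: DipoleSource

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.potentials = self.potentials - self.potentials.mean()


def elementary_pattern(i: int, L: int, i_max: float) -> InjectionPattern:
    """Elementary pattern i: +I_max at electrode i, −I_max/(L−1) elsewhere."""
    if L < 2:
        raise ValueError("need at least two electrodes")
    if not 0 <= i < L:
        raise ValueError(f"electrode index {i} out of range [0, {L})")
    if not i_max > 0:
        raise ValueError("i_max must be positive")
    cur = np.full(L, -i_max / (L - 1))
    cur[i] = i_max
    return InjectionPattern(currents=cur, method=f"elementary[{i}]", i_max=i_max)


def _basis_matrix(L: int, i_max: float) -> np.ndarray:
    """Columns are the L−1 retained elementary patterns, (L, L−1)."""
    P = np.full((L, L - 1), -i_max / (L - 1))
    P[np.arange(L - 1), np.arange(L - 1)] = i_max
    return P


def pattern_from_coefficients(
    c: np.ndarray, L: int, i_max: float, method: str = "combination"
) -> InjectionPattern:
    """Currents of Σ c_i p_i on the elementary basis."""
    cur = _basis_matrix(L, i_max) @ np.asarray(c, dtype=float)
    return InjectionPattern(currents=cur, method=method, i_max=i_max)


def coefficients_from_pattern(currents: np.ndarray, i_max: float) -> np.ndarray:
    """Unique elementary-basis coefficients of a zero-sum pattern.

    Solves the (L−1)-dimensional linear map from coefficients to the first
    L−1 electrode currents (the last current is determined by conservation).
    """
    currents = np.asarray(currents, dtype=float)
    L = len(currents)
    if abs(currents.sum()) > 1e-9 * max(np.abs(currents).max(), 1e-300):
        raise ValueError("pattern must sum to zero")
    P = _basis_matrix(L, i_max)[: L - 1]
    return np.linalg.solve(P, currents[: L - 1])


def build_transfer_matrix(
    system: StiffnessSystem,
    cond: dict,
    i_max: float = 1e-3,
    tol: float = 1e-11,
    progress: bool = False,
) -> TransferMatrix:
    """Solve the L−1 elementary patterns and stack the element E fields."""
    L = system.n_electrodes
    T = system.mesh.n_elements
    out = np.empty((3 * T, L - 1))
    for j in range(L - 1):
        p = elementary_pattern(j, L, i_max)
        try:
            sol = solve_system(system, electrode_rhs(system, p.currents), cond, tol=tol)
        except Exception as exc:  # noqa: BLE001 - annotate with pattern index
            raise RuntimeError(f"forward solve failed for elementary pattern {j}") from exc
        out[:, j] = sol.E.ravel()
        if progress and (j + 1) % 16 == 0:
            print(f"  transfer matrix: {j + 1}/{L - 1} solves")
    return TransferMatrix(matrix=out, i_max=i_max, n_elements=T, n_electrodes=L)


def find_containing_element(
    mesh: TetMesh, point: np.ndarray, tissue: str | None = "brain"
) -> int:
    """Lowest-index tet whose closed simplex contains ``point``.

    Restricted to elements of the given tissue label when ``tissue`` is not
    None.  Raises if the point lies in no such element.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    cand = np.arange(mesh.n_elements)
    if tissue is not None:
        cand = cand[mesh.tissue == tissue]
    if cand.size == 0:
        raise ValueError(f"mesh has no {tissue!r} elements")
    # cheap prefilter by centroid distance, then exact barycentric test;
    # ties (point on a shared facet) resolved by lowest element index
    cent = mesh.element_centroids[cand]
    order = np.argsort(np.linalg.norm(cent - point, axis=1), kind="stable")
    g = shape_gradients(mesh)
    for subset in (order[:256], order[256:]):
        if subset.size == 0:
            continue
        e = cand[subset]
        lam123 = np.einsum("tia,ta->ti", g[e, 1:], point - mesh.nodes[mesh.tets[e, 0]])
        lam0 = 1.0 - lam123.sum(axis=1)
        inside = (lam0 >= -1e-10) & np.all(lam123 >= -1e-10, axis=1)
        if np.any(inside):
            return int(e[inside].min())
    raise ValueError(f"point {point} is not inside any {tissue!r} element")


def dipole_rhs(
    mesh: TetMesh,
    dipole: DipoleSource,
    n_total: int,
    brain_label: str = "brain",
) -> np.ndarray:
    """Partial-integration dipole load: f_n = d·∇φ_n on the 4 vertices of the
    containing (brain) tet; all other entries zero.

    ``n_total`` is the full system size N+L.  The entries sum to zero since
    the shape-function gradients of a tet sum to zero.
    """
    e = find_containing_element(mesh, dipole.position, tissue=brain_label)
    g = shape_gradients(mesh)[e]  # (4,3)
    f = np.zeros(n_total)
    f[mesh.tets[e]] = g @ dipole.moment
    return f


def eeg_topography(
    system: StiffnessSystem,
    cond: dict,
    dipole: DipoleSource,
    tol: float = 1e-11,
    brain_label: str = "brain",
) -> LeadFieldTopography:
    """Electrode potentials of a cortical dipole, zero-mean referenced."""
    f = dipole_rhs(system.mesh, dipole, system.size, brain_label=brain_label)
    if not np.any(f):
        return LeadFieldTopography(
            potentials=np.zeros(system.n_electrodes), dipole=dipole
        )
    sol = solve_system(system, f, cond, tol=tol)
    return LeadFieldTopography(potentials=sol.electrode_potentials, dipole=dipole)


def verify_reciprocity(
    system: StiffnessSystem,
    cond: dict,
    dipole: DipoleSource,
    electrode_pair: tuple[int, int],
    i_ab: float = 1e-3,
    tol: float = 1e-11,
    brain_label: str = "brain",
):
    """Relative mismatch of the reciprocity identity, both sides computed.

    Left side: Φ(a) − Φ(b) from the dipole topography.  Right side:
    d·∇ψ_ab(r)/I_ab from an independent pair-injection solve, with ∇ψ taken
    in the element containing the dipole.  Returns ``(mismatch, flagged)``;
    when |LHS| is below the noise floor the absolute mismatch is returned
    with ``flagged=True``.
    """
    a, b = electrode_pair
    if a == b:
        raise ValueError("electrode pair must be distinct")
    if not np.any(dipole.moment):
        return 0.0, False
    topo = eeg_topography(system, cond, dipole, tol=tol, brain_label=brain_label)
    lhs = topo.potentials[a] - topo.potentials[b]

    cur = np.zeros(system.n_electrodes)
    cur[a], cur[b] = i_ab, -i_ab
    sol = solve_system(system, electrode_rhs(system, cur), cond, tol=tol)
    e = find_containing_element(system.mesh, dipole.position, tissue=brain_label)
    grad_psi = -sol.E[e]  # E = −∇ψ
    rhs = float(dipole.moment @ grad_psi) / i_ab

    floor = 1e-12 * float(np.abs(topo.potentials).max())
    if abs(lhs) <= floor:
        return abs(lhs - rhs), True
    return abs(lhs - rhs) / abs(lhs), False


def lead_field_solve_counts(n_electrodes: int, n_dipoles: int) -> dict:
    """Forward-solve counts for an N-dipole lead field: direct dipole solves
    versus the reciprocity route (one solve per independent electrode pair).
    """
    if n_electrodes < 2 or n_dipoles < 1:
        raise ValueError("need at least 2 electrodes and 1 dipole")
    reciprocity = n_electrodes - 1
    direct = n_dipoles
    return {
        "direct_solves": direct,
        "reciprocity_solves": reciprocity,
        "speedup": direct / reciprocity,
    }
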