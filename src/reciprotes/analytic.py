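"""Closed-form concentric-sphere solutions used as FEM validation oracles.

Dipole in a multilayer conducting sphere: the potential is expanded in
Legendre series; for each degree n the radial profile in layer k is
A_k r^n + B_k r^{−(n+1)} plus the primary dipole term in the innermost
layer, and the coefficients follow from continuity of potential and radial
current at each interface and an insulating outer boundary.  The series
converges geometrically (ratio b/R for a dipole at radius b), so a fixed
truncation of 80 terms is far below round-off for the configurations used
here.

Point-electrode pair on a homogeneous sphere: the surface series
Σ (2n+1)/n P_n converges only conditionally on the surface, so it is summed
exactly with the generating-function identities
Σ P_n(u) = (2−2u)^{−1/2} − 1 and Σ P_n(u)/n = ln[2/(1−u+√(2−2u))];
interior points use the geometrically convergent (r/R)^n series.

Comparisons with FEM use the standard forward-model validation measures:
the relative difference measure RDM = ‖v̂₁ − v̂₂‖ of the normalized,
zero-mean patterns, and the magnitude ratio MAG = ‖v₁‖/‖v₂‖.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereModel",
    "sphere_dipole_potential",
    "sphere_point_electrode_potential",
    "rdm",
    "mag",
]


@dataclass
class SphereModel:
    """Concentric shells: ascending outer radii (m) and conductivities (S/m)."""

    radii: tuple
    conductivities: tuple

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        self.conductivities = tuple(float(s) for s in self.conductivities)
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must have equal length")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])) or self.radii[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]


def _legendre_and_derivative(u: np.ndarray, n_max: int):
    """P_n(u) and P'_n(u) for n = 0..n_max via stable recurrences."""
    u = np.asarray(u, dtype=float)
    P = np.empty((n_max + 1,) + u.shape)
    dP = np.empty_like(P)
    P[0], P[1] = 1.0, u
    dP[0], dP[1] = 0.0, 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * u * P[n] - n * P[n - 1]) / (n + 1)
    for n in range(2, n_max + 1):
        dP[n] = dP[n - 2] + (2 * n - 1) * P[n - 1]
    return P, dP


def _radial_coefficients(model: SphereModel, n: int) -> float:
    """Outer-surface radial factor u_M(1) for degree n, relative to a unit
    primary coefficient on r^{−(n+1)} in the innermost layer (radii scaled
    so the outer radius is 1)."""
    R = model.outer_radius
    r = np.asarray(model.radii) / R
    sig = np.asarray(model.conductivities)
    M = len(r)
    if M == 1:
        a1 = (n + 1) / n
        return a1 + 1.0
    # unknowns x = [A_1, A_2, B_2, ..., A_M, B_M]
    m = 2 * M - 1
    A = np.zeros((m, m))
    b = np.zeros(m)

    def idx_a(k):  # layer k (1-based) coefficient A
        return 0 if k == 1 else 2 * k - 3

    def idx_b(k):
        return 2 * k - 2

    row = 0
    for j in range(1, M):  # interface between layer j and j+1 at r[j-1]
        rj = r[j - 1]
        rn, rm = rj**n, rj ** -(n + 1)
        drn, drm = n * rj ** (n - 1), -(n + 1) * rj ** -(n + 2)
        # continuity
        A[row, idx_a(j)] = rn
        if j > 1:
            A[row, idx_b(j)] = rm
        A[row, idx_a(j + 1)] = -rn
        A[row, idx_b(j + 1)] = -rm
        if j == 1:
            b[row] = -rm  # primary term in layer 1
        row += 1
        # radial current continuity
        A[row, idx_a(j)] = sig[j - 1] * drn
        if j > 1:
            A[row, idx_b(j)] = sig[j - 1] * drm
        A[row, idx_a(j + 1)] = -sig[j] * drn
        A[row, idx_b(j + 1)] = -sig[j] * drm
        if j == 1:
            b[row] = -sig[0] * drm
        row += 1
    # insulating outer boundary at r = 1
    A[row, idx_a(M)] = n
    A[row, idx_b(M)] = -(n + 1)
    x = np.linalg.solve(A, b)
    a_m, b_m = x[idx_a(M)], x[idx_b(M)]
    return a_m + b_m  # u_M(1)


def sphere_dipole_potential(
    model: SphereModel,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    surface_points: np.ndarray,
    n_terms: int = 80,
) -> np.ndarray:
    """Surface potentials (V) of a current dipole inside the innermost shell,
    zero-mean referenced over the supplied points."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    R = model.outer_radius
    r0 = np.asarray(dipole_position, dtype=float).reshape(3) / R
    m = np.asarray(dipole_moment, dtype=float).reshape(3)
    pts = np.asarray(surface_points, dtype=float).reshape(-1, 3) / R
    b = np.linalg.norm(r0)
    if b * R >= model.radii[0]:
        raise ValueError("dipole must lie strictly inside the innermost shell")
    r0_hat = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    p_hat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    u = p_hat @ r0_hat
    P, dP = _legendre_and_derivative(u, n_terms)

    sigma1 = model.conductivities[0]
    out = np.zeros(len(pts))
    for n in range(1, n_terms + 1):
        bpow = b ** (n - 1) if n > 1 or b > 0 else 1.0
        if n > 1 and b == 0.0:
            break
        # s_n(p̂) = m·[ n b^{n-1} P_n r̂0 + b^{n-1} P'_n (p̂ − u r̂0) ]
        s = bpow * (
            n * P[n] * (m @ r0_hat) + dP[n] * (p_hat @ m - u * (m @ r0_hat))
        )
        out += s * _radial_coefficients(model, n)
    out /= 4.0 * np.pi * sigma1 * R * R
    return out - out.mean()


def _pair_series_closed(u: np.ndarray) -> np.ndarray:
    """Σ_{n≥1} (2n+1)/n P_n(u) at the surface, summed in closed form."""
    s = np.sqrt(2.0 - 2.0 * u)
    return 2.0 * (1.0 / s - 1.0) + np.log(2.0 / (1.0 - u + s))


def sphere_point_electrode_potential(
    model: SphereModel,
    point_a: np.ndarray,
    point_b: np.ndarray,
    current: float,
    points: np.ndarray,
    n_terms: int = 80,
) -> np.ndarray:
    """Potentials of point currents ±I at surface points a/b of a homogeneous
    sphere, evaluated at surface or interior points, zero-mean referenced.

    Multilayer models are not supported for point injection.  Surface points
    (|p| = R) are evaluated with the exact closed-form sum; interior points
    with the geometrically convergent (r/R)^n series truncated at
    ``n_terms``.
    """
    if len(model.radii) != 1:
        raise ValueError("point-electrode oracle supports single-shell models only")
    R = model.outer_radius
    sigma = model.conductivities[0]
    a = np.asarray(point_a, dtype=float).reshape(3)
    b = np.asarray(point_b, dtype=float).reshape(3)
    for p, name in ((a, "a"), (b, "b")):
        if abs(np.linalg.norm(p) - R) > 1e-9 * R:
            raise ValueError(f"injection point {name} must lie on the outer surface")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    rr = np.linalg.norm(pts, axis=1)
    if np.any(rr > R * (1 + 1e-9)):
        raise ValueError("evaluation points must lie inside or on the sphere")
    p_hat = pts / rr[:, None]
    out = np.zeros(len(pts))
    on_surf = np.abs(rr - R) <= 1e-9 * R
    pref = current / (4.0 * np.pi * sigma * R)
    for inj, sign in ((a, 1.0), (b, -1.0)):
        u = p_hat @ (inj / R)
        if on_surf.any():
            out[on_surf] += sign * pref * _pair_series_closed(u[on_surf])
        if (~on_surf).any():
            ui = u[~on_surf]
            t = rr[~on_surf] / R
            P, _ = _legendre_and_derivative(ui, n_terms)
            acc = np.zeros(ui.shape)
            for n in range(1, n_terms + 1):
                acc += (2 * n + 1) / n * t**n * P[n]
            out[~on_surf] += sign * pref * acc
    return out - out.mean()


def rdm(v1: np.ndarray, v2: np.ndarray) -> float:
    """Relative difference measure of two zero-meaned, normalized patterns."""
    a = np.asarray(v1, dtype=float)
    a = a - a.mean()
    b = np.asarray(v2, dtype=float)
    b = b - b.mean()
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def mag(v1: np.ndarray, v2: np.ndarray) -> float:
    """Magnitude ratio ‖v1‖/‖v2‖ of two zero-meaned patterns."""
    a = np.asarray(v1, dtype=float)
    a = a - a.mean()
    b = np.asarray(v2, dtype=float)
    b = b - b.mean()
    return float(np.linalg.norm(a) / np.linalg.norm(b))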