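"""Montage optimization: least squares, LCMV, and reciprocity selection.

Two families of methods compute an injection pattern for a cortical target
(ROI center r, outward unit normal d):

* **Transfer-matrix methods.** LS solves min‖Tc − e‖² with e = b⊗d (the
  desired field replicated on the ROI elements); LCMV minimizes ‖Tc‖²
  subject to the hard constraint T̃c = d at the target element.  Both
  combinations Σ c_i p_i are ℓ1-rescaled so the total injected (positive)
  current is exactly I_max, i.e. ‖p‖₁ = 2·I_max.

* **Reciprocity methods.** Driven only by the EEG topography of a unit
  dipole at the target: *one-source* (topography argmax vs all other
  electrodes as sinks — no per-electrode cap, by construction), *opposite*
  (10 top sources, 30 bottom sinks), *ring* (10 top sources, 10 sinks
  nearest the source centroid), and *ROADSS* (sinks nearest the reflected
  point r_s = r − |r_m − r|·d, interpolating between opposite- and
  ring-like behavior with target orientation).  All but one-source respect
  the per-electrode safety cap of I_max/10 at the defaults.

Polarity note: sources sit at the topography maximum, so with an outward
normal d the delivered current density at the target points along −d
(anodal stimulation drives current into the cortex); reversing sources and
sinks reverses the flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import ElectrodeMontage, TetMesh, facet_counts
from .sources import (
    InjectionPattern,
    LeadFieldTopography,
    TransferMatrix,
    pattern_from_coefficients,
)

__all__ = [
    "Target",
    "TargetingConfig",
    "target_from_seed",
    "ls_coefficients",
    "ls_pattern",
    "lcmv_coefficients",
    "lcmv_pattern",
    "one_source_pattern",
    "opposite_pattern",
    "ring_pattern",
    "roadss_pattern",
    "brute_force_best_pair",
]


@dataclass
class Target:
    """Cortical ROI: element indices, center r, outward unit normal d."""

    elements: np.ndarray
    center: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("target direction must be nonzero")
        self.direction = d / n
        if self.elements.size < 1:
            raise ValueError("target ROI must contain at least one element")

    def selection_vector(self, n_elements: int) -> np.ndarray:
        b = np.zeros(n_elements)
        b[self.elements] = 1.0
        return b


@dataclass
class TargetingConfig:
    """Budget and source/sink counts for the optimization methods.

    ``i_max`` is the total injected current; the safety cap per electrode
    defaults to I_max/10, realized by spreading sources over ``n_sources``
    electrodes.  Source/sink counts scale down proportionally on montages
    smaller than ``small_montage`` electrodes.
    """

    i_max: float = 1e-3
    n_sources: int = 10
    n_sinks_opposite: int = 30
    n_sinks_ring: int = 10
    small_montage: int = 40

    def counts_for(self, L: int) -> tuple[int, int, int]:
        if L >= self.small_montage:
            return self.n_sources, self.n_sinks_opposite, self.n_sinks_ring
        f = L / self.small_montage
        ns = max(1, int(round(self.n_sources * f)))
        return ns, max(1, int(round(self.n_sinks_opposite * f))), max(
            1, int(round(self.n_sinks_ring * f))
        )

    @property
    def cap(self) -> float:
        return self.i_max / self.n_sources


def target_from_seed(
    mesh: TetMesh,
    seed: np.ndarray,
    n_elements: int = 12,
    brain_label: str = "brain",
) -> Target:
    """ROI of the ``n_elements`` brain elements nearest ``seed`` that touch
    the brain outer interface; the direction is the normalized average of
    the outward interface-facet normals (facet normals from edge cross
    products, averaged over the ROI), the center the ROI centroid.
    """
    seed = np.asarray(seed, dtype=float).reshape(3)
    brain = np.where(mesh.tissue == brain_label)[0]
    if brain.size == 0:
        raise ValueError(f"mesh has no {brain_label!r} elements")

    # facets shared by a brain tet and a non-brain tet (or boundary)
    faces, counts, first = facet_counts(mesh.tets)
    is_brain = mesh.tissue == brain_label
    # recover both owners of interior facets
    f_all = np.concatenate(
        [
            mesh.tets[:, [1, 2, 3]],
            mesh.tets[:, [0, 2, 3]],
            mesh.tets[:, [0, 1, 3]],
            mesh.tets[:, [0, 1, 2]],
        ]
    )
    owner = np.tile(np.arange(mesh.n_elements), 4)
    key = np.sort(f_all, axis=1)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    starts = np.searchsorted(inv[order], np.arange(len(faces)))
    ends = np.append(starts[1:], len(order))
    interface_facets = []
    interface_tets = []
    for fi in range(len(faces)):
        own = owner[order[starts[fi] : ends[fi]]]
        bb = is_brain[own]
        if bb.any() and not bb.all():
            interface_facets.append(faces[fi])
            interface_tets.append(own[bb][0])
        elif len(own) == 1 and bb.all():  # brain facet on the mesh boundary
            interface_facets.append(faces[fi])
            interface_tets.append(own[0])
    if not interface_facets:
        raise ValueError("no brain interface facets in the mesh")
    interface_facets = np.asarray(interface_facets)
    interface_tets = np.asarray(interface_tets)

    surf_tets = np.unique(interface_tets)
    cent = mesh.element_centroids[surf_tets]
    order = np.argsort(np.linalg.norm(cent - seed, axis=1), kind="stable")
    if order.size < n_elements:
        raise ValueError("not enough brain interface elements near the seed")
    roi = surf_tets[order[:n_elements]]

    roi_set = set(roi.tolist())
    sel = np.array([t in roi_set for t in interface_tets])
    fac = interface_facets[sel]
    own = interface_tets[sel]
    p = mesh.nodes[fac]
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    # orient outward: away from the owning brain tet's centroid
    ct = mesh.element_centroids[own]
    cf = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", nrm, cf - ct) < 0
    nrm[flip] *= -1.0
    d = nrm.mean(axis=0)
    if np.linalg.norm(d) == 0:
        raise ValueError("interface normals average to zero near the seed")
    return Target(
        elements=roi, center=mesh.element_centroids[roi].mean(axis=0), direction=d
    )


def _l1_rescale(currents: np.ndarray, i_max: float) -> np.ndarray:
    """Scale so the ℓ1 norm is 2·I_max (positive currents sum to I_max)."""
    n1 = np.abs(currents).sum()
    if n1 == 0:
        raise ValueError("cannot rescale a zero pattern")
    return 2.0 * i_max * currents / n1


def ls_coefficients(transfer: TransferMatrix, target: Target) -> np.ndarray:
    """Least-squares coefficients c = (TᵀT)⁻¹Tᵀe for the objective e = b⊗d."""
    Tm = transfer.matrix
    G = Tm.T @ Tm
    # e is nonzero only on ROI rows: Tᵀe accumulates the ROI blocks
    rhs = np.zeros(Tm.shape[1])
    for el in target.elements:
        rhs += transfer.rows_for_element(int(el)).T @ target.direction
    try:
        c = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate montage: normal equations are singular") from exc
    if not np.isfinite(c).all():
        raise ValueError("degenerate montage: normal equations are singular")
    return c


def ls_pattern(
    transfer: TransferMatrix, target: Target, cfg: TargetingConfig
) -> InjectionPattern:
    """Unregularized least-squares pattern for the objective field e = b⊗d."""
    c = ls_coefficients(transfer, target)
    raw = pattern_from_coefficients(c, transfer.n_electrodes, transfer.i_max).currents
    return InjectionPattern(
        currents=_l1_rescale(raw, cfg.i_max), method="ls", i_max=cfg.i_max
    )


def lcmv_coefficients(
    transfer: TransferMatrix, target_element: int, direction: np.ndarray
) -> np.ndarray:
    """Minimum-variance coefficients c = G⁻¹T̃ᵀ(T̃G⁻¹T̃ᵀ)⁻¹d with G = TᵀT;
    the hard constraint T̃c = d holds exactly (before any rescaling)."""
    d = np.asarray(direction, dtype=float).reshape(3)
    if np.linalg.norm(d) == 0:
        raise ValueError("target direction must be nonzero")
    Tm = transfer.matrix
    G = Tm.T @ Tm
    Tt = transfer.rows_for_element(int(target_element))  # 3×(L−1)
    Ginv_Tt = np.linalg.solve(G, Tt.T)  # (L−1)×3
    S = Tt @ Ginv_Tt  # 3×3
    try:
        mu = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular 3×3 constraint system at the target") from exc
    c = Ginv_Tt @ mu
    resid = np.linalg.norm(Tt @ c - d) / np.linalg.norm(d)
    if resid > 1e-8:
        raise ValueError(f"LCMV constraint violated (residual {resid:.2e})")
    return c


def lcmv_pattern(
    transfer: TransferMatrix,
    target_element: int,
    direction: np.ndarray,
    cfg: TargetingConfig,
) -> InjectionPattern:
    """Minimum-variance pattern: LCMV coefficients, then the ℓ1 budget
    rescaling shared with the LS method."""
    c = lcmv_coefficients(transfer, target_element, direction)
    raw = pattern_from_coefficients(c, transfer.n_electrodes, transfer.i_max).currents
    return InjectionPattern(
        currents=_l1_rescale(raw, cfg.i_max), method="lcmv", i_max=cfg.i_max
    )


def _ranked(topo: LeadFieldTopography) -> np.ndarray:
    """Electrode indices by descending potential, ties by lowest index."""
    phi = topo.potentials
    return np.lexsort((np.arange(len(phi)), -phi))


def one_source_pattern(
    topo: LeadFieldTopography, cfg: TargetingConfig
) -> InjectionPattern:
    """Topography argmax as the single source; all others equal sinks.

    The per-electrode cap is deliberately not enforced here — the method
    serves as an uncapped reciprocity reference.
    """
    L = len(topo.potentials)
    if L < 2:
        raise ValueError("need at least two electrodes")
    src = int(_ranked(topo)[0])
    cur = np.full(L, -cfg.i_max / (L - 1))
    cur[src] = cfg.i_max
    return InjectionPattern(currents=cur, method="one_source", i_max=cfg.i_max)


def _sources_and_potential_sinks(topo, cfg):
    L = len(topo.potentials)
    ns, nk_opp, nk_ring = cfg.counts_for(L)
    ranked = _ranked(topo)
    return L, ns, nk_opp, nk_ring, ranked


def opposite_pattern(
    topo: LeadFieldTopography, cfg: TargetingConfig
) -> InjectionPattern:
    """Top-ranked electrodes source, bottom-ranked sink, equal splits."""
    L, ns, nk, _, ranked = _sources_and_potential_sinks(topo, cfg)
    if L < ns + nk:
        raise ValueError(
            f"montage of {L} electrodes cannot host {ns} sources + {nk} sinks; "
            "reduce the counts"
        )
    cur = np.zeros(L)
    cur[ranked[:ns]] = cfg.i_max / ns
    cur[ranked[-nk:]] = -cfg.i_max / nk
    return InjectionPattern(currents=cur, method="opposite", i_max=cfg.i_max)


def _sink_split(cur, sinks, i_max):
    cur[sinks] = -i_max / len(sinks)
    return cur


def ring_pattern(
    topo: LeadFieldTopography, montage: ElectrodeMontage, cfg: TargetingConfig
) -> InjectionPattern:
    """Sources as in *opposite*; sinks are the electrodes nearest the source
    centroid (excluding sources) — a ring around the source cluster."""
    L, ns, _, nk, ranked = _sources_and_potential_sinks(topo, cfg)
    if L < ns + nk:
        raise ValueError(
            f"montage of {L} electrodes cannot host {ns} sources + {nk} sinks"
        )
    sources = ranked[:ns]
    centroid = montage.centers[sources].mean(axis=0)
    sinks = _nearest_excluding(montage.centers, centroid, set(sources.tolist()), nk)
    cur = np.zeros(L)
    cur[sources] = cfg.i_max / ns
    return InjectionPattern(
        currents=_sink_split(cur, sinks, cfg.i_max), method="ring", i_max=cfg.i_max
    )


def roadss_pattern(
    topo: LeadFieldTopography,
    montage: ElectrodeMontage,
    target: Target,
    cfg: TargetingConfig,
) -> InjectionPattern:
    """Reciprocity-opposite-averaged-distance sink selection.

    1. sources = top-ranked electrodes (as in *opposite*/*ring*);
    2. r_m = mean source position;  3. d_rm = |r_m − r|;
    4. r_s = r − d_rm·d;  5. sinks = electrodes nearest r_s, not sources.
    Radial targets make r_s fall inside the source cluster (ring-like),
    tangential targets push it to the far side (opposite-like).
    """
    L, ns, _, _, ranked = _sources_and_potential_sinks(topo, cfg)
    if L < 2 * ns:
        raise ValueError(f"montage of {L} electrodes cannot host 2×{ns} electrodes")
    sources = ranked[:ns]
    r_m = montage.centers[sources].mean(axis=0)
    d_rm = float(np.linalg.norm(r_m - target.center))
    r_s = target.center - d_rm * target.direction
    sinks = _nearest_excluding(montage.centers, r_s, set(sources.tolist()), ns)
    cur = np.zeros(L)
    cur[sources] = cfg.i_max / ns
    return InjectionPattern(
        currents=_sink_split(cur, sinks, cfg.i_max), method="roadss", i_max=cfg.i_max
    )


def _nearest_excluding(centers, point, excluded: set, k: int) -> np.ndarray:
    d = np.linalg.norm(centers - point, axis=1)
    order = np.lexsort((np.arange(len(centers)), d))
    sel = [i for i in order if i not in excluded][:k]
    if len(sel) < k:
        raise ValueError("not enough non-source electrodes for the sink set")
    return np.asarray(sel, dtype=np.int64)


def brute_force_best_pair(
    transfer: TransferMatrix, target_element: int, direction: np.ndarray
) -> tuple[int, int]:
    """Exhaustive pole-pair search: the pair (A, B) whose unit-budget pair
    injection maximizes the directional potential gradient d·∇ψ_AB at the
    target element (A the source).  Reversing d swaps A and B.
    """
    d = np.asarray(direction, dtype=float).reshape(3)
    L = transfer.n_electrodes
    i_max = transfer.i_max
    Tt = transfer.rows_for_element(int(target_element))  # 3×(L−1), E responses
    # directional gradient response per elementary pattern: d·∇ψ = −d·E
    resp = -(d @ Tt)  # (L−1,)
    from .sources import _basis_matrix

    Pinv = np.linalg.inv(_basis_matrix(L, i_max)[: L - 1])
    best, best_val = None, -np.inf
    for a in range(L):
        for b in range(a + 1, L):
            cur = np.zeros(L)
            cur[a], cur[b] = i_max, -i_max
            val = float(resp @ (Pinv @ cur[: L - 1]))
            for pair, v in (((a, b), val), ((b, a), -val)):
                if v > best_val:
                    best, best_val = pair, v
    return best
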