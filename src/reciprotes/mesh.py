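"""Layered-sphere tetrahedral head models with scalp electrode montages.

The synthetic head is a set of concentric conducting shells (brain, CSF,
skull, scalp by default) discretized into first-order tetrahedra.  Meshing is
fully deterministic: points are laid out on concentric Fibonacci-lattice
spheres spaced at most one target edge length apart radially, and the
tessellation is the Delaunay triangulation of that point cloud (the domain is
a ball, so the Delaunay complex covers it exactly).  No randomness, no
external mesher.

All coordinates are SI meters, conductivities S/m, currents amperes,
contact impedances Ω·m² (impedance per unit contact area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "TetMesh",
    "ElectrodeMontage",
    "MeshQuality",
    "DEFAULT_CONDUCTIVITIES",
    "DEFAULT_RADII",
    "DEFAULT_LABELS",
    "generate_layered_sphere_mesh",
    "place_electrodes",
    "stretch_factor",
    "lumped_resistance_to_impedance",
    "fibonacci_sphere",
]

#: Isotropic tissue conductivities, S/m.  The brain shell uses the gray-matter
#: value; white matter and eyeballs are available as extra labels.
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "brain": 0.33,
    "wm": 0.2,
    "csf": 1.79,
    "skull": 0.008,
    "scalp": 0.35,
    "eyes": 1.5,
}

#: Default 4-layer shell outer radii, m (brain/CSF/skull/scalp).
DEFAULT_RADII: tuple[float, ...] = (0.080, 0.083, 0.088, 0.094)
DEFAULT_LABELS: tuple[str, ...] = ("brain", "csf", "skull", "scalp")


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element tissue labels.

    Attributes
    ----------
    nodes : (N, 3) float array, node positions in meters.
    tets : (T, 4) int array, 0-based node indices, positively oriented.
    tissue : (T,) array of tissue label strings.
    boundary_facets : (B, 3) int array, triangles on the outer surface.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue: np.ndarray
    boundary_facets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.tissue = np.asarray(self.tissue)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise ValueError("tet node index out of range")
        self._fix_orientation()
        if self.boundary_facets is None:
            self.boundary_facets = self._extract_boundary_facets()
        self.boundary_facets = np.ascontiguousarray(self.boundary_facets, dtype=np.int64)

    # -- derived geometry ---------------------------------------------------

    def _fix_orientation(self) -> None:
        v = _signed_volumes(self.nodes, self.tets)
        neg = v < 0
        if np.any(neg):
            self.tets[neg, 1], self.tets[neg, 2] = (
                self.tets[neg, 2].copy(),
                self.tets[neg, 1].copy(),
            )

    def _extract_boundary_facets(self) -> np.ndarray:
        faces, counts, first = facet_counts(self.tets)
        sel = counts == 1
        self._boundary_facet_tets = first[sel]
        return faces[sel]

    @property
    def boundary_facet_tets(self) -> np.ndarray:
        """Owning tet index of each boundary facet."""
        if getattr(self, "_boundary_facet_tets", None) is None:
            faces, counts, first = facet_counts(self.tets)
            own = {tuple(f): t for f, t in zip(faces[counts == 1], first[counts == 1])}
            self._boundary_facet_tets = np.array(
                [own[tuple(sorted(f))] for f in self.boundary_facets], dtype=np.int64
            )
        return self._boundary_facet_tets

    def boundary_facet_normals(self) -> np.ndarray:
        """Unit outward normals of the boundary facets (oriented away from
        the owning tet's centroid)."""
        p = self.nodes[self.boundary_facets]
        nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        cent_t = self.element_centroids[self.boundary_facet_tets]
        cent_f = p.mean(axis=1)
        flip = np.einsum("ij,ij->i", nrm, cent_f - cent_t) < 0
        nrm[flip] *= -1.0
        return nrm

    @property
    def element_volumes(self) -> np.ndarray:
        return _signed_volumes(self.nodes, self.tets)

    @property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        p = self.nodes[facets]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def facet_centroids(self, facets: np.ndarray) -> np.ndarray:
        return self.nodes[facets].mean(axis=1)


@dataclass
class ElectrodeMontage:
    """Scalp electrodes with complete-electrode-model contact surfaces.

    ``facet_indices[l]`` indexes rows of ``mesh.boundary_facets`` forming the
    contact patch of electrode *l*; ``z_contact`` is the contact impedance per
    unit area in Ω·m².
    """

    labels: list[str]
    centers: np.ndarray  # (L, 3) m
    facet_indices: list[np.ndarray]
    z_contact: np.ndarray  # (L,) Ω·m²
    contact_areas: np.ndarray  # (L,) m²
    contact_radius: float = float("nan")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)


@dataclass
class MeshQuality:
    """Per-element stretch factor and the fraction below a quality threshold."""

    stretch: np.ndarray
    threshold: float
    fraction_below: float


def _signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return (
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        / 6.0
    )


def facet_counts(tets: np.ndarray):
    """All triangular facets of a tet mesh with their tet-incidence counts.

    Returns (faces, counts, first_tet): unique sorted node triples, how many
    tets share each, and the lowest tet index owning each facet.
    """
    # 4 faces per tet, opposite each vertex
    f = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 2, 3]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 1, 2]],
        ]
    )
    owner = np.tile(np.arange(len(tets)), 4)
    fs = np.sort(f, axis=1)
    faces, inv, counts = np.unique(fs, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(inv, kind="stable")
    first_pos = np.searchsorted(inv[order], np.arange(len(faces)))
    first = owner[order[first_pos]]
    return faces, counts, first


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (golden-angle lattice)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    th = ga * i
    pts = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
    return radius * pts


def _sphere_point_count(r: float, spacing: float) -> int:
    # one point per ~hexagonal cell of side `spacing`
    area_per_pt = spacing * spacing * math.sqrt(3.0) / 2.0
    return max(6, int(round(4.0 * math.pi * r * r / area_per_pt)))


def generate_layered_sphere_mesh(
    radii=DEFAULT_RADII,
    labels=DEFAULT_LABELS,
    target_edge: float = 0.007,
) -> TetMesh:
    """Build a concentric-shell ball mesh with per-shell tissue labels.

    Parameters
    ----------
    radii : ascending outer radii of the shells, m.
    labels : tissue label per shell, innermost first.
    target_edge : requested edge length, m.  Must resolve every shell
        (no shell thinner than half an edge) and be finer than a fifth of
        the outer radius.

    The element tissue label is the shell containing the element centroid.
    """
    radii = [float(r) for r in radii]
    labels = list(labels)
    if len(radii) != len(labels):
        raise ValueError("radii and labels must have equal length")
    if len(radii) < 1:
        raise ValueError("need at least one shell")
    if any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
        raise ValueError("radii must be positive and strictly increasing")
    if target_edge >= radii[-1] / 5.0:
        raise ValueError("target_edge too coarse for the outer radius")
    inner = [0.0] + radii[:-1]
    for k, (a, b) in enumerate(zip(inner, radii)):
        # interface spheres are always meshed, so a shell keeps one element
        # layer down to a fraction of the edge length before degenerating
        if k > 0 and (b - a) < 0.25 * target_edge:
            raise ValueError(
                f"shell {k} ({labels[k]}) thinner than one element layer "
                f"({b - a:.4g} m < edge/2 = {0.5 * target_edge:.4g} m)"
            )

    # concentric sphere radii: every shell interface, plus intermediates so
    # the radial spacing never exceeds target_edge
    shell_radii: list[float] = []
    for a, b in zip(inner, radii):
        n_lay = max(1, int(round((b - a) / target_edge)))
        rr = np.linspace(a, b, n_lay + 1)[1:]
        shell_radii.extend(rr.tolist())
    shell_radii = sorted(set(shell_radii))

    pts = [np.zeros((1, 3))]
    for r in shell_radii:
        pts.append(fibonacci_sphere(_sphere_point_count(r, target_edge), r))
    points = np.vstack(pts)

    tri = Delaunay(points)
    tets = np.asarray(tri.simplices, dtype=np.int64)
    # drop exactly/near degenerate slivers produced by cospherical point sets;
    # threshold is relative to the nominal element volume so it never removes
    # genuine elements
    vols = np.abs(_signed_volumes(points, tets))
    keep = vols > 1e-9 * target_edge**3
    tets = tets[keep]

    cent = points[tets].mean(axis=1)
    rc = np.linalg.norm(cent, axis=1)
    shell_idx = np.searchsorted(np.asarray(radii), rc, side="left")
    shell_idx = np.clip(shell_idx, 0, len(labels) - 1)
    tissue = np.asarray(labels, dtype=object)[shell_idx]
    return TetMesh(nodes=points, tets=tets, tissue=tissue)


def lumped_resistance_to_impedance(resistance_ohm: float, diameter_m: float) -> float:
    """Convert a lumped contact resistance to impedance per unit area.

    A disc electrode of diameter *d* with lumped resistance *R* has
    ``z = R · π d²/4`` in Ω·m² — e.g. an 8 mm electrode at 40 kΩ gives
    about 2.01 Ω·m².
    """
    if resistance_ohm <= 0 or diameter_m <= 0:
        raise ValueError("resistance and diameter must be positive")
    return resistance_ohm * math.pi * diameter_m**2 / 4.0


def place_electrodes(
    mesh: TetMesh,
    n: int = 64,
    contact_radius: float = 0.004,
    z_contact: float = 2.01,
) -> ElectrodeMontage:
    """Place ``n`` quasi-uniform electrodes on the outer surface.

    Centers sit on a Fibonacci lattice at the outer radius.  Contact facets
    are the boundary facets whose centroid is within ``contact_radius`` of
    the electrode center; a facet within reach of several electrodes goes to
    the nearest one, so contact sets are disjoint.
    """
    if n < 2:
        raise ValueError("need at least two electrodes")
    if contact_radius <= 0 or z_contact <= 0:
        raise ValueError("contact_radius and z_contact must be positive")
    R = float(np.linalg.norm(mesh.nodes, axis=1).max())
    centers = fibonacci_sphere(n, R)
    fc = mesh.facet_centroids(mesh.boundary_facets)
    areas = mesh.facet_areas(mesh.boundary_facets)

    # nearest electrode per boundary facet, then a radius cut
    d2 = ((fc[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(fc)), nearest])
    facet_indices: list[np.ndarray] = []
    contact_areas = np.empty(n)
    for l in range(n):
        sel = np.where((nearest == l) & (dist <= contact_radius))[0]
        if sel.size == 0:
            raise ValueError(
                f"electrode {l} captured no boundary facet; refine the mesh "
                f"or enlarge contact_radius"
            )
        facet_indices.append(sel)
        contact_areas[l] = areas[sel].sum()
    return ElectrodeMontage(
        labels=[f"E{l + 1}" for l in range(n)],
        centers=centers,
        facet_indices=facet_indices,
        z_contact=np.full(n, float(z_contact)),
        contact_areas=contact_areas,
        contact_radius=float(contact_radius),
    )


_REGULAR_TET_NORM = 2.0 * math.sqrt(6.0)


def stretch_factor(mesh: TetMesh, threshold: float = 0.05) -> MeshQuality:
    """Per-element stretch factor: inscribed-sphere radius over longest edge,
    normalized so a regular tetrahedron scores 1 (factor 2√6).

    Degenerate (coplanar) elements score 0.  Also reports the fraction of
    elements below ``threshold`` (default 0.05), the usual quality criterion.
    """
    p = mesh.nodes[mesh.tets]
    vol = np.abs(_signed_volumes(mesh.nodes, mesh.tets))
    # total surface area of each tet
    pairs = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    area = np.zeros(len(p))
    for i, j, k in pairs:
        area += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1
        )
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    lmax = np.max(
        np.stack([np.linalg.norm(p[:, j] - p[:, i], axis=1) for i, j in edges]),
        axis=0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = np.where(area > 0, 3.0 * vol / area, 0.0)
        s = np.where(lmax > 0, r_in / lmax, 0.0) * _REGULAR_TET_NORM
    s = np.clip(s, 0.0, 1.0)
    return MeshQuality(
        stretch=s, threshold=threshold, fraction_below=float(np.mean(s < threshold))
    )
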