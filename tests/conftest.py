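"""Shared fixtures: coarse head models kept session-scoped so the expensive
mesh/assembly/factorization work happens once per run."""

from __future__ import annotations

import numpy as np
import pytest

from reciprotes import (
    DEFAULT_CONDUCTIVITIES,
    assemble_cem_system,
    build_transfer_matrix,
    generate_layered_sphere_mesh,
    place_electrodes,
)
from reciprotes.mesh import TetMesh


@pytest.fixture(scope="session")
def cond():
    return dict(DEFAULT_CONDUCTIVITIES)


@pytest.fixture(scope="session")
def head4(cond):
    """Coarse 4-layer head: mesh, 32-electrode montage, assembled system."""
    mesh = generate_layered_sphere_mesh(target_edge=0.0095)
    montage = place_electrodes(mesh, n=32, contact_radius=0.006)
    system = assemble_cem_system(mesh, cond, montage)
    return mesh, montage, system


@pytest.fixture(scope="session")
def head4_transfer(head4, cond):
    _, _, system = head4
    return build_transfer_matrix(system, cond, i_max=1e-3)


@pytest.fixture(scope="session")
def shell1(cond):
    """Coarse homogeneous sphere: mesh, 16-electrode montage, system."""
    mesh = generate_layered_sphere_mesh(
        radii=[0.09], labels=["brain"], target_edge=0.008
    )
    montage = place_electrodes(mesh, n=16, contact_radius=0.006)
    system = assemble_cem_system(mesh, {"brain": 0.33}, montage)
    return mesh, montage, system


def single_tet_mesh(scale: float = 1.0, label: str = "brain") -> TetMesh:
    """The corner tet on (0,0,0),(s,0,0),(0,s,0),(0,0,s)."""
    nodes = scale * np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    return TetMesh(
        nodes=nodes, tets=np.array([[0, 1, 2, 3]]), tissue=np.array([label])
    )


def regular_tet_nodes(edge: float = 1.0) -> np.ndarray:
    a = edge
    return a * np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    ) / np.sqrt(8.0)  # edge length = a


def tiny_brain_mesh(centroids, volumes, labels=None) -> TetMesh:
    """Disjoint corner tets with prescribed centroids and volumes — a minimal
    mesh for hand-computed metric fixtures."""
    centroids = np.asarray(centroids, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    nodes, tets = [], []
    for c, v in zip(centroids, volumes):
        a = (6.0 * v) ** (1.0 / 3.0)
        base = np.array(
            [[0.0, 0.0, 0.0], [a, 0.0, 0.0], [0.0, a, 0.0], [0.0, 0.0, a]]
        )
        base += c - base.mean(axis=0)
        k = len(nodes)
        nodes.extend(base.tolist())
        tets.append([k, k + 1, k + 2, k + 3])
    if labels is None:
        labels = ["brain"] * len(volumes)
    return TetMesh(
        nodes=np.asarray(nodes), tets=np.asarray(tets), tissue=np.asarray(labels)
    )
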