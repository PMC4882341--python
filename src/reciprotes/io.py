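"""Readers and writers for the package's text formats.

Meshes travel as TetGen ``.node``/``.ele`` pairs (1-based indices on disk,
0-based in memory); per-element vector fields are exported as VTK legacy
ASCII for visualization; montages as TSV; injection patterns and lead-field
topographies as CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .mesh import ElectrodeMontage, TetMesh

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_fields",
    "write_montage",
    "read_montage",
    "write_pattern",
    "read_pattern",
    "write_topography",
    "MeshParseError",
]


class MeshParseError(ValueError):
    """Malformed .node/.ele content; carries the offending file line number."""

    def __init__(self, path: str, line: int, msg: str):
        super().__init__(f"{path}:{line}: {msg}")
        self.path = path
        self.line = line


def write_mesh(mesh: TetMesh, path: str) -> None:
    """Write ``path.node`` and ``path.ele`` (TetGen dialect, 1-based).

    ``path`` is the stem; tissue labels go in the .ele attribute column as
    integer codes, with the label table in a comment line.
    """
    stem = _strip_ext(path)
    labels = sorted(set(mesh.tissue.tolist()))
    code = {lab: i + 1 for i, lab in enumerate(labels)}
    with open(stem + ".node", "w") as f:
        f.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(stem + ".ele", "w") as f:
        f.write(f"{mesh.n_elements} 4 1\n")
        f.write("# tissue codes: " + " ".join(f"{code[l]}={l}" for l in labels) + "\n")
        for i, (t, lab) in enumerate(zip(mesh.tets, mesh.tissue), start=1):
            f.write(
                f"{i} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1} {code[lab]}\n"
            )


def _strip_ext(path: str) -> str:
    for ext in (".node", ".ele"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def _data_lines(path: str):
    with open(path) as f:
        for lineno, raw in enumerate(f, start=1):
            s = raw.split("#", 1)[0].strip()
            if s:
                yield lineno, s


def read_mesh(path: str) -> TetMesh:
    """Read a TetGen ``.node``/``.ele`` pair written by :func:`write_mesh`."""
    stem = _strip_ext(path)
    npath, epath = stem + ".node", stem + ".ele"

    lines = _data_lines(npath)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise MeshParseError(npath, 0, "empty .node file") from None
    try:
        n_nodes = int(header.split()[0])
    except ValueError:
        raise MeshParseError(npath, lineno, "bad node header") from None
    nodes = np.empty((n_nodes, 3))
    seen = 0
    for lineno, s in lines:
        parts = s.split()
        if len(parts) < 4:
            raise MeshParseError(npath, lineno, "expected index x y z")
        try:
            idx = int(parts[0])
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise MeshParseError(npath, lineno, "non-numeric node entry") from None
        if not 1 <= idx <= n_nodes:
            raise MeshParseError(npath, lineno, f"node index {idx} out of range")
        nodes[idx - 1] = xyz
        seen += 1
    if seen != n_nodes:
        raise MeshParseError(npath, lineno, f"expected {n_nodes} nodes, got {seen}")

    # tissue code table from the .ele comment, if present
    code2label: dict[int, str] = {}
    with open(epath) as f:
        for raw in f:
            if raw.startswith("# tissue codes:"):
                for tok in raw.split(":", 1)[1].split():
                    c, lab = tok.split("=")
                    code2label[int(c)] = lab

    lines = _data_lines(epath)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise MeshParseError(epath, 0, "empty .ele file") from None
    parts = header.split()
    try:
        n_ele = int(parts[0])
        n_attr = int(parts[2]) if len(parts) > 2 else 0
    except ValueError:
        raise MeshParseError(epath, lineno, "bad element header") from None
    tets = np.empty((n_ele, 4), dtype=np.int64)
    tissue = np.empty(n_ele, dtype=object)
    seen = 0
    for lineno, s in lines:
        parts = s.split()
        if len(parts) < 5 + (1 if n_attr else 0):
            raise MeshParseError(epath, lineno, "expected index n1 n2 n3 n4 [label]")
        try:
            idx = int(parts[0])
            conn = [int(p) for p in parts[1:5]]
        except ValueError:
            raise MeshParseError(epath, lineno, "non-numeric element entry") from None
        if not 1 <= idx <= n_ele:
            raise MeshParseError(epath, lineno, f"element index {idx} out of range")
        for c in conn:
            if not 1 <= c <= n_nodes:
                raise MeshParseError(
                    epath, lineno, f"node index {c} out of range [1, {n_nodes}]"
                )
        tets[idx - 1] = [c - 1 for c in conn]
        if n_attr:
            code = int(parts[5])
            tissue[idx - 1] = code2label.get(code, str(code))
        else:
            tissue[idx - 1] = "tissue"
        seen += 1
    if seen != n_ele:
        raise MeshParseError(epath, lineno, f"expected {n_ele} elements, got {seen}")
    return TetMesh(nodes=nodes, tets=tets, tissue=tissue)


def write_fields(mesh: TetMesh, fields: dict[str, np.ndarray], path: str) -> None:
    """Export per-element vector (T×3) or scalar (T,) fields as VTK legacy ASCII."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("reciprotes element fields\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        cells = np.column_stack(
            [np.full(mesh.n_elements, 4, dtype=np.int64), mesh.tets]
        )
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 10, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape == (mesh.n_elements, 3):
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, arr, fmt="%.9g")
            elif arr.shape == (mesh.n_elements,):
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.9g")
            else:
                raise ValueError(f"field {name!r} has shape {arr.shape}")


def write_montage(montage: ElectrodeMontage, path: str) -> None:
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x": montage.centers[:, 0],
            "y": montage.centers[:, 1],
            "z": montage.centers[:, 2],
            "contact_radius_m": montage.contact_radius,
            "z_ohm_m2": montage.z_contact,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_montage(path: str) -> pd.DataFrame:
    """Montage table as a DataFrame (geometry only; contact facets are
    recomputed against a mesh with :func:`reciprotes.mesh.place_electrodes`)."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z", "contact_radius_m", "z_ohm_m2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage TSV missing columns: {sorted(missing)}")
    return df


def write_pattern(labels, currents: np.ndarray, path: str) -> None:
    pd.DataFrame({"electrode_label": labels, "current_A": currents}).to_csv(
        path, index=False
    )


def read_pattern(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_topography(labels, potentials: np.ndarray, path: str) -> None:
    pd.DataFrame({"electrode_label": labels, "potential_V": potentials}).to_csv(
        path, index=False
    )
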