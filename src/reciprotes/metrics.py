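"""Performance metrics for a delivered current-density field.

Given the per-element current density J of a solved injection pattern and a
cortical target, the suite reports:

* **intensity** |J| and the **directional intensity** J·d at the target
  (volume-weighted ROI averages), plus the **directionality** — the
  normalized dot product in [−1, 1];
* **global targeting error**: distance from the target center to the center
  of gravity of the suprathreshold current density on the brain (elements
  above 75% of the maximum, weights |J|·V);
* **local targeting error**: same restricted to a 3 cm neighborhood of the
  target;
* **global focality**: radius of the target-centered sphere holding half of
  the total brain current density;
* **F_loc**: ratio of the density within 1 cm of the local CoG to the
  density within 3 cm of the target.

Weights are |J|_i·V_i throughout (the volume factor makes the measures
mesh-resolution independent); sphere membership is decided by element
centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh
from .targeting import Target

__all__ = [
    "MetricsReport",
    "target_intensity",
    "global_cog_te",
    "local_cog_te",
    "global_focality",
    "f_loc",
    "normal_component_map",
    "evaluate_field",
]

THRESHOLD_FRACTION = 0.75
LOCAL_RADIUS = 0.03
FLOC_R_IN = 0.01
FLOC_R_OUT = 0.03


@dataclass
class MetricsReport:
    """The six evaluation metrics of one pattern against one target."""

    intensity: float  # |J| at target, A/m²
    directional_intensity: float  # J·d at target, A/m² (signed)
    directionality: float  # normalized dot, [−1, 1]
    te_global: float  # m
    te_local: float  # m
    focality_global: float  # m
    f_loc: float  # unitless
    threshold_fraction: float = THRESHOLD_FRACTION
    local_radius: float = LOCAL_RADIUS

    def as_dict(self) -> dict:
        return {
            "intensity_A_per_m2": self.intensity,
            "directional_intensity_A_per_m2": self.directional_intensity,
            "directionality": self.directionality,
            "te_global_m": self.te_global,
            "te_local_m": self.te_local,
            "focality_global_m": self.focality_global,
            "f_loc": self.f_loc,
        }


def _brain_arrays(mesh: TetMesh, J: np.ndarray, brain_label: str):
    sel = mesh.tissue == brain_label
    cent = mesh.element_centroids[sel]
    vol = np.abs(mesh.element_volumes)[sel]
    jmag = np.linalg.norm(J[sel], axis=1)
    return cent, vol, jmag


def target_intensity(mesh: TetMesh, J: np.ndarray, target: Target):
    """Volume-weighted mean J over the ROI: (|J̄|, J̄·d, normalized dot)."""
    if target.elements.size == 0:
        raise ValueError("empty target ROI")
    vol = np.abs(mesh.element_volumes)[target.elements]
    Jbar = (J[target.elements] * vol[:, None]).sum(axis=0) / vol.sum()
    mag = float(np.linalg.norm(Jbar))
    directional = float(Jbar @ target.direction)
    return mag, directional, (directional / mag if mag > 0 else 0.0)


def global_cog_te(
    mesh: TetMesh,
    J: np.ndarray,
    target_center: np.ndarray,
    threshold_fraction: float = THRESHOLD_FRACTION,
    brain_label: str = "brain",
) -> float:
    """Distance from the target center to the |J|·V-weighted CoG of the
    suprathreshold (≥ 75% of max |J|) brain elements."""
    cent, vol, jmag = _brain_arrays(mesh, J, brain_label)
    cog = _weighted_cog(cent, vol, jmag, threshold_fraction)
    return float(np.linalg.norm(cog - np.asarray(target_center, dtype=float)))


def _weighted_cog(cent, vol, jmag, threshold_fraction):
    if jmag.size == 0 or jmag.max() == 0:
        raise ValueError("no current density on the brain")
    keep = jmag >= threshold_fraction * jmag.max()
    w = jmag[keep] * vol[keep]
    return (cent[keep] * w[:, None]).sum(axis=0) / w.sum()


def local_cog_te(
    mesh: TetMesh,
    J: np.ndarray,
    target: Target,
    radius: float = LOCAL_RADIUS,
    threshold_fraction: float = THRESHOLD_FRACTION,
    brain_label: str = "brain",
):
    """(local CoG, TE) restricted to brain elements within ``radius`` of the
    target center; the threshold is re-applied inside the neighborhood."""
    cent, vol, jmag = _brain_arrays(mesh, J, brain_label)
    near = np.linalg.norm(cent - target.center, axis=1) <= radius
    if not near.any():
        raise ValueError("no brain elements within the local neighborhood")
    cog = _weighted_cog(cent[near], vol[near], jmag[near], threshold_fraction)
    return cog, float(np.linalg.norm(cog - target.center))


def global_focality(
    mesh: TetMesh,
    J: np.ndarray,
    target_center: np.ndarray,
    brain_label: str = "brain",
) -> float:
    """Smallest radius of a target-centered sphere containing half of the
    total brain current density (mass |J|·V, elements by centroid)."""
    cent, vol, jmag = _brain_arrays(mesh, J, brain_label)
    mass = jmag * vol
    total = mass.sum()
    if total == 0:
        raise ValueError("no current density on the brain")
    dist = np.linalg.norm(cent - np.asarray(target_center, dtype=float), axis=1)
    order = np.argsort(dist, kind="stable")
    csum = np.cumsum(mass[order])
    k = int(np.searchsorted(csum, 0.5 * total))
    return float(dist[order][min(k, len(dist) - 1)])


def f_loc(
    mesh: TetMesh,
    J: np.ndarray,
    target: Target,
    local_cog: np.ndarray,
    r_in: float = FLOC_R_IN,
    r_out: float = FLOC_R_OUT,
    brain_label: str = "brain",
) -> float:
    """Local focality: density mass within ``r_in`` of the local CoG over the
    mass within ``r_out`` of the target.  Can exceed 1 when the local CoG
    sits far from the target (the inner sphere escapes the outer one); a
    warning is emitted in that case and the ratio reported as-is."""
    cent, vol, jmag = _brain_arrays(mesh, J, brain_label)
    mass = jmag * vol
    num = mass[np.linalg.norm(cent - np.asarray(local_cog), axis=1) <= r_in].sum()
    den = mass[np.linalg.norm(cent - target.center, axis=1) <= r_out].sum()
    if den == 0:
        warnings.warn("F_loc undefined: no density mass near the target")
        return float("nan")
    ratio = float(num / den)
    if ratio > 1.0:
        warnings.warn(
            "F_loc > 1: the local CoG lies so far from the target that the "
            "inner sphere is not contained in the outer one"
        )
    return ratio


def normal_component_map(
    mesh: TetMesh,
    J: np.ndarray,
    elements: np.ndarray,
    normals: np.ndarray,
) -> np.ndarray:
    """Signed J·n̂ for the given elements and their outward unit normals."""
    elements = np.asarray(elements, dtype=np.int64)
    normals = np.asarray(normals, dtype=float)
    return np.einsum("ij,ij->i", J[elements], normals)


def evaluate_field(
    mesh: TetMesh, J: np.ndarray, target: Target, brain_label: str = "brain"
) -> MetricsReport:
    """Full metric suite for one delivered current-density field."""
    mag, directional, norm_dot = target_intensity(mesh, J, target)
    te_g = global_cog_te(mesh, J, target.center, brain_label=brain_label)
    cog_l, te_l = local_cog_te(mesh, J, target, brain_label=brain_label)
    foc_g = global_focality(mesh, J, target.center, brain_label=brain_label)
    fl = f_loc(mesh, J, target, cog_l, brain_label=brain_label)
    return MetricsReport(
        intensity=mag,
        directional_intensity=directional,
        directionality=norm_dot,
        te_global=te_g,
        te_local=te_l,
        focality_global=foc_g,
        f_loc=fl,
    )
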