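"""Grid-level rotation analyses.

A rotation applied to every vector part of a quaternion grid models a
transcriptomic state transition; comparing the rotated grid with the
original highlights locations whose relative expression profile is (in)
variant under that transition.  For a unit vector part v and a rotation by
angle theta about axis u the per-cell difference length has the closed form

    | v - R v | = 2 |sin(theta / 2)| |v_perp|

where v_perp is the component of v orthogonal to u, so the map is zero
exactly where profiles align (or anti-align) with the rotation axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .algebra import (
    QuaternionArray,
    RotationQuaternion,
    make_rotation,
    rotate,
    rotation_between,
)
from .mapping import LocationQuaternions
from .st_io import QuaternionGrid

__all__ = [
    "DifferenceLengthMap",
    "RotationEstimate",
    "rotate_grid",
    "difference_length",
    "association_probe",
    "estimate_perturbation_rotation",
    "apply_perturbation",
]

DEGENERATE_MEAN_TOL = 1e-8


@dataclass
class DifferenceLengthMap:
    """Per-cell Euclidean length of the vector part of (original - rotated)."""

    values: np.ndarray  # (R, C), >= 0
    rotation: RotationQuaternion | None = None
    empty_mask: np.ndarray | None = None  # True where the grid cell is empty


@dataclass
class RotationEstimate:
    """A perturbation rotation with a pairwise-variability diagnostic.

    ``dispersion`` is ``1 - |mean of sign-aligned unit pairwise rotation
    quaternions|``: 0 when every control/perturbed pair is related by the
    same rotation, approaching 1 as the pairwise rotations decohere.
    """

    r: RotationQuaternion
    dispersion: float
    n_pairs: int


def rotate_grid(grid: QuaternionGrid, r: RotationQuaternion) -> QuaternionGrid:
    """Rotate the vector part of every cell; real parts and occupancy kept."""
    q = grid.quaternions
    pure = QuaternionArray(np.zeros_like(q.a), q.b, q.c, q.d)
    rot = rotate(r, pure)
    return QuaternionGrid(
        quaternions=QuaternionArray(q.a.copy(), rot.b, rot.c, rot.d),
        occupancy=grid.occupancy.copy(),
        row_edges=grid.row_edges,
        col_edges=grid.col_edges,
    )


def difference_length(Q, Qrot) -> DifferenceLengthMap:
    """Length of the vector part of (Q - Qrot), cell-wise; real parts ignored."""
    qa = Q.quaternions if isinstance(Q, QuaternionGrid) else Q
    qb = Qrot.quaternions if isinstance(Qrot, QuaternionGrid) else Qrot
    if qa.shape != qb.shape:
        raise ValueError(f"shape mismatch: {qa.shape} vs {qb.shape}")
    diff = np.sqrt((qa.b - qb.b) ** 2 + (qa.c - qb.c) ** 2 + (qa.d - qb.d) ** 2)
    empty = None
    if isinstance(Q, QuaternionGrid):
        from .st_io import OCC_EMPTY

        empty = Q.occupancy == OCC_EMPTY
    return DifferenceLengthMap(values=diff, empty_mask=empty)


def association_probe(grid: QuaternionGrid, axis, angle: float) -> DifferenceLengthMap:
    """Rotate about ``axis`` by ``angle`` and return the difference-length map.

    Low values mark cells whose profile aligns (or anti-aligns) with the
    probed association axis, e.g. ``axis=(1, 1, 1)`` for a joint positive
    association of the three vector features.
    """
    r = make_rotation(np.asarray(axis, dtype=float), angle)
    dmap = difference_length(grid, rotate_grid(grid, r))
    dmap.rotation = r
    return dmap


def _unit_vectors(subset) -> np.ndarray:
    if isinstance(subset, LocationQuaternions):
        q = subset.q
    elif isinstance(subset, QuaternionArray):
        q = subset
    else:
        q = QuaternionArray.pure(np.asarray(subset, dtype=float))
    vec = q.vector().reshape(-1, 3)
    norms = np.linalg.norm(vec, axis=1)
    keep = norms > 0
    return vec[keep] / norms[keep, None]


def _chordal_mean_direction(vec: np.ndarray, label: str) -> np.ndarray:
    mean = vec.mean(axis=0)
    n = np.linalg.norm(mean)
    if n < DEGENERATE_MEAN_TOL:
        raise ValueError(
            f"mean direction of {label} has length {n:.2e}: the directions cancel; "
            "inspect the subset for opposing profiles"
        )
    return mean / n


def estimate_perturbation_rotation(
    setA,
    setB,
    n_pairs: int = 1000,
    seed: int | None = None,
) -> RotationEstimate:
    """Estimate the rotation carrying the mean direction of ``setA`` (control)
    onto the mean direction of ``setB`` (perturbed).

    The average of each subset is the chordal mean: coefficient-wise mean of
    unit vector parts, renormalized.  The dispersion diagnostic is computed
    over up to ``n_pairs`` pairwise rotations (sampled without replacement,
    seeded) after resolving each unit quaternion's sign toward the first.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    va = _unit_vectors(setA)
    vb = _unit_vectors(setB)
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("both subsets must contain locations with non-zero vectors")
    mean_a = _chordal_mean_direction(va, "setA")
    mean_b = _chordal_mean_direction(vb, "setB")
    r = rotation_between(mean_a, mean_b)

    total = len(va) * len(vb)
    n_used = min(n_pairs, total)
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_used, replace=False)
    ia, ib = np.unravel_index(flat, (len(va), len(vb)))
    coeffs = np.array(
        [rotation_between(va[i], vb[j]).coeffs() for i, j in zip(ia, ib)]
    )
    # Resolve the double cover toward the first sampled rotation.
    signs = np.where(coeffs @ coeffs[0] < 0, -1.0, 1.0)
    mean_q = (coeffs * signs[:, None]).mean(axis=0)
    dispersion = float(1.0 - np.linalg.norm(mean_q))
    return RotationEstimate(r=r, dispersion=dispersion, n_pairs=n_used)


def apply_perturbation(
    grid: QuaternionGrid, est: RotationEstimate, mask: np.ndarray | None = None
) -> QuaternionGrid:
    """Apply an estimated perturbation rotation to the masked cells of a grid."""
    if mask is None:
        return rotate_grid(grid, est.r)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    if not mask.any():
        warnings.warn("empty mask: returning the grid unchanged", UserWarning)
        return QuaternionGrid(
            quaternions=grid.quaternions.copy(),
            occupancy=grid.occupancy.copy(),
            row_edges=grid.row_edges,
            col_edges=grid.col_edges,
        )
    rotated = rotate_grid(grid, est.r)
    q = grid.quaternions
    out = QuaternionArray(
        q.a.copy(),
        np.where(mask, rotated.quaternions.b, q.b),
        np.where(mask, rotated.quaternions.c, q.c),
        np.where(mask, rotated.quaternions.d, q.d),
    )
    return QuaternionGrid(
        quaternions=out,
        occupancy=grid.occupancy.copy(),
        row_edges=grid.row_edges,
        col_edges=grid.col_edges,
    )
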