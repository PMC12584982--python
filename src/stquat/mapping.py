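"""Mapping ST count data to per-location quaternions.

Three models are provided.  The SVD model projects the unnormalized count
matrix X onto its first four singular vectors, P = U4 D4, and sets

    q_i = ( |p_i1|,  p_i2 / l_i,  p_i3 / l_i,  p_i4 / l_i ),
    l_i = sqrt(p_i2^2 + p_i3^2 + p_i4^2).

For raw counts the first singular direction is close to the library-size
direction, so the real part tracks sequencing depth (hence certainty of the
relative profile) while the unit vector part encodes the rank-3 relative
expression profile.  Locations sharing one relative profile lie on a single
line through the origin in projection space, so their unit vectors coincide
and their real parts scale with depth.

The gene model instead uses three named genes (optionally after a reduced
rank reconstruction of X), and the gene-set model assembles quaternions
from caller-supplied per-location scores for three gene sets.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import numpy as np

from .algebra import QuaternionArray
from .st_io import STCounts

__all__ = [
    "RankWarning",
    "SVDFactors",
    "LocationQuaternions",
    "svd_model",
    "gene_model",
    "geneset_model",
]

# Exact SVD below this many locations; randomized (top-4 only) above.
RANDOMIZED_SVD_THRESHOLD = 50_000


class RankWarning(UserWarning):
    """Count matrix has effective rank below the 4 factors the model uses."""


@dataclass
class SVDFactors:
    """Sign-fixed singular factors of the count matrix and the projection
    P = U4 D4 onto the first four singular vectors."""

    U: np.ndarray
    D: np.ndarray
    V: np.ndarray

    @property
    def projection(self) -> np.ndarray:
        k = min(4, len(self.D))
        P = self.U[:, :k] * self.D[:k]
        if k < 4:  # pad so the quaternion coefficients always exist
            P = np.pad(P, ((0, 0), (0, 4 - k)))
        return P


@dataclass
class LocationQuaternions:
    """Per-location quaternions with their depth and vector-projection length."""

    q: QuaternionArray  # shape (n,)
    depth: np.ndarray  # real parts, >= 0
    vec_length: np.ndarray  # l_i, Euclidean length of the rank-3 projection

    def __len__(self):
        return len(self.depth)


def _fix_svd_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the per-component sign ambiguity of the SVD.

    For each singular pair, flip signs so the entry of the V column with the
    largest magnitude is positive (ties resolved to the lowest index by
    argmax).  Makes repeated runs bit-identical.
    """
    U = U.copy()
    V = V.copy()
    for k in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, k])))
        if V[idx, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, V


def _svd(X: np.ndarray, randomized: bool, seed) -> SVDFactors:
    if randomized:
        from sklearn.utils.extmath import randomized_svd

        U, D, Vt = randomized_svd(X, n_components=4, random_state=seed)
    else:
        U, D, Vt = np.linalg.svd(X, full_matrices=False)
    U, V = _fix_svd_signs(U, Vt.T)
    return SVDFactors(U=U, D=D, V=V)


def _effective_rank(D: np.ndarray, shape) -> int:
    if len(D) == 0 or D[0] == 0:
        return 0
    tol = D[0] * max(shape) * np.finfo(float).eps
    return int(np.sum(D > tol))


def _assemble(P: np.ndarray) -> LocationQuaternions:
    depth = np.abs(P[:, 0])
    vec = P[:, 1:4].copy()
    length = np.linalg.norm(vec, axis=1)
    nz = length > 0
    vec[nz] /= length[nz, None]
    vec[~nz] = 0.0
    q = QuaternionArray(depth, vec[:, 0], vec[:, 1], vec[:, 2])
    return LocationQuaternions(q=q, depth=depth, vec_length=length)


def svd_model(
    counts: STCounts,
    randomized: bool | None = None,
    seed: int | None = None,
) -> LocationQuaternions:
    """Map locations to quaternions via the rank-4 SVD projection.

    ``randomized=None`` selects the exact SVD below
    ``RANDOMIZED_SVD_THRESHOLD`` locations and a seeded randomized top-4 SVD
    above it.
    """
    X = np.asarray(counts.counts, dtype=float)
    n, p = X.shape
    if n < 4 or p < 4:
        raise ValueError(f"SVD model needs at least 4 locations and 4 genes, got {n}x{p}")
    if not np.any(X):
        raise ValueError("count matrix is all zero")
    if randomized is None:
        randomized = n >= RANDOMIZED_SVD_THRESHOLD
    factors = _svd(X, randomized, seed)
    rank = _effective_rank(factors.D, X.shape)
    if rank < 2:
        raise ValueError(
            f"count matrix has effective rank {rank}; the rank-3 vector part is "
            "undefined — consider the gene model"
        )
    if rank < 4:
        warnings.warn(
            f"count matrix has effective rank {rank} < 4; vector directions span "
            "a reduced subspace (consider the gene model)",
            RankWarning,
            stacklevel=2,
        )
    loc = _assemble(factors.projection)
    zero_rows = ~np.any(X, axis=1)
    if np.any(zero_rows):
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero locations mapped to the zero quaternion",
            UserWarning,
            stacklevel=2,
        )
        for plane in (loc.q.a, loc.q.b, loc.q.c, loc.q.d):
            plane[zero_rows] = 0.0
        loc.depth[zero_rows] = 0.0
        loc.vec_length[zero_rows] = 0.0
    return loc


def _gene_indices(counts: STCounts, genes) -> list[int]:
    index = {str(g): k for k, g in enumerate(counts.gene_ids)}
    idx = []
    for g in genes:
        g = str(g)
        if g not in index:
            near = difflib.get_close_matches(g, index.keys(), n=3, cutoff=0.4)
            raise KeyError(f"gene {g!r} not found; near-matches: {near}")
        idx.append(index[g])
    return idx


def gene_model(
    counts: STCounts,
    genes,
    recon_rank: int = 0,
    real_part: str = "total",
    normalize: bool = False,
) -> LocationQuaternions:
    """Map locations to quaternions from three named genes.

    ``recon_rank=0`` uses the (optionally library-size normalized) expression
    directly; ``recon_rank=r`` first reconstructs the matrix at rank ``r``
    from its truncated SVD.  The vector part is the three genes' values
    renormalized to unit length; the real part is the location's total
    library size (``real_part="total"``) or the summed raw counts of the
    three genes (``real_part="genes"``).
    """
    if len(genes) != 3:
        raise ValueError("gene model needs exactly 3 gene ids")
    if real_part not in ("total", "genes"):
        raise ValueError("real_part must be 'total' or 'genes'")
    idx = _gene_indices(counts, genes)
    X = np.asarray(counts.counts, dtype=float)
    n, p = X.shape
    if recon_rank < 0 or recon_rank > min(n, p):
        raise ValueError(f"recon_rank must be in [0, {min(n, p)}]")
    lib = X.sum(axis=1)
    if normalize:
        scale = np.where(lib > 0, lib, 1.0)
        X = X / scale[:, None] * np.median(lib[lib > 0]) if np.any(lib > 0) else X
    if recon_rank > 0:
        U, D, Vt = np.linalg.svd(X, full_matrices=False)
        r = recon_rank
        X = (U[:, :r] * D[:r]) @ Vt[:r]
    vec = X[:, idx].copy()
    length = np.linalg.norm(vec, axis=1)
    nz = length > 0
    vec[nz] /= length[nz, None]
    vec[~nz] = 0.0
    depth = lib if real_part == "total" else counts.counts[:, idx].sum(axis=1).astype(float)
    q = QuaternionArray(depth, vec[:, 0], vec[:, 1], vec[:, 2])
    return LocationQuaternions(q=q, depth=depth, vec_length=length)


def geneset_model(scores: np.ndarray, depth: np.ndarray) -> LocationQuaternions:
    """Assemble quaternions from per-location scores of three gene sets.

    Scoring (e.g. gene-set enrichment or cell-type deconvolution proportions)
    is up to the caller; this only row-normalizes the scores into the unit
    vector part and places ``depth`` in the real part.
    """
    scores = np.asarray(scores, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 3:
        raise ValueError("scores must be an (n, 3) matrix")
    if len(depth) != len(scores):
        raise ValueError("depth length must match scores rows")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    vec = scores.copy()
    length = np.linalg.norm(vec, axis=1)
    nz = length > 0
    vec[nz] /= length[nz, None]
    vec[~nz] = 0.0
    if np.any(~nz):
        warnings.warn(
            f"{int((~nz).sum())} all-zero score rows mapped to a zero vector part",
            UserWarning,
            stacklevel=2,
        )
    q = QuaternionArray(depth, vec[:, 0], vec[:, 1], vec[:, 2])
    return LocationQuaternions(q=q, depth=depth, vec_length=length)
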