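"""Reading ST count data and rasterizing per-location quaternions to grids.

Supported inputs are the 10x-style sparse triplet layout (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped, genes x barcodes and
transposed on read) and a dense CSV (locations x genes, header row of gene
ids, first column location ids).  Coordinates come from a CSV with columns
``(location id, x, y)`` or ``(location id, array_row, array_col)``.

A :class:`QuaternionGrid` rasterizes per-location quaternions onto an
R x C image-convention grid (descending y = increasing row index).  Cells
inside the tissue that receive no location can optionally be filled with
the average of their non-empty 8-neighbours, iterated until stable.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy.spatial import Delaunay, QhullError

from .algebra import QuaternionArray

__all__ = [
    "STCounts",
    "QuaternionGrid",
    "OCC_EMPTY",
    "OCC_OBSERVED",
    "OCC_FILLED",
    "read_counts",
    "read_coords",
    "write_counts",
    "write_coords",
    "build_grid",
    "write_grid",
    "read_grid",
]

# Occupancy flags: each grid cell carries exactly one of these.
OCC_EMPTY = 0
OCC_OBSERVED = 1
OCC_FILLED = 2

MAX_FILL_PASSES = 10


@dataclass
class STCounts:
    """Unnormalized UMI counts for p genes at n tissue locations."""

    counts: np.ndarray  # (n, p) non-negative integers
    gene_ids: list
    location_ids: list
    coords: np.ndarray | None = None  # (n, 2) of (x, y)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (locations x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be integer-valued")
        n, p = self.counts.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} genes")
        if len(self.location_ids) != n:
            raise ValueError(f"{len(self.location_ids)} location ids for {n} locations")
        if len(set(self.location_ids)) != n:
            raise ValueError("duplicate location ids")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError(f"coords shape {self.coords.shape} != ({n}, 2)")

    @property
    def n_locations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_size(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class QuaternionGrid:
    """R x C quaternion raster of a tissue with an occupancy mask."""

    quaternions: QuaternionArray  # shape (R, C)
    occupancy: np.ndarray  # (R, C) int8 in {OCC_EMPTY, OCC_OBSERVED, OCC_FILLED}
    row_edges: np.ndarray = field(default=None)  # descending y bin edges, len R+1
    col_edges: np.ndarray = field(default=None)  # ascending x bin edges, len C+1

    def __post_init__(self):
        if self.quaternions.ndim != 2:
            raise ValueError("grid quaternions must be 2-D")
        self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
        if self.occupancy.shape != self.quaternions.shape:
            raise ValueError("occupancy shape must match quaternion shape")

    @property
    def shape(self):
        return self.quaternions.shape


def _open_maybe_gz(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_10x_file(directory, stem):
    for name in (f"{stem}.gz", stem):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no {stem}(.gz) in {directory}")


def _read_10x_dir(directory) -> STCounts:
    mtx_path = _find_10x_file(directory, "matrix.mtx")
    feat_path = _find_10x_file(directory, "features.tsv")
    bc_path = _find_10x_file(directory, "barcodes.tsv")
    mat = scio.mmread(mtx_path)  # genes x barcodes triplets
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    with _open_maybe_gz(feat_path) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if dense.shape[0] != len(genes):
        raise ValueError(
            f"features.tsv lists {len(genes)} genes but matrix has {dense.shape[0]} rows"
        )
    if dense.shape[1] != len(barcodes):
        raise ValueError(
            f"barcodes.tsv lists {len(barcodes)} barcodes but matrix has "
            f"{dense.shape[1]} columns"
        )
    return STCounts(counts=dense.T, gene_ids=genes, location_ids=barcodes)


def _read_dense_csv(path) -> STCounts:
    df = pd.read_csv(path, index_col=0)
    return STCounts(
        counts=df.to_numpy(),
        gene_ids=[str(g) for g in df.columns],
        location_ids=[str(i) for i in df.index],
    )


def read_counts(path, format: str | None = None) -> STCounts:
    """Read a count matrix as locations x genes.

    ``format`` is ``"mtx"`` (a 10x triplet directory) or ``"csv"`` (dense);
    inferred from the path when omitted.
    """
    if format is None:
        format = "mtx" if os.path.isdir(path) else "csv"
    if format == "mtx":
        return _read_10x_dir(path)
    if format == "csv":
        return _read_dense_csv(path)
    raise ValueError(f"unknown counts format {format!r}")


def read_coords(path, counts: STCounts | None = None) -> np.ndarray:
    """Read per-location coordinates and, if ``counts`` is given, align them
    to its location order and attach them.

    The CSV must have a location-id column followed by two coordinate columns
    (``x, y`` or ``array_row, array_col``).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError("coordinates CSV needs (location id, x, y) columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate location ids in coordinates: {dups[:5]}")
    xy = df.iloc[:, 1:3].to_numpy(dtype=float)
    if counts is None:
        return xy
    index = {i: k for k, i in enumerate(ids)}
    missing = [str(i) for i in counts.location_ids if str(i) not in index]
    extra = [i for i in ids if i not in {str(j) for j in counts.location_ids}]
    if missing:
        raise ValueError(
            f"{len(missing)} locations lack coordinates (e.g. {missing[:5]}); "
            f"{len(extra)} coordinate rows are unmatched"
        )
    aligned = np.array([xy[index[str(i)]] for i in counts.location_ids])
    counts.coords = aligned
    return aligned


def write_counts(counts: STCounts, path) -> None:
    """Write counts as the dense CSV dialect read by :func:`read_counts`."""
    df = pd.DataFrame(
        counts.counts, index=counts.location_ids, columns=counts.gene_ids
    )
    df.to_csv(path, index_label="location")


def write_coords(counts: STCounts, path) -> None:
    """Write per-location coordinates as (location, x, y) CSV."""
    if counts.coords is None:
        raise ValueError("counts carry no coordinates")
    df = pd.DataFrame(
        {"location": counts.location_ids,
         "x": counts.coords[:, 0],
         "y": counts.coords[:, 1]}
    )
    df.to_csv(path, index=False)


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open uniform bins [e_k, e_{k+1}), final bin closed on the right."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def build_grid(
    q: QuaternionArray,
    coords: np.ndarray,
    rows: int,
    cols: int,
    fill: bool = True,
) -> QuaternionGrid:
    """Rasterize per-location quaternions into an ``rows x cols`` grid.

    Locations are binned over the coordinate extent (x to columns, y to rows
    with descending y mapping to increasing row index).  Locations colliding
    in one cell are averaged coefficient-wise and the vector part is
    renormalized to unit length.  With ``fill=True``, empty cells inside the
    convex hull of the observed cells are replaced by the mean of their
    non-empty 8-neighbours (vector part renormalized), iterating up to
    ``MAX_FILL_PASSES`` passes.
    """
    coords = np.asarray(coords, dtype=float)
    if rows < 2 or cols < 2:
        raise ValueError("grid needs rows >= 2 and cols >= 2")
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] != len(q.a):
        raise ValueError("coords must be (n, 2) matching the quaternion count")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    x, y = coords[:, 0], coords[:, 1]
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        raise ValueError("degenerate extent: all coordinates identical")

    col_edges = np.linspace(x.min(), x.max(), cols + 1) if np.ptp(x) > 0 else None
    row_edges_y = np.linspace(y.min(), y.max(), rows + 1) if np.ptp(y) > 0 else None
    ci = _bin_indices(x, col_edges) if col_edges is not None else np.zeros(len(x), int)
    if row_edges_y is not None:
        ri = rows - 1 - _bin_indices(y, row_edges_y)  # image convention
    else:
        ri = np.zeros(len(y), int)

    planes = np.zeros((4, rows, cols))
    counts = np.zeros((rows, cols))
    coeffs = q.coeffs()
    np.add.at(counts, (ri, ci), 1.0)
    for p in range(4):
        np.add.at(planes[p], (ri, ci), coeffs[..., p])
    occ = np.where(counts > 0, OCC_OBSERVED, OCC_EMPTY).astype(np.int8)
    nz = counts > 0
    for p in range(4):
        planes[p][nz] /= counts[nz]
    # Renormalize the vector part where >1 location landed in a cell.
    multi = counts > 1
    vlen = np.sqrt(planes[1] ** 2 + planes[2] ** 2 + planes[3] ** 2)
    renorm = multi & (vlen > 0)
    for p in (1, 2, 3):
        planes[p][renorm] /= vlen[renorm]

    if fill:
        planes, occ = _fill_holes(planes, occ)

    grid = QuaternionGrid(
        quaternions=QuaternionArray(*planes),
        occupancy=occ,
        row_edges=row_edges_y[::-1] if row_edges_y is not None else None,
        col_edges=col_edges,
    )
    return grid


def _interior_mask(occ: np.ndarray) -> np.ndarray:
    """Cells inside the convex hull of the observed cells."""
    pts = np.argwhere(occ == OCC_OBSERVED)
    rows, cols = occ.shape
    if len(pts) < 3:
        return np.zeros_like(occ, dtype=bool)
    try:
        tri = Delaunay(pts.astype(float))
    except QhullError:
        # Degenerate (e.g. collinear) observations: fall back to bounding box.
        box = np.zeros_like(occ, dtype=bool)
        r0, c0 = pts.min(axis=0)
        r1, c1 = pts.max(axis=0)
        box[r0 : r1 + 1, c0 : c1 + 1] = True
        return box
    rr, cc = np.mgrid[0:rows, 0:cols]
    inside = tri.find_simplex(np.column_stack([rr.ravel(), cc.ravel()])) >= 0
    return inside.reshape(rows, cols)


def _fill_holes(planes: np.ndarray, occ: np.ndarray):
    interior = _interior_mask(occ)
    rows, cols = occ.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for _ in range(MAX_FILL_PASSES):
        holes = np.argwhere((occ == OCC_EMPTY) & interior)
        if len(holes) == 0:
            break
        new_planes = planes.copy()
        new_occ = occ.copy()
        changed = False
        for r, c in holes:
            acc = np.zeros(4)
            n = 0
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and occ[rr, cc] != OCC_EMPTY:
                    acc += planes[:, rr, cc]
                    n += 1
            if n == 0:
                continue
            acc /= n
            vlen = np.linalg.norm(acc[1:])
            if vlen > 0:
                acc[1:] /= vlen
            new_planes[:, r, c] = acc
            new_occ[r, c] = OCC_FILLED
            changed = True
        planes, occ = new_planes, new_occ
        if not changed:
            break
    return planes, occ


def write_grid(grid: QuaternionGrid, path, frequency_domain: bool = False) -> None:
    """Write the four coefficient planes + occupancy to a self-describing
    NumPy ``.npz`` container (bit-faithful round trip)."""
    data = {
        "a": grid.quaternions.a,
        "b": grid.quaternions.b,
        "c": grid.quaternions.c,
        "d": grid.quaternions.d,
        "occupancy": grid.occupancy,
        "frequency_domain": np.array(bool(frequency_domain)),
    }
    if grid.row_edges is not None:
        data["row_edges"] = grid.row_edges
    if grid.col_edges is not None:
        data["col_edges"] = grid.col_edges
    np.savez(path, **data)


def read_grid(path) -> QuaternionGrid:
    with np.load(path) as z:
        for plane in ("a", "b", "c", "d", "occupancy"):
            if plane not in z:
                raise ValueError(f"grid container missing plane {plane!r}")
        return QuaternionGrid(
            quaternions=QuaternionArray(z["a"], z["b"], z["c"], z["d"]),
            occupancy=z["occupancy"],
            row_edges=z["row_edges"] if "row_edges" in z else None,
            col_edges=z["col_edges"] if "col_edges" in z else None,
        )
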