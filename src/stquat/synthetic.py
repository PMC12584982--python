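"""Synthetic ST count data for exercising every analysis stage.

Two generators are provided.  ``simulate_fig1`` builds the canonical
multi-population worked example: 30 locations and five genes split into
three populations with fixed relative-abundance profiles

    population 1: (0.5, 0.2, 0.1, 0.1, 0.1)
    population 2: (0.1, 0.1, 0.1, 0.2, 0.5)
    population 3: (0.1, 0.3, 0.3, 0.2, 0.1)

and, within each population, library sizes scaling linearly over a 1-to-10
range (ten equally spaced multiples of a base depth; the default base of 100
keeps every count integral).  Noise-free, each population's rows are exact
scalar multiples of one profile, so the SVD projection places them on a
single line through the origin — the property the quaternion mapping relies
on.

``simulate_domains`` lays one location per cell of an R x C raster and
assigns each cell a profile through a domain map (half-planes, quadrants or
a disk), optionally with multinomial sampling noise.  These spatially
structured fixtures exercise grid building, filtering and the edge-detecting
(bi)convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .st_io import STCounts

__all__ = [
    "FIG1_PROFILES",
    "SimSpec",
    "simulate_fig1",
    "simulate_domains",
    "half_plane_map",
    "quadrant_map",
    "disk_map",
]

FIG1_PROFILES = np.array(
    [
        [0.5, 0.2, 0.1, 0.1, 0.1],
        [0.1, 0.1, 0.1, 0.2, 0.5],
        [0.1, 0.3, 0.3, 0.2, 0.1],
    ]
)
FIG1_LOCATIONS_PER_POP = 10


@dataclass
class SimSpec:
    """Parameters of a multi-population count simulation."""

    profiles: np.ndarray  # (n_pop, p), rows sum to 1
    library_sizes: np.ndarray  # per-location positive depths
    assignment: np.ndarray  # per-location profile index
    noise: str = "none"  # "none" | "multinomial"
    seed: int | None = None

    def __post_init__(self):
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if np.any(self.profiles < 0):
            raise ValueError("profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("each profile must sum to 1")
        if self.noise not in ("none", "multinomial"):
            raise ValueError("noise must be 'none' or 'multinomial'")
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min() < 0 or self.assignment.max() >= len(self.profiles):
            raise ValueError("profile index out of range")
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")


def _draw_counts(spec: SimSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    n = len(spec.assignment)
    p = spec.profiles.shape[1]
    counts = np.zeros((n, p), dtype=int)
    for i in range(n):
        prof = spec.profiles[spec.assignment[i]]
        size = spec.library_sizes[i]
        if spec.noise == "multinomial":
            counts[i] = rng.multinomial(int(round(size)), prof)
        else:
            counts[i] = np.round(size * prof).astype(int)
    return counts


def simulate_fig1(base_depth: int = 100) -> STCounts:
    """The three-population worked example: 30 locations x 5 genes, noise
    free, with within-population depths ``base_depth * (1, 2, ..., 10)``.

    Locations are laid out on a 3 x 10 raster (one row per population) so
    the result can also feed the grid pipeline.
    """
    per = FIG1_LOCATIONS_PER_POP
    assignment = np.repeat(np.arange(3), per)
    sizes = np.tile(base_depth * np.arange(1, per + 1, dtype=float), 3)
    spec = SimSpec(
        profiles=FIG1_PROFILES,
        library_sizes=sizes,
        assignment=assignment,
        noise="none",
    )
    counts = _draw_counts(spec)
    coords = np.column_stack(
        [np.tile(np.arange(per, dtype=float), 3), np.repeat(np.arange(3, 0, -1.0), per)]
    )
    return STCounts(
        counts=counts,
        gene_ids=[f"gene{g + 1}" for g in range(5)],
        location_ids=[f"loc{i + 1}" for i in range(3 * per)],
        coords=coords,
    )


def half_plane_map(rows: int, cols: int, orientation: str = "vertical") -> np.ndarray:
    """Two domains split by a vertical (left/right) or horizontal boundary."""
    rr, cc = np.mgrid[0:rows, 0:cols]
    if orientation == "vertical":
        return (cc >= cols // 2).astype(int)
    if orientation == "horizontal":
        return (rr >= rows // 2).astype(int)
    raise ValueError("orientation must be 'vertical' or 'horizontal'")


def quadrant_map(rows: int, cols: int) -> np.ndarray:
    """Four domains, one per quadrant."""
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (rr >= rows // 2).astype(int) * 2 + (cc >= cols // 2).astype(int)


def disk_map(rows: int, cols: int, radius: float | None = None) -> np.ndarray:
    """Domain 1 inside a central disk, domain 0 outside."""
    if radius is None:
        radius = min(rows, cols) / 4.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    dist = np.sqrt((rr - (rows - 1) / 2.0) ** 2 + (cc - (cols - 1) / 2.0) ** 2)
    return (dist <= radius).astype(int)


def simulate_domains(
    rows: int,
    cols: int,
    domain_map: np.ndarray,
    profiles: np.ndarray,
    depth_range: tuple[float, float] = (100.0, 1000.0),
    noise: str = "none",
    seed: int | None = None,
) -> STCounts:
    """Spatially structured counts with one location per grid cell.

    ``domain_map`` (R x C of profile indices) assigns each cell a
    relative-abundance profile; library sizes ramp linearly in raster order
    from ``depth_range[0]`` to ``depth_range[1]``.  With
    ``noise="multinomial"`` the counts are multinomial draws at each cell's
    depth (seeded); otherwise deterministic rounding.
    """
    domain_map = np.asarray(domain_map, dtype=int)
    if domain_map.shape != (rows, cols):
        raise ValueError(f"domain_map shape {domain_map.shape} != ({rows}, {cols})")
    n = rows * cols
    lo, hi = float(depth_range[0]), float(depth_range[1])
    sizes = np.linspace(lo, hi, n) if n > 1 else np.array([lo])
    spec = SimSpec(
        profiles=profiles,
        library_sizes=sizes,
        assignment=domain_map.ravel(),
        noise=noise,
        seed=seed,
    )
    counts = _draw_counts(spec)
    rr, cc = np.mgrid[0:rows, 0:cols]
    # x = column, y descending with row (image convention used by build_grid)
    coords = np.column_stack([cc.ravel().astype(float), (rows - 1 - rr).ravel().astype(float)])
    p = spec.profiles.shape[1]
    return STCounts(
        counts=counts,
        gene_ids=[f"gene{g + 1}" for g in range(p)],
        location_ids=[f"cell_{r}_{c}" for r, c in zip(rr.ravel(), cc.ravel())],
        coords=coords,
    )
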