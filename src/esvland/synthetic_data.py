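"""Synthetic multi-date landscapes with known ground truth.

Emulates what a Landsat-derived 6-class LULC raster series supplies to the
pipeline: an initial categorical map with chosen class proportions and
optional patchiness, a per-pixel Markov sampling model that evolves it under
a prescribed row-stochastic transition matrix, and a rectangular zone tiling
standing in for administrative regions.  Every generator is deterministic
under a fixed seed.

The per-pixel sampling model treats pixels as independent draws — the
statistical idealisation under which transition-matrix recovery tests are
exact; real land change is spatially dependent.  Patchiness is produced by
majority-filtering an i.i.d. field, which is enough to exercise the CA's
contiguity suitability without a geostatistical simulator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .land_cover_io import CategoryScheme, LandCoverGrid, SIX_CLASS_SCHEME, codes_to_indices

__all__ = ["SyntheticLandscapeSpec", "generate_initial", "evolve", "generate_zones"]


@dataclasses.dataclass
class SyntheticLandscapeSpec:
    """Recipe for a synthetic landscape.

    class_proportions
        Target class shares (simplex over the scheme's classes).  The
        default mix is a plausible arid-basin composition: grassland and
        unutilized desert dominant, moderate cropland, little forest, water
        and built-up land.
    transition_matrix
        Row-stochastic matrix used by :func:`evolve`.
    autocorrelation
        Majority-filter radius applied to the i.i.d. field; 0 keeps pixels
        independent.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_proportions: tuple[float, ...] = (0.04, 0.43, 0.11, 0.03, 0.01, 0.38)
    transition_matrix: np.ndarray | None = None
    autocorrelation: int = 0
    n_zones: int = 1
    seed: int = 0
    scheme: CategoryScheme = SIX_CLASS_SCHEME

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("class proportions must be non-negative")
        if p.shape != (self.scheme.n_classes,):
            raise ValueError(
                f"need {self.scheme.n_classes} proportions, got {p.shape}"
            )
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"class proportions must sum to 1, got {p.sum()}")
        if self.autocorrelation < 0:
            raise ValueError("autocorrelation radius must be ≥ 0")
        if self.n_zones < 1:
            raise ValueError("n_zones must be ≥ 1")


def generate_initial(spec: SyntheticLandscapeSpec) -> LandCoverGrid:
    """Draw a categorical map with the spec's class proportions.

    Pixels are sampled i.i.d.; with ``autocorrelation`` r > 0 the field is
    then majority-filtered over a (2r+1)² window, producing contiguous
    patches (this shifts proportions slightly toward the majority classes).
    """
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.class_proportions, dtype=float)
    idx = rng.choice(spec.scheme.n_classes, size=spec.shape, p=p)
    if spec.autocorrelation > 0:
        idx = _majority_filter(idx, spec.autocorrelation, spec.scheme.n_classes)
    values = np.asarray(spec.scheme.codes)[idx]
    return LandCoverGrid(values=values, cell_size=spec.cell_size, scheme=spec.scheme)


def _majority_filter(idx: np.ndarray, radius: int, n_classes: int) -> np.ndarray:
    size = 2 * radius + 1
    kernel = np.ones((size, size))
    counts = np.stack(
        [ndimage.correlate((idx == k).astype(float), kernel, mode="constant") for k in range(n_classes)]
    )
    return counts.argmax(axis=0)


def evolve(
    grid: LandCoverGrid,
    transition_matrix: np.ndarray,
    steps: int = 1,
    seed: int = 0,
) -> LandCoverGrid:
    """Resample every pixel's class from its transition-matrix row, ``steps`` times.

    Pixels are independent, so expected class areas follow the matrix-power
    projection exactly; nodata pixels are left untouched.
    """
    A = np.asarray(transition_matrix, dtype=float)
    n = grid.scheme.n_classes
    if A.shape != (n, n):
        raise ValueError(f"transition matrix must be {n}×{n}")
    if not np.allclose(A.sum(axis=1), 1.0):
        raise ValueError("transition-matrix rows must sum to 1")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(A, axis=1)
    cdf[:, -1] = 1.0  # guard accumulation error
    codes = np.asarray(grid.scheme.codes)
    values = grid.values.copy()
    valid = grid.valid_mask
    idx = codes_to_indices(grid.scheme, values[valid])
    for _ in range(steps):
        u = rng.random(idx.shape)
        idx = (u[:, None] > cdf[idx]).sum(axis=1)
    values[valid] = codes[idx]
    return LandCoverGrid(values=values, cell_size=grid.cell_size, scheme=grid.scheme, origin=grid.origin)


def generate_zones(spec: SyntheticLandscapeSpec) -> np.ndarray:
    """Tile the grid into ``n_zones`` contiguous rectangles, labels 1..n_zones.

    The tiling is as square as the zone count allows (16 zones on 400×400 →
    a 4×4 grid of 100×100 tiles); uneven divisions split as evenly as
    possible.
    """
    rows, cols = spec.shape
    n = spec.n_zones
    if n > rows * cols:
        raise ValueError(f"n_zones={n} exceeds the pixel count {rows * cols}")
    zr = int(np.sqrt(n))
    while n % zr != 0:
        zr -= 1
    zc = n // zr
    if rows < zr or cols < zc:
        # fall back to a 1×n strip split along the longer axis
        zr, zc = (n, 1) if rows >= cols else (1, n)
    row_edges = np.linspace(0, rows, zr + 1).astype(int)
    col_edges = np.linspace(0, cols, zc + 1).astype(int)
    zones = np.zeros(spec.shape, dtype=np.int32)
    label = 1
    for i in range(zr):
        for j in range(zc):
            zones[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = label
            label += 1
    return zones
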