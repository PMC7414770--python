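"""Cellular-automaton half of CA-Markov: spatial allocation of projected areas.

The Markov chain says how much area each class gains or loses; the CA says
where.  Each pixel's affinity for class j is its neighbourhood density of j
(a contiguity filter over a (2r+1)×(2r+1) window), weighted by the Markov
probability of its current class converting to j.  Pixels are then assigned
to classes by a global greedy ranking under hard per-class quotas obtained
from the projected areas by largest-remainder rounding, so realised pixel
counts meet the Markov marginals exactly.

The only stochastic element is an additive seeded jitter (ε = 1e-9 of the
score scale) used to break ties reproducibly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .land_cover_io import LandCoverGrid, codes_to_indices, cross_tabulate, tabulate_areas
from .markov import TransitionProbabilityMatrix, estimate_probabilities, project_areas

__all__ = [
    "CAParams",
    "SuitabilityStack",
    "neighborhood_suitability",
    "largest_remainder_quotas",
    "allocate",
    "run_prediction",
]

_JITTER_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class CAParams:
    """Tuning knobs of the allocation step.

    kernel_radius
        Half-width r of the contiguity window; the default 2 gives the
        classical 5×5 filter.
    iterations
        Allocation passes per projection step.  Each pass recomputes
        suitability from the current map; quotas stay fixed within a step.
    seed
        Seed of the tie-breaking jitter — the only randomness.
    quota_tolerance
        Maximum allowed relative deviation (of total landscape area) between
        realised and target class areas after rounding to whole pixels.
    """

    kernel_radius: int = 2
    iterations: int = 1
    seed: int = 0
    quota_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.kernel_radius < 1:
            raise ValueError("kernel_radius must be ≥ 1")
        if self.iterations < 1:
            raise ValueError("iterations must be ≥ 1")
        if self.quota_tolerance < 0:
            raise ValueError("quota_tolerance must be ≥ 0")


@dataclasses.dataclass
class SuitabilityStack:
    """One non-negative suitability surface per class, in scheme order."""

    layers: np.ndarray  # (n_classes, rows, cols)

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("suitability stack must be (n_classes, rows, cols)")
        if not np.isfinite(self.layers).all() or (self.layers < 0).any():
            raise ValueError("suitability values must be finite and non-negative")


def neighborhood_suitability(grid: LandCoverGrid, params: CAParams) -> SuitabilityStack:
    """Per-class neighbourhood density with edge truncation.

    The suitability of class c at a pixel is the fraction of valid pixels in
    the (2r+1)×(2r+1) window centred there (window clipped at the raster
    edge) that carry class c.  Values lie in [0, 1] and, where the window
    holds no nodata, sum to 1 across classes.
    """
    size = 2 * params.kernel_radius + 1
    kernel = np.ones((size, size))
    valid = grid.valid_mask.astype(float)
    denom = ndimage.correlate(valid, kernel, mode="constant", cval=0.0)
    layers = np.zeros((grid.scheme.n_classes,) + grid.shape)
    for k, code in enumerate(grid.scheme.codes):
        indicator = ((grid.values == code) & grid.valid_mask).astype(float)
        count = ndimage.correlate(indicator, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, count / np.maximum(denom, 1e-300), 0.0)
        layers[k] = frac
    return SuitabilityStack(layers=np.clip(layers, 0.0, None))


def largest_remainder_quotas(target_areas: np.ndarray, n_pixels: int) -> np.ndarray:
    """Round target class areas to integer pixel quotas summing to ``n_pixels``.

    Largest-remainder (Hamilton) rounding of the area shares; ties broken by
    class order.
    """
    target_areas = np.asarray(target_areas, dtype=float)
    total = target_areas.sum()
    if total <= 0:
        raise ValueError("target areas must have positive total")
    ideal = target_areas / total * n_pixels
    floors = np.floor(ideal).astype(int)
    short = n_pixels - floors.sum()
    if short < 0:
        raise ValueError("infeasible quotas: targets exceed landscape size")
    remainders = ideal - floors
    order = np.argsort(-remainders, kind="stable")
    quotas = floors.copy()
    quotas[order[:short]] += 1
    return quotas


def _assign_under_quotas(scores: np.ndarray, quotas: np.ndarray) -> np.ndarray:
    """Greedy assignment: visit (pixel, class) pairs by descending score,
    give each unassigned pixel the best class whose quota is unfilled."""
    n_pix, n_cls = scores.shape
    flat_order = np.argsort(-scores, axis=None, kind="stable")
    assigned = np.full(n_pix, -1, dtype=np.int64)
    remaining = quotas.astype(np.int64).copy()
    n_left = n_pix
    for flat in flat_order:
        p, c = divmod(int(flat), n_cls)
        if assigned[p] >= 0 or remaining[c] == 0:
            continue
        assigned[p] = c
        remaining[c] -= 1
        n_left -= 1
        if n_left == 0:
            break
    return assigned


def allocate(
    grid_t: LandCoverGrid,
    A: TransitionProbabilityMatrix,
    steps: int = 1,
    params: CAParams = CAParams(),
) -> LandCoverGrid:
    """Advance the landscape ``steps`` Markov periods with spatial allocation.

    Per step: (1) target areas via :func:`project_areas`; (2) per-pixel score
    for converting class i → j is ``A_ij × suitability_j`` plus seeded
    jitter; (3) greedy assignment under exact largest-remainder quotas.
    Nodata pixels are untouched.  Fixed seed ⇒ pixel-identical output.
    """
    if grid_t.scheme != A.scheme:
        raise ValueError("grid and transition matrix use different class schemes")
    if steps < 1:
        raise ValueError("steps must be ≥ 1")
    rng = np.random.default_rng(params.seed)
    current = grid_t
    for _ in range(steps):
        areas = tabulate_areas(current)
        target = project_areas(areas.as_vector(), A, 1)
        valid = current.valid_mask
        n_valid = int(valid.sum())
        quotas = largest_remainder_quotas(target, n_valid)
        if quotas.sum() != n_valid:
            raise ValueError("infeasible quotas: targets exceed landscape size")
        new_values = current.values.copy()
        for _pass in range(params.iterations):
            suit = neighborhood_suitability(
                LandCoverGrid(new_values, current.cell_size, current.scheme, current.origin),
                params,
            )
            cls_idx = codes_to_indices(current.scheme, current.values[valid])
            # scores: (n_valid, n_classes)
            suit_flat = suit.layers[:, valid].T
            scores = A.A[cls_idx] * suit_flat
            scores = scores + _JITTER_EPS * rng.random(scores.shape)
            assigned = _assign_under_quotas(scores, quotas)
            codes = np.asarray(current.scheme.codes)
            new_values[valid] = codes[assigned]
        realized = np.array([int((new_values[valid] == c).sum()) for c in current.scheme.codes])
        dev = np.abs(realized * current.cell_area_km2 - target).max() / max(target.sum(), 1e-300)
        if dev > params.quota_tolerance + 1.0 / max(n_valid, 1):
            raise RuntimeError(
                f"realised areas deviate from targets by {dev:.3g} (> quota_tolerance)"
            )
        current = LandCoverGrid(new_values, current.cell_size, current.scheme, current.origin)
    return current


def run_prediction(
    grid_a: LandCoverGrid,
    grid_b: LandCoverGrid,
    dates: tuple[float, float],
    horizon_dates: list[float],
    params: CAParams = CAParams(),
) -> tuple[TransitionProbabilityMatrix, list[tuple[float, LandCoverGrid]]]:
    """Calibrate on two dated maps and simulate the listed horizon dates.

    The transition matrix is estimated from the calibration pair; each
    horizon must lie an integer number of calibration periods after the
    second date (the matrix is applied once per period, not rescaled).
    Returns the estimated matrix and ``[(date, simulated grid), ...]``.
    """
    d0, d1 = dates
    if not d1 > d0:
        raise ValueError(f"calibration dates must increase, got {dates}")
    period = d1 - d0
    for h in horizon_dates:
        if h <= d1:
            raise ValueError(f"horizon {h} is not after the calibration end {d1}")
        k = (h - d1) / period
        if not np.isclose(k, round(k)):
            raise ValueError(
                f"horizon {h} is not aligned to the {period}-year calibration "
                f"period from {d1}; use rescale_period explicitly for such horizons"
            )
    A = estimate_probabilities(cross_tabulate(grid_a, grid_b), period_years=period)
    out: list[tuple[float, LandCoverGrid]] = []
    current, current_date = grid_b, d1
    for h in sorted(horizon_dates):
        steps = int(round((h - current_date) / period))
        current = allocate(current, A, steps=steps, params=params)
        current_date = h
        out.append((h, current))
    return A, out
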