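"""Markov half of CA-Markov: transition-probability estimation and area projection.

A first-order Markov chain over LULC classes: S_{t+1} = S_t · A, where S is
the row vector of class areas (or proportions) and A the row-stochastic
transition-probability matrix estimated from a cross-tabulation of two dates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .land_cover_io import CategoryScheme, CrossTab, SIX_CLASS_SCHEME

__all__ = [
    "TransitionProbabilityMatrix",
    "estimate_probabilities",
    "project_areas",
    "rescale_period",
    "read_matrix",
    "write_matrix",
]

_ROW_SUM_TOL = 1e-9


@dataclasses.dataclass
class TransitionProbabilityMatrix:
    """Row-stochastic matrix A of inter-class transition probabilities.

    ``period_years`` records the calibration interval the probabilities
    refer to; applying the matrix once advances the chain by that interval.
    ``approx_note`` is set by :func:`rescale_period` when the requested
    horizon is not an integer multiple of the period.
    """

    A: np.ndarray
    scheme: CategoryScheme = SIX_CLASS_SCHEME
    period_years: float = 1.0
    approx_note: str | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.scheme.n_classes
        if self.A.shape != (n, n):
            raise ValueError(f"matrix must be {n}×{n}, got {self.A.shape}")
        if (self.A < -_ROW_SUM_TOL).any() or (self.A > 1 + _ROW_SUM_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = self.A.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError(f"rows must sum to 1, got sums {rows}")
        if self.period_years <= 0:
            raise ValueError("period_years must be positive")

    @property
    def n(self) -> int:
        return self.scheme.n_classes

    def to_frame(self) -> pd.DataFrame:
        codes = list(self.scheme.codes)
        return pd.DataFrame(self.A, index=codes, columns=codes)


def estimate_probabilities(crosstab: CrossTab, period_years: float = 1.0) -> TransitionProbabilityMatrix:
    """Row-normalise a cross-tabulation: A_ij = area(i→j) / Σ_j area(i→j).

    A class absent at the start date gives a zero row; it is replaced by the
    identity row (the absent class trivially persists), keeping the matrix
    row-stochastic.
    """
    counts = crosstab.areas_km2
    if (counts < 0).any():
        raise ValueError("negative transition areas")
    row_sums = counts.sum(axis=1)
    if not (row_sums > 0).any():
        raise ValueError("cross-tabulation is entirely empty")
    n = counts.shape[0]
    A = np.eye(n)
    nonzero = row_sums > 0
    A[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    return TransitionProbabilityMatrix(A=A, scheme=crosstab.scheme, period_years=period_years)


def project_areas(S: np.ndarray | pd.Series, A: TransitionProbabilityMatrix, steps: int) -> np.ndarray:
    """Project class areas ``steps`` periods forward: S · A^steps.

    ``S`` may be areas or proportions; it is never renormalised.  Total mass
    is preserved exactly by row-stochasticity.
    """
    if steps < 1:
        raise ValueError(f"steps must be ≥ 1, got {steps}")
    vec = np.asarray(S, dtype=float)
    if vec.shape != (A.n,):
        raise ValueError(f"state vector must have length {A.n}, got {vec.shape}")
    if (vec < 0).any():
        raise ValueError("state vector entries must be non-negative")
    return vec @ np.linalg.matrix_power(A.A, steps)


def rescale_period(A: TransitionProbabilityMatrix, target_years: float) -> TransitionProbabilityMatrix:
    """Re-express the matrix over a different interval via matrix power.

    For a target that is an integer multiple of the calibration period the
    result is exact (A^k).  Otherwise the nearest-integer power is used and
    the approximation is recorded in ``approx_note``; continuous-time
    embedding (matrix logarithm) is deliberately out of scope.
    """
    if target_years <= 0:
        raise ValueError(f"target_years must be positive, got {target_years}")
    ratio = target_years / A.period_years
    k = max(1, int(round(ratio)))
    note = None
    if not np.isclose(ratio, k):
        note = (
            f"target {target_years}y is not an integer multiple of the "
            f"{A.period_years}y period; using nearest power k={k}"
        )
    return TransitionProbabilityMatrix(
        A=np.linalg.matrix_power(A.A, k),
        scheme=A.scheme,
        period_years=A.period_years * k,
        approx_note=note,
    )


# ---------------------------------------------------------------------------
# CSV I/O — class codes label both axes
# ---------------------------------------------------------------------------


def write_matrix(A: TransitionProbabilityMatrix, path: str | Path) -> Path:
    path = Path(path)
    A.to_frame().to_csv(path, index_label="from_code")
    return path


def read_matrix(
    path: str | Path,
    scheme: CategoryScheme = SIX_CLASS_SCHEME,
    period_years: float = 1.0,
) -> TransitionProbabilityMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = [int(c) for c in df.index]
    if codes != list(scheme.codes):
        raise ValueError(f"{path}: matrix rows {codes} do not match scheme codes {scheme.codes}")
    return TransitionProbabilityMatrix(A=df.to_numpy(), scheme=scheme, period_years=period_years)
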