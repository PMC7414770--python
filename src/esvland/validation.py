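"""Agreement between simulated and observed categorical maps (Kappa).

Kappa = (P0 − Pc) / (1 − Pc), where P0 is the observed proportion of
matching pixels and Pc the agreement expected by chance from the two maps'
marginal class frequencies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .land_cover_io import LandCoverGrid, codes_to_indices

__all__ = ["AgreementReport", "kappa_agreement", "kappa_from_confusion"]


@dataclasses.dataclass
class AgreementReport:
    """Confusion matrix (reference rows × simulated columns) and Kappa.

    ``degenerate`` flags the case Pc == 1 (both maps single-class and equal),
    where the Kappa ratio is 0/0; perfect agreement is reported as 1.
    ``passed`` applies the conventional 0.70 acceptance threshold; the
    threshold is configurable in :func:`kappa_agreement`.
    """

    confusion: pd.DataFrame
    p0: float
    pc: float
    kappa: float
    degenerate: bool = False
    threshold: float = 0.70

    @property
    def passed(self) -> bool:
        return self.kappa >= self.threshold

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.confusion.to_csv(path)
        summary = path.with_suffix(".summary.txt")
        with open(summary, "w") as fh:
            fh.write(
                f"P0 {self.p0:.6f}\nPc {self.pc:.6f}\nkappa {self.kappa:.6f}\n"
                f"degenerate {self.degenerate}\nthreshold {self.threshold}\n"
                f"passed {self.passed}\n"
            )
        return path


def kappa_from_confusion(
    confusion: np.ndarray, threshold: float = 0.70, labels: list[str] | None = None
) -> AgreementReport:
    """Compute P0, Pc and Kappa from a pixel-count confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p0 = float(np.trace(confusion) / total)
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    pc = float((row * col).sum() / total**2)
    degenerate = np.isclose(pc, 1.0)
    kappa = 1.0 if degenerate else (p0 - pc) / (1.0 - pc)
    if labels is None:
        labels = [str(i) for i in range(confusion.shape[0])]
    frame = pd.DataFrame(confusion.astype(int), index=labels, columns=labels)
    return AgreementReport(
        confusion=frame, p0=p0, pc=pc, kappa=float(kappa), degenerate=bool(degenerate), threshold=threshold
    )


def kappa_agreement(
    reference: LandCoverGrid, simulated: LandCoverGrid, threshold: float = 0.70
) -> AgreementReport:
    """Chance-corrected agreement between two maps of the same landscape.

    Pixels nodata in either map are excluded pairwise.  Shape or scheme
    mismatch is a hard error.
    """
    if reference.shape != simulated.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {simulated.shape}")
    if reference.scheme != simulated.scheme:
        raise ValueError("class-scheme mismatch between reference and simulated maps")
    scheme = reference.scheme
    shared = reference.valid_mask & simulated.valid_mask
    if not shared.any():
        raise ValueError("no jointly valid pixels to compare")
    a = reference.values[shared]
    b = simulated.values[shared]
    ai = codes_to_indices(scheme, a)
    bi = codes_to_indices(scheme, b)
    n = scheme.n_classes
    confusion = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    return kappa_from_confusion(confusion, threshold=threshold, labels=list(scheme.names))
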