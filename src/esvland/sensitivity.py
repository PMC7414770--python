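"""Elasticity of total ESV to per-class value-coefficient perturbations.

The coefficient of sensitivity CS_k is the standard elasticity: the relative
change of total ESV divided by the relative change applied to class k's
value coefficient (the whole nine-function column is scaled together,
default ±50%).  Because the valuation is linear in the coefficients, CS_k
equals class k's signed share of total ESV and is independent of the
perturbation size; with two or more value-carrying classes every CS_k < 1,
i.e. the total is inelastic to any single class's coefficient — the estimate
is robust to coefficient uncertainty.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .esv_valuation import ESVCoefficientTable, UnitConvention, compute_esv
from .land_cover_io import AreaTable

__all__ = ["SensitivityReport", "coefficient_sensitivity"]


@dataclasses.dataclass
class SensitivityReport:
    """Per-class |percent change of total ESV| and CS under a ±delta scaling."""

    table: pd.DataFrame  # columns: pct_change_total, cs
    delta: float

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index_label="class")
        return path


def coefficient_sensitivity(
    areas: AreaTable,
    coeffs: ESVCoefficientTable,
    delta: float = 0.5,
    unit_convention: UnitConvention = "paper-table",
) -> SensitivityReport:
    """Perturb each class's coefficient column by +delta and measure the total.

    CS_k = (ΔESV/ESV) / (ΔVC_k/VC_k); for the linear valuation this is
    computed by an explicit re-valuation with the scaled column, not by the
    share shortcut, so the identity CS_k == share_k is a testable property
    rather than an assumption.
    """
    if not (0 < delta <= 1):
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    base = compute_esv(areas, coeffs, unit_convention)
    total = base.total_yuan
    if total == 0:
        raise ValueError("total ESV is zero; sensitivity undefined")
    rows = {}
    for cls in coeffs.VC.columns:
        perturbed = compute_esv(areas, coeffs.scaled(cls, 1.0 + delta), unit_convention)
        rel_change = (perturbed.total_yuan - total) / total
        cs = rel_change / delta
        rows[cls] = {"pct_change_total": abs(100.0 * rel_change), "cs": cs}
    return SensitivityReport(table=pd.DataFrame(rows).T, delta=delta)
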