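"""Equivalent-factor ecosystem-service valuation (benefit transfer).

The value of the landscape is the bilinear form

    ESV   = Σ_i A_i · VC_i        (per LULC class i)
    ESV_f = Σ_i A_i · VC_if       (per service function f)

where A_i is the area of class i and VC the coefficient table: nine service
functions × six LULC classes, in yuan·hm⁻²·a⁻¹, anchored to the regional
equivalent factor

    E_a = (1/7) Σ_c M_c p_c q_c / M

— one seventh of the economic value of one hectare's average annual grain
output (crops c: rice, wheat, corn; sown areas M_c, prices p_c, yields q_c).

Unit convention
---------------
Coefficient tables of this kind are stated per hm² while area tables are
commonly printed in km².  Published summary tables in this literature often
multiply the km² areas by the per-hm² coefficients directly, i.e. omit the
km²→hm² factor of 100 on the reported 10⁸-yuan scale.  Both conventions are
supported and every result records which one produced it:

* ``"paper-table"`` (default): km² areas × coefficients, matching the
  published reporting scale;
* ``"strict-si"``: areas converted to hm² first (values 100× larger).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .land_cover_io import (
    KM2_TO_HM2,
    AreaTable,
    CategoryScheme,
    LandCoverGrid,
    SIX_CLASS_SCHEME,
    tabulate_areas,
)

__all__ = [
    "SERVICE_FUNCTIONS",
    "UnitConvention",
    "ESVCoefficientTable",
    "GrainEconomyTable",
    "ESVResult",
    "ChangeRateTable",
    "round_half_up",
    "equivalent_factor",
    "compute_esv",
    "esv_by_function",
    "esv_by_zone",
    "change_rate",
    "contribution_shares",
]

#: The nine ecosystem service functions, in the conventional table order.
SERVICE_FUNCTIONS = (
    "gas regulation",
    "climate regulation",
    "water conservation",
    "waste treatment",
    "soil formation and protection",
    "biodiversity conservation",
    "food production",
    "raw material",
    "recreational culture",
)

UnitConvention = Literal["paper-table", "strict-si"]

#: Default divisor for reported values: 10^8 yuan.
DEFAULT_REPORT_SCALE = 1e8


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class ESVCoefficientTable:
    """Value coefficients VC_if: service functions (rows) × LULC classes.

    Units: yuan·hm⁻²·a⁻¹.  Built-up land may carry negative entries (it is
    valued by replacement cost of the services it degrades); all other
    classes must be non-negative.  The per-class totals VC_i are the column
    sums; a printed "Total" row may be checked against them to the printed
    precision.
    """

    VC: pd.DataFrame  # index: SERVICE_FUNCTIONS, columns: class names
    scheme: CategoryScheme = SIX_CLASS_SCHEME
    negative_allowed: tuple[str, ...] = ("built-up land",)

    def __post_init__(self) -> None:
        self.VC = self.VC.astype(float)
        if list(self.VC.index) != list(SERVICE_FUNCTIONS):
            self.VC = self.VC.reindex(list(SERVICE_FUNCTIONS))
            if self.VC.isna().any().any():
                raise ValueError(
                    f"coefficient table must carry the {len(SERVICE_FUNCTIONS)} "
                    "service-function rows"
                )
        missing = set(self.scheme.names) - set(self.VC.columns)
        if missing:
            raise ValueError(f"coefficient table lacks classes {sorted(missing)}")
        self.VC = self.VC[list(self.scheme.names)]
        for cls in self.VC.columns:
            if cls in self.negative_allowed:
                continue
            if (self.VC[cls] < 0).any():
                raise ValueError(f"negative coefficients for class '{cls}'")

    @property
    def totals(self) -> pd.Series:
        """Per-class total coefficients VC_i (column sums)."""
        return self.VC.sum(axis=0)

    def check_total_row(self, printed: Mapping[str, float], tol: float = 0.025) -> None:
        """Verify a printed per-class total row against the column sums."""
        for cls, value in printed.items():
            got = float(self.totals[cls])
            if abs(got - value) > tol:
                raise ValueError(
                    f"total for '{cls}' is {got:.2f}, printed row says {value:.2f}"
                )

    def scaled(self, cls: str, factor: float) -> "ESVCoefficientTable":
        """A copy with one class's whole coefficient column multiplied by ``factor``."""
        vc = self.VC.copy()
        vc[cls] = vc[cls] * factor
        return ESVCoefficientTable(VC=vc, scheme=self.scheme, negative_allowed=tuple(
            set(self.negative_allowed) | ({cls} if factor < 0 else set())
        ))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.VC.to_csv(path, index_label="service_function")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, scheme: CategoryScheme = SIX_CLASS_SCHEME) -> "ESVCoefficientTable":
        df = pd.read_csv(path, index_col=0)
        df = df[df.index.str.lower() != "total"]  # a printed Total row is derived, not data
        df.index.name = None
        df.columns.name = None
        return cls(VC=df, scheme=scheme)


@dataclasses.dataclass
class GrainEconomyTable:
    """Sown area, price and yield of the grain crops anchoring E_a.

    One row per crop (conventionally rice, wheat, corn): area M_c in hm²,
    price p_c in yuan/t, yield q_c in t/hm².
    """

    crops: pd.DataFrame  # columns: area_hm2, price_yuan_per_t, yield_t_per_hm2

    def __post_init__(self) -> None:
        need = {"area_hm2", "price_yuan_per_t", "yield_t_per_hm2"}
        missing = need - set(self.crops.columns)
        if missing:
            raise ValueError(f"grain table missing columns {sorted(missing)}")
        if (self.crops[list(need)] <= 0).any().any():
            raise ValueError("grain areas, prices and yields must be positive")

    @property
    def total_area_hm2(self) -> float:
        return float(self.crops["area_hm2"].sum())


def equivalent_factor(grain: GrainEconomyTable) -> float:
    """Regional equivalent factor E_a in yuan/hm²: (1/7) Σ M_c p_c q_c / M."""
    M = grain.total_area_hm2
    if M <= 0:
        raise ValueError("total grain area is zero")
    numer = (
        grain.crops["area_hm2"]
        * grain.crops["price_yuan_per_t"]
        * grain.crops["yield_t_per_hm2"]
    ).sum()
    return float(numer / M / 7.0)


@dataclasses.dataclass
class ESVResult:
    """Valuation output: per-category values in raw yuan plus reporting rules.

    ``values_yuan`` is indexed by LULC class, service function or zone label
    depending on ``kind``.  ``report()`` divides by ``report_scale``
    (default 10⁸) and rounds half-up to the printed precision.
    """

    values_yuan: pd.Series
    kind: Literal["class", "function", "zone"]
    unit_convention: UnitConvention = "paper-table"
    report_scale: float = DEFAULT_REPORT_SCALE

    @property
    def total_yuan(self) -> float:
        return float(self.values_yuan.sum())

    def report(self, decimals: int = 2) -> pd.Series:
        scaled = self.values_yuan / self.report_scale
        return scaled.map(lambda v: round_half_up(v, decimals))

    def report_total(self, decimals: int = 2) -> float:
        return round_half_up(self.total_yuan / self.report_scale, decimals)


def _area_factor(unit_convention: UnitConvention) -> float:
    if unit_convention == "paper-table":
        return 1.0
    if unit_convention == "strict-si":
        return KM2_TO_HM2
    raise ValueError(f"unknown unit convention {unit_convention!r}")


def compute_esv(
    areas: AreaTable,
    coeffs: ESVCoefficientTable,
    unit_convention: UnitConvention = "paper-table",
    report_scale: float = DEFAULT_REPORT_SCALE,
) -> ESVResult:
    """Per-class ESV: A_i × VC_i under the declared unit convention."""
    if list(areas.areas_km2.index) != list(coeffs.VC.columns):
        a, c = set(areas.areas_km2.index), set(coeffs.VC.columns)
        raise ValueError(
            f"class mismatch between areas and coefficients: {sorted(a ^ c)}"
        )
    values = areas.areas_km2 * _area_factor(unit_convention) * coeffs.totals
    return ESVResult(values_yuan=values, kind="class",
                     unit_convention=unit_convention, report_scale=report_scale)


def esv_by_function(
    areas: AreaTable,
    coeffs: ESVCoefficientTable,
    unit_convention: UnitConvention = "paper-table",
    report_scale: float = DEFAULT_REPORT_SCALE,
) -> ESVResult:
    """Per-function ESV_f: Σ_i A_i × VC_if.  Sums to the per-class total."""
    if list(areas.areas_km2.index) != list(coeffs.VC.columns):
        a, c = set(areas.areas_km2.index), set(coeffs.VC.columns)
        raise ValueError(
            f"class mismatch between areas and coefficients: {sorted(a ^ c)}"
        )
    vec = areas.areas_km2.to_numpy() * _area_factor(unit_convention)
    values = pd.Series(coeffs.VC.to_numpy() @ vec, index=list(SERVICE_FUNCTIONS))
    return ESVResult(values_yuan=values, kind="function",
                     unit_convention=unit_convention, report_scale=report_scale)


def esv_by_zone(
    grid: LandCoverGrid,
    zones: np.ndarray,
    coeffs: ESVCoefficientTable,
    unit_convention: UnitConvention = "paper-table",
    report_scale: float = DEFAULT_REPORT_SCALE,
) -> dict[int, ESVResult]:
    """Per-zone valuation: masked area tabulation, then :func:`compute_esv`.

    ``zones`` is an integer label grid aligned with ``grid``.  When the zone
    labels partition the valid mask, zone totals sum to the whole-landscape
    total exactly (additivity of the bilinear form).
    """
    zones = np.asarray(zones)
    if zones.shape != grid.shape:
        raise ValueError(f"zone grid shape {zones.shape} does not match {grid.shape}")
    out: dict[int, ESVResult] = {}
    for z in np.unique(zones):
        mask = zones == z
        if not (mask & grid.valid_mask).any():
            continue
        areas = tabulate_areas(grid, mask=mask)
        out[int(z)] = compute_esv(areas, coeffs, unit_convention, report_scale)
    return out


@dataclasses.dataclass
class ChangeRateTable:
    """Percentage change per category and for the total between two dates.

    Categories whose start value is zero are undefined (NaN) and listed in
    ``undefined`` rather than silently reported as 0.
    """

    pct_change: pd.Series
    total_pct_change: float
    undefined: tuple[str, ...] = ()

    def report(self, decimals: int = 2) -> pd.Series:
        return self.pct_change.map(
            lambda v: np.nan if pd.isna(v) else round_half_up(v, decimals)
        )


def _as_series(x: AreaTable | ESVResult | pd.Series) -> pd.Series:
    if isinstance(x, AreaTable):
        return x.areas_km2
    if isinstance(x, ESVResult):
        return x.values_yuan
    return pd.Series(x)


def change_rate(
    start: AreaTable | ESVResult | pd.Series,
    end: AreaTable | ESVResult | pd.Series,
) -> ChangeRateTable:
    """100 × (end − start)/start per category and for the total."""
    s, e = _as_series(start), _as_series(end)
    if list(s.index) != list(e.index):
        raise ValueError("category mismatch between start and end tables")
    zero = s == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (e - s) / s
    pct[zero] = np.nan
    s_tot, e_tot = float(s.sum()), float(e.sum())
    if s_tot == 0:
        raise ValueError("total of the start table is zero; change rate undefined")
    return ChangeRateTable(
        pct_change=pct,
        total_pct_change=100.0 * (e_tot - s_tot) / s_tot,
        undefined=tuple(s.index[zero]),
    )


def contribution_shares(result: ESVResult | AreaTable | pd.Series) -> pd.Series:
    """Per-category share of the total, in percent (signed for negatives)."""
    s = _as_series(result)
    total = float(s.sum())
    if total == 0:
        raise ValueError("total is zero; contribution shares undefined")
    return 100.0 * s / total
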