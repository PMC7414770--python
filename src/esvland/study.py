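"""Bundled reference tables for the northern-Tianshan arid-zone study region.

These are the published per-hm² value-coefficient table (nine service
functions × six LULC classes, regionally rescaled to the local equivalent
factor E_a = 1,304.86 yuan/hm²) and the regional per-class area series for
six dates, 1980–2030 (the 2020 and 2030 areas are CA-Markov projections).
They are the inputs of the tables-only reproduction path: every published
summary value (per-class and per-function ESV on the 10⁸-yuan scale, change
rates, contribution shares, sensitivity) is recomputed from these two tables
alone.
"""

from __future__ import annotations

import pandas as pd

from .esv_valuation import ESVCoefficientTable, SERVICE_FUNCTIONS
from .land_cover_io import AreaTable, SIX_CLASS_SCHEME

__all__ = [
    "STUDY_YEARS",
    "study_coefficients",
    "study_areas",
    "study_area_table",
    "PRINTED_TOTAL_ROW",
]

STUDY_YEARS = (1980, 1990, 2000, 2010, 2020, 2030)

_CLASS_ORDER = list(SIX_CLASS_SCHEME.names)  # forestland … unutilized land

# Value coefficients, yuan·hm⁻²·a⁻¹.  Built-up land is valued by replacement
# cost (negative water-supply and waste-treatment terms).  The cropland
# recreational-culture entry is kept at its printed 3-decimal value 13.049.
_VC_ROWS: dict[str, list[float]] = {
    #                      forest     grass      crop      water     built-up   unutilized
    "gas regulation":     [4567.01,  1043.89,   652.43,      0.00,      0.00,    0.00],
    "climate regulation": [3523.12,  1174.37,  1161.33,    600.24,      0.00,    0.00],
    "water conservation": [4175.55,  1043.89,   782.92,  26593.05,      0.00,   39.15],
    "waste treatment":    [1709.37,  1709.37,  2139.97,  23722.36,  -9799.50,   13.05],
    "soil formation and protection":
                          [5088.95,  2544.48,  1905.10,     13.05,  -3209.96,   26.10],
    "biodiversity conservation":
                          [4253.84,  1422.29,   926.45,   3249.10,      0.00,  443.65],
    "food production":    [130.49,    391.46,  1304.86,    130.49,      0.00,   13.05],
    "raw material":       [3392.64,    65.24,   130.49,     13.05,      0.00,    0.00],
    "recreational culture":
                          [1670.22,    52.19,    13.049,  5663.09,      0.00,   13.05],
}

#: The printed per-class "Total" coefficient row (for consistency checks; the
#: working totals are always recomputed as column sums).
PRINTED_TOTAL_ROW = {
    "forestland": 28511.19,
    "grassland": 9447.19,
    "cropland": 9016.58,
    "water body": 59984.41,
    "built-up land": -13009.45,
    "unutilized land": 548.04,
}

# Per-class areas, km².
_AREAS: dict[int, list[float]] = {
    1980: [3722.82, 40938.98, 10204.99, 3093.59, 643.15, 37206.00],
    1990: [3977.29, 40888.34, 9847.97, 2956.23, 812.80, 36917.37],
    2000: [4012.11, 40428.76, 10411.99, 3272.74, 994.48, 36279.92],
    2010: [3970.33, 39461.50, 11767.30, 3392.38, 1095.13, 35713.36],
    2020: [3851.32, 38142.28, 13732.84, 3368.96, 1540.78, 34763.82],
    2030: [3846.26, 36252.00, 13713.22, 3357.56, 1908.00, 33390.00],
}


def study_coefficients() -> ESVCoefficientTable:
    """The bundled nine-function × six-class coefficient table."""
    vc = pd.DataFrame(_VC_ROWS, index=_CLASS_ORDER).T
    vc = vc.reindex(list(SERVICE_FUNCTIONS))
    return ESVCoefficientTable(VC=vc, scheme=SIX_CLASS_SCHEME)


def study_areas() -> pd.DataFrame:
    """Per-class areas (km²), classes × years."""
    return pd.DataFrame(
        {year: vals for year, vals in _AREAS.items()}, index=_CLASS_ORDER
    )


def study_area_table(year: int) -> AreaTable:
    """The :class:`AreaTable` of one study date."""
    if year not in _AREAS:
        raise KeyError(f"no bundled areas for {year}; have {STUDY_YEARS}")
    return AreaTable(
        areas_km2=pd.Series(_AREAS[year], index=_CLASS_ORDER), scheme=SIX_CLASS_SCHEME
    )
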