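"""Categorical land-cover rasters: containers, file I/O, area and transition tables.

The spatial unit throughout is a single-band integer raster whose codes name
land-use/land-cover (LULC) classes.  The default scheme is the six-class
system common in Chinese LUCC mapping: cropland, forestland, grassland,
water body, built-up land and unutilized land.  Areas are tabulated in km²;
conversion to hm² (``KM2_TO_HM2``) is an explicit step so that valuation code
can declare which convention it uses.

Supported raster formats:

* ESRI ASCII grid (``.asc``/``.agr``/``.txt``) — plain-text, carries cell
  size and origin in its header;
* single-band TIFF (``.tif``/``.tiff``) via :mod:`tifffile` — the cell size
  must be supplied by the caller because plain TIFF has no georeference.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoryScheme",
    "LandCoverGrid",
    "AreaTable",
    "CrossTab",
    "SIX_CLASS_SCHEME",
    "KM2_TO_HM2",
    "read_grid",
    "write_grid",
    "tabulate_areas",
    "cross_tabulate",
    "read_area_table",
    "write_area_table",
    "codes_to_indices",
]


def codes_to_indices(scheme: "CategoryScheme", values: np.ndarray) -> np.ndarray:
    """Map class codes to 0-based scheme positions (codes need not be sorted)."""
    codes = np.asarray(scheme.codes)
    sorter = np.argsort(codes, kind="stable")
    pos = np.searchsorted(codes, np.asarray(values), sorter=sorter)
    return sorter[pos]

#: hm² (hectares) per km².
KM2_TO_HM2 = 100.0


@dataclasses.dataclass(frozen=True)
class CategoryScheme:
    """Ordered class codes with human-readable names and a nodata code."""

    codes: tuple[int, ...]
    names: tuple[str, ...]
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", names)
        if len(set(codes)) != len(codes):
            raise ValueError(f"class codes must be unique, got {codes}")
        if len(names) != len(codes):
            raise ValueError("need exactly one name per class code")
        if self.nodata_code in codes:
            raise ValueError(f"nodata code {self.nodata_code} collides with a class code")

    @property
    def n_classes(self) -> int:
        return len(self.codes)

    def index_of(self, code: int) -> int:
        return self.codes.index(code)

    def name_of(self, code: int) -> str:
        return self.names[self.index_of(code)]


#: Six-class LULC scheme used throughout: codes 1..6 in coefficient-table
#: column order (forestland, grassland, cropland, water body, built-up,
#: unutilized).
SIX_CLASS_SCHEME = CategoryScheme(
    codes=(1, 2, 3, 4, 5, 6),
    names=(
        "forestland",
        "grassland",
        "cropland",
        "water body",
        "built-up land",
        "unutilized land",
    ),
)


@dataclasses.dataclass
class LandCoverGrid:
    """A 2-D categorical raster: the spatial state of the land system.

    Parameters
    ----------
    values
        2-D integer array; every non-nodata entry must be a code of
        ``scheme``.
    cell_size
        Pixel edge length in metres.
    scheme
        The class scheme the codes refer to.
    origin
        Optional ``(xllcorner, yllcorner)`` in map units; carried through
        I/O untouched, never interpreted.
    """

    values: np.ndarray
    cell_size: float
    scheme: CategoryScheme = SIX_CLASS_SCHEME
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError("grid values must be integers")
            self.values = self.values.astype(np.int32)
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self._validate_codes()

    def _validate_codes(self) -> None:
        allowed = set(self.scheme.codes) | {self.scheme.nodata_code}
        present = set(np.unique(self.values).tolist())
        unknown = present - allowed
        if unknown:
            n_bad = int(np.isin(self.values, sorted(unknown)).sum())
            raise ValueError(
                f"grid contains codes {sorted(unknown)} not in the class scheme "
                f"({n_bad} pixel(s) affected)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels that carry a class (not nodata)."""
        return self.values != self.scheme.nodata_code

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def class_counts(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Pixel count per class (scheme order), optionally under a mask."""
        vals = self.values if mask is None else self.values[mask]
        return np.array([int((vals == c).sum()) for c in self.scheme.codes])


@dataclasses.dataclass
class AreaTable:
    """Per-class areas A_i in km² for one date."""

    areas_km2: pd.Series  # indexed by class name, scheme order
    scheme: CategoryScheme = SIX_CLASS_SCHEME

    def __post_init__(self) -> None:
        if isinstance(self.areas_km2, dict):
            self.areas_km2 = pd.Series(self.areas_km2)
        self.areas_km2 = self.areas_km2.astype(float)
        if (self.areas_km2 < 0).any():
            neg = self.areas_km2[self.areas_km2 < 0]
            raise ValueError(f"negative class areas: {neg.to_dict()}")

    @property
    def total_km2(self) -> float:
        return float(self.areas_km2.sum())

    @property
    def areas_hm2(self) -> pd.Series:
        return self.areas_km2 * KM2_TO_HM2

    def as_vector(self) -> np.ndarray:
        return self.areas_km2.to_numpy()


@dataclasses.dataclass
class CrossTab:
    """Cross-tabulated transition areas A_ij (km²) between two dates.

    Entry ``(i, j)`` is the area that moved from class i (earlier date, rows)
    to class j (later date, columns) over the shared valid mask.
    """

    areas_km2: np.ndarray  # (n, n)
    scheme: CategoryScheme = SIX_CLASS_SCHEME

    def __post_init__(self) -> None:
        self.areas_km2 = np.asarray(self.areas_km2, dtype=float)
        n = self.scheme.n_classes
        if self.areas_km2.shape != (n, n):
            raise ValueError(
                f"cross-tabulation must be {n}×{n}, got {self.areas_km2.shape}"
            )
        if (self.areas_km2 < 0).any():
            raise ValueError("cross-tabulation contains negative areas")

    def row_totals(self) -> np.ndarray:
        return self.areas_km2.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.areas_km2.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas_km2, index=list(self.scheme.names), columns=list(self.scheme.names)
        )


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASCII_SUFFIXES = {".asc", ".agr", ".txt", ".grd"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, tuple[float, float], int | None]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: truncated ASCII grid (no data rows)")
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: ASCII grid header missing '{key}'")
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise IOError(
            f"{path}: data block is {data.shape}, header says ({nrows}, {ncols})"
        )
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    nodata = header.get("nodata_value")
    return data, header["cellsize"], origin, None if nodata is None else int(nodata)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_grid(
    path: str | Path,
    scheme: CategoryScheme = SIX_CLASS_SCHEME,
    cell_size: float | None = None,
) -> LandCoverGrid:
    """Read a single-band categorical raster into a :class:`LandCoverGrid`.

    ESRI ASCII grids carry cell size, origin and nodata in their header; any
    file nodata value is remapped to ``scheme.nodata_code``.  For TIFF the
    ``cell_size`` argument is required (plain TIFF stores no georeference).
    Codes outside the scheme raise a :class:`ValueError` naming the offending
    values and the number of affected pixels.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        values = np.asarray(tifffile.imread(path))
        if cell_size is None:
            raise ValueError("cell_size is required when reading TIFF rasters")
        origin = (0.0, 0.0)
        file_nodata = None
    elif suffix in _ASCII_SUFFIXES:
        values, file_cell, origin, file_nodata = _read_ascii_grid(path)
        if cell_size is None:
            cell_size = file_cell
    else:
        raise IOError(f"unsupported raster format: {path.name}")
    values = np.asarray(values)
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: raster is not integer-valued")
    values = values.astype(np.int32)
    if file_nodata is not None and file_nodata != scheme.nodata_code:
        values = np.where(values == file_nodata, scheme.nodata_code, values)
    return LandCoverGrid(values=values, cell_size=float(cell_size), scheme=scheme, origin=origin)


def write_grid(grid: LandCoverGrid, path: str | Path) -> Path:
    """Write a grid as ESRI ASCII (``.asc`` etc.) or single-band TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, grid.values.astype(np.int32))
    elif suffix in _ASCII_SUFFIXES:
        nrows, ncols = grid.shape
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {grid.origin[0]:.6f}\n"
            f"yllcorner {grid.origin[1]:.6f}\n"
            f"cellsize {grid.cell_size:.6f}\n"
            f"NODATA_value {grid.scheme.nodata_code}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, grid.values, fmt="%d")
    else:
        raise IOError(f"unsupported raster format: {path.name}")
    return path


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_areas(grid: LandCoverGrid, mask: np.ndarray | None = None) -> AreaTable:
    """Per-class area A_i = pixel count × cell area, in km², nodata excluded.

    ``mask`` optionally restricts tabulation to a pixel subset (used for
    zonal accounting); nodata pixels are excluded either way.
    """
    full_mask = grid.valid_mask if mask is None else (grid.valid_mask & mask)
    if not full_mask.any():
        raise ValueError("empty landscape: every pixel is nodata (or masked out)")
    counts = grid.class_counts(full_mask)
    areas = counts * grid.cell_area_km2
    return AreaTable(
        areas_km2=pd.Series(areas, index=list(grid.scheme.names)), scheme=grid.scheme
    )


def cross_tabulate(grid_t: LandCoverGrid, grid_t1: LandCoverGrid) -> CrossTab:
    """Transition areas between two dates of the same landscape.

    Pixels that are nodata at either date are excluded pairwise, so the row
    sums equal the date-t area table and the column sums the date-t+1 table
    over the shared valid mask (exact conservation).
    """
    if grid_t.shape != grid_t1.shape:
        raise ValueError(f"shape mismatch: {grid_t.shape} vs {grid_t1.shape}")
    if grid_t.scheme != grid_t1.scheme:
        raise ValueError("class-scheme mismatch between the two dates")
    if not np.isclose(grid_t.cell_size, grid_t1.cell_size):
        raise ValueError(
            f"cell-size mismatch: {grid_t.cell_size} vs {grid_t1.cell_size}"
        )
    scheme = grid_t.scheme
    shared = grid_t.valid_mask & grid_t1.valid_mask
    a = grid_t.values[shared]
    b = grid_t1.values[shared]
    ai = codes_to_indices(scheme, a)
    bi = codes_to_indices(scheme, b)
    n = scheme.n_classes
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    return CrossTab(areas_km2=counts * grid_t.cell_area_km2, scheme=scheme)


# ---------------------------------------------------------------------------
# Table I/O  (CSV: class_code,class_name,area_km2)
# ---------------------------------------------------------------------------


def write_area_table(table: AreaTable, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "class_code": list(table.scheme.codes),
            "class_name": list(table.scheme.names),
            "area_km2": table.areas_km2.to_numpy(),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_area_table(path: str | Path, scheme: CategoryScheme = SIX_CLASS_SCHEME) -> AreaTable:
    df = pd.read_csv(path)
    missing = {"class_code", "class_name", "area_km2"} - set(df.columns)
    if missing:
        raise IOError(f"{path}: area table missing columns {sorted(missing)}")
    df = df.set_index("class_name").reindex(list(scheme.names))
    if df["area_km2"].isna().any():
        absent = df.index[df["area_km2"].isna()].tolist()
        raise ValueError(f"{path}: area table lacks classes {absent}")
    areas = df["area_km2"].rename(None)
    areas.index.name = None
    return AreaTable(areas_km2=areas, scheme=scheme)
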