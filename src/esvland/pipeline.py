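"""Config-driven orchestration: rasters (or synthetic stand-ins, or bare
area tables) in, CSV report bundle out.

Three modes:

``tables``
    Start from per-date area tables and a coefficient table; emit the
    valuation reports (per-class, per-function, change rates, contribution
    shares, sensitivity).  This is the reproduction path for published
    summary tables.
``rasters``
    Load dated land-cover rasters, cross-tabulate, estimate the transition
    matrix, simulate the requested horizons with the CA, then run the same
    valuation reports on observed + simulated dates.
``synthetic``
    As ``rasters``, but the maps are generated: an initial landscape, a
    second date evolved under a prescribed transition matrix, plus a
    held-out third date used for Kappa validation of the simulation.

Every run writes a ``run_log.txt`` recording the seed, unit convention and
package versions; outputs are deterministic (byte-identical) under a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import study
from .ca_allocation import CAParams, run_prediction
from .esv_valuation import (
    ESVCoefficientTable,
    UnitConvention,
    change_rate,
    compute_esv,
    contribution_shares,
    esv_by_function,
    esv_by_zone,
    round_half_up,
)
from .land_cover_io import AreaTable, SIX_CLASS_SCHEME, read_area_table, read_grid, tabulate_areas, write_grid
from .sensitivity import coefficient_sensitivity
from .synthetic_data import SyntheticLandscapeSpec, evolve, generate_initial, generate_zones
from .validation import kappa_agreement

__all__ = ["RunConfig", "PipelineError", "run", "reproduce_tables"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; loadable from a YAML key-value file."""

    output_dir: str | Path = "esvland_run"
    mode: str = "tables"  # tables | rasters | synthetic
    seed: int = 0
    unit_convention: UnitConvention = "paper-table"
    report_scale: float = 1e8
    sensitivity_delta: float = 0.5
    # tables mode: year -> area-table CSV path; None means the bundled study tables
    area_tables: dict[int, str] | None = None
    coefficients_csv: str | None = None
    change_periods: list[tuple[int, int]] | None = None
    # rasters mode
    rasters: list[tuple[int, str]] | None = None  # [(date, path), ...]
    cell_size: float | None = None
    # synthetic mode
    synthetic: dict | None = None
    n_zones: int = 1
    # simulation
    horizons: list[int] | None = None
    kernel_radius: int = 2
    iterations: int = 1
    config_version: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("tables", "rasters", "synthetic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "area_tables" in raw and raw["area_tables"] is not None:
            raw["area_tables"] = {int(k): v for k, v in raw["area_tables"].items()}
        if "rasters" in raw and raw["rasters"] is not None:
            raw["rasters"] = [(int(d), p) for d, p in raw["rasters"]]
        if "change_periods" in raw and raw["change_periods"] is not None:
            raw["change_periods"] = [tuple(int(x) for x in pr) for pr in raw["change_periods"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _load_coefficients(config: RunConfig) -> ESVCoefficientTable:
    if config.coefficients_csv is None:
        return study.study_coefficients()
    return ESVCoefficientTable.from_csv(config.coefficients_csv)


def _valuation_reports(
    areas_by_year: dict[int, AreaTable],
    coeffs: ESVCoefficientTable,
    config: RunConfig,
    outdir: Path,
) -> dict[str, pd.DataFrame]:
    years = sorted(areas_by_year)
    conv = config.unit_convention
    per_class = {y: compute_esv(areas_by_year[y], coeffs, conv, config.report_scale) for y in years}
    per_func = {y: esv_by_function(areas_by_year[y], coeffs, conv, config.report_scale) for y in years}

    area_df = pd.DataFrame({y: areas_by_year[y].areas_km2 for y in years})
    cls_df = pd.DataFrame({y: per_class[y].report() for y in years})
    cls_df.loc["Total"] = [per_class[y].report_total() for y in years]
    fun_df = pd.DataFrame({y: per_func[y].report() for y in years})
    fun_df.loc["Total"] = [per_func[y].report_total() for y in years]

    periods = config.change_periods or ([(years[0], years[-1])] if len(years) > 1 else [])
    for a, b in periods:
        col = f"change_{a}_{b}_pct"
        ar = change_rate(areas_by_year[a], areas_by_year[b])
        area_df[col] = ar.report()
        cr = change_rate(per_class[a], per_class[b])
        cls_df[col] = pd.concat(
            [cr.report(), pd.Series({"Total": round_half_up(cr.total_pct_change)})]
        )
        fr = change_rate(per_func[a], per_func[b])
        fun_df[col] = pd.concat(
            [fr.report(), pd.Series({"Total": round_half_up(fr.total_pct_change)})]
        )

    shares_df = pd.DataFrame(
        {y: contribution_shares(per_class[y]).map(lambda v: round_half_up(v)) for y in years}
    )
    sens_frames = []
    for y in years:
        rep = coefficient_sensitivity(
            areas_by_year[y], coeffs, config.sensitivity_delta, conv
        )
        t = rep.table.copy()
        t.insert(0, "year", y)
        sens_frames.append(t)
    sens_df = pd.concat(sens_frames).rename_axis("class")

    reports = {
        "areas_km2": area_df,
        "esv_by_class": cls_df,
        "esv_by_function": fun_df,
        "contribution_shares_pct": shares_df,
        "sensitivity": sens_df,
    }
    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.csv")
    return reports


def _write_log(config: RunConfig, outdir: Path, extra: dict) -> None:
    import esvland

    lines = {
        "esvland_version": esvland.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "unit_convention": config.unit_convention,
        "report_scale": config.report_scale,
        "kernel_radius": config.kernel_radius,
        **extra,
    }
    with open(outdir / "run_log.txt", "w") as fh:
        for k, v in lines.items():
            fh.write(f"{k}: {v}\n")


def reproduce_tables(
    output_dir: str | Path,
    unit_convention: UnitConvention = "paper-table",
) -> dict[str, pd.DataFrame]:
    """Tables-only reproduction with the bundled study tables and the
    published change periods (1980–2010, 2010–2030, 1980–2030)."""
    config = RunConfig(
        output_dir=output_dir,
        mode="tables",
        unit_convention=unit_convention,
        change_periods=[(1980, 2010), (2010, 2030), (1980, 2030)],
    )
    return run(config)


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the configured workflow; returns the report tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        coeffs = _load_coefficients(config)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("load-coefficients", str(exc)) from exc

    extra: dict = {}
    if config.mode == "tables":
        try:
            if config.area_tables is None:
                areas_by_year = {y: study.study_area_table(y) for y in study.STUDY_YEARS}
            else:
                areas_by_year = {
                    y: read_area_table(p) for y, p in config.area_tables.items()
                }
        except Exception as exc:
            raise PipelineError("load-areas", str(exc)) from exc
    else:
        areas_by_year, extra = _spatial_stages(config, coeffs, outdir)

    try:
        reports = _valuation_reports(areas_by_year, coeffs, config, outdir)
    except Exception as exc:
        raise PipelineError("valuation", str(exc)) from exc
    _write_log(config, outdir, extra)
    return reports


def _spatial_stages(
    config: RunConfig, coeffs: ESVCoefficientTable, outdir: Path
) -> tuple[dict[int, AreaTable], dict]:
    params = CAParams(
        kernel_radius=config.kernel_radius,
        iterations=config.iterations,
        seed=config.seed,
    )
    extra: dict = {}
    zones = None
    if config.mode == "synthetic":
        try:
            syn = dict(config.synthetic or {})
            dates = syn.pop("dates", [2000, 2005])
            spec = SyntheticLandscapeSpec(seed=config.seed, n_zones=config.n_zones, **syn)
            if spec.transition_matrix is None:
                raise ValueError("synthetic mode needs a transition_matrix in `synthetic`")
            g0 = generate_initial(spec)
            A_true = np.asarray(spec.transition_matrix, dtype=float)
            g1 = evolve(g0, A_true, steps=1, seed=config.seed + 1)
            grids = [(int(dates[0]), g0), (int(dates[1]), g1)]
            if config.n_zones > 1:
                zones = generate_zones(spec)
            # held-out truth one period past calibration, for Kappa
            period = int(dates[1]) - int(dates[0])
            truth = evolve(g1, A_true, steps=1, seed=config.seed + 2)
            extra["holdout_date"] = int(dates[1]) + period
        except Exception as exc:
            raise PipelineError("synthesize", str(exc)) from exc
    else:
        try:
            if not config.rasters or len(config.rasters) < 2:
                raise ValueError("rasters mode needs at least two dated rasters")
            grids = [
                (int(d), read_grid(p, cell_size=config.cell_size))
                for d, p in sorted(config.rasters)
            ]
            truth = None
        except Exception as exc:
            raise PipelineError("load-rasters", str(exc)) from exc

    (d0, g0), (d1, g1) = grids[0], grids[1]
    horizons = [int(h) for h in (config.horizons or [])]
    try:
        areas_by_year = {d: tabulate_areas(g) for d, g in grids}
        sim_maps: list[tuple[int, object]] = []
        if horizons:
            A, sim_maps = run_prediction(g0, g1, (d0, d1), horizons, params)
            A.to_frame().to_csv(outdir / "transition_matrix.csv", index_label="from_code")
            for h, g in sim_maps:
                write_grid(g, outdir / f"simulated_{h}.asc")
                areas_by_year[h] = tabulate_areas(g)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    if config.mode == "synthetic" and truth is not None and sim_maps:
        try:
            h0, sim0 = sim_maps[0]
            report = kappa_agreement(truth, sim0)
            report.write(outdir / "kappa_confusion.csv")
            extra["kappa_holdout"] = f"{report.kappa:.4f}"
        except Exception as exc:
            raise PipelineError("validate", str(exc)) from exc

    if zones is not None:
        try:
            zonal = esv_by_zone(g1, zones, coeffs, config.unit_convention, config.report_scale)
            zdf = pd.DataFrame({z: r.report() for z, r in zonal.items()}).T.rename_axis("zone")
            zdf["total"] = [r.report_total() for r in zonal.values()]
            zdf.to_csv(outdir / "esv_by_zone.csv")
        except Exception as exc:
            raise PipelineError("zonal-valuation", str(exc)) from exc
    return areas_by_year, extra
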