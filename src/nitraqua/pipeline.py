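"""Configuration-driven end-to-end runner.

Stages: QA/QC (if triplicate data is given) -> descriptive statistics
and group tests -> leave-one-out cross-validation of every requested
interpolator -> ranking -> gridded surface of the best method ->
IPNOA/IPNOC hazard reports. Outputs are deterministic for a fixed
config and seed: CSV summaries are written at fixed precision and
contain no timestamps, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import qaqc
from .data_model import SampleTable, read_wells_csv, write_grid_ascii, write_wells_csv
from .hazard import (
    IpnoaInputs,
    SewerZone,
    ipnoc_ny,
    score_ipnoa,
    write_hazard_report,
)
from .interpolation import InterpolatorSpec, VariogramModel, grid_geometry_for, predict_grid
from .synthetic import FieldSpec, generate_triplicates, generate_well_table
from .validation import CvResult, loocv, rank_methods, write_cv_report

log = logging.getLogger("nitraqua")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class GridGeometry:
    cellsize: float
    ncols: Optional[int] = None
    nrows: Optional[int] = None
    xll: Optional[float] = None
    yll: Optional[float] = None


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``wells_csv`` or ``field_spec`` must be set; the
    latter generates the wells synthetically.
    """

    out_dir: Path
    wells_csv: Optional[Path] = None
    field_spec: Optional[FieldSpec] = None
    qa_csv: Optional[Path] = None
    qa_synthetic: bool = False
    methods: list[InterpolatorSpec] = dc_field(default_factory=list)
    grid: Optional[GridGeometry] = None
    ipnoa_inputs: dict[str, IpnoaInputs] = dc_field(default_factory=dict)
    sewer_zones: list[SewerZone] = dc_field(default_factory=list)
    rank_criterion: str = "rmse"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.wells_csv is None and self.field_spec is None:
            raise PipelineError("config: either wells_csv or a synthetic field spec is required")
        if not self.methods:
            raise PipelineError("config: at least one interpolator must be requested")


@dataclass
class PipelineReport:
    """Paths of every artifact written plus the in-memory summary."""

    out_dir: Path
    files: dict[str, Path]
    cv_results: list[CvResult]
    ranking: list[str]
    summary: dict


def _spec_from_dict(d: dict) -> InterpolatorSpec:
    vg = None
    if "variogram" in d:
        v = d["variogram"]
        vg = VariogramModel(
            kind=v.get("kind", "spherical"),
            nugget=float(v["nugget"]),
            partial_sill=float(v["partial_sill"]),
            range_m=float(v["range_m"]),
        )
    return InterpolatorSpec(
        method=d["method"],
        idw_power=float(d.get("idw_power", 2.0)),
        idw_neighbors=int(d["idw_neighbors"]) if "idw_neighbors" in d else None,
        variogram=vg,
        variogram_kind=d.get("variogram_kind", "spherical"),
        n_bins=int(d.get("n_bins", 12)),
        max_lag=float(d["max_lag"]) if "max_lag" in d else None,
        spline_tension=float(d.get("spline_tension", 0.0)),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a TOML file."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    field_spec = None
    if "synthetic" in raw:
        s = raw["synthetic"]
        v = s["variogram"]
        field_spec = FieldSpec(
            n_wells=int(s["n_wells"]),
            extent=tuple(float(x) for x in s["extent"]),  # type: ignore[arg-type]
            variogram=VariogramModel(
                kind=v.get("kind", "spherical"),
                nugget=float(v["nugget"]),
                partial_sill=float(v["partial_sill"]),
                range_m=float(v["range_m"]),
            ),
            landuse_means={k: float(x) for k, x in s["landuse_means"].items()},
            landuse_props={k: float(x) for k, x in s["landuse_props"].items()},
            climate_split=float(s.get("climate_split", 0.75)),
            noise_sd=float(s.get("noise_sd", 1.0)),
            seed=int(s.get("seed", raw.get("seed", 0))),
        )

    ipnoa_inputs = {}
    for lu, d in raw.get("ipnoa", {}).items():
        def _amt(v):
            return tuple(float(x) for x in v) if isinstance(v, list) else float(v)

        ipnoa_inputs[lu] = IpnoaInputs(
            inorganic_fert=_amt(d.get("inorganic", 0)),
            organic_fert=_amt(d.get("organic", 0)),
            sludge=_amt(d.get("sludge", 0)),
            soil_n=float(d["soil_n"]),
            irrigation=d["irrigation"],
            rainfall=float(d["rainfall"]),
            temperature=float(d["temperature"]),
            tillage=d["tillage"],
            fert_application=d["fert_application"],
        )

    zones = [
        SewerZone(
            pipe_length=float(z["pipe_length"]),
            pipe_age=float(z["pipe_age"]),
            pipe_life=float(z["pipe_life"]),
            base_leakage=float(z["base_leakage"]),
            inhabitants=int(z.get("inhabitants", 0)),
            per_capita_n=float(z.get("per_capita_n", 0.0)),
            infiltration=float(z.get("infiltration", 0.0)),
            n_load=float(z["n_load"]) if "n_load" in z else None,
        )
        for z in raw.get("sewer_zones", [])
    ]

    grid = None
    if "grid" in raw:
        g = raw["grid"]
        grid = GridGeometry(
            cellsize=float(g["cellsize"]),
            ncols=int(g["ncols"]) if "ncols" in g else None,
            nrows=int(g["nrows"]) if "nrows" in g else None,
            xll=float(g["xll"]) if "xll" in g else None,
            yll=float(g["yll"]) if "yll" in g else None,
        )

    return PipelineConfig(
        out_dir=Path(raw.get("out_dir", "nitraqua_out")),
        wells_csv=Path(raw["wells_csv"]) if "wells_csv" in raw else None,
        field_spec=field_spec,
        qa_csv=Path(raw["qa_csv"]) if "qa_csv" in raw else None,
        qa_synthetic=bool(raw.get("qa_synthetic", False)),
        methods=[_spec_from_dict(d) for d in raw.get("interpolators", [])],
        grid=grid,
        ipnoa_inputs=ipnoa_inputs,
        sewer_zones=zones,
        rank_criterion=raw.get("rank_criterion", "rmse"),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
    )


def _descriptive_stats(samples: SampleTable) -> pd.DataFrame:
    rows = []
    nit = samples.nitrate
    for label, mask in [("total", np.ones(len(samples), bool))] + [
        (f"climate:{c}", samples.climate == c) for c in np.unique(samples.climate)
    ] + [(f"land_use:{u}", samples.land_use == u) for u in np.unique(samples.land_use)]:
        vals = nit[mask]
        if vals.size < 2:
            continue
        g = qaqc.group_summary(vals)
        rows.append(
            {
                "group": label,
                "n": g.n,
                "min": round(float(vals.min()), 4),
                "max": round(float(vals.max()), 4),
                "mean": round(g.mean, 4),
                "sd": round(g.sd, 4),
                "stderr": round(g.stderr, 4),
                "ci95_lo": round(g.ci95_lo, 4),
                "ci95_hi": round(g.ci95_hi, 4),
                "pct_above_50": round(float(np.mean(vals > 50.0) * 100.0), 2),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis; returns the report bundle.

    Raises :class:`PipelineError` naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}

    # --- stage: input wells -------------------------------------------------
    try:
        if config.field_spec is not None:
            samples, _truth = generate_well_table(config.field_spec)
            wells_path = out / "wells.csv"
            write_wells_csv(samples, wells_path)
            files["wells"] = wells_path
            log.info("generated %d synthetic wells", len(samples))
        else:
            samples = read_wells_csv(config.wells_csv)  # type: ignore[arg-type]
            log.info("read %d wells from %s", len(samples), config.wells_csv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage wells: {exc}") from exc

    # --- stage: QA/QC -------------------------------------------------------
    try:
        trips = None
        if config.qa_csv is not None:
            trips = qaqc.read_triplicates_csv(config.qa_csv)
        elif config.qa_synthetic:
            trips = generate_triplicates([5.0, 25.0, 50.0], cv=0.01, bias=0.05,
                                         seed=config.seed)
        if trips:
            qa_rows = [qaqc.assess_triplicate(t) for t in trips]
            qa_df = pd.DataFrame(qa_rows).round(6)
            qa_path = out / "qaqc_report.csv"
            qa_df.to_csv(qa_path, index=False)
            files["qaqc"] = qa_path
            summary["qa_all_acceptable"] = bool(all(r["recovery_acceptable"] for r in qa_rows))
            log.info("QA/QC: %d triplicates assessed", len(trips))
    except Exception as exc:
        raise PipelineError(f"stage qaqc: {exc}") from exc

    # --- stage: descriptive statistics and group tests ----------------------
    try:
        stats_df = _descriptive_stats(samples)
        stats_path = out / "descriptive_stats.csv"
        stats_df.to_csv(stats_path, index=False)
        files["stats"] = stats_path

        nit = samples.nitrate
        climates = np.unique(samples.climate)
        if len(climates) == 2:
            a = nit[samples.climate == climates[0]]
            b = nit[samples.climate == climates[1]]
            if a.size >= 2 and b.size >= 2:
                tt = qaqc.two_sample_ttest(a, b)
                summary["climate_ttest"] = {
                    "t": round(tt.statistic, 6),
                    "p": round(tt.pvalue, 6),
                    "df": round(tt.df, 2),
                }
        groups = [nit[samples.land_use == u] for u in np.unique(samples.land_use)]
        groups = [g for g in groups if g.size >= 1]
        if len(groups) >= 2 and sum(g.size for g in groups) > len(groups):
            try:
                an = qaqc.oneway_anova(groups)
                summary["landuse_anova"] = {"F": round(an.F, 6), "p": round(an.pvalue, 6)}
            except ValueError:
                summary["landuse_anova"] = None
    except Exception as exc:
        raise PipelineError(f"stage stats: {exc}") from exc

    # --- stage: cross-validation and ranking --------------------------------
    try:
        cv_results = [loocv(samples, spec) for spec in config.methods]
        cv_path = out / "cv_report.csv"
        write_cv_report(cv_results, cv_path)
        files["cv"] = cv_path
        ranking = rank_methods(cv_results, criterion=config.rank_criterion)
        summary["ranking"] = ranking
        summary["cv"] = {
            r.method: {
                "mre": round(r.mre, 6),
                "rmse": round(r.rmse, 6),
                "pct_rmse": round(r.pct_rmse, 6),
                "n_evaluated": r.n_evaluated,
            }
            for r in cv_results
        }
        log.info("cross-validation ranking (%s): %s", config.rank_criterion, ranking)
    except Exception as exc:
        raise PipelineError(f"stage crossval: {exc}") from exc

    # --- stage: best-method surface -----------------------------------------
    try:
        best = ranking[0]
        best_spec = next(s for s in config.methods if s.method == best)
        geom = config.grid
        if geom is None:
            span = samples.xy.max(axis=0) - samples.xy.min(axis=0)
            geom = GridGeometry(cellsize=float(max(span) / 40.0))
        if geom.ncols is None or geom.nrows is None or geom.xll is None or geom.yll is None:
            ncols, nrows, xll, yll = grid_geometry_for(samples, geom.cellsize)
        else:
            ncols, nrows, xll, yll = geom.ncols, geom.nrows, geom.xll, geom.yll
        surface = predict_grid(samples, best_spec, ncols, nrows, xll, yll, geom.cellsize)
        asc_path = out / f"surface_{best}.asc"
        write_grid_ascii(surface, asc_path)
        files["surface"] = asc_path
        summary["surface"] = {"method": best, "ncols": ncols, "nrows": nrows}
        log.info("wrote %dx%d %s surface", nrows, ncols, best)
    except Exception as exc:
        raise PipelineError(f"stage surface: {exc}") from exc

    # --- stage: hazard indices ----------------------------------------------
    try:
        if config.ipnoa_inputs:
            scores = {lu: score_ipnoa(inp) for lu, inp in config.ipnoa_inputs.items()}
            hz_path = out / "hazard_ipnoa.csv"
            write_hazard_report(scores, hz_path)
            files["ipnoa"] = hz_path
            summary["ipnoa"] = {
                lu: {"hi": s.hi, "level": s.level, "label": s.label}
                for lu, s in scores.items()
            }
        if config.sewer_zones:
            res = ipnoc_ny(config.sewer_zones)
            summary["ipnoc"] = {
                "ny_literal_kg_m_per_year": round(res.ny_literal, 2),
                "ny_per_metre_kg_per_year": round(res.ny_per_metre, 2),
                "total_pipe_length_m": round(res.total_length, 2),
            }
    except Exception as exc:
        raise PipelineError(f"stage hazard: {exc}") from exc

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files["summary"] = summary_path
    return PipelineReport(out_dir=out, files=files, cv_results=cv_results,
                          ranking=ranking, summary=summary)
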