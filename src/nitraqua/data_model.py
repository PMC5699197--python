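"""Domain types and file I/O for georeferenced well-sample data.

Coordinates are planar projected metres (UTM-like map space); all
distances downstream are Euclidean, so no geodesy is performed here.
Rasters follow the ESRI ASCII grid convention: row 0 is the
northernmost row, the header georeferences the lower-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

CLIMATES = ("arid", "semi_arid")
LAND_USES = ("agricultural", "steppe", "residential", "mixed")
SEASONS = ("spring", "summer")

WELL_COLUMNS = ("well_id", "x", "y", "elev", "climate", "land_use", "season", "nitrate")

DEFAULT_NODATA = -9999.0


class SchemaError(ValueError):
    """The input table does not have the expected columns/structure."""


class DuplicateSampleError(ValueError):
    """Two rows share the same (well_id, season) key."""


@dataclass(frozen=True)
class WellSample:
    """One georeferenced nitrate measurement with climate and land-use labels.

    Units: x/y/elev in metres, nitrate in mg/L. Labels are closed
    vocabularies; unknown climate, land-use or season strings are rejected
    (the survey design has no industrial stations, for instance).
    """

    well_id: str
    x: float
    y: float
    elev: float
    climate: str
    land_use: str
    season: str
    nitrate: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "elev", "nitrate"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(float(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.nitrate < 0:
            raise ValueError(f"nitrate must be >= 0 mg/L, got {self.nitrate}")
        if self.climate not in CLIMATES:
            raise ValueError(f"unknown climate {self.climate!r}; expected one of {CLIMATES}")
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land_use {self.land_use!r}; expected one of {LAND_USES}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {SEASONS}")


@dataclass(frozen=True)
class SampleTable:
    """An ordered, validated collection of :class:`WellSample`.

    Invariants: non-empty; no duplicate (well_id, season) pair.
    """

    samples: tuple[WellSample, ...]

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("SampleTable must be non-empty")
        keys = [(s.well_id, s.season) for s in self.samples]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            for k in keys:
                if k in seen:
                    raise DuplicateSampleError(f"duplicate (well_id, season) pair {k}")
                seen.add(k)

    @classmethod
    def from_samples(cls, samples: Iterable[WellSample]) -> "SampleTable":
        return cls(tuple(samples))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[WellSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> WellSample:
        return self.samples[i]

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in metres."""
        return np.array([(s.x, s.y) for s in self.samples], dtype=float)

    @property
    def nitrate(self) -> np.ndarray:
        return np.array([s.nitrate for s in self.samples], dtype=float)

    @property
    def land_use(self) -> np.ndarray:
        return np.array([s.land_use for s in self.samples])

    @property
    def climate(self) -> np.ndarray:
        return np.array([s.climate for s in self.samples])

    def subset(self, indices: Sequence[int]) -> "SampleTable":
        return SampleTable(tuple(self.samples[i] for i in indices))

    def drop(self, index: int) -> "SampleTable":
        return SampleTable(self.samples[:index] + self.samples[index + 1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": s.well_id,
                    "x": s.x,
                    "y": s.y,
                    "elev": s.elev,
                    "climate": s.climate,
                    "land_use": s.land_use,
                    "season": s.season,
                    "nitrate": s.nitrate,
                }
                for s in self.samples
            ],
            columns=list(WELL_COLUMNS),
        )


def read_wells_csv(path: str | Path) -> SampleTable:
    """Read a well-sample table from CSV.

    Expected header: ``well_id,x,y,elev,climate,land_use,season,nitrate``
    (comma separated, "." decimal mark, UTF-8). Rows with non-numeric
    values are rejected with a 1-based data-row number in the message
    (the header is row 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    samples: list[WellSample] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        fields: dict[str, object] = {"well_id": str(row["well_id"])}
        for col in ("x", "y", "elev", "nitrate"):
            raw = row[col]
            try:
                fields[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} for {col!r} at row {pos}"
                ) from None
        for col in ("climate", "land_use", "season"):
            fields[col] = str(row[col]).strip() if pd.notna(row[col]) else ""
        try:
            samples.append(WellSample(**fields))  # type: ignore[arg-type]
        except DuplicateSampleError:
            raise
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: {exc}") from None
    return SampleTable(tuple(samples))


def write_wells_csv(table: SampleTable, path: str | Path) -> None:
    """Write a :class:`SampleTable` to CSV (lossless to 10 sig. digits)."""
    table.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class Surface:
    """A regular raster of interpolated nitrate (mg/L) with an ESRI-style
    georeferencing header.

    ``values`` has shape (nrows, ncols) with row 0 the NORTHERNMOST row;
    (xll, yll) locate the lower-left corner of the lower-left cell.
    Cells are either finite or equal to the ``nodata`` sentinel.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be > 0, got {self.cellsize}")
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != (nrows, ncols) = "
                f"({self.nrows}, {self.ncols})"
            )
        not_nodata = self.values != self.nodata
        if not np.all(np.isfinite(self.values[not_nodata])):
            raise ValueError("surface values must be finite or the nodata sentinel")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) coordinate arrays of cell centres, shape (nrows, ncols).

        Row 0 is the northernmost row, consistent with ``values``.
        """
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata


def write_grid_ascii(surface: Surface, path: str | Path) -> None:
    """Write a :class:`Surface` as an ESRI ASCII grid (.asc).

    Six header lines (ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value) followed by data rows north to south. Values are
    formatted with 10 significant digits so a re-read reproduces them
    well within 1e-4 mg/L; nodata cells are written as the sentinel
    verbatim.
    """
    lines = [
        f"ncols {surface.ncols}",
        f"nrows {surface.nrows}",
        f"xllcorner {surface.xll:.10g}",
        f"yllcorner {surface.yll:.10g}",
        f"cellsize {surface.cellsize:.10g}",
        f"NODATA_value {surface.nodata:.10g}",
    ]
    for row in surface.values:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_grid_ascii(path: str | Path) -> Surface:
    """Read an ESRI ASCII grid written by :func:`write_grid_ascii`."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if len(text) < 7:
        raise SchemaError(f"{path}: truncated ASCII grid")
    header: dict[str, float] = {}
    for line in text[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = np.array([[float(v) for v in line.split()] for line in text[6:]])
    return Surface(
        ncols=ncols,
        nrows=nrows,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header["nodata_value"],
        values=values,
    )
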