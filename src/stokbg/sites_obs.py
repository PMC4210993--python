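"""Monitors, hourly observations, gridded model fields, and site classification.

All internal geometry is planar, in kilometres, in a single projection; readers
that receive lon/lat project once at ingest with a local equirectangular
projection.  Time is an integer hour index relative to a configured epoch, so
that every series in a study shares one clock.

A monitoring site carries the regulatory *objective* label of its operator
(highest concentration, population exposure, source impact, general
background / regional transport, or welfare related).  Sites whose objective is
general background *and* that lie far enough from the local-source region are
the ones whose observations can be taken as exact ("hard") measurements of the
regional background concentration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Default screening distance (km) between a background-objective site and the
#: local-source region for the site's data to count as hard background data.
DEFAULT_BACKGROUND_DISTANCE_KM = 60.0


class SchemaError(ValueError):
    """A tabular input is missing required columns or has malformed ones."""


class ValidationError(ValueError):
    """A tabular input has rows that violate the data model's invariants."""


class Objective(str, enum.Enum):
    """Regulatory monitoring objective of a site."""

    HIGHEST_CONCENTRATION = "highest_concentration"
    POPULATION_EXPOSURE = "population_exposure"
    SOURCE_IMPACT = "source_impact"
    GENERAL_BACKGROUND = "general_background"
    WELFARE_RELATED = "welfare_related"


@dataclass(frozen=True)
class SpaceTimePoint:
    """A space/time coordinate p = (s, t): planar km easting/northing, hour index."""

    x: float
    y: float
    t: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates ({self.x}, {self.y})")
        if self.t != int(self.t):
            raise ValidationError(f"hour index must be an integer, got {self.t!r}")
        object.__setattr__(self, "t", int(self.t))


@dataclass(frozen=True)
class MonitorSite:
    """A fixed monitoring site with planar coordinates (km) and its objective."""

    site_id: str
    x: float
    y: float
    objective: Objective
    scale: str | None = None  # "urban", "regional", or other free-form label

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"site {self.site_id}: non-finite coordinates")


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of half-open square cells, 0-based.

    Cell (i, j) covers [origin + i*cell_size, origin + (i+1)*cell_size) in x
    and likewise in y; a point on a right/top outer edge is outside the grid.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("nx, ny must be >= 1")

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.origin_x + (i + 0.5) * self.cell_size,
            self.origin_y + (j + 0.5) * self.cell_size,
        )

    def all_cell_centers(self) -> np.ndarray:
        """(nx*ny, 2) array of cell-center coordinates, i-major order."""
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        xs = self.origin_x + (ii.ravel() + 0.5) * self.cell_size
        ys = self.origin_y + (jj.ravel() + 0.5) * self.cell_size
        return np.column_stack([xs, ys])


def locate_in_grid(grid: GridSpec, x: float, y: float) -> tuple[int, int] | None:
    """Cell index (i, j) containing a point, or None if the point is outside.

    Cells are half-open, so a point exactly on the right or top outer boundary
    of the grid is outside.
    """
    i = math.floor((x - grid.origin_x) / grid.cell_size)
    j = math.floor((y - grid.origin_y) / grid.cell_size)
    if 0 <= i < grid.nx and 0 <= j < grid.ny:
        return (i, j)
    return None


def distance_km(a, b) -> float:
    """Euclidean planar distance in km between two points.

    Accepts anything with ``.x``/``.y`` attributes or a 2-sequence (x, y).
    """
    ax, ay = _xy(a)
    bx, by = _xy(b)
    return math.hypot(ax - bx, ay - by)


def _xy(p) -> tuple[float, float]:
    if hasattr(p, "x") and hasattr(p, "y"):
        return float(p.x), float(p.y)
    return float(p[0]), float(p[1])


@dataclass(frozen=True)
class LocalProjection:
    """Local equirectangular projection from lon/lat (degrees) to planar km.

    Adequate for study domains a few hundred km across: x errors stay well
    below the 12-km model grid cell at these scales.
    """

    ref_lon: float
    ref_lat: float

    def to_xy(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = EARTH_RADIUS_KM * np.cos(np.deg2rad(self.ref_lat)) * np.deg2rad(lon - self.ref_lon)
        y = EARTH_RADIUS_KM * np.deg2rad(lat - self.ref_lat)
        return x, y


@dataclass(frozen=True)
class LocalSourceRegion:
    """The set of grid cells whose local emissions are removed in the zero-out run."""

    cells: frozenset[tuple[int, int]]
    reference_point: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("LocalSourceRegion requires at least one cell")

    @classmethod
    def from_cells(
        cls,
        cells: Iterable[tuple[int, int]],
        grid: GridSpec,
        reference_point: tuple[float, float] | None = None,
    ) -> "LocalSourceRegion":
        """Build a region from cell indices; default anchor is the cell-centroid."""
        cellset = frozenset((int(i), int(j)) for i, j in cells)
        if not cellset:
            raise ValidationError("LocalSourceRegion requires at least one cell")
        for i, j in cellset:
            if not (0 <= i < grid.nx and 0 <= j < grid.ny):
                raise ValidationError(f"region cell ({i}, {j}) outside grid")
        if reference_point is None:
            centers = np.array([grid.cell_center(i, j) for i, j in sorted(cellset)])
            reference_point = (float(centers[:, 0].mean()), float(centers[:, 1].mean()))
        return cls(cells=cellset, reference_point=reference_point)


@dataclass
class ObservationSeries:
    """Hour-indexed observed concentrations at one site for one pollutant."""

    site_id: str
    pollutant: str
    unit: str
    hours: np.ndarray  # int, strictly increasing
    values: np.ndarray  # float, >= 0

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.hours.shape != self.values.shape:
            raise ValidationError("hours and values must be the same length")
        if self.hours.size and np.any(np.diff(self.hours) <= 0):
            raise ValidationError(f"site {self.site_id}: duplicate or unsorted hours")
        if np.any(self.values < 0):
            raise ValidationError(f"site {self.site_id}: negative concentration value")

    def __len__(self) -> int:
        return int(self.hours.size)


@dataclass
class GriddedHourlyField:
    """An hourly concentration field on a regular grid (e.g., a chemistry-model run).

    ``values`` has shape (nx, ny, n_times); NaN marks a missing cell-hour.
    """

    grid: GridSpec
    times: np.ndarray  # int hour indices, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.nx, self.grid.ny, self.times.size)
        if self.values.shape != expected:
            raise ValidationError(
                f"field shape {self.values.shape} does not match grid/time axes {expected}"
            )
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("field time axis must be strictly increasing")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValidationError("negative concentrations in gridded field")

    def cell_series(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) at one cell."""
        if not (0 <= i < self.grid.nx and 0 <= j < self.grid.ny):
            raise ValidationError(f"cell ({i}, {j}) outside grid")
        return self.times, self.values[i, j, :]


# ---------------------------------------------------------------------------
# Time handling


def hour_index(timestamps, epoch: str | pd.Timestamp) -> np.ndarray:
    """Convert ISO-8601 timestamps to integer hours since ``epoch`` (floored)."""
    ts = pd.to_datetime(timestamps)
    epoch_ts = pd.Timestamp(epoch)
    delta = (pd.DatetimeIndex(np.atleast_1d(np.asarray(ts))) - epoch_ts).total_seconds()
    return np.floor(np.asarray(delta) / 3600.0).astype(np.int64)


def hour_to_timestamp(hours, epoch: str | pd.Timestamp) -> pd.DatetimeIndex:
    epoch_ts = pd.Timestamp(epoch)
    return epoch_ts + pd.to_timedelta(np.asarray(hours, dtype=np.int64), unit="h")


# ---------------------------------------------------------------------------
# Tabular I/O

_OBS_COLUMNS = ("site_id", "timestamp", "pollutant", "value")


def read_observations(
    path,
    epoch: str | pd.Timestamp,
    schema: Mapping[str, str] | None = None,
    analysis_year: int | None = None,
    window_years: int = 1,
) -> dict[tuple[str, str], ObservationSeries]:
    """Read hourly observations from a delimited file into per-(site, pollutant) series.

    Required columns: site_id, timestamp (ISO-8601), pollutant, value; an
    optional ``unit`` column must be consistent per pollutant.  ``schema`` maps
    required names to the file's actual column names.  If ``analysis_year`` is
    given, rows outside [analysis_year - window_years, analysis_year +
    window_years] are dropped at ingest (the estimation window extends one year
    either side of the year of analysis by default).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observations file missing column(s): {', '.join(missing)}")
    if "unit" not in df.columns:
        df["unit"] = ""

    bad = df.index[pd.to_numeric(df["value"], errors="coerce") < 0]
    if len(bad):
        raise ValidationError(f"negative observation value at row {int(bad[0])}")

    ts = pd.to_datetime(df["timestamp"])
    if analysis_year is not None:
        keep = (ts.dt.year >= analysis_year - window_years) & (
            ts.dt.year <= analysis_year + window_years
        )
        df = df.loc[keep].copy()
        ts = ts.loc[keep]
    df["hour"] = hour_index(ts, epoch)

    dup = df.duplicated(subset=["site_id", "pollutant", "hour"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (site, pollutant, hour) key: ({row['site_id']}, "
            f"{row['pollutant']}, hour {int(row['hour'])})"
        )

    out: dict[tuple[str, str], ObservationSeries] = {}
    for (site, pollutant), g in df.groupby(["site_id", "pollutant"], sort=True):
        units = g["unit"].astype(str).unique()
        if len(units) > 1:
            raise ValidationError(f"inconsistent units for ({site}, {pollutant}): {units}")
        g = g.sort_values("hour")
        out[(str(site), str(pollutant))] = ObservationSeries(
            site_id=str(site),
            pollutant=str(pollutant),
            unit=str(units[0]),
            hours=g["hour"].to_numpy(),
            values=g["value"].to_numpy(dtype=float),
        )
    return out


def write_observations(
    observations: Mapping[tuple[str, str], ObservationSeries] | Iterable[ObservationSeries],
    path,
    epoch: str | pd.Timestamp,
) -> None:
    """Write observation series to the tabular format ``read_observations`` accepts."""
    series = (
        list(observations.values())
        if isinstance(observations, Mapping)
        else list(observations)
    )
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "site_id": s.site_id,
                    "timestamp": hour_to_timestamp(s.hours, epoch).strftime(
                        "%Y-%m-%dT%H:%M:%S"
                    ),
                    "pollutant": s.pollutant,
                    "value": s.values,
                    "unit": s.unit,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(_OBS_COLUMNS) + ["unit"]
    )
    # %.17g keeps the write -> read cycle bit-exact for doubles
    df.to_csv(path, index=False, float_format="%.17g")


_SITE_COLUMNS = ("site_id", "objective")


def read_sites(
    path,
    projection: LocalProjection | None = None,
    schema: Mapping[str, str] | None = None,
) -> list[MonitorSite]:
    """Read site metadata; coordinates either planar (x, y in km) or lon/lat.

    If the file has lon/lat columns, a :class:`LocalProjection` is required (or
    one is built about the mean lon/lat of the file).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sites file missing column(s): {', '.join(missing)}")

    if {"x", "y"}.issubset(df.columns):
        xs = df["x"].to_numpy(dtype=float)
        ys = df["y"].to_numpy(dtype=float)
    elif {"lon", "lat"}.issubset(df.columns):
        if projection is None:
            projection = LocalProjection(
                ref_lon=float(df["lon"].mean()), ref_lat=float(df["lat"].mean())
            )
        xs, ys = projection.to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    else:
        raise SchemaError("sites file needs either x/y (km) or lon/lat columns")

    if df["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in sites file")

    sites = []
    for k, row in enumerate(df.itertuples(index=False)):
        scale = getattr(row, "scale", None)
        scale = None if scale is None or (isinstance(scale, float) and math.isnan(scale)) else str(scale)
        sites.append(
            MonitorSite(
                site_id=str(row.site_id),
                x=float(xs[k]),
                y=float(ys[k]),
                objective=Objective(str(row.objective)),
                scale=scale,
            )
        )
    return sites


def write_sites(sites: Sequence[MonitorSite], path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "objective": [s.objective.value for s in sites],
            "scale": [s.scale for s in sites],
        }
    ).to_csv(path, index=False)


def read_gridded_field(path, grid: GridSpec) -> GriddedHourlyField:
    """Read a gridded hourly field from long-format tabular (i, j, hour, value)."""
    df = pd.read_csv(path)
    missing = [c for c in ("i", "j", "hour", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"gridded file missing column(s): {', '.join(missing)}")
    times = np.sort(df["hour"].unique()).astype(np.int64)
    tpos = {int(t): k for k, t in enumerate(times)}
    values = np.full((grid.nx, grid.ny, times.size), np.nan)
    ii = df["i"].to_numpy(dtype=int)
    jj = df["j"].to_numpy(dtype=int)
    if np.any((ii < 0) | (ii >= grid.nx) | (jj < 0) | (jj >= grid.ny)):
        raise ValidationError("gridded file has cell indices outside the grid")
    kk = df["hour"].map(tpos).to_numpy(dtype=int)
    values[ii, jj, kk] = df["value"].to_numpy(dtype=float)
    return GriddedHourlyField(grid=grid, times=times, values=values)


def write_gridded_field(field: GriddedHourlyField, path) -> None:
    nx, ny, nt = field.values.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nt), indexing="ij"
    )
    vals = field.values.ravel()
    ok = np.isfinite(vals)
    pd.DataFrame(
        {
            "i": ii.ravel()[ok],
            "j": jj.ravel()[ok],
            "hour": field.times[kk.ravel()[ok]],
            "value": vals[ok],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class SitePartition:
    """Exhaustive, disjoint split of a site roster into background / nonbackground."""

    background: tuple[MonitorSite, ...]
    nonbackground: tuple[MonitorSite, ...]

    @property
    def background_ids(self) -> frozenset[str]:
        return frozenset(s.site_id for s in self.background)

    @property
    def nonbackground_ids(self) -> frozenset[str]:
        return frozenset(s.site_id for s in self.nonbackground)


def classify_sites(
    sites: Sequence[MonitorSite],
    region: LocalSourceRegion,
    min_distance_km: float = DEFAULT_BACKGROUND_DISTANCE_KM,
) -> SitePartition:
    """Partition sites into background vs nonbackground.

    A site is background iff its objective is general background *and* it lies
    at least ``min_distance_km`` from the local-source region's reference
    point; every other site is nonbackground.
    """
    if min_distance_km < 0:
        raise ValidationError("min_distance_km must be >= 0")
    if not sites:
        raise ValidationError("classify_sites: empty site set")
    bg, nbg = [], []
    for s in sites:
        if (
            s.objective is Objective.GENERAL_BACKGROUND
            and distance_km(s, region.reference_point) >= min_distance_km
        ):
            bg.append(s)
        else:
            nbg.append(s)
    return SitePartition(background=tuple(bg), nonbackground=tuple(nbg))
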