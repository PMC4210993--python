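"""Ratio statistics from paired total / zero-out model runs, and hard/soft data.

The zero-out-to-total concentration ratio at a station's grid cell,
r_t = zeroout_t / total_t, estimates the fraction of the observed total that is
regional background.  Its temporal mean mu_R and variance sigma2_R (computed
after trimming ratios below the 1st and above the 99th percentile) turn an
observation z at a nonbackground station into a *soft* background datum with
mean z * mu_R and known measurement-error variance z**2 * sigma2_R.
Observations at background stations enter unchanged as *hard* (exact) data.

The ratio statistics are per-station constants: the model runs that produce
them need not cover the same years as the observations (pairing is by station
cell, never by timestamp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .sites_obs import (
    GriddedHourlyField,
    MonitorSite,
    ObservationSeries,
    SpaceTimePoint,
    ValidationError,
    locate_in_grid,
)

DEFAULT_TRIM_PERCENTILES = (1.0, 99.0)


@dataclass(frozen=True)
class HardDatum:
    """An exact background observation (measurement-error variance zero)."""

    point: SpaceTimePoint
    value: float
    source_site: str

    error_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("hard datum value must be >= 0")
        if self.error_variance != 0.0:
            raise ValidationError("hard data have error variance exactly 0")


@dataclass(frozen=True)
class SoftDatum:
    """An uncertain background datum: mean z*mu_R, error variance z**2*sigma2_R."""

    point: SpaceTimePoint
    mean: float
    error_variance: float
    source_site: str

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValidationError("soft datum mean must be >= 0")
        if self.error_variance < 0:
            raise ValidationError("soft datum error variance must be >= 0")


@dataclass(frozen=True)
class RatioSeries:
    """Hour-indexed zero-out/total ratios at one station's grid cell."""

    site_id: str
    cell: tuple[int, int]
    hours: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "hours", np.asarray(self.hours, dtype=np.int64))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.hours.shape != self.values.shape:
            raise ValidationError("ratio hours/values length mismatch")
        if self.values.size and (not np.all(np.isfinite(self.values)) or np.any(self.values < 0)):
            raise ValidationError("ratio values must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RatioStats:
    """Temporal mean/variance of the zero-out/total ratio at one station."""

    site_id: str
    mu_R: float
    sigma2_R: float
    n_raw: int
    n_used: int

    def __post_init__(self) -> None:
        if self.mu_R < 0 or self.sigma2_R < 0:
            raise ValidationError("ratio statistics must be >= 0")
        if self.n_used > self.n_raw:
            raise ValidationError("n_used cannot exceed n_raw")


def hourly_ratio_series(
    total: GriddedHourlyField,
    zeroout: GriddedHourlyField,
    site: MonitorSite,
) -> RatioSeries:
    """Zero-out/total ratio for every hour with positive total at the site's cell.

    Hours where either field is missing, or where total is zero (so the ratio
    is undefined), are omitted from the series.
    """
    if total.grid != zeroout.grid:
        raise ValidationError("total and zero-out fields are on different grids")
    if not np.array_equal(total.times, zeroout.times):
        raise ValidationError("total and zero-out fields have different time axes")
    cell = locate_in_grid(total.grid, site.x, site.y)
    if cell is None:
        raise ValidationError(f"site {site.site_id} lies outside the model grid")
    times, tot = total.cell_series(*cell)
    _, zo = zeroout.cell_series(*cell)
    ok = np.isfinite(tot) & np.isfinite(zo) & (tot > 0)
    return RatioSeries(site_id=site.site_id, cell=cell, hours=times[ok], values=zo[ok] / tot[ok])


def trim_outliers(
    series: RatioSeries,
    lo_pct: float = DEFAULT_TRIM_PERCENTILES[0],
    hi_pct: float = DEFAULT_TRIM_PERCENTILES[1],
) -> RatioSeries:
    """Drop ratios strictly below the lo percentile or above the hi percentile.

    Percentiles use linear interpolation between order statistics; survivor
    order is preserved and the operation is idempotent.
    """
    if len(series) == 0:
        raise ValidationError("cannot trim an empty ratio series")
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValidationError("need 0 <= lo_pct < hi_pct <= 100")
    lo, hi = np.percentile(series.values, [lo_pct, hi_pct])
    keep = (series.values >= lo) & (series.values <= hi)
    return RatioSeries(
        site_id=series.site_id,
        cell=series.cell,
        hours=series.hours[keep],
        values=series.values[keep],
    )


def ratio_stats(series: RatioSeries, n_raw: int | None = None) -> RatioStats:
    """Mean and unbiased (n-1) variance of a (typically trimmed) ratio series."""
    n = len(series)
    if n < 2:
        raise ValidationError("ratio statistics need at least 2 values")
    return RatioStats(
        site_id=series.site_id,
        mu_R=float(np.mean(series.values)),
        sigma2_R=float(np.var(series.values, ddof=1)),
        n_raw=int(n_raw) if n_raw is not None else n,
        n_used=n,
    )


def station_ratio_stats(
    total: GriddedHourlyField,
    zeroout: GriddedHourlyField,
    site: MonitorSite,
    lo_pct: float = DEFAULT_TRIM_PERCENTILES[0],
    hi_pct: float = DEFAULT_TRIM_PERCENTILES[1],
) -> RatioStats:
    """Convenience: ratio series -> trim -> moments for one station."""
    raw = hourly_ratio_series(total, zeroout, site)
    trimmed = trim_outliers(raw, lo_pct, hi_pct)
    return ratio_stats(trimmed, n_raw=len(raw))


def build_soft_data(
    obs: ObservationSeries,
    stats: RatioStats,
    site: MonitorSite,
) -> list[SoftDatum]:
    """One soft datum per observed hour: mean z*mu_R, variance z**2*sigma2_R.

    The ratio statistics are constant in time, so every observed hour gets a
    datum even if the model-run ratio series had no data at that hour.
    """
    if stats.site_id != site.site_id or obs.site_id != site.site_id:
        raise ValidationError(
            f"site mismatch: obs {obs.site_id}, stats {stats.site_id}, site {site.site_id}"
        )
    if len(obs) < 1:
        raise ValidationError("observation series is empty")
    return [
        SoftDatum(
            point=SpaceTimePoint(site.x, site.y, int(h)),
            mean=float(z) * stats.mu_R,
            error_variance=float(z) ** 2 * stats.sigma2_R,
            source_site=site.site_id,
        )
        for h, z in zip(obs.hours, obs.values)
    ]


def build_hard_data(
    obs: ObservationSeries,
    site: MonitorSite,
    background_ids: Iterable[str],
) -> list[HardDatum]:
    """One hard datum per observed hour at a background-classified site."""
    if site.site_id not in set(background_ids):
        raise ValidationError(
            f"site {site.site_id} is not classified background; cannot build hard data"
        )
    if obs.site_id != site.site_id:
        raise ValidationError(f"site mismatch: obs {obs.site_id} vs site {site.site_id}")
    return [
        HardDatum(
            point=SpaceTimePoint(site.x, site.y, int(h)),
            value=float(z),
            source_site=site.site_id,
        )
        for h, z in zip(obs.hours, obs.values)
    ]


# ---------------------------------------------------------------------------
# Tabular I/O so model-run processing and kriging can run as separate stages


def write_ratio_stats(stats: Iterable[RatioStats], path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "mu_R": s.mu_R,
                "sigma2_R": s.sigma2_R,
                "n_raw": s.n_raw,
                "n_used": s.n_used,
            }
            for s in stats
        ]
    ).to_csv(path, index=False)


def read_ratio_stats(path) -> dict[str, RatioStats]:
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "mu_R", "sigma2_R", "n_raw", "n_used") if c not in df.columns]
    if missing:
        raise ValidationError(f"ratio-stats file missing column(s): {', '.join(missing)}")
    return {
        str(r.site_id): RatioStats(
            site_id=str(r.site_id),
            mu_R=float(r.mu_R),
            sigma2_R=float(r.sigma2_R),
            n_raw=int(r.n_raw),
            n_used=int(r.n_used),
        )
        for r in df.itertuples(index=False)
    }
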