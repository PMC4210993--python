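"""Synthetic scenarios with the statistical structure the estimator assumes.

A scenario is built from three layers:

* a Gaussian space/time random field for the regional background B(s, t),
  with a nested separable exponential covariance and a constant mean — the
  exact data-generating model the kriging step assumes;
* a deterministic local-source field L(s, t) = sum of point sources with
  exponential spatial decay and a diurnal cycle, concentrated in a designated
  zero-out cell block — a stylized stand-in for dispersion-model output;
* noisy observation and chemistry-model layers: monitor observations are
  Z = B + L plus Gaussian noise, and the paired "total"/"zero-out" gridded
  fields are cell values of Z and B times independent multiplicative
  lognormal noise.

Every stage of the estimation pipeline can therefore be exercised against
known truth, with all randomness driven by one seed.

Sampling is exact: each separable structure's hourly exponential temporal
factor is an AR(1) process, so a draw is (spatial Cholesky factor) times
(AR(1) innovations), summed over structures.  No thinning or interpolation is
involved; the joint covariance over all requested points and hours matches
the requested model up to the Cholesky jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .covariance import CovarianceModel, CovarianceStructure
from .sites_obs import (
    GriddedHourlyField,
    GridSpec,
    LocalSourceRegion,
    MonitorSite,
    Objective,
    ObservationSeries,
    ValidationError,
    distance_km,
)

#: Default true background covariance: a long-range synoptic structure, a
#: mesoscale structure, and a short local structure (sills sum to 1).
DEFAULT_BACKGROUND_MODEL = CovarianceModel(
    structures=(
        CovarianceStructure(sill=0.55, spatial_range=300.0, temporal_range=36.0),
        CovarianceStructure(sill=0.35, spatial_range=90.0, temporal_range=12.0),
        CovarianceStructure(sill=0.10, spatial_range=25.0, temporal_range=3.0),
    )
)


@dataclass(frozen=True)
class LocalSource:
    """A point source with exponential spatial decay and a diurnal cycle."""

    x: float
    y: float
    strength: float
    decay_km: float
    diurnal_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.strength < 0 or self.decay_km <= 0:
            raise ValidationError("source strength must be >= 0 and decay_km > 0")
        if not (0 <= self.diurnal_amplitude <= 1):
            raise ValidationError("diurnal amplitude must be in [0, 1]")


@dataclass(frozen=True)
class MonitorSpec:
    site_id: str
    x: float
    y: float
    objective: Objective


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario; the seed is mandatory.

    Defaults mirror the target application's geometry: a 12-km model grid, a
    4 x 4 block of zero-out cells in the middle, point sources inside the
    block, ~10 background monitors at least 60 km out and ~10 nonbackground
    monitors in and around the block.
    """

    seed: int
    grid: GridSpec = field(default_factory=lambda: GridSpec(0.0, 0.0, 12.0, 30, 30))
    n_hours: int = 720
    background_model: CovarianceModel = DEFAULT_BACKGROUND_MODEL
    background_mean: float = 7.8
    region_cells: tuple[tuple[int, int], ...] = tuple(
        (i, j) for i in range(13, 17) for j in range(13, 17)
    )
    sources: tuple[LocalSource, ...] = (
        LocalSource(x=165.0, y=170.0, strength=8.0, decay_km=8.0, diurnal_amplitude=0.5),
        LocalSource(x=178.0, y=176.0, strength=6.0, decay_km=6.0, diurnal_amplitude=0.5),
        LocalSource(x=172.0, y=186.0, strength=4.0, decay_km=10.0, diurnal_amplitude=0.3),
    )
    monitors: tuple[MonitorSpec, ...] | None = None  # None: default roster
    obs_noise_sd: float = 0.1
    ratio_noise_sigma: float = 0.05
    min_background_distance_km: float = 60.0
    pollutant: str = "SYN"
    unit: str = "ug/m3"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("scenario seed is mandatory")


def default_monitors(grid: GridSpec, region: LocalSourceRegion) -> tuple[MonitorSpec, ...]:
    """Deterministic default roster: 10 background ring sites + 10 nonbackground."""
    cx, cy = region.reference_point
    bg = []
    for k in range(10):
        ang = 2 * math.pi * k / 10 + 0.2
        rad = 85.0 + 20.0 * (k % 3)
        bg.append(
            MonitorSpec(
                site_id=f"BG{k:02d}",
                x=cx + rad * math.cos(ang),
                y=cy + rad * math.sin(ang),
                objective=Objective.GENERAL_BACKGROUND,
            )
        )
    nb_xy = [
        (166.0, 171.0), (177.0, 175.0), (171.0, 185.0),  # next to the sources
        (160.0, 180.0), (185.0, 165.0), (175.0, 160.0),  # elsewhere in the block
        (140.0, 150.0), (205.0, 195.0), (150.0, 210.0), (215.0, 155.0),  # near-urban ring
    ]
    nb = [
        MonitorSpec(
            site_id=f"NB{k:02d}",
            x=x,
            y=y,
            objective=Objective.SOURCE_IMPACT if k < 6 else Objective.POPULATION_EXPOSURE,
        )
        for k, (x, y) in enumerate(nb_xy)
    ]
    return tuple(bg + nb)


def ring_background_monitors(
    n: int,
    region: LocalSourceRegion,
    rng: np.random.Generator,
    r_min: float = 65.0,
    r_max: float = 170.0,
) -> tuple[MonitorSpec, ...]:
    """n background sites at random angles/radii in an annulus around the region."""
    cx, cy = region.reference_point
    ang = rng.uniform(0, 2 * math.pi, size=n)
    rad = rng.uniform(r_min, r_max, size=n)
    return tuple(
        MonitorSpec(
            site_id=f"BG{k:03d}",
            x=float(cx + rad[k] * math.cos(ang[k])),
            y=float(cy + rad[k] * math.sin(ang[k])),
            objective=Objective.GENERAL_BACKGROUND,
        )
        for k in range(n)
    )


def tiny_config(seed: int) -> ScenarioConfig:
    """A seconds-scale scenario for smoke tests and the CLI demo."""
    grid = GridSpec(0.0, 0.0, 12.0, 12, 12)
    region_cells = tuple((i, j) for i in range(5, 7) for j in range(5, 7))
    region = LocalSourceRegion.from_cells(region_cells, grid)
    cx, cy = region.reference_point
    monitors = tuple(
        MonitorSpec(f"BG{k}", cx + 66.0 * math.cos(a), cy + 66.0 * math.sin(a), Objective.GENERAL_BACKGROUND)
        for k, a in enumerate(np.linspace(0.3, 2 * math.pi + 0.3, 6, endpoint=False))
    ) + (
        MonitorSpec("NB0", cx + 1.0, cy - 2.0, Objective.SOURCE_IMPACT),
        MonitorSpec("NB1", cx - 4.0, cy + 5.0, Objective.POPULATION_EXPOSURE),
    )
    return ScenarioConfig(
        seed=seed,
        grid=grid,
        n_hours=96,
        region_cells=region_cells,
        sources=(LocalSource(x=cx, y=cy, strength=5.0, decay_km=8.0, diurnal_amplitude=0.5),),
        monitors=monitors,
    )


# ---------------------------------------------------------------------------
# Field sampling


def sample_gaussian_field(
    points: np.ndarray,
    n_hours: int,
    model: CovarianceModel,
    rng: np.random.Generator,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Exact zero-mean draw of the nested separable field at points x hours.

    Returns an (n_points, n_hours) array whose covariance between entries
    (a, t1) and (b, t2) is C(|s_a - s_b|, |t1 - t2|) for the given model.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    out = np.zeros((n, n_hours))
    D = cdist(points, points)
    for s in model.structures:
        R = np.exp(-3.0 * D / s.spatial_range)
        R[np.diag_indices_from(R)] += jitter
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("requested covariance model is not positive definite") from exc
        rho = math.exp(-3.0 / s.temporal_range)
        W = np.empty((n, n_hours))
        W[:, 0] = rng.standard_normal(n)
        innov_sd = math.sqrt(1.0 - rho * rho)
        for k in range(1, n_hours):
            W[:, k] = rho * W[:, k - 1] + innov_sd * rng.standard_normal(n)
        out += math.sqrt(s.sill) * (L @ W)
    return out


def simulate_background(
    config: ScenarioConfig,
    points: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Background field at the given points: mean + GRF, floored at 0.

    Returns (field, floor_fraction); the floor fraction is the share of values
    that were negative before flooring (kept below ~1% by sensible configs so
    the Gaussian moment structure survives essentially intact).
    """
    f = config.background_mean + sample_gaussian_field(
        points, config.n_hours, config.background_model, rng
    )
    neg = f < 0
    floor_fraction = float(np.mean(neg))
    f[neg] = 0.0
    return f, floor_fraction


def local_field(
    points: np.ndarray,
    hours: np.ndarray,
    sources: tuple[LocalSource, ...],
) -> np.ndarray:
    """Closed-form local-source field L(s, t) at points x hours (always >= 0)."""
    points = np.asarray(points, dtype=float)
    hours = np.asarray(hours, dtype=np.int64)
    out = np.zeros((points.shape[0], hours.size))
    if not sources:
        return out
    diurnal_phase = np.sin(2.0 * np.pi * (hours % 24) / 24.0)
    for src in sources:
        d = np.hypot(points[:, 0] - src.x, points[:, 1] - src.y)
        profile = 1.0 + src.diurnal_amplitude * diurnal_phase
        out += src.strength * np.exp(-d / src.decay_km)[:, None] * profile[None, :]
    return out


# ---------------------------------------------------------------------------
# Scenario assembly


@dataclass
class Scenario:
    """A fully realized synthetic study: truth, observations, and model fields."""

    config: ScenarioConfig
    region: LocalSourceRegion
    sites: list[MonitorSite]
    observations: dict[str, ObservationSeries]
    total_field: GriddedHourlyField
    zeroout_field: GriddedHourlyField
    hours: np.ndarray
    truth_background: dict[str, np.ndarray]  # per monitor, over hours
    truth_local: dict[str, np.ndarray]
    floor_fraction: float

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def monitor_receptors(self, site_ids=None) -> pd.DataFrame:
        """Monitors as an estimation-receptor table (receptor_id, x, y)."""
        sites = [s for s in self.sites if site_ids is None or s.site_id in set(site_ids)]
        return pd.DataFrame(
            {"receptor_id": [s.site_id for s in sites],
             "x": [s.x for s in sites],
             "y": [s.y for s in sites]}
        )

    def local_concentrations(self, receptors: pd.DataFrame) -> pd.DataFrame:
        """Dispersion-model stand-in: closed-form local values at receptors."""
        pts = receptors[["x", "y"]].to_numpy(dtype=float)
        L = local_field(pts, self.hours, self.config.sources)
        rows = []
        for k, rid in enumerate(receptors["receptor_id"]):
            rows.append(pd.DataFrame({"receptor_id": str(rid), "hour": self.hours, "local": L[k]}))
        return pd.concat(rows, ignore_index=True)

    def in_region_site_ids(self) -> list[str]:
        """Nonbackground monitors located inside the zero-out cell block."""
        from .sites_obs import locate_in_grid

        ids = []
        for s in self.sites:
            cell = locate_in_grid(self.grid, s.x, s.y)
            if cell in self.region.cells and s.objective is not Objective.GENERAL_BACKGROUND:
                ids.append(s.site_id)
        return ids

    def pipeline_inputs(self, receptors: pd.DataFrame | None = None):
        """Bundle scenario outputs as hybrid-pipeline inputs (monitors as receptors)."""
        from .hybrid_eval import PipelineInputs

        receptors = receptors if receptors is not None else self.monitor_receptors()
        return PipelineInputs(
            sites=self.sites,
            observations=self.observations,
            region=self.region,
            total_field=self.total_field,
            zeroout_field=self.zeroout_field,
            local=self.local_concentrations(receptors),
            receptors=receptors,
            estimation_hours=self.hours,
        )


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Draw a complete scenario from its config; deterministic given the seed.

    The background field is sampled *jointly* at all grid-cell centers and
    monitor locations so the gridded model fields and the point observations
    are realizations of one consistent field.
    """
    region = LocalSourceRegion.from_cells(config.region_cells, config.grid)
    monitors = config.monitors if config.monitors is not None else default_monitors(config.grid, region)

    for m in monitors:
        if m.objective is Objective.GENERAL_BACKGROUND:
            d = distance_km((m.x, m.y), region.reference_point)
            if d < config.min_background_distance_km:
                raise ValidationError(
                    f"background-labeled monitor {m.site_id} is only {d:.1f} km from the "
                    f"local-source region (< {config.min_background_distance_km} km)"
                )

    sites = [
        MonitorSite(site_id=m.site_id, x=m.x, y=m.y, objective=m.objective)
        for m in monitors
    ]
    hours = np.arange(config.n_hours, dtype=np.int64)

    cell_centers = config.grid.all_cell_centers()
    mon_xy = np.array([[m.x, m.y] for m in monitors])
    all_pts = np.vstack([cell_centers, mon_xy])

    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_obs, rng_zo, rng_tot = (np.random.default_rng(s) for s in ss.spawn(4))

    B_all, floor_fraction = simulate_background(config, all_pts, rng_field)
    L_all = local_field(all_pts, hours, config.sources)
    Z_all = B_all + L_all

    n_cells = cell_centers.shape[0]
    B_cells = B_all[:n_cells].reshape(config.grid.nx, config.grid.ny, config.n_hours)
    Z_cells = Z_all[:n_cells].reshape(config.grid.nx, config.grid.ny, config.n_hours)

    sig = config.ratio_noise_sigma
    zo_vals = B_cells * np.exp(rng_zo.normal(0.0, sig, size=B_cells.shape)) if sig > 0 else B_cells.copy()
    tot_vals = Z_cells * np.exp(rng_tot.normal(0.0, sig, size=Z_cells.shape)) if sig > 0 else Z_cells.copy()
    zeroout_field = GriddedHourlyField(grid=config.grid, times=hours, values=zo_vals)
    total_field = GriddedHourlyField(grid=config.grid, times=hours, values=tot_vals)

    observations: dict[str, ObservationSeries] = {}
    truth_background: dict[str, np.ndarray] = {}
    truth_local: dict[str, np.ndarray] = {}
    for k, m in enumerate(monitors):
        z = Z_all[n_cells + k]
        noise = rng_obs.normal(0.0, config.obs_noise_sd, size=z.shape) if config.obs_noise_sd > 0 else 0.0
        obs = np.maximum(z + noise, 0.0)
        observations[m.site_id] = ObservationSeries(
            site_id=m.site_id,
            pollutant=config.pollutant,
            unit=config.unit,
            hours=hours,
            values=obs,
        )
        truth_background[m.site_id] = B_all[n_cells + k]
        truth_local[m.site_id] = L_all[n_cells + k]

    return Scenario(
        config=config,
        region=region,
        sites=sites,
        observations=observations,
        total_field=total_field,
        zeroout_field=zeroout_field,
        hours=hours,
        truth_background=truth_background,
        truth_local=truth_local,
        floor_fraction=floor_fraction,
    )
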