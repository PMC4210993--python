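"""Hybrid totals (kriged background + local dispersion) and their evaluation.

Because dispersion is largely additive, the total concentration at a receptor
is modelled as Z = Z_LS + B: the local-source contribution from a dispersion
model plus the kriged regional background.  The *old hybrid* variant treats
every monitor's observations as hard data when kriging the background — which
re-introduces local-source signal into the background and double-counts it
once Z_LS is added.  The *new hybrid* downweights nonbackground monitors via
ratio-based soft data, which is the double-counting fix under evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariance import (
    CovarianceModel,
    TransformedDataset,
    TransformSpec,
    empirical_covariance,
    fit_covariance,
    transform,
    DEFAULT_N_STRUCTURES,
    DEFAULT_SPATIAL_EDGES,
    DEFAULT_TEMPORAL_EDGES,
)
from .sites_obs import (
    GriddedHourlyField,
    LocalSourceRegion,
    MonitorSite,
    ObservationSeries,
    SitePartition,
    ValidationError,
    classify_sites,
    hour_to_timestamp,
)
from .soft_data import (
    HardDatum,
    build_hard_data,
    build_soft_data,
    station_ratio_stats,
    RatioStats,
)
from .stok import NeighborhoodSpec, estimate_background_at_receptors

MONTHLY_COVERAGE_THRESHOLD = 0.75


@dataclass(frozen=True)
class HybridEstimate:
    """Additive total at one receptor-hour: total = background + local exactly."""

    receptor_id: str
    hour: int
    background: float
    local: float

    @property
    def total(self) -> float:
        return self.background + self.local


@dataclass
class CombineResult:
    """Joined hybrid frame plus the keys that failed to match."""

    frame: pd.DataFrame  # receptor_id, hour, background, local, total
    unmatched_background: pd.DataFrame
    unmatched_local: pd.DataFrame


def read_local_concentrations(path) -> pd.DataFrame:
    """Read dispersion-model output (receptor_id, hour, value[, source_tag]).

    Multiple source tags (e.g., onroad and stationary) are summed per
    (receptor, hour) at load.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("receptor_id", "hour", "value") if c not in df.columns]
    if missing:
        raise ValidationError(f"local-concentration file missing column(s): {', '.join(missing)}")
    if np.any(df["value"].to_numpy(dtype=float) < 0):
        raise ValidationError("negative local concentration")
    out = (
        df.groupby(["receptor_id", "hour"], as_index=False)["value"].sum()
        .rename(columns={"value": "local"})
    )
    out["receptor_id"] = out["receptor_id"].astype(str)
    return out


def combine_hybrid(background: pd.DataFrame, local: pd.DataFrame) -> CombineResult:
    """Inner-join background and local on (receptor_id, hour); total is their sum.

    Unmatched keys on either side are reported, not silently dropped; duplicate
    keys on either side are an error.
    """
    bg = background.rename(columns={"value": "background"}).copy()
    lc = local.rename(columns={"value": "local"}).copy() if "value" in local.columns else local.copy()
    for name, df in (("background", bg), ("local", lc)):
        if df.duplicated(subset=["receptor_id", "hour"]).any():
            raise ValidationError(f"duplicate (receptor, hour) keys in {name} input")
    bg["receptor_id"] = bg["receptor_id"].astype(str)
    lc["receptor_id"] = lc["receptor_id"].astype(str)
    merged = bg.merge(lc[["receptor_id", "hour", "local"]], on=["receptor_id", "hour"], how="outer", indicator=True)
    matched = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    matched["total"] = matched["background"] + matched["local"]
    return CombineResult(
        frame=matched.reset_index(drop=True),
        unmatched_background=merged[merged["_merge"] == "left_only"][["receptor_id", "hour"]].reset_index(drop=True),
        unmatched_local=merged[merged["_merge"] == "right_only"][["receptor_id", "hour"]].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    """Per-site and pooled comparison of predictions against observations."""

    per_site: pd.DataFrame  # site_id, n, bias, rmse, ratio_of_means, frac_within_factor2
    pooled: dict
    aggregation: str
    flagged_months: pd.DataFrame | None = None  # (site_id, month) with low coverage


def _metrics(pred: np.ndarray, obs: np.ndarray) -> dict:
    err = pred - obs
    with np.errstate(invalid="ignore", divide="ignore"):
        rom = float(np.mean(pred) / np.mean(obs)) if np.mean(obs) != 0 else np.nan
    pos = obs > 0
    within = np.empty(obs.size, dtype=bool)
    within[pos] = (pred[pos] >= obs[pos] / 2.0) & (pred[pos] <= 2.0 * obs[pos])
    within[~pos] = pred[~pos] == 0
    return {
        "n": int(obs.size),
        "bias": float(np.mean(err)),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "ratio_of_means": rom,
        "frac_within_factor2": float(np.mean(within)),
    }


def evaluate(
    pred: pd.DataFrame,
    obs: Mapping[str, ObservationSeries] | pd.DataFrame,
    aggregation: str = "hourly",
    epoch: str | pd.Timestamp | None = None,
) -> EvalReport:
    """Pair predictions with observations by (site, hour) and score them.

    ``pred`` needs columns site_id (or receptor_id), hour, value.  For
    ``aggregation="monthly"`` an epoch is required to place hours into
    calendar months; monthly values are means over the paired hours of the
    month, and site-months with < 75% paired-hour coverage are flagged.
    The factor-of-2 criterion is boundary-inclusive.
    """
    p = pred.rename(columns={"receptor_id": "site_id", "total": "value"}).copy()
    for col in ("site_id", "hour", "value"):
        if col not in p.columns:
            raise ValidationError(f"prediction frame missing column {col}")
    if isinstance(obs, pd.DataFrame):
        o = obs.rename(columns={"receptor_id": "site_id"})[["site_id", "hour", "value"]].copy()
    else:
        o = pd.concat(
            [
                pd.DataFrame({"site_id": s.site_id, "hour": s.hours, "value": s.values})
                for s in obs.values()
            ],
            ignore_index=True,
        )
    p["site_id"] = p["site_id"].astype(str)
    o["site_id"] = o["site_id"].astype(str)
    pairs = p.merge(o, on=["site_id", "hour"], suffixes=("_pred", "_obs"))
    pairs = pairs[np.isfinite(pairs["value_pred"]) & np.isfinite(pairs["value_obs"])]
    if pairs.empty:
        raise ValidationError("no overlapping (site, hour) pairs to evaluate")

    flagged = None
    if aggregation == "monthly":
        if epoch is None:
            raise ValidationError("monthly aggregation requires an epoch")
        ts = hour_to_timestamp(pairs["hour"].to_numpy(), epoch)
        pairs = pairs.assign(month=ts.to_period("M").astype(str))
        grouped = pairs.groupby(["site_id", "month"], as_index=False).agg(
            value_pred=("value_pred", "mean"),
            value_obs=("value_obs", "mean"),
            n_hours=("hour", "size"),
        )
        month_hours = {
            m: pd.Period(m).days_in_month * 24 for m in grouped["month"].unique()
        }
        grouped["coverage"] = grouped["n_hours"] / grouped["month"].map(month_hours)
        flagged = grouped.loc[
            grouped["coverage"] < MONTHLY_COVERAGE_THRESHOLD, ["site_id", "month", "coverage"]
        ].reset_index(drop=True)
        pairs = grouped
    elif aggregation != "hourly":
        raise ValidationError(f"unknown aggregation {aggregation!r}")

    per_site_rows = []
    for site, g in pairs.groupby("site_id", sort=True):
        per_site_rows.append(
            {"site_id": site, **_metrics(g["value_pred"].to_numpy(), g["value_obs"].to_numpy())}
        )
    pooled = _metrics(pairs["value_pred"].to_numpy(), pairs["value_obs"].to_numpy())
    return EvalReport(
        per_site=pd.DataFrame(per_site_rows),
        pooled=pooled,
        aggregation=aggregation,
        flagged_months=flagged,
    )


# ---------------------------------------------------------------------------
# Full background->hybrid pipeline (new vs old variants)


@dataclass
class PipelineInputs:
    """Everything the background/hybrid pipeline consumes, pre-loaded."""

    sites: Sequence[MonitorSite]
    observations: Mapping[str, ObservationSeries]  # keyed by site_id (one pollutant)
    region: LocalSourceRegion
    total_field: GriddedHourlyField
    zeroout_field: GriddedHourlyField
    local: pd.DataFrame  # receptor_id, hour, local
    receptors: pd.DataFrame  # receptor_id, x, y
    estimation_hours: np.ndarray


@dataclass
class PipelineParams:
    min_distance_km: float = 60.0
    trim_percentiles: tuple[float, float] = (1.0, 99.0)
    spatial_edges: tuple = DEFAULT_SPATIAL_EDGES
    temporal_edges: tuple = DEFAULT_TEMPORAL_EDGES
    n_structures: int = DEFAULT_N_STRUCTURES
    fit_seed: int = 0
    fit_starts: int = 8
    neighborhood: NeighborhoodSpec | None = None  # None: derive from fitted model
    floor: bool = True
    covariance_model: CovarianceModel | None = None  # skip fitting when given
    #: which data feed the covariance fit: "hard" (default) or "all".  Hard
    #: data are exact samples of the background field; soft means carry known
    #: measurement error that would otherwise inflate the fitted sill.
    fit_on: str = "hard"


@dataclass
class HybridRunResult:
    background: pd.DataFrame
    hybrid: pd.DataFrame
    combine: CombineResult
    model: CovarianceModel
    transform_spec: TransformSpec
    partition: SitePartition
    ratio_stats: dict[str, RatioStats]
    dataset: TransformedDataset


def build_dataset(
    inputs: PipelineInputs,
    params: PipelineParams,
    use_soft: bool,
) -> tuple[TransformedDataset, TransformSpec, SitePartition, dict[str, RatioStats]]:
    """Classify sites and assemble the transformed hard+soft dataset.

    With ``use_soft=False`` (the old-hybrid variant) every monitor's
    observations enter as hard data and no ratio statistics are computed.
    """
    partition = classify_sites(list(inputs.sites), inputs.region, params.min_distance_km)
    site_by_id = {s.site_id: s for s in inputs.sites}

    hard: list[HardDatum] = []
    soft = []
    stats: dict[str, RatioStats] = {}
    if use_soft:
        hard_sites = partition.background
        for s in partition.nonbackground:
            if s.site_id not in inputs.observations:
                continue
            st = station_ratio_stats(
                inputs.total_field,
                inputs.zeroout_field,
                s,
                *params.trim_percentiles,
            )
            stats[s.site_id] = st
            soft.extend(build_soft_data(inputs.observations[s.site_id], st, s))
    else:
        hard_sites = tuple(inputs.sites)
    hard_ids = {s.site_id for s in hard_sites}
    for s in hard_sites:
        if s.site_id not in inputs.observations:
            continue
        hard.extend(build_hard_data(inputs.observations[s.site_id], site_by_id[s.site_id], hard_ids))
    if not hard:
        raise ValidationError("pipeline has no hard data")

    # Offset over every *exact* datum: hard values plus any soft datum whose
    # error variance degenerated to zero (e.g., identity model runs).  Values
    # are summed in sorted order so the offset does not depend on assembly
    # order.
    exact_vals = np.sort(
        np.array(
            [d.value for d in hard]
            + [d.mean for d in soft if d.error_variance == 0.0]
        )
    )
    tspec = TransformSpec(offset=float(np.mean(exact_vals)))
    dataset = transform(hard, soft, tspec)
    return dataset, tspec, partition, stats


def run_hybrid(
    inputs: PipelineInputs,
    params: PipelineParams | None = None,
    use_soft: bool = True,
) -> HybridRunResult:
    """End-to-end: classify, build data, fit covariance, krige, combine with local."""
    params = params or PipelineParams()
    dataset, tspec, partition, stats = build_dataset(inputs, params, use_soft)

    if params.covariance_model is not None:
        model = params.covariance_model
    else:
        if params.fit_on == "hard":
            fit_data = dataset.subset(np.flatnonzero(dataset.is_hard))
        elif params.fit_on == "all":
            fit_data = dataset
        else:
            raise ValidationError(f"fit_on must be 'hard' or 'all', got {params.fit_on!r}")
        emp = empirical_covariance(fit_data, params.spatial_edges, params.temporal_edges)
        model = fit_covariance(
            emp,
            n_structures=params.n_structures,
            seed=params.fit_seed,
            n_starts=params.fit_starts,
        )
    nbhd = params.neighborhood or NeighborhoodSpec.from_model(model)

    background = estimate_background_at_receptors(
        inputs.receptors,
        inputs.estimation_hours,
        dataset,
        model,
        nbhd,
        tspec,
        floor=params.floor,
    )
    combine = combine_hybrid(background, inputs.local)
    return HybridRunResult(
        background=background,
        hybrid=combine.frame,
        combine=combine,
        model=model,
        transform_spec=tspec,
        partition=partition,
        ratio_stats=stats,
        dataset=dataset,
    )


def run_new_hybrid(inputs: PipelineInputs, params: PipelineParams | None = None) -> HybridRunResult:
    """Ratio-based soft data at nonbackground monitors (the double-counting fix)."""
    return run_hybrid(inputs, params, use_soft=True)


def run_old_hybrid(inputs: PipelineInputs, params: PipelineParams | None = None) -> HybridRunResult:
    """Every monitor hard — the earlier approach that double-counts local sources."""
    return run_hybrid(inputs, params, use_soft=False)


# ---------------------------------------------------------------------------
# Leave-one-site-out cross-validation


@dataclass
class LooResult:
    frame: pd.DataFrame  # site_id, hour, observed_x, estimate_x, variance, residual, std_residual
    summary: dict


def loo_crossvalidate(
    data: TransformedDataset,
    model: CovarianceModel,
    spec: NeighborhoodSpec,
    max_hours_per_site: int | None = None,
) -> LooResult:
    """Site-withheld cross-validation over the hard data.

    For each background site, the site's *entire* series is withheld (a single
    withheld hour would leak through the same site's adjacent hours) and each
    of its hard data is re-estimated from the remaining data.  Residuals are
    estimate - observed; standardized residuals divide by the kriging standard
    deviation.  ``max_hours_per_site`` caps the evaluation at that many evenly
    spaced hours per site.
    """
    from .stok import SpaceTimePoint, UnestimablePointError, krige, select_neighborhood

    hard_sites = sorted(set(data.site_ids[data.is_hard]))
    if len(hard_sites) < 2:
        raise ValidationError("site-withheld cross-validation needs >= 2 hard-data sites")
    rows = []
    for site in hard_sites:
        withheld = np.flatnonzero((data.site_ids == site) & data.is_hard)
        rest = data.subset(np.flatnonzero(data.site_ids != site))
        if max_hours_per_site is not None and withheld.size > max_hours_per_site:
            sel = np.linspace(0, withheld.size - 1, max_hours_per_site).round().astype(int)
            withheld = withheld[np.unique(sel)]
        for i in withheld:
            p = SpaceTimePoint(float(data.x[i]), float(data.y[i]), int(data.t[i]))
            try:
                idx = select_neighborhood(p, rest, spec)
                res = krige(p, rest.subset(idx), model)
            except UnestimablePointError:
                continue
            resid = res.estimate_x - data.values[i]
            std = resid / np.sqrt(res.error_variance) if res.error_variance > 0 else np.nan
            rows.append(
                {
                    "site_id": site,
                    "hour": int(data.t[i]),
                    "observed_x": float(data.values[i]),
                    "estimate_x": res.estimate_x,
                    "variance": res.error_variance,
                    "residual": float(resid),
                    "std_residual": float(std),
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError("cross-validation produced no estimable points")
    std = frame["std_residual"].to_numpy()
    std = std[np.isfinite(std)]
    summary = {
        "n": int(len(frame)),
        "residual_mean": float(frame["residual"].mean()),
        "residual_rmse": float(np.sqrt(np.mean(frame["residual"] ** 2))),
        "std_residual_mean": float(np.mean(std)) if std.size else np.nan,
        "std_residual_variance": float(np.var(std, ddof=1)) if std.size > 1 else np.nan,
    }
    return LooResult(frame=frame, summary=summary)
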