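"""Space/time ordinary kriging with measurement-error (soft) data.

The estimator at a target point p0 is the best linear unbiased combination of
nearby transformed data: weights solve the ordinary-kriging system with
left-hand matrix K_ij = C(r_ij, tau_ij) + delta_ij * v_i, where v_i is the
datum's measurement-error variance (zero for hard data), plus the
unbiasedness constraint sum(lambda) = 1.  The kriging variance is
C(0, 0) - sum_i lambda_i C(r_i0, tau_i0) - mu.  At a hard datum's own
space/time point the estimator reproduces the observation exactly with zero
variance; soft data are downweighted in proportion to their error variance.

Estimation is local: a neighborhood of the nearest hard and soft data within a
space/time search window is kriged for each target point, which keeps an
hourly, multi-receptor problem tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import (
    CovarianceModel,
    TransformSpec,
    TransformedDataset,
    evaluate_covariance,
)
from .sites_obs import SpaceTimePoint, ValidationError


class UnestimablePointError(ValueError):
    """No datum falls inside the search window around the target point."""


class KrigingError(RuntimeError):
    """The kriging system could not be solved reliably."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Search window and quota for local kriging neighborhoods.

    ``st_metric_ratio`` (km per hour) converts a temporal lag into a
    spatial-equivalent distance for nearest-neighbor ranking: the combined
    distance is d = r + st_metric_ratio * tau.
    """

    max_hard: int = 30
    max_soft: int = 30
    space_radius: float = 500.0
    time_radius: float = 72.0
    st_metric_ratio: float = 10.0

    def __post_init__(self) -> None:
        if min(self.max_hard, self.max_soft) <= 0:
            raise ValidationError("neighborhood quotas must be positive")
        if min(self.space_radius, self.time_radius, self.st_metric_ratio) <= 0:
            raise ValidationError("neighborhood radii and metric ratio must be positive")

    @classmethod
    def from_model(cls, model: CovarianceModel, **kwargs) -> "NeighborhoodSpec":
        """Default metric ratio from the dominant structure's range ratio a_r1/a_t1."""
        dom = model.dominant
        return cls(st_metric_ratio=dom.spatial_range / dom.temporal_range, **kwargs)


@dataclass(frozen=True)
class KrigingResult:
    """Solution of one local kriging system, on the transformed scale."""

    estimate_x: float
    error_variance: float
    weights: np.ndarray
    lagrange: float
    datum_ids: tuple[str, ...]


@dataclass(frozen=True)
class BackgroundEstimate:
    """A back-transformed background estimate at one space/time point."""

    point: SpaceTimePoint
    value: float  # floored value if flooring applied
    variance: float
    raw_value: float  # pre-floor value (equal to value unless floored)
    floored: bool = False
    extrapolated: bool = False
    unestimable: bool = False


def select_neighborhood(
    p0: SpaceTimePoint,
    data: TransformedDataset,
    spec: NeighborhoodSpec,
) -> np.ndarray:
    """Indices of the nearest hard/soft data inside the search window.

    Candidates within both radii are ranked by combined distance
    d = r + st_metric_ratio * tau; the nearest ``max_hard`` hard and
    ``max_soft`` soft data are kept, ties broken by (distance, datum id).
    """
    if len(data) == 0:
        raise UnestimablePointError("no data available")
    tau = np.abs(data.t - p0.t)
    cand = np.flatnonzero(tau <= spec.time_radius)
    if cand.size == 0:
        raise UnestimablePointError(f"no data within {spec.time_radius} h of hour {p0.t}")
    r = np.hypot(data.x[cand] - p0.x, data.y[cand] - p0.y)
    inside = r <= spec.space_radius
    cand = cand[inside]
    r = r[inside]
    if cand.size == 0:
        raise UnestimablePointError(
            f"no data within {spec.space_radius} km and {spec.time_radius} h of target"
        )
    d = r + spec.st_metric_ratio * tau[cand]
    order = np.lexsort((data.datum_ids[cand].astype(str), d))
    ranked = cand[order]
    hard = data.is_hard[ranked]
    keep_hard = ranked[hard][: spec.max_hard]
    keep_soft = ranked[~hard][: spec.max_soft]
    return np.sort(np.concatenate([keep_hard, keep_soft]))


def _resolve_collocated(data: TransformedDataset) -> TransformedDataset:
    """Merge or reject data sharing an identical (x, y, t) coordinate.

    Hard beats soft; two hard data with different values are an error (the
    system would be inconsistent); collocated soft data merge by
    precision-weighted averaging.  A soft datum with zero error variance is
    hard by definition.
    """
    coords = np.column_stack([data.x, data.y, data.t])
    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return data
    keep_rows: list[int] = []
    merged: dict[int, tuple[float, float]] = {}
    for g in np.flatnonzero(counts > 1):
        rows = np.flatnonzero(inverse == g)
        hard_rows = rows[data.is_hard[rows]]
        if hard_rows.size:
            vals = data.values[hard_rows]
            if np.ptp(vals) > 0:
                ids = ", ".join(str(i) for i in data.datum_ids[hard_rows])
                raise KrigingError(f"conflicting collocated hard data: {ids}")
            keep_rows.append(int(hard_rows[0]))
        else:
            w = 1.0 / data.error_variances[rows]
            merged[int(rows[0])] = (
                float(np.sum(w * data.values[rows]) / np.sum(w)),
                float(1.0 / np.sum(w)),
            )
            keep_rows.append(int(rows[0]))
    keep_rows.extend(int(i) for i in np.flatnonzero(counts[inverse] == 1))
    keep = np.sort(np.array(keep_rows, dtype=int))
    out = data.subset(keep)
    for row, (val, var) in merged.items():
        pos = int(np.searchsorted(keep, row))
        out.values[pos] = val
        out.error_variances[pos] = var
    return out


def krige(
    p0: SpaceTimePoint,
    neighborhood: TransformedDataset,
    model: CovarianceModel,
) -> KrigingResult:
    """Solve the ordinary-kriging-with-measurement-error system at one point."""
    nb = _resolve_collocated(neighborhood)
    n = len(nb)
    if n == 0:
        raise UnestimablePointError("empty neighborhood")

    dx = nb.x[:, None] - nb.x[None, :]
    dy = nb.y[:, None] - nb.y[None, :]
    dt = np.abs(nb.t[:, None] - nb.t[None, :]).astype(float)
    C = np.asarray(evaluate_covariance(model, np.hypot(dx, dy), dt))
    c00 = model.total_sill
    r0 = np.hypot(nb.x - p0.x, nb.y - p0.y)
    t0 = np.abs(nb.t - p0.t).astype(float)
    k0 = np.asarray(evaluate_covariance(model, r0, t0))

    A = np.empty((n + 1, n + 1))
    A[:n, :n] = C + np.diag(nb.error_variances)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    b = np.append(k0, 1.0)

    sol = None
    for ridge in (0.0, 1e-10 * c00):
        try:
            M = A.copy()
            if ridge:
                M[np.arange(n), np.arange(n)] += ridge
            cand = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            continue
        if np.all(np.isfinite(cand)):
            sol = cand
            break
    if sol is None:
        raise KrigingError("singular kriging system (after ridge retry)")

    lam = sol[:n]
    mu = float(sol[n])
    est = float(lam @ nb.values)
    var = float(c00 - lam @ k0 - mu)
    if var < 0:
        if var < -1e-9 * max(1.0, c00):
            raise KrigingError(f"kriging variance {var} is negative beyond round-off")
        var = 0.0
    return KrigingResult(
        estimate_x=est,
        error_variance=var,
        weights=lam,
        lagrange=mu,
        datum_ids=tuple(str(i) for i in nb.datum_ids),
    )


def estimate_background(
    points,
    data: TransformedDataset,
    model: CovarianceModel,
    spec: NeighborhoodSpec,
    transform_spec: TransformSpec | None = None,
    floor: bool = True,
) -> list[BackgroundEstimate]:
    """Krige each target point and add back the offset.

    Unestimable points (empty search window) are returned flagged with NaN
    values rather than dropped.  Back-transformed negatives are floored at 0
    by default (flagged, raw value preserved).  Points whose hour lies outside
    the data's time span are flagged as extrapolated.
    """
    offset = transform_spec.offset if transform_spec is not None else data.offset
    if len(data) == 0:
        raise ValidationError("estimate_background: no data")
    tmin, tmax = int(data.t.min()), int(data.t.max())
    out: list[BackgroundEstimate] = []
    for p in points:
        extrap = p.t < tmin or p.t > tmax
        try:
            idx = select_neighborhood(p, data, spec)
            res = krige(p, data.subset(idx), model)
        except UnestimablePointError:
            out.append(
                BackgroundEstimate(
                    point=p, value=np.nan, variance=np.nan, raw_value=np.nan,
                    extrapolated=extrap, unestimable=True,
                )
            )
            continue
        raw = res.estimate_x + offset
        floored = bool(floor and raw < 0)
        out.append(
            BackgroundEstimate(
                point=p,
                value=0.0 if floored else raw,
                variance=res.error_variance,
                raw_value=raw,
                floored=floored,
                extrapolated=extrap,
            )
        )
    return out


def estimate_background_at_receptors(
    receptors: pd.DataFrame,
    hours,
    data: TransformedDataset,
    model: CovarianceModel,
    spec: NeighborhoodSpec,
    transform_spec: TransformSpec | None = None,
    floor: bool = True,
) -> pd.DataFrame:
    """Tabular wrapper: estimate at every (receptor, hour) combination.

    ``receptors`` needs columns receptor_id, x, y; returns a frame with
    receptor_id, hour, value, variance and flag columns.
    """
    for col in ("receptor_id", "x", "y"):
        if col not in receptors.columns:
            raise ValidationError(f"receptors frame missing column {col}")
    hours = np.asarray(hours, dtype=np.int64)
    rows = []
    for rec in receptors.itertuples(index=False):
        pts = [SpaceTimePoint(float(rec.x), float(rec.y), int(h)) for h in hours]
        for est in estimate_background(pts, data, model, spec, transform_spec, floor):
            rows.append(
                {
                    "receptor_id": rec.receptor_id,
                    "hour": est.point.t,
                    "value": est.value,
                    "variance": est.variance,
                    "floored": est.floored,
                    "extrapolated": est.extrapolated,
                    "unestimable": est.unestimable,
                }
            )
    return pd.DataFrame(rows)
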