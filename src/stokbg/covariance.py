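"""Offset transform and the nested space/time exponential covariance model.

The background field B(p) is modelled as a homogeneous/stationary space/time
random field X(p) plus a constant offset o_B equal to the mean of all observed
hard (background) concentrations; kriging operates on the transformed data
x(p) = b(p) - o_B and the offset is added back afterwards.

The covariance of X is a nested sum of separable space/time exponential
structures,

    C(r, tau) = sum_i c_i * exp(-3 r / a_ri) * exp(-3 tau / a_ti),

where c_i is the i-th sill and a_ri / a_ti are its spatial (km) and temporal
(hours) ranges.  The factor 3 makes each range the ~95% decorrelation scale,
the common geostatistical convention.  Three structures are the default; the
count is configurable.

Soft data enter empirical covariance estimation through their means only;
their error variances are deliberately ignored at this stage (a documented
approximation — the variances re-enter on the kriging system diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .sites_obs import ValidationError
from .soft_data import HardDatum, SoftDatum

# the first bin [0, 1e-9) isolates collocated (same-location) pairs so the
# empirical C(0, tau) profile pins the sill at the origin
DEFAULT_SPATIAL_EDGES = (0.0, 1e-9) + tuple(float(e) for e in np.arange(25.0, 401.0, 25.0))
DEFAULT_TEMPORAL_EDGES = (0.0, 1.0, 2.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
DEFAULT_N_STRUCTURES = 3
DEFAULT_N_STARTS = 20


@dataclass(frozen=True)
class TransformSpec:
    """The additive offset o_B subtracted from background data before kriging."""

    offset: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset):
            raise ValidationError("offset must be finite")


def compute_offset(hard_data: Sequence[HardDatum]) -> TransformSpec:
    """o_B = arithmetic mean of all hard (observed background) values."""
    if not hard_data:
        raise ValidationError("compute_offset: no hard data")
    return TransformSpec(offset=float(np.mean([d.value for d in hard_data])))


@dataclass
class TransformedDataset:
    """Hard and soft data on the transformed (offset-removed) scale, as arrays.

    A datum is *hard* exactly when its error variance is zero; the arrays are
    kept sorted by (t, datum_id) so that downstream assembly is deterministic.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    values: np.ndarray  # transformed scale: original value/mean minus offset
    error_variances: np.ndarray
    site_ids: np.ndarray  # per-datum originating site
    datum_ids: np.ndarray  # unique "site:hour" labels
    offset: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.error_variances = np.asarray(self.error_variances, dtype=float)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.datum_ids = np.asarray(self.datum_ids, dtype=object)
        n = self.x.size
        for name in ("y", "t", "values", "error_variances", "site_ids", "datum_ids"):
            if getattr(self, name).size != n:
                raise ValidationError(f"TransformedDataset field {name} has wrong length")
        if np.any(self.error_variances < 0):
            raise ValidationError("error variances must be >= 0")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def is_hard(self) -> np.ndarray:
        return self.error_variances == 0.0

    @property
    def n_hard(self) -> int:
        return int(np.count_nonzero(self.is_hard))

    @property
    def n_soft(self) -> int:
        return int(len(self) - self.n_hard)

    def subset(self, idx) -> "TransformedDataset":
        return TransformedDataset(
            x=self.x[idx],
            y=self.y[idx],
            t=self.t[idx],
            values=self.values[idx],
            error_variances=self.error_variances[idx],
            site_ids=self.site_ids[idx],
            datum_ids=self.datum_ids[idx],
            offset=self.offset,
        )

    def sorted_canonical(self) -> "TransformedDataset":
        order = np.lexsort((self.datum_ids.astype(str), self.t))
        return self.subset(order)


def transform(
    hard: Sequence[HardDatum],
    soft: Sequence[SoftDatum],
    spec: TransformSpec,
) -> TransformedDataset:
    """Shift every hard value and soft mean by -o_B; error variances unchanged."""
    n = len(hard) + len(soft)
    if n == 0:
        raise ValidationError("transform: no data")
    x = np.empty(n)
    y = np.empty(n)
    t = np.empty(n, dtype=np.int64)
    vals = np.empty(n)
    ev = np.empty(n)
    sids = np.empty(n, dtype=object)
    dids = np.empty(n, dtype=object)
    for k, d in enumerate(list(hard) + list(soft)):
        x[k], y[k], t[k] = d.point.x, d.point.y, d.point.t
        vals[k] = (d.value if isinstance(d, HardDatum) else d.mean) - spec.offset
        ev[k] = d.error_variance
        sids[k] = d.source_site
        dids[k] = f"{d.source_site}:{d.point.t}"
    return TransformedDataset(
        x=x, y=y, t=t, values=vals, error_variances=ev,
        site_ids=sids, datum_ids=dids, offset=spec.offset,
    ).sorted_canonical()


def inverse_transform_values(values, spec: TransformSpec) -> np.ndarray:
    """Back to concentration scale: b = x + o_B."""
    return np.asarray(values, dtype=float) + spec.offset


# ---------------------------------------------------------------------------
# Covariance model


@dataclass(frozen=True)
class CovarianceStructure:
    """One separable exponential structure: sill, spatial range (km), temporal range (h)."""

    sill: float
    spatial_range: float
    temporal_range: float

    def __post_init__(self) -> None:
        if self.sill <= 0 or self.spatial_range <= 0 or self.temporal_range <= 0:
            raise ValidationError("sill and ranges must be > 0")


@dataclass(frozen=True)
class CovarianceModel:
    """Nested (additive) space/time exponential covariance model."""

    structures: tuple[CovarianceStructure, ...]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValidationError("covariance model needs at least one structure")
        object.__setattr__(self, "structures", tuple(self.structures))

    @property
    def total_sill(self) -> float:
        return float(sum(s.sill for s in self.structures))

    @property
    def dominant(self) -> CovarianceStructure:
        """Structure with the largest sill."""
        return max(self.structures, key=lambda s: s.sill)

    def evaluate(self, r, tau) -> np.ndarray | float:
        return evaluate_covariance(self, r, tau)


def evaluate_covariance(model: CovarianceModel, r, tau) -> np.ndarray | float:
    """C(r, tau) = sum_i c_i exp(-3 r / a_ri) exp(-3 tau / a_ti); lags >= 0."""
    r = np.asarray(r, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(r < 0) or np.any(tau < 0):
        raise ValidationError("covariance lags must be >= 0")
    out = np.zeros(np.broadcast_shapes(r.shape, tau.shape))
    for s in model.structures:
        out += s.sill * np.exp(-3.0 * r / s.spatial_range) * np.exp(-3.0 * tau / s.temporal_range)
    return out if out.ndim else float(out)


def save_covariance_model(model: CovarianceModel, path, offset: float | None = None) -> None:
    """Serialize a fitted model (and optionally the offset) as YAML."""
    doc = {
        "structures": [
            {
                "sill": float(s.sill),
                "spatial_range": float(s.spatial_range),
                "temporal_range": float(s.temporal_range),
            }
            for s in model.structures
        ]
    }
    if offset is not None:
        doc["offset"] = float(offset)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_covariance_model(path) -> tuple[CovarianceModel, float | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = CovarianceModel(
        structures=tuple(
            CovarianceStructure(
                sill=float(s["sill"]),
                spatial_range=float(s["spatial_range"]),
                temporal_range=float(s["temporal_range"]),
            )
            for s in doc["structures"]
        )
    )
    return model, (float(doc["offset"]) if "offset" in doc else None)


# ---------------------------------------------------------------------------
# Empirical covariance


@dataclass
class EmpiricalCovariance:
    """Binned empirical space/time covariance surface of the transformed data.

    ``estimate[i, j]`` is the mean pair product over pairs whose spatial lag
    falls in [spatial_edges[i], spatial_edges[i+1]) and temporal lag in
    [temporal_edges[j], temporal_edges[j+1]); bins with no pairs carry NaN.
    ``mean_spatial_lag`` / ``mean_temporal_lag`` are the pair-count-weighted
    mean lags of each bin (the representative lags used when fitting).
    """

    spatial_edges: np.ndarray
    temporal_edges: np.ndarray
    estimate: np.ndarray
    n_pairs: np.ndarray
    mean_spatial_lag: np.ndarray
    mean_temporal_lag: np.ndarray

    @classmethod
    def from_surface(
        cls,
        spatial_lags: Sequence[float],
        temporal_lags: Sequence[float],
        surface: np.ndarray,
        n_pairs: np.ndarray | None = None,
    ) -> "EmpiricalCovariance":
        """Build a surface directly from values at given lags (one bin per lag)."""
        r = np.asarray(spatial_lags, dtype=float)
        t = np.asarray(temporal_lags, dtype=float)
        surface = np.asarray(surface, dtype=float)
        if surface.shape != (r.size, t.size):
            raise ValidationError("surface shape must be (n_spatial, n_temporal)")
        n = np.ones_like(surface) if n_pairs is None else np.asarray(n_pairs, dtype=float)
        redges = np.append(r, r[-1] + 1.0)
        tedges = np.append(t, t[-1] + 1.0)
        rr, tt = np.meshgrid(r, t, indexing="ij")
        return cls(
            spatial_edges=redges,
            temporal_edges=tedges,
            estimate=surface,
            n_pairs=n,
            mean_spatial_lag=rr,
            mean_temporal_lag=tt,
        )


def empirical_covariance(
    data: TransformedDataset,
    spatial_edges: Sequence[float] = DEFAULT_SPATIAL_EDGES,
    temporal_edges: Sequence[float] = DEFAULT_TEMPORAL_EDGES,
) -> EmpiricalCovariance:
    """Binned mean-of-pair-products covariance estimator.

    Data are grouped by exact spatial location so that, for each integer
    temporal lag, cross products between all location pairs reduce to matrix
    multiplications over the common hour axis.  Hard values and soft means are
    used alike (residuals are already centred by the offset); a datum pairs
    with itself only in the (0, 0) bin, where the self products estimate the
    variance.
    """
    if len(data) < 2:
        raise ValidationError("empirical covariance needs at least 2 data")
    sedges = np.asarray(spatial_edges, dtype=float)
    tedges = np.asarray(temporal_edges, dtype=float)
    if sedges.size < 2 or tedges.size < 2:
        raise ValidationError("need at least one spatial and one temporal bin")
    ns, nt = sedges.size - 1, tedges.size - 1

    xy = np.column_stack([data.x, data.y])
    locs, inv = np.unique(xy, axis=0, return_inverse=True)
    m = locs.shape[0]
    t0 = int(data.t.min())
    T = int(data.t.max()) - t0 + 1

    V = np.zeros((m, T))
    M = np.zeros((m, T))
    V[inv, data.t - t0] = data.values
    M[inv, data.t - t0] = 1.0
    V *= M  # guard against stale writes

    D = cdist(locs, locs)
    sbin = np.searchsorted(sedges, D, side="right") - 1
    svalid = (sbin >= 0) & (D < sedges[-1])

    sums = np.zeros((ns, nt))
    counts = np.zeros((ns, nt))
    rsums = np.zeros((ns, nt))
    tsums = np.zeros((ns, nt))

    iu = np.triu_indices(m)
    pair_bin = sbin[iu]
    pair_ok = svalid[iu]
    pair_d = D[iu]

    max_tau = min(T - 1, int(np.ceil(tedges[-1])))
    for tau in range(0, max_tau + 1):
        tb = int(np.searchsorted(tedges, tau, side="right")) - 1
        if tb < 0 or tau >= tedges[-1]:
            continue
        if tau == 0:
            S = V @ V.T
            N = M @ M.T
        else:
            S = V[:, :-tau] @ V[:, tau:].T
            N = M[:, :-tau] @ M[:, tau:].T
            diag_s = np.diagonal(S).copy()
            diag_n = np.diagonal(N).copy()
            S = S + S.T
            N = N + N.T
            np.fill_diagonal(S, diag_s)
            np.fill_diagonal(N, diag_n)
        ps = S[iu]
        pn = N[iu]
        ok = pair_ok & (pn > 0)
        if not np.any(ok):
            continue
        b = pair_bin[ok]
        sums[:, tb] += np.bincount(b, weights=ps[ok], minlength=ns)
        counts[:, tb] += np.bincount(b, weights=pn[ok], minlength=ns)
        rsums[:, tb] += np.bincount(b, weights=(pair_d[ok] * pn[ok]), minlength=ns)
        tsums[:, tb] += np.bincount(b, weights=pn[ok], minlength=ns) * tau

    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(counts > 0, sums / counts, np.nan)
        mr = np.where(counts > 0, rsums / counts, np.nan)
        mt = np.where(counts > 0, tsums / counts, np.nan)
    return EmpiricalCovariance(
        spatial_edges=sedges,
        temporal_edges=tedges,
        estimate=est,
        n_pairs=counts,
        mean_spatial_lag=mr,
        mean_temporal_lag=mt,
    )


# ---------------------------------------------------------------------------
# Fitting


def _gather_bins(emp: EmpiricalCovariance):
    """Nonmissing bins as flat, canonically ordered (r, tau, value, weight)."""
    ok = np.isfinite(emp.estimate) & (emp.n_pairs > 0)
    rc = emp.mean_spatial_lag.copy()
    tc = emp.mean_temporal_lag.copy()
    # fall back to geometric centers where mean lags were not recorded
    scent = 0.5 * (emp.spatial_edges[:-1] + emp.spatial_edges[1:])
    tcent = 0.5 * (emp.temporal_edges[:-1] + emp.temporal_edges[1:])
    gr, gt = np.meshgrid(scent, tcent, indexing="ij")
    rc = np.where(np.isfinite(rc), rc, gr)
    tc = np.where(np.isfinite(tc), tc, gt)
    r = rc[ok]
    t = tc[ok]
    c = emp.estimate[ok]
    w = emp.n_pairs[ok]
    order = np.lexsort((t, r))
    return r[order], t[order], c[order], w[order]


def _model_from_params(theta: np.ndarray, k: int) -> CovarianceModel:
    params = np.exp(theta).reshape(k, 3)
    return CovarianceModel(
        structures=tuple(
            CovarianceStructure(sill=p[0], spatial_range=p[1], temporal_range=p[2])
            for p in params
        )
    )


def fit_covariance(
    emp: EmpiricalCovariance,
    n_structures: int = DEFAULT_N_STRUCTURES,
    bounds: dict | None = None,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> CovarianceModel:
    """Weighted least-squares fit of a nested exponential model to binned covariance.

    Weights are pair counts; parameters are optimized in log space with
    multi-start local optimization (deterministic given ``seed``).  Fits are
    grown recursively: the best k-structure fit seeds the (k+1)-structure fit
    (with a vanishingly small extra structure), so adding structures can never
    worsen the weighted SSE.  Structures are returned sorted by descending sill.

    ``bounds`` may override the default search box with keys ``sill``,
    ``spatial_range``, ``temporal_range`` mapping to (lo, hi) tuples.
    """
    r, t, c, w = _gather_bins(emp)
    if r.size < 3 * n_structures:
        raise ValidationError(
            f"insufficient nonmissing bins ({r.size}) for {n_structures} structures"
        )
    c00 = float(np.nanmax(c))
    if not np.isfinite(c00) or c00 <= 0:
        raise ValidationError("empirical covariance has no positive values; cannot fit")

    rpos = r[r > 0]
    tpos = t[t > 0]
    r_lo = float(rpos.min()) / 10.0 if rpos.size else 1e-2
    r_hi = float(r.max()) * 10.0 if r.max() > 0 else 1e3
    t_lo = float(tpos.min()) / 10.0 if tpos.size else 1e-2
    t_hi = float(t.max()) * 10.0 if t.max() > 0 else 1e3
    box = {
        "sill": (1e-6 * c00, 10.0 * c00),
        "spatial_range": (max(r_lo, 1e-3), max(r_hi, 1.0)),
        "temporal_range": (max(t_lo, 1e-3), max(t_hi, 1.0)),
    }
    if bounds:
        box.update({k: (float(v[0]), float(v[1])) for k, v in bounds.items()})

    lo = np.log([box["sill"][0], box["spatial_range"][0], box["temporal_range"][0]])
    hi = np.log([box["sill"][1], box["spatial_range"][1], box["temporal_range"][1]])
    sw = np.sqrt(w)

    def residuals(theta: np.ndarray, k: int) -> np.ndarray:
        params = np.exp(theta).reshape(k, 3)
        model = np.zeros_like(c)
        for sill, a_r, a_t in params:
            model += sill * np.exp(-3.0 * r / a_r) * np.exp(-3.0 * t / a_t)
        return sw * (model - c)

    def run_fit(theta0: np.ndarray, k: int):
        res = least_squares(
            residuals,
            np.clip(theta0, np.tile(lo, k), np.tile(hi, k)),
            args=(k,),
            bounds=(np.tile(lo, k), np.tile(hi, k)),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        return res.x, float(np.sum(res.fun**2))

    rng = np.random.default_rng(seed)
    heuristic = np.log(
        [
            max(c00, box["sill"][0]),
            float(np.median(r[r > 0])) if rpos.size else box["spatial_range"][1] / 2,
            max(float(np.median(t[t > 0])) if tpos.size else 1.0, box["temporal_range"][0]),
        ]
    )

    best_theta, best_sse = None, np.inf
    for k in range(1, n_structures + 1):
        starts = []
        if k == 1:
            starts.append(heuristic)
        else:
            # nest: previous best plus a negligible extra structure
            tiny = np.log([box["sill"][0], np.exp(heuristic[1]), np.exp(heuristic[2])])
            starts.append(np.concatenate([best_theta, tiny]))
        for _ in range(n_starts):
            starts.append(np.concatenate([rng.uniform(lo, hi) for _ in range(k)]))
        k_best_theta, k_best_sse = None, np.inf
        for theta0 in starts:
            try:
                theta, sse = run_fit(np.asarray(theta0, dtype=float), k)
            except Exception:
                continue
            if sse < k_best_sse:
                k_best_theta, k_best_sse = theta, sse
        if k_best_theta is None:
            raise ValidationError("covariance fit failed from every start")
        best_theta, best_sse = k_best_theta, k_best_sse

    model = _model_from_params(best_theta, n_structures)
    ordered = tuple(sorted(model.structures, key=lambda s: -s.sill))
    return replace(model, structures=ordered)
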