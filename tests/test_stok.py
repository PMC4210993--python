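import math

import numpy as np
import pytest

from stokbg.covariance import TransformedDataset
from stokbg.sites_obs import SpaceTimePoint
from stokbg.stok import (
    KrigingError,
    NeighborhoodSpec,
    UnestimablePointError,
    estimate_background,
    krige,
    select_neighborhood,
)

from conftest import random_dataset, random_model


def _dataset(rows, offset=0.0):
    """rows: (x, y, t, value, error_variance, site_id)."""
    arr = list(rows)
    return TransformedDataset(
        x=[r[0] for r in arr],
        y=[r[1] for r in arr],
        t=[r[2] for r in arr],
        values=[r[3] for r in arr],
        error_variances=[r[4] for r in arr],
        site_ids=np.array([r[5] for r in arr], dtype=object),
        datum_ids=np.array([f"{r[5]}:{r[2]}" for r in arr], dtype=object),
        offset=offset,
    )


def brute_force_krige(p0, ds, model):
    """Independent oracle: bordered-matrix inversion of the constrained LS problem."""
    n = len(ds)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            r = math.hypot(ds.x[i] - ds.x[j], ds.y[i] - ds.y[j])
            tau = abs(int(ds.t[i]) - int(ds.t[j]))
            K[i, j] = sum(
                s.sill
                * math.exp(-3 * r / s.spatial_range)
                * math.exp(-3 * tau / s.temporal_range)
                for s in model.structures
            )
            if i == j:
                K[i, j] += ds.error_variances[i]
    k0 = np.array(
        [
            sum(
                s.sill
                * math.exp(-3 * math.hypot(ds.x[i] - p0.x, ds.y[i] - p0.y) / s.spatial_range)
                * math.exp(-3 * abs(int(ds.t[i]) - p0.t) / s.temporal_range)
                for s in model.structures
            )
            for i in range(n)
        ]
    )
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K
    A[:n, n] = 1
    A[n, :n] = 1
    sol = np.linalg.inv(A) @ np.append(k0, 1.0)
    lam, mu = sol[:n], sol[n]
    c00 = sum(s.sill for s in model.structures)
    return float(lam @ ds.values), float(c00 - lam @ k0 - mu)


class TestSelectNeighborhood:
    SPEC = NeighborhoodSpec(max_hard=2, max_soft=2, space_radius=50.0, time_radius=12.0,
                            st_metric_ratio=5.0)

    def test_all_data_beyond_radii_is_unestimable(self):
        ds = _dataset([(100.0, 0.0, 0, 1.0, 0.0, "a"), (0.0, 0.0, 40, 1.0, 0.0, "b")])
        with pytest.raises(UnestimablePointError):
            select_neighborhood(SpaceTimePoint(0.0, 0.0, 0), ds, self.SPEC)

    def test_keeps_nearest_within_quota(self):
        ds = _dataset(
            [
                (1.0, 0.0, 0, 1.0, 0.0, "a"),
                (2.0, 0.0, 0, 1.0, 0.0, "b"),
                (30.0, 0.0, 0, 1.0, 0.0, "c"),
            ]
        )
        idx = select_neighborhood(SpaceTimePoint(0.0, 0.0, 0), ds, self.SPEC)
        assert set(ds.site_ids[idx]) == {"a", "b"}

    def test_tie_broken_by_datum_id(self):
        ds = _dataset(
            [
                (1.0, 0.0, 0, 1.0, 0.0, "zz"),
                (-1.0, 0.0, 0, 1.0, 0.0, "aa"),
            ]
        )
        spec = NeighborhoodSpec(max_hard=1, max_soft=1, space_radius=50.0, time_radius=12.0,
                                st_metric_ratio=5.0)
        idx = select_neighborhood(SpaceTimePoint(0.0, 0.0, 0), ds, spec)
        assert list(ds.site_ids[idx]) == ["aa"]

    def test_hard_and_soft_quotas_are_separate(self):
        rows = [(float(k + 1), 0.0, 0, 1.0, 0.0, f"h{k}") for k in range(4)]
        rows += [(float(k + 1), 1.0, 0, 1.0, 0.5, f"s{k}") for k in range(4)]
        ds = _dataset(rows)
        idx = select_neighborhood(SpaceTimePoint(0.0, 0.0, 0), ds, self.SPEC)
        kept = set(ds.site_ids[idx])
        assert kept == {"h0", "h1", "s0", "s1"}

    def test_temporal_lag_enters_combined_distance(self):
        ds = _dataset(
            [
                (10.0, 0.0, 0, 1.0, 0.0, "near_space"),
                (1.0, 0.0, 10, 1.0, 0.0, "near_time"),
            ]
        )
        spec = NeighborhoodSpec(max_hard=1, max_soft=1, space_radius=100.0, time_radius=48.0,
                                st_metric_ratio=5.0)
        idx = select_neighborhood(SpaceTimePoint(0.0, 0.0, 0), ds, spec)
        # d(near_space) = 10; d(near_time) = 1 + 5*10 = 51
        assert list(ds.site_ids[idx]) == ["near_space"]


class TestKrigeClosedForms:
    def test_coincident_hard_datum_is_exact(self, simple_model):
        ds = _dataset([(3.0, 4.0, 7, 2.5, 0.0, "a"), (10.0, 0.0, 0, -1.0, 0.0, "b")])
        res = krige(SpaceTimePoint(3.0, 4.0, 7), ds, simple_model)
        assert res.estimate_x == pytest.approx(2.5, abs=1e-10)
        assert res.error_variance == pytest.approx(0.0, abs=1e-10)

    def test_single_hard_datum_closed_form(self, simple_model):
        ds = _dataset([(5.0, 0.0, 0, 2.5, 0.0, "a")])
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        c = math.exp(-3 * 5.0 / 10.0)
        assert res.weights[0] == pytest.approx(1.0, abs=1e-10)
        assert res.estimate_x == pytest.approx(2.5, abs=1e-10)
        assert res.error_variance == pytest.approx(2 * (1.0 - c), abs=1e-10)

    def test_single_collocated_soft_datum(self, simple_model):
        ds = _dataset([(0.0, 0.0, 0, 2.5, 0.7, "a")])
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        assert res.estimate_x == pytest.approx(2.5, abs=1e-10)
        assert res.error_variance == pytest.approx(0.7, abs=1e-10)

    def test_symmetric_pair_gets_equal_weights(self, simple_model):
        ds = _dataset([(5.0, 0.0, 0, 1.0, 0.0, "a"), (-5.0, 0.0, 0, 3.0, 0.0, "b")])
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        assert res.weights == pytest.approx([0.5, 0.5], abs=1e-10)
        assert res.estimate_x == pytest.approx(2.0, abs=1e-10)


class TestKrigeProperties:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            model = random_model(rng, n_structures=int(rng.integers(1, 4)))
            ds = random_dataset(rng, n_hard=int(rng.integers(1, 6)), n_soft=int(rng.integers(0, 5)))
            p0 = SpaceTimePoint(float(rng.uniform(0, 100)), float(rng.uniform(0, 100)),
                                int(rng.integers(0, 49)))
            res = krige(p0, ds, model)
            est, var = brute_force_krige(p0, ds, model)
            assert res.estimate_x == pytest.approx(est, abs=1e-8)
            assert res.error_variance == pytest.approx(var, abs=1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        for trial in range(50):
            model = random_model(rng)
            ds = random_dataset(rng, n_hard=6, n_soft=4)
            p0 = SpaceTimePoint(50.0, 50.0, 24)
            res = krige(p0, ds, model)
            assert np.sum(res.weights) == pytest.approx(1.0, abs=1e-10)

    def test_adding_a_datum_never_increases_variance(self):
        rng = np.random.default_rng(10)
        for trial in range(30):
            model = random_model(rng)
            ds = random_dataset(rng, n_hard=8, n_soft=2)
            p0 = SpaceTimePoint(40.0, 60.0, 12)
            var_small = krige(p0, ds.subset(np.arange(len(ds) - 1)), model).error_variance
            var_full = krige(p0, ds, model).error_variance
            assert var_full <= var_small + 1e-9

    def test_soft_datum_with_huge_variance_loses_its_weight(self, simple_model):
        ds = _dataset(
            [
                (5.0, 0.0, 0, 1.0, 0.0, "hard"),
                (2.0, 0.0, 0, 50.0, 1e8, "soft"),
            ]
        )
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        soft_w = res.weights[list(ds.site_ids).index("soft")]
        assert abs(soft_w) < 1e-5

    def test_soft_datum_with_zero_variance_acts_hard(self, simple_model):
        ds = _dataset([(3.0, 0.0, 2, 1.7, 0.0, "s")])
        res = krige(SpaceTimePoint(3.0, 0.0, 2), ds, simple_model)
        assert res.estimate_x == pytest.approx(1.7, abs=1e-10)
        assert res.error_variance == pytest.approx(0.0, abs=1e-10)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(12)
        model = random_model(rng)
        ds = random_dataset(rng, n_hard=6, n_soft=3)
        p0 = SpaceTimePoint(30.0, 30.0, 20)
        base = krige(p0, ds, model)
        shifted = ds.subset(np.arange(len(ds)))
        shifted.values = shifted.values + 11.5
        res = krige(p0, shifted, model)
        assert res.estimate_x == pytest.approx(base.estimate_x + 11.5, abs=1e-8)
        assert res.error_variance == pytest.approx(base.error_variance, abs=1e-10)


class TestCollocatedRules:
    def test_hard_beats_soft(self, simple_model):
        ds = _dataset(
            [
                (0.0, 0.0, 0, 2.0, 0.0, "h"),
                (0.0, 0.0, 0, 9.0, 0.5, "s"),
            ]
        )
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        assert res.estimate_x == pytest.approx(2.0, abs=1e-10)

    def test_conflicting_hard_duplicates_are_an_error(self, simple_model):
        ds = _dataset(
            [
                (0.0, 0.0, 0, 2.0, 0.0, "h1"),
                (0.0, 0.0, 0, 3.0, 0.0, "h2"),
            ]
        )
        with pytest.raises(KrigingError, match="collocated"):
            krige(SpaceTimePoint(1.0, 0.0, 0), ds, simple_model)

    def test_soft_duplicates_merge_by_precision(self, simple_model):
        ds = _dataset(
            [
                (0.0, 0.0, 0, 1.0, 1.0, "s1"),
                (0.0, 0.0, 0, 3.0, 0.5, "s2"),
            ]
        )
        res = krige(SpaceTimePoint(0.0, 0.0, 0), ds, simple_model)
        # precision-weighted mean: (1/1 + 3/0.5)/(1/1 + 1/0.5) = 7/3
        assert res.estimate_x == pytest.approx(7.0 / 3.0, abs=1e-9)
        assert res.error_variance == pytest.approx(1.0 / 3.0, abs=1e-9)


class TestEstimateBackground:
    def test_offset_added_back(self, simple_model):
        ds = _dataset([(0.0, 0.0, 0, 3.0, 0.0, "a")], offset=7.0)
        spec = NeighborhoodSpec(st_metric_ratio=1.0)
        [est] = estimate_background([SpaceTimePoint(0.0, 0.0, 0)], ds, simple_model, spec)
        assert est.value == pytest.approx(10.0)

    def test_negative_estimate_floored_and_flagged(self, simple_model):
        ds = _dataset([(0.0, 0.0, 0, -9.0, 0.0, "a")], offset=7.0)
        spec = NeighborhoodSpec(st_metric_ratio=1.0)
        [est] = estimate_background([SpaceTimePoint(0.0, 0.0, 0)], ds, simple_model, spec)
        assert est.value == 0.0
        assert est.floored
        assert est.raw_value == pytest.approx(-2.0)

    def test_unestimable_points_reported_not_dropped(self, simple_model):
        ds = _dataset([(0.0, 0.0, 0, 1.0, 0.0, "a")])
        spec = NeighborhoodSpec(space_radius=10.0, time_radius=5.0, st_metric_ratio=1.0)
        ests = estimate_background(
            [SpaceTimePoint(0.0, 0.0, 0), SpaceTimePoint(500.0, 500.0, 0)],
            ds, simple_model, spec,
        )
        assert len(ests) == 2
        assert not ests[0].unestimable
        assert ests[1].unestimable and np.isnan(ests[1].value)

    def test_hour_outside_data_span_flagged_extrapolated(self, simple_model):
        ds = _dataset([(0.0, 0.0, 5, 1.0, 0.0, "a")])
        spec = NeighborhoodSpec(st_metric_ratio=1.0)
        [est] = estimate_background([SpaceTimePoint(0.0, 0.0, 60)], ds, simple_model, spec)
        assert est.extrapolated
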