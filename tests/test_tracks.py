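"""Phenotype metrics: jump filter, MSD, Clark-Evans ratio, magnitudes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from synphen.simulate import ConditionKinetics, TrackSimParams, simulate_tracks
from synphen.tracks import (
    compute_msd, filter_tracks, motility_slope, nearest_neighbor_ratio,
    response_magnitude, summarize_phenotypes,
)


def _track(cell_id, xs, ys, dt=0.5, **labels):
    n = len(xs)
    base = {"condition": "X", "replicate": 1, "field": 1}
    base.update(labels)
    return pd.DataFrame({
        "cell_id": cell_id, "frame": np.arange(n), "t": np.arange(n) * dt,
        "x": xs, "y": ys, "area": 100.0, **base})


class TestFilter:
    def test_track_with_one_big_jump_removed_entirely(self):
        good = _track(1, [0, 5, 8], [0, 0, 0])
        bad = _track(2, [0, 5, 8, 258], [0, 0, 0, 0])
        out = filter_tracks(pd.concat([good, bad]))
        assert set(out["cell_id"]) == {1}

    def test_small_steps_retained_verbatim(self):
        t = _track(1, [0, 100, 250], [0, 0, 0])  # steps 100, 150
        out = filter_tracks(t)
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      t.reset_index(drop=True))

    def test_step_exactly_at_threshold_retained(self):
        t = _track(1, [0.0, 200.0], [0.0, 0.0])
        assert len(filter_tracks(t)) == 2

    def test_empty_input_gives_empty_output(self):
        empty = _track(1, [], [])
        assert filter_tracks(empty).empty


class TestMSD:
    def test_ballistic_track_quadratic_msd(self):
        v = 3.0  # px per frame
        t = _track(1, v * np.arange(20), np.zeros(20))
        curve = compute_msd(t, lags=np.arange(1, 6) * 0.5)
        ks = np.arange(1, 6)
        np.testing.assert_allclose(curve.msd, (v * ks) ** 2)

    def test_stationary_tracks_zero_msd(self):
        t = pd.concat([_track(i, np.full(10, i), np.full(10, 2.0 * i))
                       for i in range(5)])
        curve = compute_msd(t, lags=[0.5, 1.0, 2.0])
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_brownian_msd_matches_4_d_tau(self):
        p = TrackSimParams(conditions={"X": ConditionKinetics(100.0, 0.0)},
                           n_cells_init=500, n_frames=49, n_replicates=1,
                           seed=10)
        tracks, _ = simulate_tracks(p)
        lags = np.arange(1, 13) * 0.5
        curve = compute_msd(tracks, lags)
        theory = 4 * 100.0 * curve.lags
        assert np.all(np.abs(curve.msd - theory) / theory < 0.05)

    def test_msd_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        xs = np.cumsum(rng.normal(0, 5, size=15))
        ys = np.cumsum(rng.normal(0, 5, size=15))
        t = _track(1, xs, ys)
        theta = 0.7
        xr = 100 + xs * np.cos(theta) - ys * np.sin(theta)
        yr = -40 + xs * np.sin(theta) + ys * np.cos(theta)
        tr = _track(1, xr, yr)
        lags = [0.5, 1.0, 1.5]
        np.testing.assert_allclose(compute_msd(t, lags).msd,
                                   compute_msd(tr, lags).msd, rtol=1e-10)

    def test_too_long_lags_dropped_with_record(self):
        t = _track(1, np.arange(5.0), np.zeros(5))
        curve = compute_msd(t, lags=[0.5, 1.0, 10.0])
        assert 10.0 in curve.dropped and len(curve.lags) == 2


class TestSlope:
    def test_exact_line_recovers_slope(self):
        lags = np.arange(1, 13) * 0.5
        curve = compute_msd(_track(1, np.zeros(2), np.zeros(2)), [0.5])
        curve.lags, curve.msd = lags, 400.0 * lags
        assert motility_slope(curve) == pytest.approx(400.0)

    def test_constant_msd_zero_slope(self):
        lags = np.arange(1, 13) * 0.5
        curve = compute_msd(_track(1, np.zeros(2), np.zeros(2)), [0.5])
        curve.lags, curve.msd = lags, np.full_like(lags, 7.0)
        assert motility_slope(curve) == pytest.approx(0.0, abs=1e-12)

    def test_brownian_slope_recovers_diffusion_coefficient(self):
        p = TrackSimParams(conditions={"X": ConditionKinetics(50.0, 0.0)},
                           n_cells_init=500, n_frames=49, n_replicates=1,
                           seed=11)
        tracks, _ = simulate_tracks(p)
        curve = compute_msd(tracks, np.arange(1, 13) * 0.5)
        d_hat = motility_slope(curve) / 4.0
        assert abs(d_hat - 50.0) / 50.0 < 0.10

    def test_too_few_lags_error(self):
        curve = compute_msd(_track(1, np.arange(3.0), np.zeros(3)),
                            [0.5, 1.0])
        with pytest.raises(ValueError):
            motility_slope(curve, lag_min=0.5, lag_max=1.0)


class TestNeighborRatio:
    def test_two_cells_mean_distance_is_separation(self):
        s = nearest_neighbor_ratio(np.array([[0.0, 0.0], [3.0, 4.0]]),
                                   area=100.0)
        assert s.r_mean == pytest.approx(5.0)

    def test_csr_expectation_formula(self):
        s = nearest_neighbor_ratio(np.random.default_rng(0).uniform(
            0, 100, (50, 2)), area=100.0 ** 2)
        lam = 50 / 100.0 ** 2
        assert s.r_expected == pytest.approx(1 / (2 * np.sqrt(lam)))

    def test_csr_ratio_calibrated_to_one(self):
        rng = np.random.default_rng(42)
        ratios = [nearest_neighbor_ratio(rng.uniform(0, 1024, (500, 2)),
                                         1024.0 ** 2).ratio
                  for _ in range(20)]
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_cluster_below_one_grid_above_one(self):
        kw = dict(n_cells_init=500, n_frames=2, n_replicates=1)
        ratios = {}
        for pattern in ("thomas_cluster", "poisson", "grid"):
            p = TrackSimParams(conditions={"X": ConditionKinetics(0.0, 0.0)},
                               spatial_pattern=pattern, seed=21, **kw)
            t, _ = simulate_tracks(p)
            pos = t.loc[t.frame == 0, ["x", "y"]].to_numpy()
            ratios[pattern] = nearest_neighbor_ratio(pos, 1024.0 ** 2).ratio
        assert ratios["thomas_cluster"] < ratios["poisson"] < ratios["grid"]
        assert ratios["thomas_cluster"] < 1 < ratios["grid"]

    def test_needs_more_cells_than_neighbor_order(self):
        with pytest.raises(ValueError):
            nearest_neighbor_ratio(np.zeros((2, 2)), 10.0, k=2)


class TestSummaries:
    def test_no_division_count_fc_is_one_and_area_passthrough(self):
        p = TrackSimParams(conditions={"X": ConditionKinetics(
            30.0, 0.0, area_mean=200.0, area_cv=0.0)},
            n_cells_init=60, n_frames=49, n_replicates=2, seed=14)
        tracks, _ = simulate_tracks(p)
        pheno = summarize_phenotypes(tracks, field_area=1024.0 ** 2)
        assert np.allclose(pheno["count_fc"], 1.0)
        assert np.allclose(pheno["cyto_area"], 200.0)

    def test_exponential_growth_of_count_fc(self):
        rate = 0.03
        p = TrackSimParams(conditions={"X": ConditionKinetics(20.0, rate)},
                           n_cells_init=800, n_frames=49, n_replicates=1,
                           seed=15)
        tracks, _ = simulate_tracks(p)
        pheno = summarize_phenotypes(tracks, field_area=1024.0 ** 2)
        expected = np.exp(rate * 24.0)
        assert abs(pheno["count_fc"].iloc[0] - expected) / expected < 0.10

    def test_no_cells_at_t0_is_an_error(self):
        t = _track(1, np.arange(5.0), np.zeros(5))
        t["frame"] += 1
        with pytest.raises(ValueError):
            summarize_phenotypes(t)


class TestMagnitude:
    def _pheno(self, rows):
        return pd.DataFrame(rows)

    def test_identical_to_reference_gives_zero(self):
        df = self._pheno([
            dict(condition="PBS", replicate=1, count_fc=2.0, motility=100.0,
                 nn_ratio=1.0, cyto_area=500.0),
            dict(condition="EGF", replicate=1, count_fc=2.0, motility=100.0,
                 nn_ratio=1.0, cyto_area=500.0)])
        out = response_magnitude(df)
        assert out.loc[out.condition == "EGF", "magnitude"].iloc[0] == 0.0

    def test_single_doubled_metric_gives_one(self):
        df = self._pheno([
            dict(condition="PBS", replicate=1, count_fc=2.0, motility=100.0,
                 nn_ratio=1.0, cyto_area=500.0),
            dict(condition="EGF", replicate=1, count_fc=4.0, motility=100.0,
                 nn_ratio=1.0, cyto_area=500.0)])
        out = response_magnitude(df)
        assert out.loc[out.condition == "EGF", "magnitude"].iloc[0] == \
            pytest.approx(1.0)

    def test_three_four_five_magnitude(self):
        df = self._pheno([
            dict(condition="PBS", replicate=1, count_fc=1.0, motility=1.0,
                 nn_ratio=1.0, cyto_area=1.0),
            dict(condition="EGF", replicate=1, count_fc=1.3, motility=0.6,
                 nn_ratio=1.0, cyto_area=1.0)])
        out = response_magnitude(df)
        assert out.loc[out.condition == "EGF", "magnitude"].iloc[0] == \
            pytest.approx(0.5)

    @given(scale=st.floats(0.1, 5.0))
    def test_magnitude_homogeneous_in_relative_changes(self, scale):
        rel = np.array([0.2, -0.1, 0.05, 0.3])
        base = np.array([2.0, 100.0, 1.0, 500.0])
        rows = [dict(condition="PBS", replicate=1, count_fc=base[0],
                     motility=base[1], nn_ratio=base[2], cyto_area=base[3])]
        for name, r in (("A", rel), ("B", rel * scale)):
            v = base * (1 + r)
            rows.append(dict(condition=name, replicate=1, count_fc=v[0],
                             motility=v[1], nn_ratio=v[2], cyto_area=v[3]))
        out = response_magnitude(pd.DataFrame(rows)).set_index("condition")
        assert out.loc["B", "magnitude"] == pytest.approx(
            scale * out.loc["A", "magnitude"])

    def test_zero_reference_metric_is_an_error(self):
        df = self._pheno([
            dict(condition="PBS", replicate=1, count_fc=0.0, motility=1.0,
                 nn_ratio=1.0, cyto_area=1.0),
            dict(condition="EGF", replicate=1, count_fc=1.0, motility=1.0,
                 nn_ratio=1.0, cyto_area=1.0)])
        with pytest.raises(ValueError):
            response_magnitude(df)
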