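"""Peri-event matrices, shuffle nulls, per-animal summaries, group stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lutphysio.io_formats import events_from_records
from lutphysio.perievent import (
    average_trace,
    build_matrix,
    compare_groups,
    dunn_test,
    per_animal_summary,
    shuffle_null,
)
from lutphysio.photometry import DffTrace


def _events(times, animal="m1", kind="void"):
    return events_from_records(
        [
            {"event_id": f"{kind}{i}", "animal_id": animal, "kind": kind,
             "t_align_s": t, "t_start_s": t - 1, "t_end_s": t + 1}
            for i, t in enumerate(times)
        ]
    )


def _flat_trace(n=6000, fs=10.0, level=0.05):
    return DffTrace(np.full(n, level), fs)


class TestBuildMatrix:
    def test_flat_trace_gives_zero_row(self):
        mat = build_matrix(_flat_trace(), _events([300.0]), "percent")
        assert mat.n_events == 1
        assert np.allclose(mat.values, 0.0)

    def test_rows_equal_direct_recomputation(self):
        rng = np.random.default_rng(10)
        dff = DffTrace(rng.normal(0.05, 0.01, 8000), 10.0)
        times = [200.0, 400.0, 600.0]
        mat = build_matrix(dff, _events(times), "percent")
        for row, t in zip(mat.values, times):
            i, w = int(t * 10), 600
            base = dff.values[i - w : i].mean()
            oracle = (dff.values[i - w : i + w + 1] - base) / base * 100.0
            assert np.allclose(row, oracle, rtol=1e-12)

    def test_out_of_bounds_event_dropped(self):
        mat = build_matrix(_flat_trace(2000), _events([30.0, 100.0]), "percent")
        assert mat.n_events == 1  # only t=100 fits in a 200 s trace

    def test_no_usable_events_gives_empty_matrix(self):
        mat = build_matrix(_flat_trace(2000), _events([]), "percent")
        assert mat.n_events == 0 and mat.values.shape == (0, 1201)

    def test_rows_ordered_by_animal_then_time(self):
        ev = pd.concat(
            [_events([400.0, 200.0], animal="m2"), _events([300.0], animal="m1")]
        )
        ev = ev.assign(event_id=[f"e{i}" for i in range(len(ev))])
        mat = build_matrix(_flat_trace(8000), ev, "raw")
        assert list(mat.rows["animal_id"]) == ["m1", "m2", "m2"]
        assert list(mat.rows["t_align_s"]) == [300.0, 200.0, 400.0]


class TestShuffleNull:
    def test_zero_events_empty(self):
        assert shuffle_null(_flat_trace(), 0, seed=1).n_events == 0

    def test_same_seed_same_times(self):
        a = shuffle_null(_flat_trace(), 5, seed=42)
        b = shuffle_null(_flat_trace(), 5, seed=42)
        assert np.array_equal(a.rows["t_align_s"], b.rows["t_align_s"])

    def test_windows_fit_inside_trace(self):
        mat = shuffle_null(_flat_trace(3000), 20, seed=3)
        assert ((mat.rows["t_align_s"] >= 60.0)
                & (mat.rows["t_align_s"] <= 240.0)).all()

    def test_exclusion_zones_respected(self):
        zones = [(100.0, 200.0)]
        mat = shuffle_null(_flat_trace(6000), 30, seed=4, exclusion_zones=zones)
        t = mat.rows["t_align_s"].to_numpy()
        assert not ((t >= 100.0) & (t <= 200.0)).any()

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="exclusion"):
            shuffle_null(_flat_trace(3000), 10, seed=5,
                         exclusion_zones=[(0.0, 300.0)], max_tries=50)

    def test_null_mean_near_zero_on_transient_free_trace(self):
        rng = np.random.default_rng(6)
        dff = DffTrace(rng.normal(0.0, 0.01, 20000), 10.0)
        means = []
        for seed in range(200):
            mat = shuffle_null(dff, 5, seed=seed, normalization="raw")
            means.append(mat.values.mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand) <= 3 * se + 1e-12


class TestAverageTrace:
    def test_single_row_mean_is_row_sem_zero(self):
        mat = build_matrix(_flat_trace(), _events([300.0]), "raw")
        mean, sem, n = average_trace(mat)
        assert n == 1 and np.allclose(mean, mat.values[0]) and np.all(sem == 0)

    def test_matches_column_loop_oracle(self):
        rng = np.random.default_rng(11)
        dff = DffTrace(rng.normal(0.05, 0.01, 8000), 10.0)
        mat = build_matrix(dff, _events([200.0, 400.0, 600.0]), "percent")
        mean, sem, n = average_trace(mat)
        for j in range(mat.values.shape[1]):
            col = mat.values[:, j]
            assert mean[j] == pytest.approx(col.mean(), rel=1e-12)
            assert sem[j] == pytest.approx(col.std(ddof=1) / np.sqrt(3), rel=1e-12)

    def test_duplicating_rows_halves_sem_factor(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, (4, 50))
        from lutphysio.perievent import PeriEventMatrix

        rows = pd.DataFrame({"event_id": list("abcd"), "animal_id": "m",
                             "kind": "void", "t_align_s": range(4),
                             "flagged": False})
        m1 = PeriEventMatrix(vals, np.arange(50) / 10, rows, "raw")
        m2 = PeriEventMatrix(np.vstack([vals, vals]), m1.lags,
                             pd.concat([rows, rows]), "raw")
        mean1, sem1, _ = average_trace(m1)
        mean2, sem2, _ = average_trace(m2)
        assert np.allclose(mean1, mean2)
        # 1/sqrt(2) up to the ddof=1 correction: exact ratio sqrt((n-1)/(2n-1))
        assert np.allclose(sem2 / sem1, np.sqrt(3.0 / 7.0), rtol=1e-9)


class TestPerAnimalSummary:
    def _matrix(self, n_animals=4, n_rows=12, seed=1):
        rng = np.random.default_rng(seed)
        dff = DffTrace(rng.normal(0.05, 0.01, 60000), 10.0)
        frames = []
        for a in range(n_animals):
            times = np.linspace(200, 5500, n_rows) + a * 3.1
            frames.append(_events(list(times), animal=f"m{a}"))
        ev = pd.concat(frames)
        ev = ev.assign(event_id=[f"e{i}" for i in range(len(ev))])
        return build_matrix(dff, ev, "raw")

    def test_four_animals_times_ten_gives_forty(self):
        out = per_animal_summary(self._matrix(), (0.0, 10.0), 10, seed=2)
        assert len(out) == 40
        assert (out.groupby("animal_id").size() == 10).all()

    def test_full_subsample_is_deterministic_identity(self):
        mat = self._matrix(n_rows=6)
        a = per_animal_summary(mat, (0.0, 10.0), 6, seed=1)
        b = per_animal_summary(mat, (0.0, 10.0), 6, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_same_seed_same_subsample(self):
        mat = self._matrix()
        a = per_animal_summary(mat, (-5.0, 5.0), 5, seed=7)
        b = per_animal_summary(mat, (-5.0, 5.0), 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_value_is_mean_over_stat_window(self):
        mat = self._matrix(n_animals=1, n_rows=3)
        out = per_animal_summary(mat, (0.0, 30.0), 3, seed=0)
        cols = (mat.lags >= 0.0) & (mat.lags <= 30.0)
        for _, r in out.iterrows():
            i = mat.rows.index[mat.rows["event_id"] == r["event_id"]][0]
            assert r["value"] == pytest.approx(mat.values[i, cols].mean())

    def test_animal_with_too_few_rows_errors(self):
        mat = self._matrix(n_rows=4)
        with pytest.raises(ValueError, match="m0"):
            per_animal_summary(mat, (0.0, 10.0), 10, seed=1)


class TestCompareGroups:
    def test_identical_constant_groups_no_rejections(self):
        x = np.ones(10)
        rep = compare_groups(x, x, x)
        assert rep["kruskal_p"] == 1.0
        assert all(p["p_adj"] == 1.0 for p in rep["pairwise"])

    def test_separated_groups_rejected(self):
        rng = np.random.default_rng(13)
        void = rng.normal(3.0, 1.0, 32)
        nvc = rng.normal(1.0, 1.0, 32)
        null = rng.normal(0.0, 1.0, 32)
        rep = compare_groups(void, nvc, null)
        assert rep["kruskal_p"] < 1e-6
        pair = {tuple(p["pair"]): p for p in rep["pairwise"]}
        assert pair[("void", "null")]["p_adj"] < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups(np.ones(3), np.array([]), np.ones(3))

    def test_dunn_null_calibration_uniform_p(self):
        # permuting labels of pooled identical data -> uniform p over seeds
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            pooled = rng.normal(0, 1, 60)
            g = pooled.reshape(3, 20)
            ps.append(stats.kruskal(*g).pvalue)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_dunn_matches_hand_computation_no_ties(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0]),
                  "c": np.array([7.0, 8.0, 9.0])}
        out = {tuple(p["pair"]): p for p in dunn_test(groups)}
        n = 9
        var = n * (n + 1) / 12.0
        se = np.sqrt(var * (1 / 3 + 1 / 3))
        z_ab = (2.0 - 5.0) / se
        assert out[("a", "b")]["z"] == pytest.approx(z_ab)
        assert out[("a", "c")]["z"] == pytest.approx((2.0 - 8.0) / se)
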