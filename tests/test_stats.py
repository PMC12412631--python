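"""Block deltas, t-statistics, ROI selection, paired tests and the
cluster-mass permutation test."""

import numpy as np
import pandas as pd
import pytest

from hdnirs.forward import SensitivityMatrix
from hdnirs.stats import (
    block_delta,
    block_deltas,
    cluster_permutation,
    group_summary,
    paired_ttest,
    select_max_t,
    select_roi_vertices,
    t_critical,
    tstat,
)

FS = 10.0


class TestBlockDelta:
    def _trace(self, fn, duration=60.0):
        t = np.arange(0, duration, 1 / FS)
        return np.array([fn(x) for x in t]), t

    def test_flat_trace_zero(self):
        y, _ = self._trace(lambda x: 0.7)
        assert block_delta(y, onset=20.0, fs=FS) == pytest.approx(0.0)

    def test_constant_plateau_returns_plateau(self):
        y, t = self._trace(lambda x: 3.0 if 27.0 <= x < 38.0 else 0.0)
        assert block_delta(y, onset=20.0, fs=FS) == pytest.approx(3.0)

    def test_ramp_matches_windowed_mean_oracle(self):
        y, t = self._trace(lambda x: 0.1 * x)
        onset = 20.0
        # oracle: explicit sample-index windows, start-inclusive/end-exclusive
        task = [i for i in range(len(t)) if onset + 7 <= i / FS < onset + 18]
        base = [i for i in range(len(t)) if onset - 2 <= i / FS < onset]
        expected = np.mean(y[task]) - np.mean(y[base])
        assert block_delta(y, onset, FS) == pytest.approx(expected, rel=1e-12)

    def test_insufficient_coverage_error(self):
        y = np.zeros(100)
        with pytest.raises(ValueError, match="window"):
            block_delta(y, onset=5.0, fs=FS)
        with pytest.raises(ValueError, match="window"):
            block_delta(y, onset=1.0, fs=FS)

    def test_vectorized_matches_scalar(self, rng):
        y = rng.normal(0, 1, 2000)
        onsets = np.array([30.0, 80.0, 130.0])
        got = block_deltas(y, onsets, FS)
        assert got == pytest.approx([block_delta(y, o, FS) for o in onsets])


class TestTStat:
    def test_hand_computed_value(self):
        res = tstat(np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0))
        assert res.mean == pytest.approx(2.0)
        assert res.se == pytest.approx(1.0 / np.sqrt(3.0))

    def test_symmetric_deltas_zero(self):
        assert tstat(np.array([0.5, -0.5])).t == pytest.approx(0.0)

    def test_degenerate_equal_deltas_flagged_infinite(self):
        res = tstat(np.array([2.0, 2.0, 2.0]))
        assert res.degenerate and res.t == np.inf
        res = tstat(np.array([-1.0, -1.0]))
        assert res.t == -np.inf

    def test_too_few_blocks_error(self):
        with pytest.raises(ValueError, match="two"):
            tstat(np.array([1.0]))

    def test_equals_paired_test_against_zero(self, rng):
        x = rng.normal(0.3, 1.0, 12)
        assert tstat(x).t == pytest.approx(paired_ttest(x, np.zeros(12)).t)


class TestTCritical:
    def test_seventeen_subjects(self):
        assert round(t_critical(17, 0.05), 2) == 2.12

    def test_alpha_one_gives_zero(self):
        assert t_critical(10, alpha=1.0) == pytest.approx(0.0)

    def test_normal_limit(self):
        assert t_critical(100000, 0.05) == pytest.approx(1.96, abs=0.005)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            t_critical(1)


def _toy_S(values, surface=None):
    values = np.asarray(values, float)
    C, V = values.shape
    if surface is None:
        surface = ["brain"] * V
    verts = pd.DataFrame(
        {"x": np.arange(V, dtype=float), "y": 0.0, "z": -15.0, "surface": surface}
    )
    ch = pd.DataFrame(
        {"source_id": np.arange(C), "detector_id": np.arange(C) + 50,
         "separation": 30.0, "distance_class": "NN30", "is_short": False}
    )
    return SensitivityMatrix(values[None, :, :], (760.0,), ch, verts)


class TestSelectRoiVertices:
    def test_uniform_sensitivity_keeps_none(self):
        S = _toy_S(np.full((2, 5), 0.5))
        assert len(select_roi_vertices(S, [0, 1])) == 0  # none exceed the mean

    def test_two_level_keeps_high_level(self):
        vals = np.array([[0.02, 0.5, 0.02, 0.5, 0.02]])
        S = _toy_S(vals)
        got = select_roi_vertices(S, [0], threshold=0.01)
        np.testing.assert_array_equal(got, [1, 3])

    def test_threshold_above_max_errors(self):
        S = _toy_S(np.array([[0.3, 0.2]]))
        with pytest.raises(ValueError, match="threshold|above"):
            select_roi_vertices(S, [0], threshold=1.5)

    def test_brain_surface_restriction(self):
        vals = np.array([[0.1, 0.9, 0.1, 0.9]])
        S = _toy_S(vals, surface=["brain", "scalp", "brain", "scalp"])
        got = select_roi_vertices(S, [0], threshold=0.01, surface="brain")
        assert set(got) <= {0, 2}


class TestSelectMaxT:
    def _table(self, ids, ts, subject="s1"):
        return pd.DataFrame(
            {"subject": subject, "id": ids, "t": ts, "delta": np.asarray(ts) * 0.1}
        )

    def test_single_candidate(self):
        out = select_max_t(self._table([4], [1.2]))
        assert out["id"].iloc[0] == 4

    def test_tie_breaks_to_lowest_id(self):
        out = select_max_t(self._table([3, 7, 9], [1.0, 2.5, 2.5]))
        assert out["id"].iloc[0] == 7

    def test_hbr_selects_lowest_t(self):
        out = select_max_t(self._table([1, 2, 3], [-3.0, 0.5, 1.0]),
                           chromophore="hbr")
        assert out["id"].iloc[0] == 1

    def test_matches_exhaustive_scan(self, rng):
        ids = np.arange(40)
        ts = rng.normal(0, 1, 40)
        out = select_max_t(self._table(ids, ts))
        assert out["id"].iloc[0] == ids[np.argmax(ts)]
        assert out["t"].iloc[0] == pytest.approx(ts.max())

    def test_top_n_mean_delta(self, rng):
        ids = np.arange(30)
        ts = rng.normal(0, 1, 30)
        tab = self._table(ids, ts)
        out = select_max_t(tab, n_top=5)
        expect = tab.sort_values("t", ascending=False).head(5)["delta"].mean()
        assert out["delta"].iloc[0] == pytest.approx(expect)

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="candidates"):
            select_max_t(pd.DataFrame(columns=["subject", "id", "t", "delta"]))


class TestPairedTtest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_ttest(a, a)
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed(self):
        res = paired_ttest(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0))
        from scipy import stats as sps

        assert res.p == pytest.approx(
            2 * sps.t.sf(2.0 * np.sqrt(3.0), 2), rel=1e-9
        )

    def test_swap_negates_t_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 1, 10)
        r1, r2 = paired_ttest(a, b), paired_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        a, b = rng.normal(0, 1, 15), rng.normal(0.2, 1, 15)
        res = paired_ttest(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_nan_pairs_dropped(self):
        a = np.array([1.0, np.nan, 3.0, 4.0])
        b = np.array([0.0, 1.0, np.nan, 2.0])
        res = paired_ttest(a, b)
        assert res.n == 2

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="pairs"):
            paired_ttest(np.array([1.0, np.nan]), np.array([0.0, 1.0]))


def _grid_positions(n, pitch=20.0):
    return np.column_stack([np.arange(n) * pitch, np.zeros(n), np.zeros(n)])


class TestClusterPermutation:
    def test_strong_contiguous_effect_detected(self, rng):
        pos = _grid_positions(20)
        X = rng.normal(0, 1, (12, 20))
        X[:, 5:10] += 3.0  # strong 5-channel effect, neighbours within 33 mm
        res = cluster_permutation(pos, X, radius=33.0, n_perm=200, seed=0)
        assert res.mask[5:10].all()
        detected = [i for c in res.clusters for i in c]
        p_of = {i: p for c, p in zip(res.clusters, res.cluster_p) for i in c}
        assert min(p_of[i] for i in range(5, 10)) <= 1.5 / 201

    def test_radius_zero_gives_singleton_clusters(self, rng):
        pos = _grid_positions(10)
        X = rng.normal(0, 1, (10, 10))
        X[:, 3] += 3.0
        res = cluster_permutation(pos, X, radius=0.0, n_perm=100, seed=1)
        assert all(len(c) == 1 for c in res.clusters)

    def test_isolated_channel_forms_singleton_cluster(self, rng):
        pos = _grid_positions(5, pitch=100.0)  # nothing within 33 mm
        X = rng.normal(0, 0.1, (10, 5))
        X[:, 2] += 2.0
        res = cluster_permutation(pos, X, radius=33.0, n_perm=100, seed=2)
        assert any(len(c) == 1 and c[0] == 2 for c in res.clusters)

    def test_growing_radius_never_increases_cluster_count(self, rng):
        pos = _grid_positions(15, pitch=15.0)
        X = rng.normal(0, 1, (10, 15)) + 1.0
        counts = []
        for radius in (0.0, 16.0, 31.0, 100.0):
            res = cluster_permutation(pos, X, radius=radius, n_perm=20, seed=3)
            counts.append(len(res.clusters))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_seeded_determinism(self, rng):
        pos = _grid_positions(8)
        X = rng.normal(0, 1, (9, 8))
        a = cluster_permutation(pos, X, n_perm=50, seed=7)
        b = cluster_permutation(pos, X, n_perm=50, seed=7)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_allclose(a.cluster_p, b.cluster_p)

    def test_input_validation(self, rng):
        pos = _grid_positions(4)
        X = rng.normal(0, 1, (5, 4))
        with pytest.raises(ValueError, match="permutation"):
            cluster_permutation(pos, X, n_perm=0)
        with pytest.raises(ValueError, match="subjects"):
            cluster_permutation(pos, X[:1], n_perm=10)

    def test_null_familywise_rate_controlled_quick(self):
        """Coarse null-calibration check (the acceptance suite runs the
        full 500-replicate version)."""
        rng = np.random.default_rng(123)
        pos = _grid_positions(20, pitch=15.0)
        hits = 0
        reps = 60
        for r in range(reps):
            X = rng.normal(0, 1, (15, 20))
            res = cluster_permutation(pos, X, radius=33.0, n_perm=100,
                                      seed=int(rng.integers(2**31)))
            hits += res.mask.any()
        assert hits / reps < 0.2


class TestGroupSummary:
    def test_two_subject_hand_value(self):
        out = group_summary(np.array([[1.0, 5.0], [3.0, 5.0]]))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(1.0)
        assert row["t"] == pytest.approx(2.0)

    def test_identical_subjects_flagged_degenerate(self):
        out = group_summary(np.array([[2.0], [2.0], [2.0]]))
        assert out.iloc[0]["degenerate"]

    def test_single_subject_channel_unavailable(self):
        out = group_summary(np.array([[1.0, np.nan], [np.nan, np.nan]]))
        assert not out.iloc[0]["available"]
        assert not out.iloc[1]["available"]

    def test_matches_direct_recomputation(self, rng):
        X = rng.normal(0, 1, (8, 6))
        out = group_summary(X)
        for ch in range(6):
            se = X[:, ch].std(ddof=1) / np.sqrt(8)
            assert out.iloc[ch]["t"] == pytest.approx(X[:, ch].mean() / se)
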