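import itertools

import numpy as np
import pytest

from drivestress.palpitation import (
    gate_artifacts,
    kmeans_rr,
    sdrr_windows,
    select_palpitations,
    tension_threshold,
)
from drivestress.rpeak import RRSeries


def rr_series(values, times=None, stage="driving"):
    values = np.asarray(values, float)
    times = np.arange(1, values.size + 1, dtype=float) if times is None else np.asarray(times, float)
    return RRSeries(values, times, np.array([stage] * values.size, dtype=object))


def brute_force_inertia(values, k):
    """Global k-means optimum by enumerating every assignment (tiny n only)."""
    values = np.asarray(values, float)
    best = np.inf
    for labels in itertools.product(range(k), repeat=values.size):
        labels = np.asarray(labels)
        if np.unique(labels).size != k:
            continue
        sse = 0.0
        for c in range(k):
            members = values[labels == c]
            sse += float(np.sum((members - members.mean()) ** 2))
        best = min(best, sse)
    return best


class TestKMeans:
    def test_two_well_separated_groups(self):
        vals = [600, 610, 590, 900, 910, 890]
        model = kmeans_rr(rr_series(vals), k=2, seed=0)
        np.testing.assert_allclose(model.centroids, [600.0, 900.0])
        counts = np.bincount(model.assignments)
        assert list(counts) == [3, 3]
        # exhaustive-partition check: this assignment is the global optimum
        assert model.inertia == pytest.approx(brute_force_inertia(vals, 2))

    def test_identical_values_degenerate(self):
        model = kmeans_rr(rr_series([700.0] * 6), k=2, seed=0)
        assert model.k == 1
        assert model.k_reduced
        assert model.centroids[0] == pytest.approx(700.0)
        assert model.inertia == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_optimum_on_small_instances(self, k, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(400, 1100, size=rng.integers(k + 2, 11)), 1)
        model = kmeans_rr(vals, k=k, seed=seed)
        assert model.inertia == pytest.approx(brute_force_inertia(vals, model.k), abs=1e-6)

    def test_assignments_map_to_nearest_centroid(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(400, 1100, size=60)
        model = kmeans_rr(vals, k=3, seed=4)
        dist = np.abs(vals[:, None] - model.centroids[None, :])
        np.testing.assert_array_equal(model.assignments, np.argmin(dist, axis=1))

    def test_spread_is_member_sample_sd(self):
        model = kmeans_rr(rr_series([590, 600, 610, 890, 900, 910]), k=2, seed=0)
        np.testing.assert_allclose(model.spreads, [10.0, 10.0])


class TestSelection:
    @pytest.fixture()
    def balanced(self):
        rr = rr_series([590, 600, 610, 890, 900, 910])
        return kmeans_rr(rr, k=2, seed=0), rr

    def test_above_threshold_arithmetic(self, balanced):
        model, rr = balanced
        assert tension_threshold(model, "above") == pytest.approx(760.0)
        events = select_palpitations(model, rr, "above")
        assert set(events.event_rr_ms) == {890, 900, 910}

    def test_below_mirror_threshold(self, balanced):
        model, rr = balanced
        assert tension_threshold(model, "below") == pytest.approx(740.0)
        events = select_palpitations(model, rr, "below")
        assert set(events.event_rr_ms) == {590, 600, 610}

    def test_no_value_meeting_predicate_gives_empty_events(self, balanced):
        model, _ = balanced
        mid = rr_series([750.0, 755.0])
        events = select_palpitations(model, mid, "above")
        assert events.n == 0

    def test_flagging_invariant_to_rr_order(self, balanced):
        model, rr = balanced
        perm = np.array([3, 1, 5, 0, 2, 4])
        shuffled = RRSeries(rr.rr_ms[perm], rr.rr_times[perm], rr.stage[perm])
        a = select_palpitations(kmeans_rr(shuffled, 2, seed=0), shuffled, "above")
        b = select_palpitations(model, rr, "above")
        np.testing.assert_array_equal(np.sort(a.event_rr_ms), np.sort(b.event_rr_ms))

    def test_flag_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(400, 1100, size=200)
        counts = [int(np.sum(vals >= thr)) for thr in np.linspace(400, 1100, 15)]
        assert counts == sorted(counts, reverse=True)

    def test_event_times_strictly_increasing(self, balanced):
        model, rr = balanced
        events = select_palpitations(model, rr, "above")
        assert np.all(np.diff(events.event_times) > 0)


class TestArtifactGate:
    def test_dropout_interval_removed(self):
        vals = [750.0] * 20 + [1500.0]  # one missed beat doubles the interval
        gated = gate_artifacts(rr_series(vals))
        assert gated.n == 20
        assert gated.rr_ms.max() == pytest.approx(750.0)

    def test_tachycardic_episode_survives(self):
        vals = [750.0] * 50 + [525.0] * 5
        gated = gate_artifacts(rr_series(vals))
        assert gated.n == 55


def test_sdrr_windows_collapse():
    # 3 windows of 30 s; SD of each window's RR values, stamped at window end
    times = np.concatenate([np.arange(5, 30, 5), np.arange(35, 60, 5), np.arange(65, 90, 5)])
    vals = np.concatenate([[700, 710, 690, 700, 700], [800] * 5, [600, 620, 600, 620, 600]])
    out = sdrr_windows(rr_series(vals, times=times), window_s=30.0)
    assert out.n == 3
    assert out.rr_ms[0] == pytest.approx(np.std([700, 710, 690, 700, 700], ddof=1))
    assert out.rr_ms[1] == pytest.approx(0.0)


def test_planted_tachycardia_recovered(elderly_report, elderly_session):
    """Short-RR flagging recovers the planted episodes and little else."""
    _, _, truth, _ = elderly_session
    events = elderly_report.events
    planted = truth.true_palpitation_times
    hits = sum(np.min(np.abs(events.event_times - t)) < 0.05 for t in planted)
    assert hits / planted.size >= 0.8
    # false flags among baseline beats stay rare
    n_baseline = truth.true_peak_times.size - planted.size
    false_flags = sum(np.min(np.abs(planted - t)) > 0.05 for t in events.event_times)
    assert false_flags / n_baseline <= 0.10
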