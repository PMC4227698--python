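"""SKM idealization, dead-time imposition, and cluster segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pegblock.idealize import (
    IdealizedEvents,
    critical_time,
    impose_dead_time,
    segment_clusters,
    skm_idealize,
)
from pegblock.schemes import CLOSED, OPEN, Conditions, Edge, KineticScheme, RateLaw
from pegblock.simulate import DwellSequence, render_trace, simulate_dwells


def _fixed_dwells(durs_ms, start_open=False):
    codes = np.arange(len(durs_ms)) % 2
    if start_open:
        codes = 1 - codes
    return codes.astype(np.int8), np.asarray(durs_ms) / 1e3


def _events(codes, durs):
    return IdealizedEvents(np.asarray(codes, np.int8), np.asarray(durs, float),
                           np.full(len(durs), np.nan))


class TestSkmIdealize:
    def test_zero_noise_exact_recovery(self):
        codes, durs = _fixed_dwells([5.0, 3.0, 7.0, 2.0, 6.0, 4.0, 8.0])
        tr = render_trace((codes, durs), amplitudes=(0.0, 7.0), noise_sd=0.0,
                          filter_cutoff=None, seed=0)
        ev = skm_idealize(tr)
        assert np.array_equal(ev.class_codes, codes)
        # durations recovered to within one sampling interval
        assert np.abs(ev.durations - durs).max() <= 1.0 / tr.sample_rate + 1e-12

    def test_round_trip_through_noise(self, two_state):
        """render -> skm -> dead time recovers the dwell sequence of a
        slow-gating channel at realistic SNR."""
        slow = KineticScheme(
            ["C", "O"], {"C": CLOSED, "O": OPEN},
            [Edge("C", "O", RateLaw(40.0), "opening"),
             Edge("O", "C", RateLaw(60.0), "closing")],
        )
        d = simulate_dwells(slow, Conditions(), n_events=300, seed=21)
        tr = render_trace(d, noise_sd=0.7, seed=22)
        ev = impose_dead_time(skm_idealize(tr), 0.2e-3)
        # the fair reference is the true sequence with the same dead time
        codes_t, durs_t = d.class_dwells()
        truth = impose_dead_time(_events(codes_t, durs_t), 0.2e-3)
        assert abs(len(ev) - len(truth)) <= 4
        assert ev.open_durations().sum() == pytest.approx(
            truth.open_durations().sum(), rel=0.02)

    def test_per_sample_misclassification_below_one_percent(self):
        rng = np.random.default_rng(30)
        durs = rng.exponential(0.01, size=400)  # 10 ms dwells >> filter rise
        codes = (np.arange(400) % 2).astype(np.int8)
        tr = render_trace((codes, durs), amplitudes=(0.0, 10.0), noise_sd=1.0, seed=31)
        ev = skm_idealize(tr)
        # reconstruct per-sample labels from both event lists
        def per_sample(cds, ds):
            n = int(np.floor(ds.sum() * tr.sample_rate))
            edges = np.concatenate(([0.0], np.cumsum(ds)))
            mid = (np.arange(n) + 0.5) / tr.sample_rate
            return cds[np.clip(np.searchsorted(edges, mid, "right") - 1, 0, len(ds) - 1)]
        truth = per_sample(codes, durs)
        decoded = per_sample(ev.class_codes, ev.durations)
        m = min(truth.size, decoded.size)
        assert np.mean(truth[:m] != decoded[:m]) < 0.01

    def test_label_symmetry_broken_by_amplitude_order(self):
        codes, durs = _fixed_dwells([5.0, 4.0, 6.0, 3.0, 5.0])
        tr = render_trace((codes, durs), noise_sd=0.5, seed=33)
        ev_a = skm_idealize(tr, init_amplitudes=[0.0, 7.0])
        ev_b = skm_idealize(tr, init_amplitudes=[7.0, 0.0])
        assert np.array_equal(ev_a.class_codes, ev_b.class_codes)
        assert np.array_equal(ev_a.durations, ev_b.durations)

    def test_offset_invariance(self):
        codes, durs = _fixed_dwells([5.0, 4.0, 6.0, 3.0, 5.0])
        tr = render_trace((codes, durs), noise_sd=0.5, seed=34)
        shifted = render_trace((codes, durs), noise_sd=0.5, seed=34)
        shifted.samples = shifted.samples + 5.0
        ev_a, ev_b = skm_idealize(tr), skm_idealize(shifted)
        assert np.array_equal(ev_a.class_codes, ev_b.class_codes)
        assert np.array_equal(ev_a.durations, ev_b.durations)

    def test_too_short_trace_rejected(self):
        tr = render_trace((np.array([0]), np.array([0.0005])), noise_sd=0.0,
                          filter_cutoff=None)
        with pytest.raises(ValueError):
            skm_idealize(tr)


class TestImposeDeadTime:
    def test_zero_dead_time_is_identity(self):
        ev = _events([0, 1, 0], [0.005, 0.0001, 0.004])
        out = impose_dead_time(ev, 0.0)
        assert np.array_equal(out.durations, ev.durations)

    def test_short_gap_absorbed_and_flanks_merged(self):
        ev = _events([1, 0, 1], [0.005, 0.0001, 0.005])
        out = impose_dead_time(ev, 0.0002)
        assert len(out) == 1
        assert out.class_codes[0] == 1
        assert out.durations[0] == pytest.approx(0.0101, abs=1e-15)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        durs = rng.exponential(0.002, 301)
        ev = _events(np.arange(301) % 2, durs)
        once = impose_dead_time(ev, 0.0005)
        twice = impose_dead_time(once, 0.0005)
        assert np.array_equal(once.class_codes, twice.class_codes)
        assert np.array_equal(once.durations, twice.durations)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-5, max_value=0.05), min_size=3, max_size=60),
        st.floats(min_value=1e-5, max_value=5e-3),
        st.booleans(),
    )
    def test_total_duration_conserved(self, durs, td, start_open):
        codes, secs = _fixed_dwells(np.asarray(durs) * 1e3, start_open)
        ev = _events(codes, secs)
        if td > ev.total_time:
            return
        try:
            out = impose_dead_time(ev, td)
        except ValueError:
            return  # dead time consumed the whole record
        assert abs(out.total_time - ev.total_time) < 1e-12
        assert np.all(out.durations >= td)
        assert np.all(out.class_codes[1:] != out.class_codes[:-1])

    def test_dead_time_longer_than_record_rejected(self):
        ev = _events([0, 1], [0.001, 0.001])
        with pytest.raises(ValueError):
            impose_dead_time(ev, 1.0)


class TestSegmentClusters:
    def test_all_short_closings_give_one_cluster(self):
        ev = _events([0, 1, 0, 1, 0], [0.001] * 5)
        assert segment_clusters(ev, tau_crit=0.01) == [(0, 5)]

    def test_tiny_tau_crit_isolates_each_opening(self):
        ev = _events([0, 1, 0, 1, 0, 1], [0.002] * 6)
        clusters = segment_clusters(ev, tau_crit=1e-9)
        n_open = int((ev.class_codes == 1).sum())
        assert len(clusters) == n_open

    def test_cluster_count_recovered_on_separated_scheme(self):
        s = KineticScheme(
            ["C", "O", "D1"],
            {"C": CLOSED, "O": OPEN, "D1": CLOSED},
            [
                Edge("C", "O", RateLaw(1000.0), "opening"),
                Edge("O", "C", RateLaw(300.0), "closing"),
                Edge("O", "D1", RateLaw(60.0), "d_on"),
                Edge("D1", "O", RateLaw(0.5), "d_off"),  # 2 s desensitized
            ],
        )
        d = simulate_dwells(s, Conditions(), n_events=30_000, seed=17)
        true_clusters = d.cluster_ids.max() + 1
        codes, durs = d.class_dwells()
        ev = _events(codes, durs)
        found = len(segment_clusters(ev, tau_crit=0.03))
        assert abs(found - true_clusters) / true_clusters < 0.05


class TestCriticalTime:
    def test_equal_misclassification_at_solution(self):
        tc = critical_time(0.001, 0.7, 0.5, 0.3)
        lhs = 0.7 * np.exp(-tc / 0.001)
        rhs = 0.3 * (1 - np.exp(-tc / 0.5))
        assert lhs == pytest.approx(rhs, rel=1e-8)
        assert 0.001 < tc < 0.5
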