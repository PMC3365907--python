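"""Spike detection, burst partitioning, metrics and classification."""

import dataclasses

import numpy as np
import pytest

from conftest import gaussian_bumps, make_trajectory_from_function
from hrsweep.metrics import (
    BURST_CHAOTIC,
    BURST_REGULAR,
    DEFAULT_CRITERIA,
    PLATEAU,
    QUIESCENCE,
    SQUARE_WAVE,
    TONIC,
    Burst,
    BurstPartition,
    ClassificationCriteria,
    analyze_trajectory,
    classify_activity,
    classify_burst_topology,
    compute_metrics,
    detect_spikes,
    distinct_isi_count,
    isi_bifurcation_record,
    partition_bursts,
)


def analyze_constructed(f, t0, t1, criteria=DEFAULT_CRITERIA, nseg=600):
    traj = make_trajectory_from_function(f, t0, t1, nseg=nseg)
    spikes = detect_spikes(traj, (t0, t1), criteria)
    part = partition_bursts(spikes, traj, criteria)
    return traj, spikes, part


class TestDetectSpikes:
    def test_tall_maxima_counted_short_ones_not(self):
        """Six injected maxima above threshold and three below give six spikes."""
        tall = [8, 11, 14, 17, 20, 23]
        short = [27, 30, 33]
        f = gaussian_bumps(tall + short, [3.0] * 6 + [0.5] * 3)
        _traj, spikes, _ = analyze_constructed(f, 0.0, 40.0)
        assert len(spikes) == 6
        assert np.allclose(np.sort(spikes.times), tall, atol=0.02)
        assert len(spikes.all_max_times) == 9

    def test_flat_trace_has_no_spikes(self):
        f = lambda t: -1.5 + 1e-6 * np.sin(0.1 * np.asarray(t))
        _traj, spikes, _ = analyze_constructed(f, 0.0, 40.0)
        assert len(spikes) == 0

    def test_empty_window(self, square_wave_traj):
        traj, _p, (t_lo, _) = square_wave_traj
        spikes = detect_spikes(traj, (t_lo, t_lo))
        assert len(spikes) == 0

    def test_spike_count_independent_of_sampling(self, square_wave_traj):
        """Events come from root-finding, so SC never depends on sampling."""
        traj, _p, (t_lo, t_hi) = square_wave_traj
        s = detect_spikes(traj, (t_lo, t_hi))
        assert len(s) > 0  # ...and there is no sampling knob to change


class TestPartitionBursts:
    def test_two_bursts_of_four(self):
        """Spike gaps [1,1,1,20,1,1,1] with matching dwells give 2x4 spikes."""
        spikes1 = [8, 9, 10, 11]
        spikes2 = [31, 32, 33, 34]
        f = gaussian_bumps(spikes1 + spikes2, [3.0] * 8)
        _traj, _spikes, part = analyze_constructed(f, 0.0, 42.0)
        assert part.n_bursts == 2
        assert [b.n_spikes for b in part.bursts] == [4, 4]
        assert part.bursts[0].t_next_on == pytest.approx(part.bursts[1].t_on)
        assert not part.tonic

    def test_no_dwell_marks_tonic(self):
        """A trace never dwelling below theta_q is a single tonic train."""
        f = gaussian_bumps(np.arange(5, 40, 3), [2.0] * 12, width=0.8, baseline=0.5)
        _traj, spikes, part = analyze_constructed(f, 0.0, 42.0)
        assert part.tonic
        assert part.n_bursts == 1

    def test_growing_terminal_isi_is_not_split(self, square_wave_traj):
        """Square-wave bursts keep their slow terminal spikes in one burst."""
        traj, _p, window = square_wave_traj
        spikes = detect_spikes(traj, window)
        part = partition_bursts(spikes, traj)
        assert part.n_bursts >= 5
        sn = [b.n_spikes for b in part.bursts]
        assert len(set(sn)) == 1  # no burst lost a terminal spike to a split


class TestComputeMetrics:
    def _partition_from_bursts(self, bursts):
        e = np.empty(0)
        spikes_t = np.concatenate([b.spike_times for b in bursts])
        from hrsweep.metrics import SpikeTrain

        train = SpikeTrain(
            spikes_t, np.ones_like(spikes_t), 0.0, -1.0, 1.0, (0.0, 100.0), spikes_t, np.ones_like(spikes_t)
        )
        return BurstPartition(tuple(bursts), False, (0.0, 100.0), -0.8, train, 0)

    def test_duty_cycle_arithmetic(self):
        """Duration 8 over period 28 gives DC = 2/7."""
        b1 = Burst(np.array([1.0, 3.0, 5.0]), np.ones(3), 0.0, 8.0, 28.0)
        b2 = Burst(np.array([29.0, 31.0, 33.0]), np.ones(3), 28.0, 36.0, None)
        m = compute_metrics(self._partition_from_bursts([b1, b2]))
        assert m.dc == pytest.approx(2.0 / 7.0)
        assert m.dc is not None and 0 <= m.dc <= 1

    def test_uniform_sn_has_zero_deviation(self):
        bursts = [
            Burst(np.arange(6) + 30.0 * k, np.ones(6), 30.0 * k, 30.0 * k + 6, 30.0 * (k + 1))
            for k in range(3)
        ]
        bursts[-1] = dataclasses.replace(bursts[-1], t_next_on=None)
        m = compute_metrics(self._partition_from_bursts(bursts))
        assert list(m.sn) == [6, 6, 6]
        assert m.sn_deviation == 0

    def test_single_burst_is_insufficient(self):
        b = Burst(np.array([1.0, 2.0]), np.ones(2), 0.0, 3.0, None)
        m = compute_metrics(self._partition_from_bursts([b]))
        assert m.insufficient
        assert m.dc is None


class TestDistinctIsi:
    def test_exact_duplicates_collapse(self):
        assert distinct_isi_count(np.array([1.0, 1.0, 1.0, 2.0]), 1e-3) == 2

    def test_tolerance_merges_near_values(self):
        # classes: {1.0, 1.0005}, {2.0, 2.001}, {3.0}
        isis = np.array([1.0, 1.0005, 2.0, 2.001, 3.0])
        assert distinct_isi_count(isis, 1e-3) == 3
        # merging is against the class representative, not the neighbor
        assert distinct_isi_count(np.array([1.0, 1.0009, 1.002]), 1e-3) == 2

    def test_empty(self):
        assert distinct_isi_count(np.empty(0), 1e-3) == 0


class TestClassification:
    def test_quiescence_when_no_spikes(self):
        f = lambda t: -1.5 + 0.001 * np.exp(-np.asarray(t) / 5.0)
        traj, spikes, part = analyze_constructed(f, 0.0, 40.0)
        m = compute_metrics(part)
        assert classify_activity(m).primary == QUIESCENCE

    def test_regular_bursting(self, square_wave_traj):
        traj, _p, window = square_wave_traj
        rec = analyze_trajectory(traj, window)
        assert rec.activity.primary == BURST_REGULAR
        assert rec.metrics.sn_deviation == 0
        assert 0 <= rec.metrics.dc <= 1

    def test_tonic_single_spike_trains(self):
        """One spike per dwell-separated train classifies as tonic spiking."""
        f = gaussian_bumps(np.arange(10, 90, 10), [3.0] * 8)
        _traj, _s, part = analyze_constructed(f, 0.0, 95.0, nseg=1200)
        m = compute_metrics(part)
        assert classify_activity(m).primary == TONIC

    def test_chaotic_by_distinct_isis(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.uniform(3.0, 9.0, 30)) + 8.0
        f = gaussian_bumps(times, [3.0] * 30)
        _traj, _s, part = analyze_constructed(f, 0.0, float(times[-1] + 10), nseg=2500)
        m = compute_metrics(part)
        assert m.n_distinct_isi > DEFAULT_CRITERIA.chaos_spike_limit
        assert classify_activity(m).primary == BURST_CHAOTIC


class TestTopology:
    def test_square_wave_preset(self, square_wave_traj):
        traj, _p, window = square_wave_traj
        rec = analyze_trajectory(traj, window)
        assert rec.activity.topology == SQUARE_WAVE

    def test_plateau_preset(self, plateau_traj):
        traj, _p, window = plateau_traj
        rec = analyze_trajectory(traj, window)
        assert rec.activity.topology == PLATEAU

    def test_constructed_growing_terminal_isis(self):
        """Constant amplitudes with geometrically growing ISIs: square wave."""
        isis = 2.0 * 1.25 ** np.arange(6)
        spikes = 8.0 + np.concatenate([[0.0], np.cumsum(isis)])
        centers = np.concatenate([spikes, spikes + 40.0])
        f = gaussian_bumps(centers, [3.0] * len(centers))
        traj, s, part = analyze_constructed(f, 0.0, 90.0, nseg=1500)
        assert part.n_bursts >= 1
        assert classify_burst_topology(part, traj) == SQUARE_WAVE

    def test_square_wave_terminal_isi_is_maximal(self, square_wave_traj):
        """The defining signature: last ISI of each burst is its largest."""
        traj, _p, window = square_wave_traj
        rec = analyze_trajectory(traj, window)
        for isis in rec.metrics.isis_per_burst:
            if len(isis) >= 2:
                assert isis[-1] == pytest.approx(np.max(isis))


class TestIsiRecord:
    def test_regular_burster_isi_multiset(self, square_wave_traj):
        """A regular n-spike burster shows at most n distinct ISIs."""
        traj, _p, window = square_wave_traj
        rec = analyze_trajectory(traj, window)
        isis = isi_bifurcation_record(rec.metrics)
        n = int(rec.metrics.sn[0])
        assert len(isis) == rec.metrics.n_spikes - 1
        assert rec.metrics.n_distinct_isi <= n

    def test_tonic_single_isi(self):
        f = gaussian_bumps(np.arange(10, 90, 10), [3.0] * 8)
        _traj, _s, part = analyze_constructed(f, 0.0, 95.0, nseg=1200)
        m = compute_metrics(part)
        assert m.n_distinct_isi == 1


class TestCriteriaValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ClassificationCriteria(spike_fraction=1.5)
        with pytest.raises(ValueError):
            ClassificationCriteria(chaos_spike_limit=0)
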