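"""Binning conventions, normalization, latency rule, population average."""

import numpy as np
import pytest

from rmtg_valence import psth, qc, synthetic_data as sd
from rmtg_valence.psth import EventSchedule, NormalizedPsth

from conftest import constructed_train


def single_event_schedule(label="reward_cue", onset=10.0, duration=2.0):
    return EventSchedule(((label, onset, duration),))


class TestAlignAndBin:
    def test_edge_spike_goes_to_right_bin(self):
        """A spike exactly on a bin edge belongs to the bin starting there."""
        schedule = single_event_schedule()
        train = constructed_train([10.050], span=(0.0, 20.0))
        matrix = psth.align_and_bin(train, schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        hit = np.flatnonzero(matrix.counts[0])
        assert matrix.bin_edges[hit[0]] == pytest.approx(0.050)

    def test_mean_count_matches_rate(self, reward_schedule):
        config = sd.UnitGenConfig("u0", 20.0)
        train = sd.generate_spike_train(config, reward_schedule, 250.0, seed=2)
        matrix = psth.align_and_bin(train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        mean = matrix.counts.mean()
        se = matrix.counts.std(ddof=1) / np.sqrt(matrix.counts.size)
        assert abs(mean - 1.0) < 3 * se + 0.05

    def test_suppressed_bins_empty(self):
        schedule = psth.make_schedule([("footshock", 30, 0.01)], interval=3.0,
                                      start=2.0)
        kernel = sd.ResponseKernel("footshock", 0.0, 0.1, 0.0)
        config = sd.UnitGenConfig("u0", 30.0, kernels=(kernel,))
        train = sd.generate_spike_train(config, schedule, schedule.end + 5,
                                        seed=0)
        matrix = psth.align_and_bin(train, schedule, "footshock",
                                    window=(0.5, 0.5), bin_width=0.05)
        sel = (matrix.bin_edges[:-1] >= 0.0) & (matrix.bin_edges[:-1] < 0.1)
        assert matrix.counts[:, sel].sum() == 0

    def test_missing_label_rejected(self, reward_schedule, null_train):
        with pytest.raises(ValueError, match="no events"):
            psth.align_and_bin(null_train, reward_schedule, "siren",
                               window=(1.0, 0.6))

    def test_count_conservation_with_blanking(self):
        """Bin counts + spikes inside the excluded mask = aligned spikes."""
        schedule = single_event_schedule("footshock", onset=10.0, duration=0.01)
        raw = constructed_train([9.5, 10.002, 10.004, 10.02, 10.4],
                                span=(0.0, 20.0))
        blanked = qc.blank_shock_artifact(raw, [10.0])
        matrix = psth.align_and_bin(blanked, schedule, "footshock",
                                    window=(1.0, 0.5), bin_width=0.05)
        in_window = np.sum((raw.spike_times >= 9.0) & (raw.spike_times < 10.5))
        removed = np.sum((raw.spike_times >= 10.0) & (raw.spike_times < 10.01))
        assert matrix.counts.sum() + removed == in_window
        assert matrix.excluded.sum() == pytest.approx(0.01)

    def test_sustained_binning_same_code_path(self):
        """Minutes-scale analysis reuses align_and_bin with 5 min bins."""
        schedule = single_event_schedule("licl", onset=900.0, duration=600.0)
        config = sd.UnitGenConfig("u0", 5.0)
        train = sd.generate_spike_train(config, schedule, 2700.0, seed=1)
        matrix = psth.align_and_bin(train, schedule, "licl",
                                    window=(900.0, 1800.0), bin_width=300.0)
        assert matrix.counts.shape == (1, 9)
        rate = matrix.counts.sum() / 2700.0
        assert rate == pytest.approx(5.0, rel=0.15)


class TestNormalize:
    def test_centering_under_null(self, null_train, reward_schedule):
        matrix = psth.align_and_bin(null_train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        z = psth.normalize(matrix)
        assert abs(z.normalized_rate[z.bin_centers < 0].mean()) < 0.3

    def test_kernel_bins_positive(self, reward_schedule):
        kernel = sd.ResponseKernel("reward_cue", 0.0, 0.2, 3.0)
        config = sd.UnitGenConfig("u0", 10.0, kernels=(kernel,))
        train = sd.generate_spike_train(config, reward_schedule, 250.0, seed=0)
        matrix = psth.align_and_bin(train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        z = psth.normalize(matrix)
        sel = (z.bin_centers > 0) & (z.bin_centers < 0.2)
        assert np.all(z.normalized_rate[sel] > 0)

    def test_silent_unit_flagged(self, reward_schedule):
        train = constructed_train([], span=(0.0, 250.0), unit_id="silent")
        matrix = psth.align_and_bin(train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        z = psth.normalize(matrix)
        assert np.all(z.normalized_rate == 0.0)
        assert "silent_unit" in z.flags and "zero_baseline" in z.flags

    def test_fold_dialect(self, null_train, reward_schedule):
        matrix = psth.align_and_bin(null_train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        fold = psth.normalize(matrix, method="fold")
        assert fold.normalization_method == "fold"
        assert abs(fold.normalized_rate[fold.bin_centers < 0].mean() - 1.0) < 0.1


class TestLatency:
    def make_psth(self, values, width=0.05):
        values = np.asarray(values, dtype=float)
        centers = width / 2 + width * np.arange(values.size)
        return NormalizedPsth(unit_id="u", stimulus="s", bin_centers=centers,
                              normalized_rate=values, baseline_mean=10.0,
                              baseline_sd=1.0)

    def test_first_attainment_of_peak(self):
        p = self.make_psth([0, 2, 5, 5, 1])
        lat, ambiguous = psth.latency_to_extreme(p, (0.0, 0.25), "excited")
        assert lat == pytest.approx(0.10)
        assert not ambiguous

    def test_monotone_decreasing_trough_is_last_bin(self):
        p = self.make_psth([5, 4, 3, 2, 1])
        lat, _ = psth.latency_to_extreme(p, (0.0, 0.25), "inhibited")
        assert lat == pytest.approx(0.20)

    def test_flat_trace_flagged(self):
        p = self.make_psth([1, 1, 1, 1])
        lat, ambiguous = psth.latency_to_extreme(p, (0.0, 0.2), "excited")
        assert lat == pytest.approx(0.0)
        assert ambiguous

    def test_planted_latency_recovered(self):
        schedule = psth.make_schedule([("siren", 60, 1.0)], interval=3.0,
                                      start=2.0)
        kernel = sd.ResponseKernel("siren", 0.10, 0.1, 20.0)
        config = sd.UnitGenConfig("u0", 10.0, kernels=(kernel,))
        train = sd.generate_spike_train(config, schedule, schedule.end + 5,
                                        seed=0)
        matrix = psth.align_and_bin(train, schedule, "siren",
                                    window=(1.0, 0.6), bin_width=0.05)
        z = psth.normalize(matrix)
        lat, _ = psth.latency_to_extreme(z, (0.0, 0.6), "excited")
        assert lat == pytest.approx(0.10, abs=0.051)


class TestPopulationAverage:
    def test_single_psth_is_identity(self):
        p = TestLatency().make_psth([0, 1, 2])
        centers, mean, sem, n = psth.population_average([p])
        np.testing.assert_allclose(mean, p.normalized_rate)
        assert n == 1 and np.all(np.isnan(sem))

    def test_opposite_traces_cancel(self):
        a = TestLatency().make_psth([1, -2, 3])
        b = TestLatency().make_psth([-1, 2, -3])
        _, mean, _, _ = psth.population_average([a, b])
        np.testing.assert_allclose(mean, 0.0)

    def test_mixed_bins_rejected(self):
        a = TestLatency().make_psth([1, 2, 3])
        b = TestLatency().make_psth([1, 2, 3, 4])
        with pytest.raises(ValueError, match="bin structures"):
            psth.population_average([a, b])
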