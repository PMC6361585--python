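"""Generator contracts: rates, determinism, planted truth, defects."""

import numpy as np
import pytest

from rmtg_valence import psth, synthetic_data as sd
from rmtg_valence.psth import EventSchedule

from conftest import poisson_train

DEAD = sd.DEAD_TIME_S


def effective_rate(rate):
    # an absolute dead time tau thins a Poisson process to rate/(1+rate*tau)
    return rate / (1.0 + rate * DEAD)


class TestSpikeGeneration:
    def test_poisson_mean_count(self):
        """Baseline 10 Hz, 100 s: mean count over seeds sits in the Poisson
        99% band around 1000 (dead-time thinning costs ~1.5%)."""
        counts = [poisson_train(10.0, 100.0, seed=s).n_spikes
                  for s in range(100)]
        band = 2.576 * np.sqrt(1000.0)
        assert 1000.0 - band < np.mean(counts) < 1000.0 + band
        assert abs(np.mean(counts) - effective_rate(10.0) * 100.0) \
            < 3.0 * np.sqrt(1000.0 / 100)

    def test_full_suppression_kernel(self):
        """Gain-0 kernel silences every one of its 50 windows."""
        schedule = psth.make_schedule([("footshock", 50, 0.01)], interval=3.0,
                                      start=2.0)
        kernel = sd.ResponseKernel("footshock", 0.0, 1.0, 0.0)
        config = sd.UnitGenConfig("u0", 20.0, kernels=(kernel,))
        train = sd.generate_spike_train(config, schedule, schedule.end + 5,
                                        seed=7)
        for onset in schedule.onsets("footshock"):
            inside = (train.spike_times >= onset) & (train.spike_times < onset + 1)
            assert inside.sum() == 0

    def test_excitation_kernel_rate(self):
        """Gain-3 kernel triples the in-window PSTH rate (within 3 SE)."""
        schedule = psth.make_schedule([("footshock", 50, 0.01)], interval=3.0,
                                      start=2.0)
        kernel = sd.ResponseKernel("footshock", 0.01, 0.1, 3.0)
        config = sd.UnitGenConfig("u0", 10.0, kernels=(kernel,))
        counts = []
        for seed in range(30):
            train = sd.generate_spike_train(config, schedule, schedule.end + 5,
                                            seed=seed)
            for onset in schedule.onsets("footshock"):
                lo, hi = onset + 0.01, onset + 0.11
                counts.append(np.searchsorted(train.spike_times, hi)
                              - np.searchsorted(train.spike_times, lo))
        rate = np.mean(counts) / 0.1
        se = np.std(counts, ddof=1) / 0.1 / np.sqrt(len(counts))
        assert abs(rate - 30.0) < 3.0 * se + (30.0 - effective_rate(30.0))

    def test_determinism(self, reward_schedule):
        config = sd.make_archetype("valence_encoding", "u0")
        a = sd.generate_spike_train(config, reward_schedule, 250.0, seed=5)
        b = sd.generate_spike_train(config, reward_schedule, 250.0, seed=5)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_rejects_bad_inputs(self, reward_schedule):
        config = sd.UnitGenConfig("u0", 10.0)
        with pytest.raises(ValueError, match="session length"):
            sd.generate_spike_train(config, reward_schedule, -1.0, seed=0)
        with pytest.raises(ValueError, match="baseline rate"):
            sd.UnitGenConfig("u0", 0.0)
        with pytest.raises(ValueError, match="gain"):
            sd.ResponseKernel("footshock", 0.0, 0.1, -1.0)
        with pytest.raises(ValueError, match="overlap"):
            sd.ResponseKernel("footshock", 0.0, 0.2, 2.0,
                              second_phase=(0.1, 0.1, 0.5))

    def test_rate_conservation_across_windows(self):
        """Empirical rate tracks the configured rate function (100 seeds)."""
        schedule = EventSchedule((("siren", 10.0, 1.0),))
        kernel = sd.ResponseKernel("siren", 0.0, 1.0, 2.0)
        config = sd.UnitGenConfig("u0", 8.0, kernels=(kernel,))
        in_win, out_win = [], []
        for seed in range(100):
            t = sd.generate_spike_train(config, schedule, 30.0, seed=seed)
            in_win.append(np.sum((t.spike_times >= 10) & (t.spike_times < 11)))
            out_win.append(np.sum(t.spike_times < 10) / 10.0)
        for observed, expected in ((np.mean(in_win), effective_rate(16.0)),
                                   (np.mean(out_win), effective_rate(8.0))):
            se = np.sqrt(expected / 100 / (1 if expected > 10 else 10))
            assert abs(observed - expected) < 4.0 * np.sqrt(expected / 100) + 0.3


class TestPopulation:
    def test_planted_proportions_echo_spec(self, reward_schedule):
        spec = [(sd.make_archetype("valence_encoding", "val"), 4),
                (sd.make_archetype("unresponsive", "bg"), 6)]
        trains, truth = sd.generate_population(spec, reward_schedule, 250.0,
                                               seed=0)
        assert len(trains) == 10
        assert len(truth.units) == 10              # truth completeness
        assert truth.fraction(lambda u: u.valence_encoding) == 0.4

    def test_empty_spec(self, reward_schedule):
        trains, truth = sd.generate_population([], reward_schedule, 250.0,
                                               seed=0)
        assert trains == [] and truth.units == {}

    def test_biphasic_truth(self):
        schedule = EventSchedule((("licl", 900.0, 600.0),))
        spec = [(sd.make_archetype("licl_biphasic", "b"), 3)]
        _, truth = sd.generate_population(spec, schedule, 2800.0, seed=1)
        assert all(u.categories["licl"] == "biphasic"
                   for u in truth.units.values())

    def test_duplicate_ids_rejected(self, reward_schedule):
        spec = [(sd.make_archetype("unresponsive", "u"), 1),
                (sd.make_archetype("unresponsive", "u"), 1)]
        with pytest.raises(ValueError, match="duplicate"):
            sd.generate_population(spec, reward_schedule, 250.0, seed=0)


class TestDefects:
    def test_injected_refractory_violations(self, reward_schedule):
        from rmtg_valence.qc import refractory_violation_fraction

        config = sd.UnitGenConfig(
            "u0", 10.0, defects=sd.Defects(refractory_violation_fraction=0.01))
        train = sd.generate_spike_train(config, reward_schedule, 250.0, seed=3)
        frac = refractory_violation_fraction(train)
        assert 0.005 < frac < 0.015

    def test_drift_slope_changes_rate(self):
        schedule = EventSchedule(())
        config = sd.UnitGenConfig("u0", 10.0,
                                  defects=sd.Defects(drift_slope=-0.5))
        train = sd.generate_spike_train(config, schedule, 1200.0, seed=3)
        early = np.sum(train.spike_times < 300) / 300.0
        late = np.sum(train.spike_times >= 900) / 300.0
        assert early - late > 4.0   # expect ~7.5 Hz drop over 15-20 min

    def test_artifact_spikes_at_onsets(self):
        schedule = psth.make_schedule([("footshock", 20, 0.01)], interval=3.0,
                                      start=2.0)
        config = sd.UnitGenConfig(
            "u0", 1.0, defects=sd.Defects(artifact_labels=("footshock",)))
        train = sd.generate_spike_train(config, schedule, schedule.end + 5,
                                        seed=3)
        for onset in schedule.onsets("footshock"):
            assert np.any(np.isclose(train.spike_times, onset + 0.001))


class TestCalcium:
    def test_silent_noiseless_trace_is_zero(self):
        schedule = EventSchedule(())
        spec = [(sd.UnitGenConfig("c0", 1e-9 + 0.001), 1)]
        # a practically silent unit: expect no spikes in 10 s at 0.001 Hz
        traces, _ = sd.generate_calcium_traces(spec, schedule, 10.0,
                                               noise_sd=0.0, seed=0)
        assert np.allclose(traces[0].dF_F, 0.0)

    def test_kernel_peak_follows_spike(self):
        kernel = sd.calcium_kernel(frame_rate=20.0)
        assert kernel[0] < kernel.max()
        assert np.argmax(kernel) > 0
        assert np.isclose(kernel.max(), 0.2)

    def test_planted_shock_transient_detectable(self):
        schedule = psth.make_schedule([("footshock", 30, 0.01)], interval=30.0,
                                      start=15.0)
        kernel = sd.ResponseKernel("footshock", 0.0, 0.5, 8.0)
        spec = [(sd.UnitGenConfig("c0", 5.0, kernels=(kernel,)), 1)]
        traces, _ = sd.generate_calcium_traces(spec, schedule,
                                               schedule.end + 15.0,
                                               noise_sd=0.02, seed=4)
        trace = traces[0]
        t = np.arange(trace.dF_F.size) / trace.sample_rate
        post = []
        for onset in schedule.onsets("footshock"):
            post.append(trace.dF_F[(t >= onset) & (t < onset + 2)].mean()
                        - trace.dF_F[(t >= onset - 5) & (t < onset)].mean())
        post = np.array(post)
        assert post.mean() > 3.0 * post.std(ddof=1) / np.sqrt(post.size)

    def test_negative_noise_rejected(self, reward_schedule):
        with pytest.raises(ValueError, match="noise"):
            sd.generate_calcium_traces([(sd.UnitGenConfig("c", 5.0), 1)],
                                       reward_schedule, 250.0, noise_sd=-1.0)


class TestCppGenerator:
    def test_partition_is_exact(self):
        session = sd.generate_cpp_session(0.5, 20.0, 900.0, seed=0)
        total = sum(e - s for _, s, e in session.occupancy)
        assert total == pytest.approx(900.0, abs=1e-9)
        assert session.occupancy[0][1] == 0.0
        assert session.occupancy[-1][2] == 900.0

    def test_bias_governs_entry_fractions(self):
        paired = unpaired = 0
        for seed in range(40):
            session = sd.generate_cpp_session(0.2, 5.0, 1000.0, seed=seed)
            chambers = [c for c, _, _ in session.occupancy]
            paired += chambers.count("paired")
            unpaired += chambers.count("unpaired")
        frac = paired / (paired + unpaired)
        n = paired + unpaired
        assert abs(frac - 0.2) < 2.58 * np.sqrt(0.2 * 0.8 / n) + 0.01

    def test_symmetric_bias_balances(self):
        diffs = []
        for seed in range(200):
            session = sd.generate_cpp_session(0.5, 10.0, 900.0, seed=seed)
            chambers = [c for c, _, _ in session.occupancy]
            diffs.append(chambers.count("paired") - chambers.count("unpaired"))
        assert abs(np.mean(diffs)) < 3.0 * np.std(diffs) / np.sqrt(len(diffs))

    def test_invalid_bias_rejected(self):
        with pytest.raises(ValueError, match="bias"):
            sd.generate_cpp_session(1.0, 20.0, 900.0, seed=0)
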