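"""Window significance testing and the derived per-neuron classifiers."""

import numpy as np
import pytest

from rmtg_valence import psth, response_stats as rs, synthetic_data as sd
from rmtg_valence.psth import EventSchedule

from conftest import session_length


def matrix_for(config, schedule, label, seed, window=(1.0, 2.0)):
    train = sd.generate_spike_train(config, schedule, session_length(schedule),
                                    seed=seed)
    return psth.align_and_bin(train, schedule, label, window=window,
                              bin_width=0.05)


class TestWindowResponseTest:
    def test_identical_windows_not_significant(self, null_train,
                                               reward_schedule):
        matrix = psth.align_and_bin(null_train, reward_schedule, "reward_cue",
                                    window=(1.0, 0.6), bin_width=0.05)
        profile = rs.window_response_test(matrix, (0.1, 0.3),
                                          baseline_window=(0.1, 0.3))
        assert profile.p_value == 1.0
        assert profile.direction == "none"

    def test_needs_six_trials(self, reward_schedule):
        config = sd.UnitGenConfig("u0", 10.0)
        short = EventSchedule(tuple(reward_schedule.events[:5]))
        matrix = matrix_for(config, short, "reward_cue", seed=0,
                            window=(1.0, 0.6))
        with pytest.raises(ValueError, match="6 trials"):
            rs.window_response_test(matrix, (0.0, 0.1))

    def test_planted_excitation_detected(self, reward_schedule):
        kernel = sd.ResponseKernel("reward_cue", 0.0, 0.1, 3.0)
        config = sd.UnitGenConfig("u0", 10.0, kernels=(kernel,))
        hits = 0
        for seed in range(20):
            matrix = matrix_for(config, reward_schedule, "reward_cue",
                                seed=seed, window=(1.0, 0.6))
            profile = rs.window_response_test(matrix, (0.0, 0.1))
            hits += profile.direction == "excited"
        assert hits >= 18             # >= 90% sensitivity at gain 3

    def test_planted_inhibition_detected(self, reward_schedule):
        kernel = sd.ResponseKernel("reward_cue", 0.2, 0.2, 0.2)
        config = sd.UnitGenConfig("u0", 10.0, kernels=(kernel,))
        hits = 0
        for seed in range(20):
            matrix = matrix_for(config, reward_schedule, "reward_cue",
                                seed=seed, window=(1.0, 0.6))
            profile = rs.window_response_test(matrix, (0.2, 0.4))
            hits += profile.direction == "inhibited"
        assert hits >= 18

    def test_direction_matches_magnitude_sign(self, phasic_schedule):
        """sign(magnitude) == direction for every responsive unit."""
        spec = [(sd.make_archetype("valence_encoding", "v"), 10),
                (sd.make_archetype("unresponsive", "n"), 5)]
        trains, _ = sd.generate_population(spec, phasic_schedule,
                                           session_length(phasic_schedule),
                                           seed=21)
        for train in trains:
            for stim, window in (("reward_cue", (0.2, 0.4)),
                                 ("footshock", (0.0, 0.1))):
                matrix = psth.align_and_bin(train, phasic_schedule, stim,
                                            window=(1.0, 0.6), bin_width=0.05)
                p = rs.window_response_test(matrix, window)
                if p.direction == "excited":
                    assert p.magnitude > 0
                elif p.direction == "inhibited":
                    assert p.magnitude < 0

    def test_window_disjointness(self):
        """Reward (200-400 ms) and aversive (0-100 ms) windows touch
        disjoint bins of a shared matrix."""
        edges = -1.0 + 0.05 * np.arange(33)
        left = edges[:-1]
        reward = (left >= 0.2) & (left < 0.4)
        aversive = (left >= 0.0) & (left < 0.1)
        assert not np.any(reward & aversive)


class TestRmtgClassifier:
    def test_planted_valence_unit(self, phasic_schedule):
        config = sd.make_archetype("valence_encoding", "v0")
        profiles = {}
        for stim, window in (("reward_cue", rs.REWARD_CUE_WINDOW),
                             ("footshock", rs.AVERSIVE_WINDOW)):
            matrix = matrix_for(config, phasic_schedule, stim, seed=3,
                                window=(1.0, 0.6))
            profiles[stim] = rs.window_response_test(matrix, window)
        label = rs.classify_rmtg_profile(profiles)
        assert label.valence_encoding

    def test_unresponsive_unit(self, phasic_schedule):
        config = sd.make_archetype("unresponsive", "n0")
        profiles = {}
        for stim, window in (("reward_cue", rs.REWARD_CUE_WINDOW),
                             ("footshock", rs.AVERSIVE_WINDOW)):
            matrix = matrix_for(config, phasic_schedule, stim, seed=5,
                                window=(1.0, 0.6))
            profiles[stim] = rs.window_response_test(matrix, window)
        label = rs.classify_rmtg_profile(profiles)
        assert not label.valence_encoding
        assert label.withheld_reason is None

    def test_missing_stimulus_withheld(self):
        label = rs.classify_rmtg_profile({})
        assert label.withheld_reason is not None

    def test_proportion_arithmetic(self):
        """22 inhibited of 30 responsive = 73%."""
        tally = {"excited": 8, "inhibited": 22, "none": 29}
        responsive = tally["excited"] + tally["inhibited"]
        assert round(100 * tally["inhibited"] / responsive) == 73


class TestVtaCellTyping:
    @pytest.mark.parametrize("archetype,expected", [
        ("pda_delayed_inhibition", "pDA"),
        ("ramping", "ramping"),
        ("reward_inhibited", "reward_inhibited"),
        ("unresponsive", "unclassified"),
    ])
    def test_archetype_recovery(self, reward_schedule, archetype, expected):
        config = sd.make_archetype(archetype, "u0")
        hits = 0
        for seed in range(10):
            matrix = matrix_for(config, reward_schedule, "reward_cue",
                                seed=seed)
            hits += rs.classify_vta_cell_type(matrix).label == expected
        assert hits >= (9 if expected != "unclassified" else 8)

    def test_precedence_pda_over_ramping(self, reward_schedule):
        """A unit significant in both windows is typed pDA."""
        kernels = (sd.ResponseKernel("reward_cue", 0.0, 2.0, 3.0),)
        config = sd.UnitGenConfig("u0", 10.0, kernels=kernels)
        matrix = matrix_for(config, reward_schedule, "reward_cue", seed=1)
        assert rs.classify_vta_cell_type(matrix).label == "pDA"


class TestAversiveInhibitionTyping:
    def make_matrix(self, archetype, seed):
        schedule = psth.make_schedule([("footshock", 50, 0.01)], interval=4.0,
                                      start=2.0)
        config = sd.make_archetype(archetype, "u0")
        return matrix_for(config, schedule, "footshock", seed=seed,
                          window=(1.0, 0.6))

    @pytest.mark.parametrize("archetype,expected", [
        ("pda_delayed_inhibition", "delayed_inhibition"),
        ("pda_immediate_inhibition", "immediate_inhibition"),
        ("pda_excitation_only", "excitation_only"),
    ])
    def test_archetype_recovery(self, archetype, expected):
        hits = sum(rs.classify_aversive_inhibition_type(
            self.make_matrix(archetype, seed)) == expected
            for seed in range(10))
        assert hits >= 9

    def test_null_mostly_none(self):
        hits = sum(rs.classify_aversive_inhibition_type(
            self.make_matrix("unresponsive", seed)) == "none"
            for seed in range(10))
        assert hits >= 8


class TestSustainedClassifier:
    def sustained_matrix(self, archetype, stimulus, seed):
        onset = 900.0
        schedule = EventSchedule(((stimulus, onset, 600.0),))
        config = sd.make_archetype(archetype, "u0")
        train = sd.generate_spike_train(config, schedule, onset + 1860.0,
                                        seed=seed)
        return psth.align_and_bin(train, schedule, stimulus,
                                  window=(onset, 1860.0), bin_width=60.0)

    def test_biphasic_recovery(self):
        hits = 0
        for seed in range(10):
            matrix = self.sustained_matrix("licl_biphasic", "licl", seed)
            result = rs.classify_sustained_response(matrix, "licl")
            hits += result.pattern == "biphasic"
        assert hits >= 9

    def test_opponent_directions(self):
        matrix = self.sustained_matrix("cocaine_biphasic", "cocaine", 2)
        result = rs.classify_sustained_response(matrix, "cocaine")
        assert result.initial.direction == "inhibited"
        assert result.rebound.direction == "excited"

    def test_saline_mostly_none(self):
        hits = 0
        for seed in range(10):
            matrix = self.sustained_matrix("saline", "licl", seed)
            result = rs.classify_sustained_response(matrix, "licl")
            hits += result.pattern == "none"
        assert hits >= 8              # ~ (1 - alpha)^2 of seeds

    def test_short_recording_marks_phase_unavailable(self):
        onset = 900.0
        schedule = EventSchedule((("licl", onset, 600.0),))
        config = sd.make_archetype("licl_biphasic", "u0")
        train = sd.generate_spike_train(config, schedule, onset + 900.0,
                                        seed=0)
        matrix = psth.align_and_bin(train, schedule, "licl",
                                    window=(onset, 900.0), bin_width=60.0)
        result = rs.classify_sustained_response(matrix, "licl")
        assert result.rebound.direction == "unavailable"
        assert np.isnan(result.rebound.p)

    def test_needs_baseline(self):
        onset = 300.0
        schedule = EventSchedule((("licl", onset, 600.0),))
        config = sd.make_archetype("saline", "u0")
        train = sd.generate_spike_train(config, schedule, onset + 1860.0,
                                        seed=0)
        matrix = psth.align_and_bin(train, schedule, "licl",
                                    window=(onset, 1860.0), bin_width=60.0)
        with pytest.raises(ValueError, match="baseline"):
            rs.classify_sustained_response(matrix, "licl")
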