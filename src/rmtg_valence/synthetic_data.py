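"""Synthetic spike trains, calcium traces, and place-conditioning logs
with planted ground truth.

Every downstream stage of the pipeline is tested against data generated
here, where the true response category of each unit is known by
construction. The generative models are deliberately simple and exactly
controllable:

* spiking — inhomogeneous Poisson process, realized by thinning, whose
  rate is a baseline multiplied by stimulus-locked kernels (gain > 1
  excitation, gain < 1 inhibition, gain 0 full suppression). Kernels can
  carry a second phase of opposite sign to plant opponent-process
  biphasic responses, and can ramp linearly to their gain to emulate
  sustained ramping activations.
* burstiness — an added Poisson cluster (Neyman-Scott) process, giving
  the burst detector a non-Poisson positive control.
* quality defects — rate drift (Hz/min added to the baseline), injected
  refractory violations (a fraction of spikes duplicated 0.5 ms later),
  and shock-artifact spikes planted 1 ms after chosen event onsets.
* calcium — the unit's spike train convolved with a difference-of-
  exponentials indicator kernel, sampled on the frame grid, plus white
  Gaussian noise.
* behavior — a three-chamber Markov walk (side chambers reached only
  through the center) with a controllable bias toward the paired side and
  exponential dwell times.

Identical (config, schedule, seed) triples reproduce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .cpp import CppSession
from .psth import EventSchedule
from .qc import SpikeTrain

#: absolute refractory dead time imposed on every clean generated train,
#: so that defect-free units pass the < 0.2% / 1 ms acceptance rule the
#: way well-isolated biological units do
DEAD_TIME_S = 0.0015


@dataclass(frozen=True)
class ResponseKernel:
    """Multiplicative, stimulus-locked rate kernel.

    The primary phase spans ``[onset + latency, onset + latency +
    duration)`` with rate factor ``gain`` (``shape="ramp"`` interpolates
    the factor linearly from 1 to ``gain`` across the phase). An optional
    ``second_phase = (latency, duration, gain)`` plants a rebound of the
    opposite (or any) sign; phases must not overlap.
    """

    stimulus_label: str
    latency: float
    duration: float
    gain: float
    shape: str = "flat"
    second_phase: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.latency < 0 or self.duration <= 0:
            raise ValueError("kernel latency must be >= 0 and duration > 0")
        if not np.isfinite(self.gain) or self.gain < 0:
            raise ValueError("kernel gain must be finite and >= 0")
        if self.shape not in ("flat", "ramp"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.second_phase is not None:
            lat2, dur2, gain2 = self.second_phase
            if dur2 <= 0 or not np.isfinite(gain2) or gain2 < 0:
                raise ValueError("second phase needs duration > 0, finite gain >= 0")
            if lat2 < self.latency + self.duration:
                raise ValueError("kernel phases must not overlap")

    @property
    def max_gain(self) -> float:
        g = max(1.0, self.gain)
        if self.second_phase is not None:
            g = max(g, self.second_phase[2])
        return g


@dataclass(frozen=True)
class BurstParams:
    """Neyman-Scott cluster process parameters layered over the baseline."""

    cluster_rate: float            # clusters per second
    spikes_per_cluster_mean: float  # >= 1
    within_isi: float              # mean within-cluster ISI, s

    def __post_init__(self):
        if self.cluster_rate <= 0 or self.within_isi <= 0:
            raise ValueError("cluster rate and within-cluster ISI must be > 0")
        if self.spikes_per_cluster_mean < 1:
            raise ValueError("spikes per cluster mean must be >= 1")


@dataclass(frozen=True)
class Defects:
    """Injectable QC defects; all default to absent."""

    drift_slope: float = 0.0                 # Hz per minute, added to baseline
    refractory_violation_fraction: float = 0.0
    artifact_labels: tuple[str, ...] = ()    # spike planted 1 ms after onsets

    def __post_init__(self):
        f = self.refractory_violation_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("refractory violation fraction must be in [0, 1]")


@dataclass(frozen=True)
class UnitGenConfig:
    unit_id: str
    baseline_rate: float
    kernels: tuple[ResponseKernel, ...] = ()
    burstiness: BurstParams | None = None
    defects: Defects | None = None
    archetype: str = "none"        # planted cell-type archetype label
    projection_target: str = "unknown"
    gain_scale_sd: float = 0.0     # per-unit lognormal jitter of (gain - 1)

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be > 0")
        object.__setattr__(self, "kernels", tuple(self.kernels))


@dataclass(frozen=True)
class UnitTruth:
    """Planted ground truth for one generated unit."""

    unit_id: str
    categories: dict[str, str]     # stimulus -> excited|inhibited|biphasic|none
    valence_encoding: bool
    archetype: str


@dataclass(frozen=True)
class GroundTruth:
    units: dict[str, UnitTruth] = field(default_factory=dict)

    def fraction(self, predicate) -> float:
        if not self.units:
            return 0.0
        return sum(bool(predicate(u)) for u in self.units.values()) / len(self.units)


def _direction(gain: float) -> str:
    if gain > 1.0:
        return "excited"
    if gain < 1.0:
        return "inhibited"
    return "none"


def truth_for(config: UnitGenConfig) -> UnitTruth:
    """Derive the planted category labels implied by a unit's kernels."""
    categories: dict[str, str] = {}
    for k in config.kernels:
        first = _direction(k.gain)
        if k.second_phase is not None:
            second = _direction(k.second_phase[2])
            if first != "none" and second != "none" and first != second:
                categories[k.stimulus_label] = "biphasic"
                continue
        categories[k.stimulus_label] = first
    valence = (categories.get("reward_cue") == "inhibited"
               and categories.get("footshock") == "excited")
    return UnitTruth(unit_id=config.unit_id, categories=categories,
                     valence_encoding=valence, archetype=config.archetype)


def rate_function(config: UnitGenConfig, schedule: EventSchedule,
                  times: np.ndarray) -> np.ndarray:
    """Instantaneous firing rate (Hz) of the configured unit at ``times``."""
    times = np.asarray(times, dtype=float)
    base = config.baseline_rate + (config.defects.drift_slope / 60.0) * times \
        if config.defects is not None else np.full_like(times, config.baseline_rate)
    rate = np.maximum(np.asarray(base, dtype=float), 0.0)
    if not config.kernels:
        return rate
    factor = np.ones_like(times)
    for kernel in config.kernels:
        for onset in schedule.onsets(kernel.stimulus_label):
            start = onset + kernel.latency
            stop = start + kernel.duration
            sel = (times >= start) & (times < stop)
            if sel.any():
                if kernel.shape == "ramp":
                    frac = (times[sel] - start) / kernel.duration
                    factor[sel] *= 1.0 + (kernel.gain - 1.0) * frac
                else:
                    factor[sel] *= kernel.gain
            if kernel.second_phase is not None:
                lat2, dur2, gain2 = kernel.second_phase
                sel2 = (times >= onset + lat2) & (times < onset + lat2 + dur2)
                factor[sel2] *= gain2
    return rate * factor


def _apply_dead_time(spikes: np.ndarray, dead_time: float) -> np.ndarray:
    """Greedy removal of spikes closer than ``dead_time`` to the previous
    kept spike (an absolute refractory period)."""
    if dead_time <= 0 or spikes.size < 2:
        return spikes
    kept = spikes
    while True:
        bad = np.flatnonzero(np.diff(kept) < dead_time)
        if bad.size == 0:
            return kept
        # remove the later spike of the first violating pair in each run;
        # iterate so removal is equivalent to a greedy left-to-right scan
        first_of_run = bad[np.insert(np.diff(bad) > 1, 0, True)]
        kept = np.delete(kept, first_of_run + 1)


def generate_spike_train(config: UnitGenConfig, schedule: EventSchedule,
                         session_length: float, seed,
                         dead_time: float = DEAD_TIME_S) -> SpikeTrain:
    """Simulate one unit by thinning an inhomogeneous Poisson process.

    Thinning is exact for the bounded rate functions used here: candidate
    spikes are drawn homogeneously at the rate ceiling and kept with
    probability rate(t)/ceiling. Burst clusters are superimposed, a
    ``dead_time`` absolute refractory period is enforced, and configured
    defects (drift is part of the rate; violations and artifacts are
    inserted spikes) are layered on last.
    """
    if session_length <= 0:
        raise ValueError("session length must be > 0")
    for _, onset, dur in schedule.events:
        if onset < 0 or onset + dur > session_length:
            raise ValueError("schedule events must lie within [0, session_length]")
    rng = np.random.default_rng(seed)

    drift = config.defects.drift_slope if config.defects is not None else 0.0
    base_max = max(config.baseline_rate,
                   config.baseline_rate + drift / 60.0 * session_length)
    ceiling = base_max
    for k in config.kernels:
        ceiling *= k.max_gain
    n_candidates = rng.poisson(ceiling * session_length)
    candidates = np.sort(rng.uniform(0.0, session_length, n_candidates))
    accept = rng.uniform(0.0, 1.0, n_candidates) * ceiling
    spikes = candidates[accept < rate_function(config, schedule, candidates)]

    if config.burstiness is not None:
        b = config.burstiness
        n_clusters = rng.poisson(b.cluster_rate * session_length)
        centers = rng.uniform(0.0, session_length, n_clusters)
        cluster_spikes = []
        for c in centers:
            n = 1 + rng.poisson(b.spikes_per_cluster_mean - 1.0)
            offsets = np.concatenate([[0.0],
                                      np.cumsum(rng.exponential(b.within_isi, n - 1))])
            cluster_spikes.append(c + offsets)
        if cluster_spikes:
            extra = np.concatenate(cluster_spikes)
            spikes = np.sort(np.concatenate([spikes,
                                             extra[extra < session_length]]))

    spikes = _apply_dead_time(spikes, dead_time)

    if config.defects is not None:
        f = config.defects.refractory_violation_fraction
        if f > 0 and spikes.size:
            n_dup = int(round(f * spikes.size))
            chosen = rng.choice(spikes.size, size=min(n_dup, spikes.size),
                                replace=False)
            dups = spikes[chosen] + 0.0005
            spikes = np.sort(np.concatenate([spikes, dups[dups < session_length]]))
        if config.defects.artifact_labels:
            arts = [schedule.onsets(lbl) + 0.001
                    for lbl in config.defects.artifact_labels]
            arts = np.concatenate(arts) if arts else np.array([])
            spikes = np.sort(np.concatenate([spikes,
                                             arts[arts < session_length]]))

    return SpikeTrain(unit_id=config.unit_id, spike_times=spikes,
                      session_span=(0.0, float(session_length)))


def _jitter_gains(config: UnitGenConfig, rng) -> UnitGenConfig:
    """Scale every kernel's (gain - 1) by one shared lognormal factor.

    The shared factor plants per-unit response-magnitude correlations
    across stimuli (strongly shock-excited units are also strongly
    reward-inhibited), while preserving each kernel's direction.
    """
    if config.gain_scale_sd <= 0 or not config.kernels:
        return config
    s = rng.lognormal(mean=0.0, sigma=config.gain_scale_sd)
    kernels = []
    for k in config.kernels:
        second = k.second_phase
        if second is not None:
            lat2, dur2, g2 = second
            second = (lat2, dur2, max(0.0, 1.0 + s * (g2 - 1.0)))
        kernels.append(replace(k, gain=max(0.0, 1.0 + s * (k.gain - 1.0)),
                               second_phase=second))
    return replace(config, kernels=tuple(kernels))


def generate_population(pop_spec: list[tuple[UnitGenConfig, int]],
                        schedule: EventSchedule, session_length: float,
                        seed) -> tuple[list[SpikeTrain], GroundTruth]:
    """Generate a population from (config template, count) pairs.

    Unit ids are made unique by suffixing the template id; duplicate ids
    are rejected. Returns the trains plus one ground-truth record per
    unit, consistent with the kernels that generated it.
    """
    entropy = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seeds = entropy.spawn(sum(max(0, count) for _, count in pop_spec))
    trains: list[SpikeTrain] = []
    truth: dict[str, UnitTruth] = {}
    i = 0
    for template, count in pop_spec:
        if count < 1:
            raise ValueError("population counts must be >= 1")
        for j in range(count):
            uid = template.unit_id if count == 1 else f"{template.unit_id}_{j:03d}"
            if uid in truth:
                raise ValueError(f"duplicate unit id {uid!r}")
            rng = np.random.default_rng(seeds[i])
            config = replace(_jitter_gains(template, rng), unit_id=uid)
            trains.append(generate_spike_train(config, schedule,
                                               session_length, seeds[i].spawn(1)[0]))
            truth[uid] = truth_for(config)
            i += 1
    return trains, GroundTruth(units=truth)


def calcium_kernel(frame_rate: float, rise: float = 0.1, decay: float = 0.8,
                   amplitude: float = 0.2) -> np.ndarray:
    """Difference-of-exponentials indicator kernel sampled on the frame grid,
    normalized so a single spike produces a peak dF/F of ``amplitude``."""
    t = np.arange(0.0, decay * 8.0, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate calcium kernel (rise >= decay?)")
    return amplitude * k / peak


def generate_calcium_traces(pop_spec: list[tuple[UnitGenConfig, int]],
                            schedule: EventSchedule, session_length: float,
                            frame_rate: float = 5.0, noise_sd: float = 0.02,
                            seed=0, rise: float = 0.1, decay: float = 0.8,
                            amplitude: float = 0.2
                            ) -> tuple[list[CalciumTrace], GroundTruth]:
    """Spike-train-driven dF/F traces: convolved spikes plus Gaussian noise."""
    if frame_rate <= 0:
        raise ValueError("frame rate must be > 0")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    trains, truth = generate_population(pop_spec, schedule, session_length, seed)
    kernel = calcium_kernel(frame_rate, rise=rise, decay=decay,
                            amplitude=amplitude)
    n_frames = int(np.floor(session_length * frame_rate))
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA]))
    traces: list[CalciumTrace] = []
    templates = [tmpl for tmpl, count in pop_spec for _ in range(count)]
    for train, template in zip(trains, templates):
        binned = np.zeros(n_frames)
        idx = np.floor(train.spike_times * frame_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        np.add.at(binned, idx, 1.0)
        dff = np.convolve(binned, kernel)[:n_frames]
        if noise_sd > 0:
            dff = dff + noise_rng.normal(0.0, noise_sd, n_frames)
        traces.append(CalciumTrace(
            cell_id=train.unit_id,
            projection_target=template.projection_target,
            sample_rate=frame_rate,
            dF_F=dff,
            trial_onsets=np.array([o for _, o, _ in schedule.events])))
    return traces, truth


def generate_cpp_session(bias_paired: float, mean_dwell: float = 20.0,
                         session_length: float = 900.0, seed=0,
                         phase: str = "pre", animal_id: str = "animal0",
                         group: str = "sham",
                         beam_rate_per_entry: float = 3.0) -> CppSession:
    """Three-chamber Markov walk with a controllable side bias.

    The animal starts in the center; each center departure enters the
    paired chamber with probability ``bias_paired`` (else unpaired), and
    side chambers always return through the center. Dwell times are
    exponential with mean ``mean_dwell``; the final interval is truncated
    so the occupancy intervals exactly partition the session. Photobeam
    breaks accrue as 1 + Poisson(beam_rate_per_entry) per transition, so
    beam counts scale with locomotion.
    """
    if not 0.0 < bias_paired < 1.0:
        raise ValueError("bias_paired must be in (0, 1)")
    if mean_dwell <= 0 or session_length <= 0:
        raise ValueError("mean dwell and session length must be > 0")
    rng = np.random.default_rng(seed)
    occupancy: list[tuple[str, float, float]] = []
    t = 0.0
    chamber = "center"
    photobeam = 0
    while t < session_length:
        dwell = rng.exponential(mean_dwell)
        end = min(t + dwell, session_length)
        occupancy.append((chamber, t, end))
        t = end
        if t >= session_length:
            break
        if chamber == "center":
            chamber = "paired" if rng.uniform() < bias_paired else "unpaired"
        else:
            chamber = "center"
        photobeam += 1 + int(rng.poisson(beam_rate_per_entry))
    return CppSession(phase=phase, occupancy=tuple(occupancy),
                      photobeam_count=photobeam, animal_id=animal_id,
                      group=group)


# ---------------------------------------------------------------------------
# response archetypes: kernel bundles matching the planted categories the
# classifiers are expected to recover
# ---------------------------------------------------------------------------

GAIN_EXCITE = 3.0
GAIN_INHIBIT = 0.2
BASELINE_HZ = 10.0

_AVERSIVE_PHASIC = ("footshock", "siren", "bright_light")


def make_archetype(name: str, unit_id: str,
                   baseline_rate: float = BASELINE_HZ,
                   gain_excite: float = GAIN_EXCITE,
                   gain_inhibit: float = GAIN_INHIBIT,
                   gain_scale_sd: float = 0.0,
                   projection_target: str = "unknown") -> UnitGenConfig:
    """Build a unit config for a named planted response archetype.

    RMTg-like archetypes: ``valence_encoding`` (reward-cue inhibition in
    the 200-400 ms window plus fast excitation to all phasic aversive
    stimuli), ``aversive_only``, ``reward_inhibited_only``,
    ``unresponsive``. VTA-like archetypes: ``pda_delayed_inhibition``
    (phasic reward excitation; aversive early excitation then 100-500 ms
    inhibition), ``pda_immediate_inhibition``, ``pda_excitation_only``,
    ``ramping`` (sustained 200-2000 ms reward activation), and
    ``reward_inhibited``. Sustained-stimulus archetypes plant opponent
    biphasic kernels at the minutes timescale.
    """
    K = ResponseKernel

    def aversive(gain=gain_excite):
        return tuple(K(s, 0.0, 0.1, gain) for s in _AVERSIVE_PHASIC)

    if name == "unresponsive":
        kernels: tuple[ResponseKernel, ...] = ()
    elif name == "valence_encoding":
        kernels = (K("reward_cue", 0.2, 0.2, gain_inhibit),) + aversive() \
            + (K("neutral_tone", 0.0, 0.1, 1.5),)
    elif name == "aversive_only":
        kernels = aversive()
    elif name == "reward_inhibited_only":
        kernels = (K("reward_cue", 0.2, 0.2, gain_inhibit),)
    elif name == "pda_delayed_inhibition":
        kernels = (K("reward_cue", 0.0, 0.2, gain_excite),) + tuple(
            K(s, 0.0, 0.08, gain_excite, second_phase=(0.1, 0.3, gain_inhibit))
            for s in _AVERSIVE_PHASIC)
    elif name == "pda_immediate_inhibition":
        kernels = (K("reward_cue", 0.0, 0.2, gain_excite),) + tuple(
            K(s, 0.1, 0.3, gain_inhibit) for s in _AVERSIVE_PHASIC)
    elif name == "pda_excitation_only":
        kernels = (K("reward_cue", 0.0, 0.2, gain_excite),) + tuple(
            K(s, 0.0, 0.08, gain_excite) for s in _AVERSIVE_PHASIC)
    elif name == "ramping":
        kernels = (K("reward_cue", 0.2, 1.8, gain_excite, shape="ramp"),)
    elif name == "reward_inhibited":
        kernels = (K("reward_cue", 0.0, 0.2, gain_inhibit),)
    elif name == "licl_biphasic":
        kernels = (K("licl", 0.0, 600.0, 2.0, second_phase=(1200.0, 600.0, 0.5)),)
    elif name == "restraint_biphasic":
        kernels = (K("restraint", 0.0, 180.0, 2.0,
                     second_phase=(540.0, 180.0, 0.5)),)
    elif name == "cocaine_biphasic":
        kernels = (K("cocaine", 0.0, 600.0, 0.5,
                     second_phase=(1200.0, 600.0, 2.0)),)
    elif name in ("saline", "saline_ip", "saline_iv"):
        kernels = ()
    else:
        raise ValueError(f"unknown archetype {name!r}")

    archetype = {"pda_delayed_inhibition": "phasic_reward",
                 "pda_immediate_inhibition": "phasic_reward",
                 "pda_excitation_only": "phasic_reward",
                 "ramping": "ramping",
                 "reward_inhibited": "reward_inhibited"}.get(name, "none")
    return UnitGenConfig(unit_id=unit_id, baseline_rate=baseline_rate,
                         kernels=kernels, archetype=archetype,
                         gain_scale_sd=gain_scale_sd,
                         projection_target=projection_target)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def spikes_to_frame(trains: list[SpikeTrain]) -> pd.DataFrame:
    rows = [(t.unit_id, s) for t in trains for s in t.spike_times]
    return pd.DataFrame(rows, columns=["unit_id", "time_s"])


def frame_to_spikes(frame: pd.DataFrame,
                    session_span: tuple[float, float]) -> list[SpikeTrain]:
    return [SpikeTrain(unit_id=str(uid), spike_times=np.sort(g["time_s"].values),
                       session_span=session_span)
            for uid, g in frame.groupby("unit_id", sort=True)]


def schedule_to_frame(schedule: EventSchedule) -> pd.DataFrame:
    return pd.DataFrame(list(schedule.events),
                        columns=["label", "onset_s", "duration_s"])


def frame_to_schedule(frame: pd.DataFrame) -> EventSchedule:
    return EventSchedule(tuple(frame[["label", "onset_s", "duration_s"]]
                               .itertuples(index=False, name=None)))


def truth_to_json(truth: GroundTruth) -> str:
    payload = {uid: {"categories": u.categories,
                     "valence_encoding": u.valence_encoding,
                     "archetype": u.archetype}
               for uid, u in truth.units.items()}
    return json.dumps(payload, indent=2, sort_keys=True)


def calcium_to_frame(traces: list[CalciumTrace]) -> pd.DataFrame:
    """Time x cell dF/F matrix with a leading time_s column."""
    if not traces:
        return pd.DataFrame()
    n = min(t.dF_F.size for t in traces)
    data = {"time_s": np.arange(n) / traces[0].sample_rate}
    for t in traces:
        data[t.cell_id] = t.dF_F[:n]
    return pd.DataFrame(data)
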