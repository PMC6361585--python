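"""Event-aligned binning, baseline normalization, and latency extraction.

One code path serves two timescales: phasic stimuli (50 ms bins against a
1 s pre-stimulus baseline) and sustained stimuli (5 min bins against a
15 min baseline) differ only in the window and bin-width arguments.

Conventions
-----------
* Trial-relative time 0 is stimulus onset; bins are half-open
  ``[left, left + width)``, so a spike exactly on an edge belongs to the
  bin starting at that edge.
* Blanked stretches of the session (see :mod:`rmtg_valence.qc`) are carried
  through as per-bin excluded seconds, and rates are computed over the
  effective (non-blanked) bin duration.
* Normalization default is a z-score against the distribution of baseline
  bin rates, with an SD floor for near-silent units; a fold-change dialect
  (rate / baseline mean) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASIC_BIN_S = 0.05
PHASIC_BASELINE_S = 1.0
SUSTAINED_BIN_S = 300.0
SUSTAINED_BASELINE_S = 900.0
SD_FLOOR_HZ = 0.1

#: stimulus labels used throughout the pipeline
PHASIC_LABELS = ("reward_cue", "neutral_tone", "shock_cue", "footshock",
                 "siren", "bright_light")
SUSTAINED_LABELS = ("licl", "saline_ip", "restraint", "cocaine", "saline_iv")


@dataclass(frozen=True)
class EventSchedule:
    """Timestamped stimulus events: (label, onset s, duration s)."""

    events: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        events = tuple((str(l), float(o), float(d)) for l, o, d in self.events)
        object.__setattr__(self, "events", events)
        onsets = [o for _, o, _ in events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be non-decreasing")
        if any(d < 0 for _, _, d in events):
            raise ValueError("event durations must be >= 0")

    def onsets(self, label: str) -> np.ndarray:
        return np.array([o for l, o, _ in self.events if l == label])

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for l, _, _ in self.events:
            seen.setdefault(l)
        return tuple(seen)

    @property
    def end(self) -> float:
        return max((o + d for _, o, d in self.events), default=0.0)


def make_schedule(blocks: list[tuple[str, int, float]],
                  interval: float = 30.0,
                  start: float = 30.0,
                  interleave: bool = False,
                  seed: int | None = None) -> EventSchedule:
    """Build an event schedule from (label, n_trials, duration) blocks.

    Trials are spaced ``interval`` seconds apart starting at ``start``.
    With ``interleave=True`` trial labels are shuffled across the whole
    session (seeded), mimicking randomly interleaved aversive stimuli;
    otherwise blocks run back to back.
    """
    labels: list[tuple[str, float]] = []
    for label, n, duration in blocks:
        labels.extend([(label, duration)] * n)
    if interleave:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(labels))
        labels = [labels[i] for i in order]
    events = [(label, start + i * interval, duration)
              for i, (label, duration) in enumerate(labels)]
    return EventSchedule(tuple(events))


@dataclass(frozen=True)
class TrialMatrix:
    """Trials x bins spike counts aligned to one stimulus label.

    ``excluded`` holds, per trial and bin, the number of seconds blanked
    out of that bin; fully excluded bins have no usable rate.
    """

    unit_id: str
    stimulus: str
    bin_edges: np.ndarray          # relative to onset, len n_bins + 1
    counts: np.ndarray             # (n_trials, n_bins) int
    excluded: np.ndarray           # (n_trials, n_bins) float seconds
    onsets: np.ndarray             # absolute event onsets used

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_trials(self) -> int:
        return int(self.counts.shape[0])

    def rates(self) -> np.ndarray:
        """Per-trial, per-bin firing rate over effective bin duration (Hz).

        Fully blanked bins yield NaN.
        """
        effective = self.bin_width - self.excluded
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(effective > 0, self.counts / np.maximum(effective, 1e-12),
                         np.nan)
        return r

    def window_rates(self, window: tuple[float, float]) -> np.ndarray:
        """Per-trial mean rate (Hz) over the bins inside ``window``.

        Window is half-open over bin left edges: a bin belongs to the
        window when ``window[0] <= left_edge < window[1]``.
        """
        sel = self._window_mask(window)
        counts = self.counts[:, sel].sum(axis=1)
        effective = (self.bin_width - self.excluded[:, sel]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(effective > 0, counts / np.maximum(effective, 1e-12),
                            np.nan)

    def _window_mask(self, window: tuple[float, float]) -> np.ndarray:
        left = self.bin_edges[:-1]
        mask = (left >= window[0] - 1e-9) & (left < window[1] - 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} selects no bins")
        return mask


@dataclass(frozen=True)
class NormalizedPsth:
    unit_id: str
    stimulus: str
    bin_centers: np.ndarray
    normalized_rate: np.ndarray    # dimensionless, one value per bin
    baseline_mean: float           # Hz
    baseline_sd: float             # Hz
    normalization_method: str = "zscore"
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0]) \
            if self.bin_centers.size > 1 else 0.0


def align_and_bin(train, schedule: EventSchedule, label: str,
                  window: tuple[float, float],
                  bin_width: float = PHASIC_BIN_S) -> TrialMatrix:
    """Bin spikes into trials x bins aligned to every event of ``label``.

    ``window = (pre, post)`` extends from ``pre`` seconds before onset to
    ``post`` seconds after. ``bin_width`` must divide the total window.
    """
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must be (pre >= 0, post > 0)")
    total = pre + post
    n_bins = total / bin_width
    if abs(n_bins - round(n_bins)) > 1e-6:
        raise ValueError(f"bin width {bin_width} does not divide window {window}")
    n_bins = int(round(n_bins))
    onsets = schedule.onsets(label)
    if onsets.size == 0:
        raise ValueError(f"no events labeled {label!r} in schedule")

    edges = -pre + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((onsets.size, n_bins), dtype=int)
    excluded = np.zeros((onsets.size, n_bins), dtype=float)
    times = train.spike_times
    for t, onset in enumerate(onsets):
        rel = times[(times >= onset - pre) & (times < onset + post)] - onset
        idx = np.floor((rel + pre) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts[t], idx, 1)
        for a, b in train.excluded_intervals:
            ra, rb = a - onset, b - onset
            lo = np.maximum(edges[:-1], ra)
            hi = np.minimum(edges[1:], rb)
            excluded[t] += np.maximum(0.0, hi - lo)
    return TrialMatrix(unit_id=train.unit_id, stimulus=label,
                       bin_edges=edges, counts=counts,
                       excluded=excluded, onsets=onsets)


def normalize(matrix: TrialMatrix,
              baseline_window: tuple[float, float] | None = None,
              method: str = "zscore",
              sd_floor: float = SD_FLOOR_HZ) -> NormalizedPsth:
    """Baseline-normalize the trial-averaged PSTH.

    ``zscore``: per bin, (trial-mean rate - baseline mean) / max(baseline
    SD, sd_floor) where mean and SD are taken over the baseline bins'
    trial-mean rates. ``fold``: trial-mean rate / max(baseline mean,
    sd_floor). Baseline defaults to the full pre-onset part of the matrix.
    """
    if baseline_window is None:
        baseline_window = (float(matrix.bin_edges[0]), 0.0)
    if baseline_window[0] < matrix.bin_edges[0] - 1e-9 \
            or baseline_window[1] > matrix.bin_edges[-1] + 1e-9:
        raise ValueError("baseline window outside matrix window")
    rates = matrix.rates()
    mean_rate = np.nanmean(rates, axis=0)
    base_sel = matrix._window_mask(baseline_window)
    base = mean_rate[base_sel]
    flags: list[str] = []
    baseline_mean = float(np.nanmean(base))
    baseline_sd = float(np.nanstd(base, ddof=1)) if base.size > 1 else 0.0
    if matrix.counts[:, base_sel].sum() == 0:
        flags.append("zero_baseline")
    if method == "zscore":
        z = (mean_rate - baseline_mean) / max(baseline_sd, sd_floor)
    elif method == "fold":
        z = mean_rate / max(baseline_mean, sd_floor)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    z = np.nan_to_num(z, nan=0.0)
    if matrix.counts.sum() == 0:
        flags.append("silent_unit")
    return NormalizedPsth(unit_id=matrix.unit_id, stimulus=matrix.stimulus,
                          bin_centers=matrix.bin_centers, normalized_rate=z,
                          baseline_mean=baseline_mean, baseline_sd=baseline_sd,
                          normalization_method=method, flags=tuple(flags))


def latency_to_extreme(psth: NormalizedPsth,
                       response_window: tuple[float, float],
                       direction: str = "excited") -> tuple[float, bool]:
    """Left-edge time of the first bin attaining the window's extreme.

    ``excited`` units use the maximum, ``inhibited`` the minimum; for
    unclassified units the larger absolute deflection decides. Ties are
    broken by the earliest bin. Returns ``(latency_s, ambiguous)`` where
    ``ambiguous`` is True for a flat trace.
    """
    width = psth.bin_width
    left = psth.bin_centers - width / 2.0
    sel = (left >= response_window[0] - 1e-9) & (left < response_window[1] - 1e-9)
    if not sel.any():
        raise ValueError("response window selects no bins")
    vals = psth.normalized_rate[sel]
    lefts = left[sel]
    ambiguous = bool(np.ptp(vals) == 0.0)
    if direction == "inhibited":
        target = vals.min()
    elif direction == "excited":
        target = vals.max()
    else:
        target = vals.max() if abs(vals.max()) >= abs(vals.min()) else vals.min()
    idx = int(np.flatnonzero(vals == target)[0])
    return float(lefts[idx]), ambiguous


def population_average(psths: list[NormalizedPsth]):
    """Pointwise mean +/- SEM across units with identical bin structure.

    Returns ``(bin_centers, mean, sem, n)``; SEM is NaN for n = 1.
    """
    if not psths:
        raise ValueError("empty population")
    centers = psths[0].bin_centers
    for p in psths[1:]:
        if p.bin_centers.shape != centers.shape \
                or not np.allclose(p.bin_centers, centers):
            raise ValueError("mixed bin structures in population average")
    stack = np.vstack([p.normalized_rate for p in psths])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
        else np.full_like(mean, np.nan)
    return centers, mean, sem, n
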