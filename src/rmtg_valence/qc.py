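"""Unit acceptance and artifact handling applied before response analysis.

Three rules are enforced before any spike train enters the response
pipeline:

* refractory-period check — a well-isolated single unit must have fewer
  than 0.2% of its spikes arriving within 1 ms of the previous spike;
* drift exclusion — units whose baseline firing rate trends across the
  session (electrode drift) are excluded, using a Spearman rank
  correlation of per-window baseline rate against window index;
* shock-artifact blanking — the first 10 ms after each footshock are
  removed from both the spike train and the effective recording time,
  because the shock pulse itself contaminates the electrode signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

REFRACTORY_ISI_S = 0.001
REFRACTORY_MAX_FRACTION = 0.002
SHOCK_BLANK_S = 0.010
DRIFT_ALPHA = 0.05


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's sorted spike times plus session metadata.

    ``excluded_intervals`` are half-open ``[start, end)`` stretches of the
    session that downstream analyses must treat as non-recorded time
    (e.g. blanked shock artifacts); they are subtracted from effective
    durations wherever rates are computed.
    """

    unit_id: str
    spike_times: np.ndarray
    session_span: tuple[float, float] = (0.0, 0.0)
    session_id: str = "session0"
    excluded_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
        lo, hi = self.session_span
        if hi < lo:
            raise ValueError("session_span end precedes start")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.session_span[1] - self.session_span[0]


@dataclass(frozen=True)
class DriftResult:
    statistic: float
    p: float
    flagged: bool


@dataclass(frozen=True)
class QCResult:
    unit_id: str
    refractory_violation_fraction: float
    drift_statistic: float
    drift_p: float
    accepted: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def refractory_violation_fraction(train: SpikeTrain,
                                  isi_threshold: float = REFRACTORY_ISI_S) -> float:
    """Fraction of spikes whose preceding interspike interval is < 1 ms.

    The interval is half-open: an ISI of exactly ``isi_threshold`` does not
    count as a violation. With fewer than two spikes the fraction is 0
    (``evaluate_unit`` flags such units separately).
    """
    t = train.spike_times
    if t.size < 2:
        return 0.0
    violations = int(np.count_nonzero(np.diff(t) < isi_threshold))
    return violations / t.size


def detect_drift(train: SpikeTrain,
                 baseline_windows: list[tuple[float, float]],
                 alpha: float = DRIFT_ALPHA) -> DriftResult:
    """Rank-based trend test on per-window baseline firing rates.

    Spearman correlation of window rate against window index, two-sided;
    the unit is flagged when p < alpha. Empty windows contribute a rate of
    0 rather than erroring. A constant-rate train has zero trend and a
    degenerate (all-tied) rank correlation, which is never flagged.
    """
    if len(baseline_windows) < 2:
        raise ValueError("need at least 2 baseline windows to test drift")
    rates = np.array([_window_rate(train, w) for w in baseline_windows])
    if np.ptp(rates) == 0.0:
        return DriftResult(statistic=0.0, p=1.0, flagged=False)
    res = stats.spearmanr(np.arange(len(rates)), rates)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return DriftResult(statistic=stat, p=1.0, flagged=False)
    return DriftResult(statistic=stat, p=p, flagged=bool(p < alpha))


def _window_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    lo, hi = window
    effective = (hi - lo) - _excluded_overlap(train.excluded_intervals, lo, hi)
    if effective <= 0:
        return 0.0
    count = int(np.searchsorted(train.spike_times, hi, side="left")
                - np.searchsorted(train.spike_times, lo, side="left"))
    return count / effective


def _excluded_overlap(intervals, lo: float, hi: float) -> float:
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


def _merge_intervals(intervals):
    if not intervals:
        return ()
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for a, b in ordered[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def blank_shock_artifact(train: SpikeTrain,
                         shock_onsets,
                         blank_duration: float = SHOCK_BLANK_S) -> SpikeTrain:
    """Remove spikes in [onset, onset + 10 ms) after each footshock.

    The blanked stretches are appended to ``excluded_intervals`` (merged
    with any existing ones) so downstream rate computations use effective
    durations. Idempotent: blanking twice equals blanking once.
    """
    onsets = np.atleast_1d(np.asarray(shock_onsets, dtype=float))
    if onsets.size == 0:
        return train
    lo, hi = train.session_span
    if np.any(onsets < lo) or np.any(onsets > hi):
        raise ValueError("shock onsets must lie within the session span")
    windows = [(float(o), float(o) + blank_duration) for o in onsets]
    merged = _merge_intervals(list(train.excluded_intervals) + windows)
    keep = np.ones(train.spike_times.size, dtype=bool)
    for a, b in windows:
        keep &= ~((train.spike_times >= a) & (train.spike_times < b))
    return replace(train, spike_times=train.spike_times[keep],
                   excluded_intervals=merged)


def evaluate_unit(train: SpikeTrain,
                  baseline_windows: list[tuple[float, float]] | None = None,
                  violation_threshold: float = REFRACTORY_MAX_FRACTION,
                  alpha: float = DRIFT_ALPHA) -> QCResult:
    """Full acceptance decision for one unit.

    Accepted iff the refractory-violation fraction is strictly below the
    threshold AND the drift trend is not significant. ``reasons`` lists
    every failed rule plus informational flags.
    """
    reasons: list[str] = []
    frac = refractory_violation_fraction(train)
    if train.n_spikes < 2:
        reasons.append("too_few_spikes")
    refractory_ok = frac < violation_threshold
    if not refractory_ok:
        reasons.append("refractory_violations")

    if baseline_windows is not None and len(baseline_windows) >= 2:
        drift = detect_drift(train, baseline_windows, alpha=alpha)
    else:
        drift = DriftResult(statistic=np.nan, p=np.nan, flagged=False)
        reasons.append("drift_not_tested")
    if drift.flagged:
        reasons.append("rate_drift")

    accepted = refractory_ok and not drift.flagged
    return QCResult(unit_id=train.unit_id,
                    refractory_violation_fraction=frac,
                    drift_statistic=drift.statistic,
                    drift_p=drift.p,
                    accepted=accepted,
                    reasons=tuple(reasons))
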