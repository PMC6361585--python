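"""Burst detection by the 80/160 ms interspike-interval rule.

A burst opens at the first spike of any pair separated by less than
80 ms, and continues while successive intervals do not exceed 160 ms; it
closes when the next interval is more than 160 ms (strictly), or at the
end of the train. Bursts are maximal and non-overlapping: scanning
resumes after a closed burst's last spike. Note the asymmetry of the
bounds — exactly 80 ms does NOT open a burst, exactly 160 ms DOES
continue one — which differs from several common toolbox conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qc import SpikeTrain, _excluded_overlap

OPEN_ISI_S = 0.080
CONTINUE_ISI_S = 0.160


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class BurstStats:
    unit_id: str
    bursts: tuple[Burst, ...]
    pct_spikes_in_bursts: float    # percent, in [0, 100]
    n_spikes: int

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


def detect_bursts(train: SpikeTrain,
                  open_isi: float = OPEN_ISI_S,
                  continue_isi: float = CONTINUE_ISI_S) -> BurstStats:
    """Scan ISIs left to right applying the open/continue/close rule."""
    t = train.spike_times
    n = t.size
    if n < 2:
        return BurstStats(train.unit_id, (), 0.0, int(n))
    isi = np.diff(t)
    bursts: list[Burst] = []
    in_burst_spikes = 0
    i = 0
    while i < n - 1:
        if isi[i] < open_isi:
            j = i + 1
            while j < n - 1 and isi[j] <= continue_isi:
                j += 1
            bursts.append(Burst(start=float(t[i]), end=float(t[j]),
                                n_spikes=j - i + 1))
            in_burst_spikes += j - i + 1
            i = j + 1
        else:
            i += 1
    pct = 100.0 * in_burst_spikes / n
    return BurstStats(train.unit_id, tuple(bursts), pct, int(n))


def baseline_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count over effective (non-blanked) duration in ``window``, Hz."""
    lo, hi = window
    if lo < train.session_span[0] - 1e-9 or hi > train.session_span[1] + 1e-9:
        raise ValueError("window outside session span")
    effective = (hi - lo) - _excluded_overlap(train.excluded_intervals, lo, hi)
    if effective <= 0:
        raise ValueError("window has zero effective duration after exclusions")
    count = int(np.searchsorted(train.spike_times, hi, side="left")
                - np.searchsorted(train.spike_times, lo, side="left"))
    return count / effective
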