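"""Trial-based analysis of extracted calcium (dF/F) traces.

Works downstream of source extraction: each cell is a uniformly sampled
dF/F series (nominal 5 Hz after temporal downsampling) with a projection
target label (VTA or DRN for retrogradely identified populations). Trials
are 20 s windows centered on stimulus onset; traces are baseline-
subtracted per trial, smoothed with a 0.6 s moving average, and tested
with a paired t-test of response-window versus baseline-window means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TRIAL_WINDOW_S = 20.0
SMOOTH_WINDOW_S = 0.6
RESPONSE_WINDOW_S = (0.0, 2.0)
ALPHA = 0.05


@dataclass(frozen=True)
class CalciumTrace:
    cell_id: str
    projection_target: str         # "VTA" | "DRN" | "unknown"
    sample_rate: float             # Hz
    dF_F: np.ndarray
    trial_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "dF_F", np.asarray(self.dF_F, dtype=float))
        object.__setattr__(self, "trial_onsets",
                           np.asarray(self.trial_onsets, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be > 0")
        if not np.all(np.isfinite(self.dF_F)):
            raise ValueError("dF/F trace contains non-finite values")


@dataclass(frozen=True)
class TrialTensor:
    cell_id: str
    data: np.ndarray               # (n_trials, n_timepoints)
    sample_rate: float
    window: float                  # total seconds, centered on onset
    dropped_onsets: tuple[float, ...] = ()
    projection_target: str = "unknown"

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[1]
        return (np.arange(n) - n // 2) / self.sample_rate

    def window_means(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        sel = (t >= window[0]) & (t < window[1])
        if not sel.any():
            raise ValueError(f"window {window} selects no samples")
        return self.data[:, sel].mean(axis=1)


@dataclass(frozen=True)
class CellResponse:
    cell_id: str
    direction: str                 # excited | inhibited | none
    p_value: float
    magnitude: float               # mean response-window minus baseline dF/F
    degenerate: bool = False


def extract_trials(trace: CalciumTrace, onsets,
                   window: float = TRIAL_WINDOW_S) -> TrialTensor:
    """Cut symmetric ``window``-second trials centered on each onset.

    Onsets closer than window/2 to either recording edge are dropped and
    reported in ``dropped_onsets``.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    half = window / 2.0
    n_samples = int(round(window * trace.sample_rate))
    rows, dropped = [], []
    t_end = trace.t0 + trace.dF_F.size / trace.sample_rate
    for onset in onsets:
        start = int(round((onset - half - trace.t0) * trace.sample_rate))
        if onset - half < trace.t0 or onset + half > t_end \
                or start + n_samples > trace.dF_F.size or start < 0:
            dropped.append(float(onset))
            continue
        rows.append(trace.dF_F[start:start + n_samples])
    if not rows:
        raise ValueError("every trial fell outside the recording")
    return TrialTensor(cell_id=trace.cell_id, data=np.vstack(rows),
                       sample_rate=trace.sample_rate, window=window,
                       dropped_onsets=tuple(dropped),
                       projection_target=trace.projection_target)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (rows independently)."""
    x = np.atleast_2d(x)
    kernel = np.ones(width)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, x)
    den = np.convolve(np.ones(x.shape[1]), kernel, mode="same")
    return num / den


def normalize_and_smooth(tensor: TrialTensor,
                         smooth_window: float = SMOOTH_WINDOW_S) -> TrialTensor:
    """Per trial: subtract the pre-onset baseline mean, then apply a
    centered ``smooth_window``-second moving average (3 samples at 5 Hz),
    with shrinking windows at the trial edges."""
    t = tensor.times
    base = tensor.data[:, t < 0].mean(axis=1, keepdims=True)
    centered = tensor.data - base
    width = max(1, int(round(smooth_window * tensor.sample_rate)))
    smoothed = moving_average(centered, width)
    return TrialTensor(cell_id=tensor.cell_id, data=smoothed,
                       sample_rate=tensor.sample_rate, window=tensor.window,
                       dropped_onsets=tensor.dropped_onsets,
                       projection_target=tensor.projection_target)


def cell_response_test(tensor: TrialTensor,
                       response_window: tuple[float, float] = RESPONSE_WINDOW_S,
                       baseline_window: tuple[float, float] | None = None,
                       alpha: float = ALPHA) -> CellResponse:
    """Two-sided paired t-test of per-trial response vs baseline means."""
    if tensor.data.shape[0] < 5:
        raise ValueError("need at least 5 trials for the paired test")
    if baseline_window is None:
        baseline_window = (-tensor.window / 2.0, 0.0)
    resp = tensor.window_means(response_window)
    base = tensor.window_means(baseline_window)
    diff = resp - base
    magnitude = float(diff.mean())
    if np.allclose(diff, diff[0]):
        direction = "none" if magnitude == 0.0 else \
            ("excited" if magnitude > 0 else "inhibited")
        return CellResponse(tensor.cell_id, direction, np.nan, magnitude,
                            degenerate=True)
    t_stat, p = stats.ttest_rel(resp, base)
    p = float(p)
    if p < alpha:
        direction = "excited" if magnitude > 0 else "inhibited"
    else:
        direction = "none"
    return CellResponse(tensor.cell_id, direction, p, magnitude)


def projection_contrast(group_a: dict[str, list[CellResponse]],
                        group_b: dict[str, list[CellResponse]],
                        labels: tuple[str, str] = ("VTA", "DRN")) -> dict:
    """Compare two projection-defined populations.

    Each group maps stimulus -> per-cell :class:`CellResponse` lists for
    the same cells in the same order (expected keys ``reward_cue`` and
    ``footshock``). Reports, per group, the reward-vs-shock magnitude
    correlation, and across groups a chi-square contrast of the
    reward-cue inhibited/not-inhibited proportions.
    """
    from .population_analysis import compare_proportions, correlate_responses

    out: dict = {"groups": {}}
    counts = []
    for label, group in zip(labels, (group_a, group_b)):
        reward = group["reward_cue"]
        shock = group["footshock"]
        if len(reward) != len(shock) or not reward:
            raise ValueError(f"group {label}: reward/shock cell lists must "
                             "be non-empty and paired")
        x = np.array([c.magnitude for c in shock])
        y = np.array([c.magnitude for c in reward])
        corr = correlate_responses(x, y)
        inhibited = sum(c.direction == "inhibited" for c in reward)
        counts.append([inhibited, len(reward) - inhibited])
        out["groups"][label] = {
            "n_cells": len(reward),
            "reward_inhibited_fraction": inhibited / len(reward),
            "shock_excited_fraction":
                sum(c.direction == "excited" for c in shock) / len(shock),
            "reward_vs_shock_r2": corr.r_squared,
            "reward_vs_shock_p": corr.p,
            "reward_vs_shock_slope": corr.slope,
        }
    table = compare_proportions(np.array(counts))
    out["reward_inhibited_chi_square"] = table.chi_square
    out["reward_inhibited_p"] = table.p
    return out
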