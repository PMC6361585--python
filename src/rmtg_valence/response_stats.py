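"""Per-neuron significance testing in stimulus-specific windows and the
categorical labels built from it.

The elementary test pairs each trial's mean firing rate in a response
window with the same trial's baseline-window rate and applies a
two-sided Wilcoxon signed-rank test at alpha = 0.05. On top of it sit
the classifiers used throughout the pipeline:

* RMTg valence encoding — reward-cue inhibition in the 200-400 ms window
  together with footshock excitation in the 0-100 ms window;
* VTA cell typing — putative dopamine (pDA) by phasic reward-cue
  excitation 0-200 ms; ramping by sustained activation 200-2000 ms;
  reward-inhibited by 0-200 ms inhibition (precedence pDA > ramping >
  reward-inhibited);
* pDA aversive-response typing — immediate vs delayed inhibition in the
  100-500 ms window, split by the presence of an early (0-100 ms)
  excitation;
* sustained-stimulus opponent responses — per-minute rates tested by
  rank-sum against 15 baseline minutes in stimulus-specific initial and
  rebound phase windows (biphasic when both phases are significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .psth import NormalizedPsth, TrialMatrix, latency_to_extreme, normalize

ALPHA = 0.05

#: response windows (s, post-onset) — the pipeline's core analytic commitments
REWARD_CUE_WINDOW = (0.2, 0.4)
AVERSIVE_WINDOW = (0.0, 0.1)
PDA_WINDOW = (0.0, 0.2)
RAMPING_WINDOW = (0.2, 2.0)
AVERSIVE_INHIBITION_WINDOW = (0.1, 0.5)
EARLY_EXCITATION_WINDOW = (0.0, 0.1)

#: sustained-stimulus phase windows, minutes post-onset
SUSTAINED_PHASE_WINDOWS_MIN = {
    "licl": ((0.0, 10.0), (20.0, 30.0)),
    "restraint": ((0.0, 3.0), (9.0, 12.0)),
    "cocaine": ((0.0, 10.0), (20.0, 30.0)),
    "saline_ip": ((0.0, 10.0), (20.0, 30.0)),
    "saline_iv": ((0.0, 10.0), (20.0, 30.0)),
}
SUSTAINED_BASELINE_MIN = 15.0


@dataclass(frozen=True)
class ResponseProfile:
    unit_id: str
    stimulus: str
    window: tuple[float, float]
    direction: str                 # excited | inhibited | none
    p_value: float
    magnitude: float               # mean normalized rate in the window
    latency: float                 # s, first bin attaining the extreme
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RmtgLabel:
    unit_id: str
    valence_encoding: bool
    directions: dict[str, str]     # stimulus -> direction
    withheld_reason: str | None = None


@dataclass(frozen=True)
class CellTypeLabel:
    unit_id: str
    label: str                     # pDA | ramping | reward_inhibited | unclassified
    evidence: dict[str, float]     # window name -> p


@dataclass(frozen=True)
class PhaseResult:
    window_min: tuple[float, float]
    direction: str
    p: float


@dataclass(frozen=True)
class SustainedResponse:
    unit_id: str
    stimulus: str
    initial: PhaseResult
    rebound: PhaseResult
    pattern: str                   # biphasic | initial_only | rebound_only | none


def window_response_test(matrix: TrialMatrix,
                         response_window: tuple[float, float],
                         baseline_window: tuple[float, float] | None = None,
                         alpha: float = ALPHA,
                         psth: NormalizedPsth | None = None) -> ResponseProfile:
    """Wilcoxon signed-rank test of response vs baseline rates, per trial.

    By default each trial's response-window rate is paired with its rate
    in a duration-matched baseline window ending at onset (clipped to the
    available pre-onset span): matching the window durations makes the
    paired differences exchangeable under the null, which keeps the
    signed-rank test at its nominal level for short, low-count windows.
    Direction is assigned only at p < alpha, with the sign of the mean
    normalized response (so that sign(magnitude) == direction for every
    responsive unit). Trials with fully blanked windows are dropped from
    the pairing.
    """
    if matrix.n_trials < 6:
        raise ValueError("need >= 6 trials for the signed-rank test")
    if baseline_window is None:
        duration = response_window[1] - response_window[0]
        available = -float(matrix.bin_edges[0])
        if available <= 0:
            raise ValueError("matrix has no pre-onset baseline")
        baseline_window = (-min(duration, available), 0.0)
    resp = matrix.window_rates(response_window)
    base = matrix.window_rates(baseline_window)
    ok = np.isfinite(resp) & np.isfinite(base)
    resp, base = resp[ok], base[ok]
    diffs = resp - base
    flags: list[str] = []
    if psth is None:
        # magnitudes are z-scored against the full pre-onset baseline,
        # independently of the duration-matched test pairing
        psth = normalize(matrix)
    sel = (psth.bin_centers - psth.bin_width / 2.0 >= response_window[0] - 1e-9) \
        & (psth.bin_centers - psth.bin_width / 2.0 < response_window[1] - 1e-9)
    magnitude = float(psth.normalized_rate[sel].mean())

    if np.all(diffs == 0.0):
        p = 1.0
        flags.append("all_zero_differences")
    else:
        try:
            _, p = stats.wilcoxon(resp, base, zero_method="wilcox",
                                  alternative="two-sided")
            p = float(p)
        except ValueError:          # all differences zero after tie removal
            p = 1.0
            flags.append("degenerate_signed_rank")

    if p < alpha and magnitude != 0.0:
        direction = "excited" if magnitude > 0 else "inhibited"
    else:
        direction = "none"
    lat_dir = direction if direction != "none" else "auto"
    latency, ambiguous = latency_to_extreme(psth, response_window, lat_dir)
    if ambiguous:
        flags.append("flat_trace")
    return ResponseProfile(unit_id=matrix.unit_id, stimulus=matrix.stimulus,
                           window=response_window, direction=direction,
                           p_value=p, magnitude=magnitude, latency=latency,
                           flags=tuple(flags))


def classify_rmtg_profile(profiles: dict[str, ResponseProfile]) -> RmtgLabel:
    """Valence-encoding label from the per-stimulus response profiles.

    A unit is valence-encoding when it is inhibited by reward cues
    (200-400 ms window) AND excited by footshock (0-100 ms window).
    """
    unit_id = next(iter(profiles.values())).unit_id if profiles else "?"
    for needed in ("reward_cue", "footshock"):
        if needed not in profiles:
            return RmtgLabel(unit_id=unit_id, valence_encoding=False,
                             directions={s: p.direction
                                         for s, p in profiles.items()},
                             withheld_reason=f"missing stimulus {needed!r}")
    directions = {s: p.direction for s, p in profiles.items()}
    valence = (directions["reward_cue"] == "inhibited"
               and directions["footshock"] == "excited")
    return RmtgLabel(unit_id=unit_id, valence_encoding=valence,
                     directions=directions)


def response_tally(labels: list[RmtgLabel], stimulus: str) -> dict[str, int]:
    """Excitation/inhibition/none counts for one stimulus across units."""
    tally = {"excited": 0, "inhibited": 0, "none": 0}
    for label in labels:
        tally[label.directions.get(stimulus, "none")] += 1
    return tally


def classify_vta_cell_type(reward_matrix: TrialMatrix,
                           baseline_window: tuple[float, float] | None = None,
                           alpha: float = ALPHA) -> CellTypeLabel:
    """pDA / ramping / reward-inhibited typing from reward-cue trials.

    pDA: significant excitation 0-200 ms. Ramping: significant sustained
    activation 200-2000 ms (and not pDA). Reward-inhibited: significant
    inhibition 0-200 ms. Precedence pDA > ramping > reward_inhibited.
    """
    phasic = window_response_test(reward_matrix, PDA_WINDOW, baseline_window,
                                  alpha=alpha)
    sustained = window_response_test(reward_matrix, RAMPING_WINDOW,
                                     baseline_window, alpha=alpha)
    evidence = {"phasic_0_200ms": phasic.p_value,
                "sustained_200_2000ms": sustained.p_value}
    if phasic.direction == "excited":
        label = "pDA"
    elif sustained.direction == "excited":
        label = "ramping"
    elif phasic.direction == "inhibited":
        label = "reward_inhibited"
    else:
        label = "unclassified"
    return CellTypeLabel(unit_id=reward_matrix.unit_id, label=label,
                         evidence=evidence)


def classify_aversive_inhibition_type(matrix: TrialMatrix,
                                      baseline_window: tuple[float, float]
                                      | None = None,
                                      alpha: float = ALPHA) -> str:
    """pDA aversive-response typing in the 100-500 ms inhibition window.

    ``delayed_inhibition``: early (0-100 ms) excitation followed by
    100-500 ms inhibition. ``immediate_inhibition``: the inhibition
    without the early excitation. ``excitation_only``: excitation without
    the inhibition. Otherwise ``none``.
    """
    early = window_response_test(matrix, EARLY_EXCITATION_WINDOW,
                                 baseline_window, alpha=alpha)
    late = window_response_test(matrix, AVERSIVE_INHIBITION_WINDOW,
                                baseline_window, alpha=alpha)
    if late.direction == "inhibited":
        return "delayed_inhibition" if early.direction == "excited" \
            else "immediate_inhibition"
    if early.direction == "excited" or late.direction == "excited":
        return "excitation_only"
    return "none"


def classify_sustained_response(matrix: TrialMatrix, stimulus: str,
                                phase_windows_min: tuple[tuple[float, float],
                                                         tuple[float, float]]
                                | None = None,
                                baseline_min: float = SUSTAINED_BASELINE_MIN,
                                alpha: float = ALPHA) -> SustainedResponse:
    """Opponent-process typing of one unit's sustained-stimulus response.

    ``matrix`` must be a single-trial matrix binned at 60 s covering at
    least ``baseline_min`` minutes before onset. Each phase window's
    per-minute rates are tested against the baseline minutes with a
    two-sided rank-sum test; a phase extending beyond the recorded span
    is marked unavailable (p = NaN).
    """
    if phase_windows_min is None:
        phase_windows_min = SUSTAINED_PHASE_WINDOWS_MIN[stimulus]
    if abs(matrix.bin_width - 60.0) > 1e-6:
        raise ValueError("sustained classification expects 60 s bins")
    if matrix.bin_edges[0] > -baseline_min * 60.0 + 1e-6:
        raise ValueError(f"need >= {baseline_min:.0f} min pre-stimulus baseline")
    rates = np.nanmean(matrix.rates(), axis=0)
    left_min = (matrix.bin_edges[:-1]) / 60.0
    base = rates[(left_min >= -baseline_min - 1e-9) & (left_min < -1e-9)]

    results = []
    for window in phase_windows_min:
        sel = (left_min >= window[0] - 1e-9) & (left_min < window[1] - 1e-9)
        phase_rates = rates[sel]
        expected = int(round(window[1] - window[0]))
        if phase_rates.size < expected:
            results.append(PhaseResult(window, "unavailable", np.nan))
            continue
        if np.ptp(np.concatenate([phase_rates, base])) == 0.0:
            results.append(PhaseResult(window, "none", 1.0))
            continue
        _, p = stats.mannwhitneyu(phase_rates, base, alternative="two-sided")
        p = float(p)
        if p < alpha:
            direction = "excited" if np.median(phase_rates) > np.median(base) \
                else "inhibited"
        else:
            direction = "none"
        results.append(PhaseResult(window, direction, p))

    initial, rebound = results
    init_sig = initial.direction in ("excited", "inhibited")
    reb_sig = rebound.direction in ("excited", "inhibited")
    if init_sig and reb_sig:
        pattern = "biphasic"
    elif init_sig:
        pattern = "initial_only"
    elif reb_sig:
        pattern = "rebound_only"
    else:
        pattern = "none"
    return SustainedResponse(unit_id=matrix.unit_id, stimulus=stimulus,
                             initial=initial, rebound=rebound, pattern=pattern)
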