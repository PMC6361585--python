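"""Three-chamber conditioned place preference/aversion scoring.

A session is a partition of exploration time into occupancy intervals
over three chambers (stimulus-paired, unpaired, center), with side
chambers reachable only through the center. Preference is scored as
paired minus unpaired seconds (or entries); the conditioning effect is
the post-minus-pre shift of that score; locomotion is summarized by
photobeam breaks and total chamber entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHAMBERS = ("paired", "unpaired", "center")
CENTER_DEBOUNCE_S = 1.0


@dataclass(frozen=True)
class CppSession:
    """One pre- or post-conditioning free exploration."""

    phase: str                     # "pre" | "post"
    occupancy: tuple[tuple[str, float, float], ...]  # (chamber, start, end)
    photobeam_count: int = 0
    animal_id: str = "animal0"
    group: str = "sham"

    def __post_init__(self):
        validate_occupancy(self.occupancy)
        if self.photobeam_count < 0:
            raise ValueError("photobeam count must be >= 0")

    @property
    def session_length(self) -> float:
        return self.occupancy[-1][2] - self.occupancy[0][1]

    def seconds_in(self, chamber: str) -> float:
        return sum(e - s for c, s, e in self.occupancy if c == chamber)


@dataclass(frozen=True)
class PreferenceResult:
    animal_id: str
    phase: str
    score_time: float              # s, paired - unpaired
    score_entries: int             # paired - unpaired entries
    total_entries: int
    photobeam_count: int


def validate_occupancy(occupancy) -> None:
    if not occupancy:
        raise ValueError("empty occupancy log")
    prev_chamber, prev_end = None, None
    for i, (chamber, start, end) in enumerate(occupancy):
        if chamber not in CHAMBERS:
            raise ValueError(f"interval {i}: unknown chamber {chamber!r}")
        if end <= start:
            raise ValueError(f"interval {i}: end {end} <= start {start}")
        if prev_end is not None:
            if abs(start - prev_end) > 1e-9:
                raise ValueError(f"interval {i}: gap/overlap at t={start}")
            if chamber == prev_chamber:
                raise ValueError(f"interval {i}: repeated chamber {chamber!r}")
            if "center" not in (chamber, prev_chamber):
                raise ValueError(f"interval {i}: side-to-side transition "
                                 f"{prev_chamber!r} -> {chamber!r}")
        prev_chamber, prev_end = chamber, end


def entry_counts(session: CppSession,
                 center_debounce: float = CENTER_DEBOUNCE_S) -> dict[str, int]:
    """Entries per chamber (transitions into it after the first interval).

    Side-chamber entries always count; a center traversal counts as a
    center entry only when the animal dwells there at least
    ``center_debounce`` seconds.
    """
    counts = {c: 0 for c in CHAMBERS}
    for chamber, start, end in session.occupancy[1:]:
        if chamber == "center" and (end - start) < center_debounce:
            continue
        counts[chamber] += 1
    return counts


def preference_score(session: CppSession, mode: str = "time") -> float:
    """Paired-minus-unpaired seconds (``time``) or entries (``entries``);
    the center chamber is excluded from both."""
    if mode == "time":
        return session.seconds_in("paired") - session.seconds_in("unpaired")
    if mode == "entries":
        counts = entry_counts(session)
        return float(counts["paired"] - counts["unpaired"])
    raise ValueError(f"unknown mode {mode!r}")


def preference_shift(pre: float, post: float) -> float:
    """Post-conditioning preference minus pre-conditioning preference.

    Both scores must come from the same animal and the same mode; this is
    the caller's contract, enforced by :func:`summarize_animal`.
    """
    return post - pre


def locomotor_summary(session: CppSession) -> tuple[int, int]:
    """(photobeam breaks, total chamber entries)."""
    return session.photobeam_count, sum(entry_counts(session).values())


def summarize_animal(pre: CppSession, post: CppSession) -> dict:
    if pre.animal_id != post.animal_id:
        raise ValueError("pre/post sessions are from different animals")
    if (pre.phase, post.phase) != ("pre", "post"):
        raise ValueError("expected a (pre, post) session pair")
    out = {"animal_id": pre.animal_id, "group": pre.group}
    for mode in ("time", "entries"):
        s_pre = preference_score(pre, mode)
        s_post = preference_score(post, mode)
        out[f"pre_score_{mode}"] = s_pre
        out[f"post_score_{mode}"] = s_post
        out[f"shift_{mode}"] = preference_shift(s_pre, s_post)
    for phase, session in (("pre", pre), ("post", post)):
        beams, entries = locomotor_summary(session)
        out[f"{phase}_photobeam"] = beams
        out[f"{phase}_total_entries"] = entries
    return out


def group_contrast(shifts: pd.DataFrame, value: str = "shift_entries") -> dict:
    """Lesion-vs-sham contrast of preference shifts.

    ``shifts`` needs columns ``group`` (two levels), ``stimulus``, and the
    ``value`` column. With multiple stimuli: two-way ANOVA (group x
    stimulus) with Bonferroni-adjusted per-stimulus unpaired contrasts.
    With a single stimulus the ANOVA reduces to a one-factor test whose p
    equals the unpaired t-test's.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if shifts.groupby(["group", "stimulus"]).size().min() < 2:
        raise ValueError("need >= 2 animals per group x stimulus cell")
    data = shifts.rename(columns={value: "score"})[
        ["group", "stimulus", "score"]].copy()
    stimuli = sorted(data["stimulus"].unique())
    if len(stimuli) > 1:
        model = ols("score ~ C(group) * C(stimulus)", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        main_p = float(table.loc["C(group)", "PR(>F)"])
        main_f = float(table.loc["C(group)", "F"])
    else:
        model = ols("score ~ C(group)", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        main_p = float(table.loc["C(group)", "PR(>F)"])
        main_f = float(table.loc["C(group)", "F"])
    per_stim = {}
    groups = sorted(data["group"].unique())
    for stim in stimuli:
        sel = data["stimulus"] == stim
        a = data.loc[sel & (data["group"] == groups[0]), "score"]
        b = data.loc[sel & (data["group"] == groups[1]), "score"]
        _, p = stats.ttest_ind(a, b)
        per_stim[stim] = min(1.0, float(p) * len(stimuli))  # Bonferroni
    return {"main_effect_F": main_f, "main_effect_p": main_p,
            "per_stimulus_p_bonferroni": per_stim, "groups": groups}


def entry_reduction_test(pre_entries, post_entries) -> tuple[float, float]:
    """Paired t-test of total entries before vs after conditioning."""
    t, p = stats.ttest_rel(np.asarray(pre_entries, dtype=float),
                           np.asarray(post_entries, dtype=float))
    return float(t), float(p)


def occupancy_to_frame(session: CppSession) -> pd.DataFrame:
    return pd.DataFrame(list(session.occupancy),
                        columns=["chamber", "start_s", "end_s"])


def frame_to_session(frame: pd.DataFrame, phase: str = "pre",
                     photobeam_count: int = 0, animal_id: str = "animal0",
                     group: str = "sham") -> CppSession:
    occupancy = tuple(frame[["chamber", "start_s", "end_s"]]
                      .itertuples(index=False, name=None))
    return CppSession(phase=phase, occupancy=occupancy,
                      photobeam_count=photobeam_count,
                      animal_id=animal_id, group=group)
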