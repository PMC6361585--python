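"""Score the conditioned place test and contrast lesion vs sham groups.

Reads the occupancy logs, scores each session (time and entry modes),
averages each animal's three baseline exploration days into its pre
score, computes the post-minus-pre preference shift, and tests the
lesion-vs-sham contrast of shifts plus the conditioning-induced change
in total entries within each group.
"""

import json
from pathlib import Path

import pandas as pd

from rmtg_valence import cpp

DATA = Path(__file__).resolve().parents[1] / "results" / "data" / "cpp"
OUT = Path(__file__).resolve().parents[1] / "results" / "cpp"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    records = json.loads((DATA / "sessions.json").read_text())
    sessions: dict[str, dict[str, cpp.CppSession]] = {}
    for record in records:
        frame = pd.read_csv(DATA / f"{record['animal']}_{record['phase']}.csv")
        session = cpp.frame_to_session(frame, phase=record["phase"],
                                       photobeam_count=record["photobeam"],
                                       animal_id=record["animal"],
                                       group=record["group"])
        sessions.setdefault(record["animal"], {})[record["phase"]] = session

    rows = []
    for animal, by_phase in sessions.items():
        pre = [s for phase, s in by_phase.items() if phase.startswith("pre")]
        post = by_phase["post"]
        row = {"animal_id": animal, "group": post.group}
        for mode in ("time", "entries"):
            pre_score = sum(cpp.preference_score(s, mode)
                            for s in pre) / len(pre)
            post_score = cpp.preference_score(post, mode)
            row[f"pre_score_{mode}"] = pre_score
            row[f"post_score_{mode}"] = post_score
            row[f"shift_{mode}"] = cpp.preference_shift(pre_score, post_score)
        row["pre_total_entries"] = sum(
            cpp.locomotor_summary(s)[1] for s in pre) / len(pre)
        row["post_total_entries"] = cpp.locomotor_summary(post)[1]
        row["post_photobeam"] = post.photobeam_count
        rows.append(row)

    scores = pd.DataFrame(rows)
    scores["stimulus"] = "licl"       # single-stimulus design in this dataset
    scores.to_csv(OUT / "preference_scores.csv", index=False)

    for mode in ("time", "entries"):
        means = scores.groupby("group")[f"shift_{mode}"].mean()
        print(f"mean shift ({mode}): " + ", ".join(
            f"{g} = {v:.1f}" for g, v in means.items()))
        contrast = cpp.group_contrast(scores, value=f"shift_{mode}")
        print(f"  lesion main effect p = {contrast['main_effect_p']:.4f}")

    for group, sub in scores.groupby("group"):
        t, p = cpp.entry_reduction_test(sub["pre_total_entries"],
                                        sub["post_total_entries"])
        print(f"{group}: total entries pre {sub['pre_total_entries'].mean():.1f}"
              f" -> post {sub['post_total_entries'].mean():.1f}"
              f" (paired t = {t:.2f}, p = {p:.4f})")


if __name__ == "__main__":
    main()
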