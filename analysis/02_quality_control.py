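"""Apply unit acceptance rules to the simulated phasic session.

Blanks the first 10 ms after every footshock, then checks each unit's
refractory-violation fraction (< 0.2% of ISIs under 1 ms) and baseline
drift (Spearman trend across session windows). The two planted defective
units should be the ones rejected.
"""

import json
from pathlib import Path

import pandas as pd

from rmtg_valence import qc, synthetic_data as sd

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    meta = json.loads((DATA / "phasic_meta.json").read_text())
    span = (0.0, meta["session_length_s"])
    spikes = pd.read_csv(DATA / "phasic_spikes.csv")
    events = pd.read_csv(DATA / "phasic_events.csv")
    trains = sd.frame_to_spikes(spikes, span)
    shock_onsets = events.loc[events["label"] == "footshock", "onset_s"].values

    n_windows = max(4, int(span[1] // 600))
    windows = [(i * span[1] / n_windows, (i + 1) * span[1] / n_windows)
               for i in range(n_windows)]
    rows = []
    for train in trains:
        blanked = qc.blank_shock_artifact(train, shock_onsets)
        result = qc.evaluate_unit(blanked, windows)
        rows.append({"unit_id": result.unit_id,
                     "violation_fraction": result.refractory_violation_fraction,
                     "drift_p": result.drift_p,
                     "accepted": result.accepted,
                     "reasons": ";".join(result.reasons)})
    report = pd.DataFrame(rows).sort_values("unit_id")
    report.to_csv(OUT / "qc_report.csv", index=False)
    rejected = report[~report["accepted"]]
    print(f"accepted {report['accepted'].sum()}/{len(report)} units")
    print("rejected:", ", ".join(f"{r.unit_id} ({r.reasons})"
                                 for r in rejected.itertuples()))


if __name__ == "__main__":
    main()
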