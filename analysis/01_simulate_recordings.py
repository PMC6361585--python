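"""Simulate the full synthetic study and write the raw data tables.

Generates (a) an RMTg-like phasic recording session — 50 reward-cue
trials then interleaved footshock/siren/bright-light trials — over a
mixed population (valence-encoding, aversive-only, reward-inhibited,
unresponsive units, plus units with injected QC defects), (b) a
sustained LiCl session with opponent biphasic units, (c) projection-
labeled calcium traces, and (d) pre/post place-conditioning logs.
Everything is seeded; ground truth is saved alongside the data.
"""

import json
from pathlib import Path

from rmtg_valence import psth, synthetic_data as sd
from rmtg_valence.cpp import occupancy_to_frame
from rmtg_valence.psth import EventSchedule

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    reward = psth.make_schedule([("reward_cue", 50, 2.0)], interval=30.0,
                                start=30.0)
    aversive = psth.make_schedule(
        [("footshock", 30, 0.01), ("siren", 30, 1.0), ("bright_light", 30, 2.0)],
        interval=30.0, start=reward.end + 30.0, interleave=True, seed=SEED)
    schedule = EventSchedule(reward.events + aversive.events)
    spec = [(sd.make_archetype("valence_encoding", "val", gain_scale_sd=0.4), 20),
            (sd.make_archetype("aversive_only", "avr"), 8),
            (sd.make_archetype("reward_inhibited_only", "rwi"), 6),
            (sd.make_archetype("unresponsive", "bg"), 20)]
    defective = sd.UnitGenConfig(
        "defect_refractory", 10.0,
        defects=sd.Defects(refractory_violation_fraction=0.01))
    drifting = sd.UnitGenConfig("defect_drift", 10.0,
                                defects=sd.Defects(drift_slope=-0.15))
    spec += [(defective, 1), (drifting, 1)]
    trains, truth = sd.generate_population(spec, schedule, schedule.end + 30.0,
                                           seed=SEED)
    sd.spikes_to_frame(trains).to_csv(OUT / "phasic_spikes.csv", index=False)
    sd.schedule_to_frame(schedule).to_csv(OUT / "phasic_events.csv",
                                          index=False)
    (OUT / "phasic_truth.json").write_text(sd.truth_to_json(truth))
    (OUT / "phasic_meta.json").write_text(json.dumps(
        {"seed": SEED, "session_length_s": schedule.end + 30.0}, indent=2))
    print(f"phasic: {len(trains)} units, "
          f"{sum(t.n_spikes for t in trains)} spikes, "
          f"{len(schedule.events)} events")

    onset = 900.0
    sustained = EventSchedule((("licl", onset, 600.0),))
    sus_spec = [(sd.make_archetype("licl_biphasic", "bip"), 12),
                (sd.make_archetype("saline", "sal"), 10)]
    sus_trains, sus_truth = sd.generate_population(sus_spec, sustained,
                                                   onset + 1860.0,
                                                   seed=SEED + 1)
    sd.spikes_to_frame(sus_trains).to_csv(OUT / "sustained_spikes.csv",
                                          index=False)
    sd.schedule_to_frame(sustained).to_csv(OUT / "sustained_events.csv",
                                           index=False)
    (OUT / "sustained_truth.json").write_text(sd.truth_to_json(sus_truth))
    print(f"sustained: {len(sus_trains)} units over "
          f"{(onset + 1860.0) / 60:.0f} min")

    k = sd.ResponseKernel
    vta_cfg = sd.UnitGenConfig(
        "vta", 5.0, kernels=(k("reward_cue", 0.2, 1.0, 0.1),
                             k("footshock", 0.0, 1.0, 6.0)),
        gain_scale_sd=0.5, projection_target="VTA")
    drn_cfg = sd.UnitGenConfig("drn", 5.0,
                               kernels=(k("footshock", 0.0, 1.0, 6.0),),
                               projection_target="DRN")
    ca_schedule = EventSchedule(
        psth.make_schedule([("reward_cue", 30, 2.0)], interval=30.0,
                           start=15.0).events
        + psth.make_schedule([("footshock", 30, 0.01)], interval=30.0,
                             start=915.0).events)
    traces, ca_truth = sd.generate_calcium_traces(
        [(vta_cfg, 25), (drn_cfg, 25)], ca_schedule, ca_schedule.end + 15.0,
        noise_sd=0.02, seed=SEED + 2)
    sd.calcium_to_frame(traces).to_csv(OUT / "calcium_dff.csv", index=False)
    sd.schedule_to_frame(ca_schedule).to_csv(OUT / "calcium_events.csv",
                                             index=False)
    (OUT / "calcium_meta.json").write_text(json.dumps(
        {"sample_rate_hz": 5.0,
         "projection": {t.cell_id: t.projection_target for t in traces}},
        indent=2))
    print(f"calcium: {len(traces)} cells at 5 Hz")

    cpp_dir = OUT / "cpp"
    cpp_dir.mkdir(exist_ok=True)
    sessions = []
    # planted contrast: sham animals acquire a strong aversion to the
    # paired chamber (entry bias 0.5 -> 0.25) plus conditioned slowing
    # (longer dwells); lesion animals shift only weakly (0.5 -> 0.45) and
    # keep their locomotion. The baseline preference is averaged over
    # three unbiased pre-exploration days, as in the conditioning design.
    for group, bias_post, dwell_post, offset in (
            ("sham", 0.25, 15.0, 0), ("lesion", 0.45, 12.0, 1000)):
        for i in range(8):
            animal = f"{group}{i:02d}"
            day_seed = SEED + 10 + offset + 8 * i
            batch = [sd.generate_cpp_session(0.5, 12.0, 900.0,
                                             seed=day_seed + day,
                                             phase=f"pre{day}",
                                             animal_id=animal, group=group)
                     for day in range(1, 4)]
            batch.append(sd.generate_cpp_session(bias_post, dwell_post, 900.0,
                                                 seed=day_seed + 4,
                                                 phase="post",
                                                 animal_id=animal,
                                                 group=group))
            for session in batch:
                occupancy_to_frame(session).to_csv(
                    cpp_dir / f"{animal}_{session.phase}.csv", index=False)
                sessions.append({"animal": animal, "group": group,
                                 "phase": session.phase,
                                 "photobeam": session.photobeam_count})
    (cpp_dir / "sessions.json").write_text(json.dumps(sessions, indent=2))
    print(f"cpp: {len(sessions)} sessions across 16 animals")


if __name__ == "__main__":
    main()
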