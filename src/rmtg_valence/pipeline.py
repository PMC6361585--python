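"""Configuration-driven orchestration of the full analysis.

``run(config)`` synthesizes (or loads) spike trains, applies QC and
shock-artifact blanking, builds PSTHs, classifies per-neuron responses,
computes population statistics and burst metrics, scores place
conditioning, and returns a structured report bundle (also written as
CSV/JSON when an output directory is configured). Deterministic under
fixed seeds.

The default window definitions are the study's core analytic
commitments and are checked into the repo (``configs/defaults.yaml``)
as well as mirrored in :data:`DEFAULT_CONFIG`.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, burst_metrics, cpp, population_analysis, psth, qc, \
    response_stats, synthetic_data

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha": 0.05,
    "normalization": "zscore",
    "output_dir": None,
    "windows": {
        "reward_cue": [0.2, 0.4],
        "neutral_tone": [0.0, 0.1],
        "footshock": [0.0, 0.1],
        "siren": [0.0, 0.1],
        "bright_light": [0.0, 0.1],
        "pda": [0.0, 0.2],
        "ramping": [0.2, 2.0],
        "aversive_inhibition": [0.1, 0.5],
    },
    "phasic": {
        "bin_width_s": 0.05,
        "baseline_s": 1.0,
        "n_reward_trials": 50,
        "n_aversive_trials": 30,
        "trial_interval_s": 30.0,
        "population": {"valence_encoding": 8, "aversive_only": 4,
                       "reward_inhibited_only": 3, "unresponsive": 5},
        "baseline_rate_hz": 10.0,
        "gain_excite": 3.0,
        "gain_inhibit": 0.2,
        "gain_scale_sd": 0.4,
    },
    "sustained": {
        "stimulus": "licl",
        "population": {"licl_biphasic": 8, "saline": 8},
        "baseline_min": 15.0,
    },
    "cpp": {
        "n_animals": 8,
        "bias_pre": 0.5,
        "bias_post": 0.3,
        "mean_dwell_s": 20.0,
        "session_length_s": 900.0,
    },
}

AVERSIVE_STIMULI = ("footshock", "siren", "bright_light")


def load_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    config = copy.deepcopy(DEFAULT_CONFIG)
    _deep_update(config, loaded)
    return config


def _deep_update(base: dict, update: dict) -> None:
    for key, value in update.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def validate_config(config: dict) -> None:
    if not 0.0 < config["alpha"] < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    windows = config["windows"]
    for stim in ("reward_cue",) + AVERSIVE_STIMULI:
        if stim not in windows:
            raise ValueError(f"no response window configured for {stim!r}")
    for name, (lo, hi) in windows.items():
        if hi <= lo:
            raise ValueError(f"window {name!r} is empty")


def _phasic_schedule(cfg: dict, seed: int) -> psth.EventSchedule:
    blocks = [("reward_cue", cfg["n_reward_trials"], 2.0)]
    aversive = [("footshock", cfg["n_aversive_trials"], 0.01),
                ("siren", cfg["n_aversive_trials"], 1.0),
                ("bright_light", cfg["n_aversive_trials"], 2.0)]
    reward_part = psth.make_schedule(blocks, interval=cfg["trial_interval_s"])
    start = reward_part.end + cfg["trial_interval_s"]
    aversive_part = psth.make_schedule(aversive,
                                       interval=cfg["trial_interval_s"],
                                       start=start, interleave=True, seed=seed)
    return psth.EventSchedule(reward_part.events + aversive_part.events)


def _pop_spec(population: dict[str, int], baseline: float, gain_excite: float,
              gain_inhibit: float, prefix: str = "unit",
              gain_scale_sd: float = 0.0):
    spec = []
    for name, count in population.items():
        if count < 1:
            continue
        spec.append((synthetic_data.make_archetype(
            name, f"{prefix}_{name}", baseline_rate=baseline,
            gain_excite=gain_excite, gain_inhibit=gain_inhibit,
            gain_scale_sd=gain_scale_sd), count))
    return spec


def run(config: dict | None = None) -> dict:
    """Execute the configured analysis end to end; returns the report."""
    config = copy.deepcopy(DEFAULT_CONFIG) if config is None \
        else _merged(config)
    validate_config(config)
    seed = int(config["seed"])
    alpha = float(config["alpha"])

    report: dict = {
        "provenance": {
            "software_version": __version__,
            "config": copy.deepcopy(config),
            "windows": copy.deepcopy(config["windows"]),
        },
    }
    report["phasic"] = _run_phasic(config, seed, alpha)
    if config.get("sustained"):
        report["sustained"] = _run_sustained(config, seed + 1, alpha)
    if config.get("cpp"):
        report["cpp"] = _run_cpp(config, seed + 2)

    out_dir = config.get("output_dir")
    if out_dir:
        _write_report(report, Path(out_dir))
    return report


def _merged(config: dict) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    _deep_update(merged, config)
    return merged


def _run_phasic(config: dict, seed: int, alpha: float) -> dict:
    cfg = config["phasic"]
    windows = {k: tuple(v) for k, v in config["windows"].items()}
    schedule = _phasic_schedule(cfg, seed)
    session_length = schedule.end + 30.0
    spec = _pop_spec(cfg["population"], cfg["baseline_rate_hz"],
                     cfg["gain_excite"], cfg["gain_inhibit"],
                     gain_scale_sd=cfg.get("gain_scale_sd", 0.0))
    trains, truth = synthetic_data.generate_population(
        spec, schedule, session_length, seed)

    shock_onsets = schedule.onsets("footshock")
    n_qc_windows = max(2, int(session_length // 300))
    qc_windows = [(i * session_length / n_qc_windows,
                   (i + 1) * session_length / n_qc_windows)
                  for i in range(n_qc_windows)]

    qc_rows, unit_rows, accepted = [], [], []
    for train in trains:
        blanked = qc.blank_shock_artifact(train, shock_onsets)
        result = qc.evaluate_unit(blanked, qc_windows, alpha=alpha)
        qc_rows.append(result)
        if result.accepted:
            accepted.append(blanked)

    labels, profiles_by_unit = [], {}
    baseline = None  # duration-matched pairing (see response_stats)
    for train in accepted:
        profiles = {}
        for stim in ("reward_cue", "neutral_tone") + AVERSIVE_STIMULI:
            if schedule.onsets(stim).size == 0:
                continue
            post = max(windows.get(stim, (0, 0.6))[1], 0.6)
            matrix = psth.align_and_bin(train, schedule, stim,
                                        window=(cfg["baseline_s"], post),
                                        bin_width=cfg["bin_width_s"])
            window = windows.get(stim, (0.0, 0.1))
            profiles[stim] = response_stats.window_response_test(
                matrix, window, baseline, alpha=alpha)
        profiles_by_unit[train.unit_id] = profiles
        labels.append(response_stats.classify_rmtg_profile(profiles))
        stats_b = burst_metrics.detect_bursts(train)
        unit_rows.append({
            "unit_id": train.unit_id,
            "valence_encoding": labels[-1].valence_encoding,
            "pct_spikes_in_bursts": stats_b.pct_spikes_in_bursts,
            "baseline_rate_hz": burst_metrics.baseline_rate(
                train, (0.0, min(30.0, session_length))),
            **{f"{s}_direction": p.direction for s, p in profiles.items()},
            **{f"{s}_p": p.p_value for s, p in profiles.items()},
            **{f"{s}_magnitude": p.magnitude for s, p in profiles.items()},
            **{f"{s}_latency_s": p.latency for s, p in profiles.items()},
        })

    tallies = {stim: response_stats.response_tally(labels, stim)
               for stim in ("reward_cue",) + AVERSIVE_STIMULI}
    correlations = _shock_correlations(profiles_by_unit)
    truth_fraction = truth.fraction(lambda u: u.valence_encoding)
    recovered_fraction = (sum(l.valence_encoding for l in labels)
                          / len(labels)) if labels else 0.0
    return {
        "n_units": len(trains),
        "n_accepted": len(accepted),
        "qc": [vars(r) | {"reasons": list(r.reasons)} for r in qc_rows],
        "units": unit_rows,
        "tallies": tallies,
        "correlations": correlations,
        "planted_valence_fraction": truth_fraction,
        "recovered_valence_fraction": recovered_fraction,
    }


def _shock_correlations(profiles_by_unit: dict) -> dict:
    out = {}
    units = [p for p in profiles_by_unit.values()
             if "footshock" in p and p["footshock"].direction == "excited"]
    shock = np.array([p["footshock"].magnitude for p in units])
    for other in ("siren", "bright_light"):
        mags = np.array([p[other].magnitude for p in units if other in p])
        if mags.size >= 3 and shock.size == mags.size and np.ptp(shock) > 0 \
                and np.ptp(mags) > 0:
            res = population_analysis.correlate_responses(
                shock, mags, x_label="footshock", y_label=other)
            out[other] = {"r_squared": res.r_squared, "p": res.p,
                          "n": res.n, "slope": res.slope}
    return out


def _run_sustained(config: dict, seed: int, alpha: float) -> dict:
    cfg = config["sustained"]
    stimulus = cfg["stimulus"]
    baseline_min = float(cfg["baseline_min"])
    onset = baseline_min * 60.0
    session_length = onset + 1860.0
    schedule = psth.EventSchedule(((stimulus, onset, 600.0),))
    spec = _pop_spec(cfg["population"], config["phasic"]["baseline_rate_hz"],
                     config["phasic"]["gain_excite"],
                     config["phasic"]["gain_inhibit"], prefix="sus")
    trains, truth = synthetic_data.generate_population(
        spec, schedule, session_length, seed)

    rows = []
    phase_values = {"baseline": [], "initial": [], "rebound": []}
    phase_windows = response_stats.SUSTAINED_PHASE_WINDOWS_MIN[stimulus]
    for train in trains:
        matrix = psth.align_and_bin(train, schedule, stimulus,
                                    window=(onset, session_length - onset),
                                    bin_width=60.0)
        result = response_stats.classify_sustained_response(
            matrix, stimulus, alpha=alpha)
        rows.append({"unit_id": train.unit_id, "pattern": result.pattern,
                     "initial_direction": result.initial.direction,
                     "initial_p": result.initial.p,
                     "rebound_direction": result.rebound.direction,
                     "rebound_p": result.rebound.p})
        rates = np.nanmean(matrix.rates(), axis=0)
        left_min = matrix.bin_edges[:-1] / 60.0
        phase_values["baseline"].append(
            rates[(left_min >= -baseline_min) & (left_min < 0)].mean())
        for name, window in zip(("initial", "rebound"), phase_windows):
            sel = (left_min >= window[0]) & (left_min < window[1])
            phase_values[name].append(rates[sel].mean())

    group_test = population_analysis.group_time_course_test(
        pd.DataFrame(phase_values), baseline="baseline", alpha=alpha)
    biphasic = sum(r["pattern"] == "biphasic" for r in rows)
    planted = truth.fraction(
        lambda u: u.categories.get(stimulus) == "biphasic")
    return {"stimulus": stimulus, "units": rows,
            "n_biphasic": biphasic,
            "planted_biphasic_fraction": planted,
            "recovered_biphasic_fraction": biphasic / len(rows) if rows else 0.0,
            "group_time_course": group_test}


def _run_cpp(config: dict, seed: int) -> dict:
    cfg = config["cpp"]
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(cfg["n_animals"] * 2)
    for i in range(cfg["n_animals"]):
        pre = synthetic_data.generate_cpp_session(
            cfg["bias_pre"], cfg["mean_dwell_s"], cfg["session_length_s"],
            seed=seeds[2 * i], phase="pre", animal_id=f"animal{i:02d}")
        post = synthetic_data.generate_cpp_session(
            cfg["bias_post"], cfg["mean_dwell_s"], cfg["session_length_s"],
            seed=seeds[2 * i + 1], phase="post", animal_id=f"animal{i:02d}")
        rows.append(cpp.summarize_animal(pre, post))
    frame = pd.DataFrame(rows)
    return {"animals": rows,
            "mean_shift_time_s": float(frame["shift_time"].mean()),
            "mean_shift_entries": float(frame["shift_entries"].mean())}


# ---------------------------------------------------------------------------
# report output and schema
# ---------------------------------------------------------------------------

REPORT_SCHEMA: dict = {
    "provenance": {"software_version": str, "config": dict, "windows": dict},
    "phasic": {"n_units": int, "n_accepted": int, "qc": list, "units": list,
               "tallies": dict, "correlations": dict,
               "planted_valence_fraction": float,
               "recovered_valence_fraction": float},
}


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check required keys and value types of the report bundle."""
    schema = REPORT_SCHEMA if schema is None else schema
    for key, expected in schema.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        value = report[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ValueError(f"report[{key!r}] must be a mapping")
            validate_report(value, expected)
        elif not isinstance(value, expected):
            raise ValueError(f"report[{key!r}] must be {expected.__name__}")


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify, sort_keys=True)
    pd.DataFrame(report["phasic"]["units"]).to_csv(
        out_dir / "unit_classification.csv", index=False)
    pd.DataFrame(report["phasic"]["qc"]).to_csv(
        out_dir / "qc_report.csv", index=False)
    if "sustained" in report:
        pd.DataFrame(report["sustained"]["units"]).to_csv(
            out_dir / "sustained_classification.csv", index=False)
    if "cpp" in report:
        pd.DataFrame(report["cpp"]["animals"]).to_csv(
            out_dir / "cpp_scores.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def main(argv=None) -> int:
    """Run the bundled demo analysis: ``python -m rmtg_valence.pipeline``."""
    import argparse

    parser = argparse.ArgumentParser(description=run.__doc__)
    parser.add_argument("--config", default=None, help="YAML config path")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--out", default=None, help="output directory")
    args = parser.parse_args(argv)
    config = load_config(args.config) if args.config \
        else copy.deepcopy(DEFAULT_CONFIG)
    if args.seed is not None:
        config["seed"] = args.seed
    if args.out is not None:
        config["output_dir"] = args.out
    report = run(config)
    validate_report(report)
    phasic = report["phasic"]
    print(f"units: {phasic['n_units']}  accepted: {phasic['n_accepted']}  "
          f"valence-encoding: planted {phasic['planted_valence_fraction']:.2f} "
          f"recovered {phasic['recovered_valence_fraction']:.2f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
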