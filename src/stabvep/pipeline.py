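"""Session-level workflow: simulate → features → classification → stability →
VEP → report, driven by a YAML configuration.

``run_analyze`` reads a recording + hypnogram, builds the per-epoch feature
table, classifies wake substates, stratifies the configured states by beta
power, computes the stability summary and the state-sorted VEP tables, and
writes everything plus a run manifest (config hash, input checksums, versions,
exclusion counts). Reruns on identical inputs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .recording import extract_stimulus_train
from . import recording_io, simulate, spectral, stability, substate, vep

log = logging.getLogger("stabvep")

DEFAULT_ANALYSIS: dict = {
    "recording": None,          # path to EDF or delimited signals
    "hypnogram": None,          # path to delimited hypnogram
    "dialect": None,            # EDF | DELIMITED | null (infer from suffix)
    "bands": [["delta", 1.0, 4.0], ["theta", 5.0, 8.0],
              ["alpha", 9.0, 12.0], ["beta", 15.0, 35.0]],
    "stratify_states": ["QW", "AW"],
    "signed_change": False,
    "min_trials": 10,
    "vep_group_by": ["state", "beta_class", "interval"],
    "delimiter": ",",
    "out_dir": "results",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_analysis_config(source) -> dict:
    cfg = dict(DEFAULT_ANALYSIS)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        loaded = yaml.safe_load(Path(source).read_text())
    else:
        loaded = dict(source)
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise PipelineError(f"unknown analysis config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def run_analyze(config, out_dir=None) -> Path:
    """Execute the full analysis; returns the output directory.

    Fails fast — all configured input paths are checked before any signal
    processing; a stage error aborts with the stage name in the message.
    """
    cfg = load_analysis_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    for key in ("recording", "hypnogram"):
        if cfg[key] is None:
            raise PipelineError(f"analysis config must set {key!r}")
        if not Path(cfg[key]).exists():
            raise PipelineError(f"input check: missing {key} file {cfg[key]}")

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    sep = cfg["delimiter"]

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed on {cfg['recording']}: {exc}") from exc

    rec = stage("read_recording", recording_io.read_recording, cfg["recording"], cfg["dialect"])
    hyp = stage("read_hypnogram", recording_io.read_hypnogram, cfg["hypnogram"])
    train = stage("extract_stimulus_train", extract_stimulus_train, rec)
    bands = tuple(spectral.BandDefinition(*b) for b in cfg["bands"])
    features = stage("epoch_features", spectral.build_epoch_features, rec, hyp, bands)
    hyp = stage("classify_wake_substates", substate.classify_wake_substates, features, hyp)
    features["wake_substate"] = hyp.wake_substates[features["epoch_index"].to_numpy()]
    n_skipped_strata = 0
    for state in cfg["stratify_states"]:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            features = stage("stratify_by_beta", substate.stratify_by_beta, features, state)
            n_skipped_strata += len(caught)
    stab = stage("stability_summary", stability.stability_summary,
                 features, hyp, signed=cfg["signed_change"])

    waveforms, exclusions = stage(
        "vep", vep.sort_and_average, rec, train, hyp,
        features=features, group_by=tuple(cfg["vep_group_by"]),
        min_trials=cfg["min_trials"],
    )
    state_waveforms, state_exclusions = stage(
        "vep_by_state", vep.sort_and_average, rec, train, hyp,
        features=features, group_by=("state",), min_trials=cfg["min_trials"],
    )

    def magnitude_table(wfs, group_by):
        rows = []
        for label, w in sorted(wfs.items()):
            row = dict(zip(group_by, label))
            row["magnitude_uv"] = vep.vep_magnitude(w)
            row["n_trials"] = w.n_trials
            rows.append(row)
        return pd.DataFrame(rows, columns=[*group_by, "magnitude_uv", "n_trials"])

    recording_io.write_epoch_table(features, out / "epoch_features.csv", sep)
    stab.to_csv(out / "stability_summary.csv", sep=sep, index=False)
    magnitude_table(state_waveforms, ("state",)).to_csv(
        out / "vep_state_magnitudes.csv", sep=sep, index=False)
    magnitude_table(waveforms, tuple(cfg["vep_group_by"])).to_csv(
        out / "vep_group_magnitudes.csv", sep=sep, index=False)

    wf_rows = []
    for label, w in sorted(state_waveforms.items()):
        wf_rows.append(pd.DataFrame({
            "group": "/".join(label), "time_s": w.time_s,
            "mean_uv": w.mean_uv, "n_trials": w.n_trials,
        }))
    (pd.concat(wf_rows, ignore_index=True) if wf_rows
     else pd.DataFrame(columns=["group", "time_s", "mean_uv", "n_trials"])
     ).to_csv(out / "vep_waveforms.csv", sep=sep, index=False)

    manifest = {
        "package": "stabvep",
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "inputs": {k: {"path": str(cfg[k]), "sha256": _sha256(Path(cfg[k]))}
                   for k in ("recording", "hypnogram")},
        "counts": {
            "epochs": int(len(features)),
            "stimuli": int(train.n_stimuli),
            "vep_exclusions": exclusions,
            "vep_state_exclusions": state_exclusions,
            "skipped_beta_strata": n_skipped_strata,
        },
        "outputs": ["epoch_features.csv", "stability_summary.csv",
                    "vep_state_magnitudes.csv", "vep_group_magnitudes.csv",
                    "vep_waveforms.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("analysis complete: %s", out)
    return out


def run_simulate(preset_or_config, out_dir, seed: int, dialect: str = "EDF") -> Path:
    """Generate a session fixture directory from a preset name, a YAML path,
    or a SimulationConfig."""
    if isinstance(preset_or_config, simulate.SimulationConfig):
        cfg = preset_or_config
    elif isinstance(preset_or_config, str) and preset_or_config in simulate.PRESETS:
        cfg = simulate.preset_config(preset_or_config)
    elif isinstance(preset_or_config, dict):
        cfg = simulate.SimulationConfig.from_dict(preset_or_config)
    else:
        cfg = simulate.SimulationConfig.from_yaml(preset_or_config)
    paths = simulate.generate_session(cfg, out_dir, seed, dialect=dialect)
    log.info("simulated session in %s", out_dir)
    return Path(out_dir), paths


def analysis_config_for_session(session_dir, out_dir=None) -> dict:
    """Analysis config pointing at a generate_session fixture directory."""
    session_dir = Path(session_dir)
    rec = next((p for p in (session_dir / "recording.edf",
                            session_dir / "recording.csv") if p.exists()), None)
    if rec is None:
        raise PipelineError(f"no recording.edf/recording.csv in {session_dir}")
    cfg = dict(DEFAULT_ANALYSIS)
    cfg["recording"] = str(rec)
    cfg["hypnogram"] = str(session_dir / "hypnogram.csv")
    cfg["out_dir"] = str(out_dir or session_dir / "results")
    return cfg


def run_report(results_dir, plots: bool = False) -> Path:
    """Summarize analysis outputs: a state × band stability matrix, per-state
    and per-group VEP magnitudes, written as a markdown report (and optional
    PNG bar charts). Regeneration is deterministic; absent groups stay absent."""
    results = Path(results_dir)
    needed = {name: results / f"{name}.csv" for name in
              ("stability_summary", "vep_state_magnitudes", "vep_group_magnitudes")}
    for name, path in needed.items():
        if not path.exists():
            raise PipelineError(f"report: missing table {path}")
    stab = pd.read_csv(needed["stability_summary"])
    vep_state = pd.read_csv(needed["vep_state_magnitudes"])
    vep_groups = pd.read_csv(needed["vep_group_magnitudes"])

    matrix = stab.pivot(index="state", columns="band", values="p90_change_pct")
    matrix.to_csv(results / "stability_matrix_p90.csv")

    def block(df, index=False):
        return "```\n" + df.round(2).to_string(index=index) + "\n```"

    lines = ["# Analysis report", "",
             "## Epoch-by-epoch band-power instability (90th percentile change, %)", "",
             block(matrix, index=True), "",
             "## VEP magnitude by vigilance state (μV)", "",
             (block(vep_state) if len(vep_state)
              else "(no state reached the trial minimum)"), "",
             "## VEP magnitude by analysis group (μV)", "",
             (block(vep_groups) if len(vep_groups)
              else "(no group reached the trial minimum)"), ""]
    report = results / "report.md"
    report.write_text("\n".join(lines))

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        if len(vep_state):
            axes[0].bar(vep_state["state"], vep_state["magnitude_uv"], color="0.4")
        axes[0].set_ylabel("VEP magnitude (μV)")
        axes[0].set_title("VEP by vigilance state")
        beta = stab[stab["band"] == "beta"]
        axes[1].bar(beta["state"], beta["p90_change_pct"], color="0.4")
        axes[1].set_ylabel("p90 beta change (%)")
        axes[1].set_title("Beta instability by state")
        fig.tight_layout()
        fig.savefig(results / "report.png", dpi=120)
        plt.close(fig)
    return report
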