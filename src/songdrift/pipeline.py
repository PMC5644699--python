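"""End-to-end pipeline: stimuli -> synthetic cohort -> fit -> metrics/dynamics.

Drives the full analysis from a single structured-text (YAML) configuration
and writes every artifact, plus a manifest recording the configuration,
seeds, package versions and SHA-256 hashes of all outputs, into one output
directory.  Rerunning with the same configuration reproduces all outputs
bit-exactly (everything downstream of the seeds is deterministic).

Configuration schema (all sections optional unless noted)::

    seed: 1                  # global seed; stage seeds derive from it
    stimuli:
      n_songs: 35            # songs per set
      length: 33             # subunits per song
      sets:                  # default: the seven standard pairs
        - {set_id: mollis, positive: block, negative: mollis}
    truth:                   # ground-truth model for the synthetic cohort
      weights: {mollis: -87.0, block: 1.0}   # default: reference weights
      sigma: 142.0
      theta_plus: 420.0
      theta_minus: -803.0
    cohort:
      n_females: 20
      n_cycles: 18
      control_response_prob: 0.02
      exclusion_threshold: 2
    fit:
      enabled: true
      population: 48
      generations: 30
      loocv: false           # full leave-one-out pass (slow)
    dynamics:
      enabled: true
      n_reps: 50000          # Monte-Carlo repetitions for mean trajectories
"""
from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ddm import DDMParams, DynamicsConfig, first_passage_profile, mean_trajectory
from .errors import ConfigError
from .fitting import FitConfig, GAConfig, fit, loocv
from .metrics import set_metrics_table, thirds_decomposition
from .reference import REFERENCE_PARAMS, SET_PAIRS
from .stimuli import (
    StimulusSetConfig,
    build_song,
    build_stimulus_set,
    default_catalog,
    songs_to_frame,
)
from .synth import SyntheticCohortConfig, generate_cohort, recovery_report


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path_or_dict} must be a mapping")
    return cfg


def _truth_params(cfg: dict) -> DDMParams:
    section = cfg.get("truth")
    if not section:
        return REFERENCE_PARAMS
    try:
        return DDMParams(
            weights=dict(section["weights"]),
            sigma=float(section["sigma"]),
            theta_plus=float(section["theta_plus"]),
            theta_minus=float(section["theta_minus"]),
        )
    except KeyError as exc:
        raise ConfigError(f"truth section missing key: {exc}") from None


def _set_configs(cfg: dict, seed: int) -> list[StimulusSetConfig]:
    stim = cfg.get("stimuli", {})
    n_songs = int(stim.get("n_songs", 35))
    length = int(stim.get("length", 33))
    sets = stim.get("sets")
    if sets is None:
        sets = [
            {"set_id": sid, "positive": pos, "negative": neg}
            for sid, (pos, neg) in SET_PAIRS.items()
        ]
    out = []
    for i, s in enumerate(sets):
        try:
            out.append(
                StimulusSetConfig(
                    set_id=str(s["set_id"]),
                    positive=str(s["positive"]),
                    negative=str(s["negative"]),
                    n_songs=n_songs,
                    length=length,
                    seed=seed + i,
                )
            )
        except KeyError as exc:
            raise ConfigError(f"stimuli.sets[{i}] missing key: {exc}") from None
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute the configured stages and write a manifest.

    Returns the output directory.  ``seed`` overrides the config's seed.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    truth = _truth_params(cfg)
    set_cfgs = _set_configs(cfg, seed)

    outputs: list[Path] = []

    def write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs.append(path)

    def write_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        outputs.append(path)

    # stage 1: stimuli
    all_songs = []
    for sc in set_cfgs:
        all_songs.extend(build_stimulus_set(sc, catalog))
    write_df(songs_to_frame(all_songs, catalog), "songs.csv")

    # stage 2: synthetic cohort
    cohort_cfg = cfg.get("cohort", {})
    synth_cfg = SyntheticCohortConfig(
        truth=truth,
        sets=tuple(set_cfgs),
        n_females=int(cohort_cfg.get("n_females", 20)),
        n_cycles=int(cohort_cfg.get("n_cycles", 18)),
        control_response_prob=float(cohort_cfg.get("control_response_prob", 0.02)),
        exclusion_threshold=int(cohort_cfg.get("exclusion_threshold", 2)),
        seed=seed,
    )
    cohort = generate_cohort(synth_cfg)
    cohort.dataset.write_csv(out / "dataset.csv")
    outputs.append(out / "dataset.csv")
    write_json(
        {
            "weights": dict(truth.weights),
            "sigma": truth.sigma,
            "theta_plus": truth.theta_plus,
            "theta_minus": truth.theta_minus,
            "excluded_females": cohort.excluded_females,
            "seed": seed,
        },
        "truth.json",
    )

    # stage 3: fit (and optional LOOCV)
    fit_section = cfg.get("fit", {})
    fitted = truth
    if fit_section.get("enabled", True):
        ga = GAConfig(
            population=int(fit_section.get("population", 48)),
            generations=int(fit_section.get("generations", 30)),
            conv_window=int(fit_section.get("conv_window", 15)),
        )
        fit_cfg = FitConfig(ga=ga, seed=seed + 10_000)
        result = fit(cohort.dataset, fit_cfg)
        fitted = result.params
        write_json(
            {
                "weights": dict(result.params.weights),
                "sigma": result.params.sigma,
                "theta_plus": result.params.theta_plus,
                "theta_minus": result.params.theta_minus,
                "loss": result.loss,
                "flags": result.flags,
                "seed": fit_cfg.seed,
            },
            "fitted_params.json",
        )
        write_df(
            pd.DataFrame({"generation": range(len(result.trace)), "best_loss": result.trace}),
            "fit_trace.csv",
        )
        write_df(
            recovery_report(result, truth, cohort.dataset), "recovery_report.csv"
        )
        if fit_section.get("loocv", False):
            cv = loocv(cohort.dataset, fit_cfg)
            write_df(
                pd.DataFrame(
                    [
                        {
                            "held_out_id": fold.held_out_id,
                            "predicted": fold.predicted,
                            "observed": fold.observed,
                        }
                        for fold in cv.folds
                    ]
                ),
                "loocv_folds.csv",
            )
            write_json({"r_squared": cv.r_squared, "n_folds": cv.n_folds}, "loocv.json")

    # stage 4: metrics and decision dynamics at the fitted parameters
    pairs = {sc.set_id: (sc.positive, sc.negative) for sc in set_cfgs}
    usable = {
        sid: pn
        for sid, pn in pairs.items()
        if all(np.isfinite(fitted.weights.get(lab, np.nan)) for lab in pn)
    }
    write_df(set_metrics_table(usable, fitted), "set_metrics.csv")

    dyn = cfg.get("dynamics", {})
    if dyn.get("enabled", True):
        dcfg = DynamicsConfig(n_reps=int(dyn.get("n_reps", 50_000)), seed=seed + 20_000)
        rows_traj, rows_thirds = [], []
        for sid, (pos, neg) in usable.items():
            for pattern in ("switch-at-11", "switch-at-11-reversed"):
                song = build_song(pattern, (pos, neg), set_id=sid)
                traj = mean_trajectory(song, fitted, dcfg, backend="mc")
                prof = first_passage_profile(song, fitted, dcfg, backend="exact")
                thirds = thirds_decomposition(prof)
                for k, v in enumerate(traj):
                    rows_traj.append(
                        {"set_id": sid, "pattern": pattern, "step": k, "mean_evidence": v}
                    )
                rows_thirds.append(
                    {
                        "set_id": sid,
                        "pattern": pattern,
                        "p_upper_1": thirds.p_upper_thirds[0],
                        "p_upper_2": thirds.p_upper_thirds[1],
                        "p_upper_3": thirds.p_upper_thirds[2],
                        "p_lower_1": thirds.p_lower_thirds[0],
                        "p_lower_2": thirds.p_lower_thirds[1],
                        "p_lower_3": thirds.p_lower_thirds[2],
                        "p_end_respond": thirds.p_end_respond,
                        "p_end_reject": thirds.p_end_reject,
                    }
                )
        write_df(pd.DataFrame(rows_traj), "mean_trajectories.csv")
        write_df(pd.DataFrame(rows_thirds), "thirds_decomposition.csv")

    manifest = {
        "package": "songdrift",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": cfg,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out
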