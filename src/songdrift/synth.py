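"""Synthetic behavioral cohorts with the playback experiment's structure.

Given a ground-truth model, each song's response probability p_truth is
computed with the density backend; each female's response count for a song is
then Binomial(n_cycles, p_truth), conditionally independent across songs and
cycles (stimulus order was randomised in the experiment precisely to justify
this).  A 3-s unmodulated-noise negative control screens out unselective
females: a female responding more than ``exclusion_threshold`` times out of
``n_cycles`` control presentations is excluded before averaging.

Optional per-female heterogeneity perturbs p_truth on the logit scale with a
configurable SD; it is off by default and exists to stress-test fitting
robustness.  The motivation song preceding each cycle has no analysed
response and is not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datasets import ResponseDataset, ResponseRecord
from .ddm import DDMParams, propagate_density
from .errors import EmptyCohortError
from .fitting import CrossValResult, FitResult, predict_probabilities
from .stimuli import SongModel, StimulusSetConfig, build_stimulus_set


@dataclass(frozen=True)
class SyntheticCohortConfig:
    truth: DDMParams
    sets: tuple[StimulusSetConfig, ...]
    n_females: int = 20
    n_cycles: int = 18
    control_response_prob: float = 0.02
    exclusion_threshold: int = 2
    heterogeneity_sd: float = 0.0
    seed: int = 0
    grid_bins_per_sigma: int = 20
    max_bins: int = 4000

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_females < 1:
            raise ValueError("need n_females >= 1 and n_cycles >= 1")
        if self.exclusion_threshold < 0:
            raise ValueError("exclusion_threshold must be >= 0")
        if not 0.0 <= self.control_response_prob <= 1.0:
            raise ValueError("control_response_prob must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    dataset: ResponseDataset
    per_female: pd.DataFrame  # columns: set_id, song_id, female, responses
    excluded_females: dict[str, list[int]]  # set_id -> excluded female indices
    truth: DDMParams
    p_truth: dict[str, float]  # song_id -> ground-truth response probability


def _truth_probabilities(
    songs: list[SongModel], truth: DDMParams, bins_per_sigma: int, max_bins: int
) -> np.ndarray:
    labels = sorted({lab for s in songs for lab in s.subunits})
    index = {lab: i for i, lab in enumerate(labels)}
    weights = np.array([truth.weights[lab] for lab in labels])
    seqs = np.array([[index[lab] for lab in s.subunits] for s in songs], dtype=np.intp)
    res = propagate_density(
        seqs, weights, truth.sigma, truth.theta_plus, truth.theta_minus,
        bins_per_sigma, max_bins,
    )
    return res.p_respond


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticDataset:
    """Simulate one full multi-set behavioral experiment.

    Each stimulus set is tested by its own cohort of ``n_females`` females
    (as in the experiment, where sets were run on separate cohorts).  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[ResponseRecord] = []
    per_female_rows = []
    excluded: dict[str, list[int]] = {}
    p_map: dict[str, float] = {}
    for set_cfg in cfg.sets:
        songs = build_stimulus_set(set_cfg)
        if any(len(s) == 0 for s in songs):
            raise ValueError("songs must have at least one subunit")
        p = _truth_probabilities(songs, cfg.truth, cfg.grid_bins_per_sigma, cfg.max_bins)
        control = rng.binomial(cfg.n_cycles, cfg.control_response_prob, cfg.n_females)
        keep = control <= cfg.exclusion_threshold
        excluded[set_cfg.set_id] = list(np.nonzero(~keep)[0])
        if cfg.heterogeneity_sd > 0.0:
            delta = rng.normal(0.0, cfg.heterogeneity_sd, cfg.n_females)
        else:
            delta = np.zeros(cfg.n_females)
        # response counts drawn for all females, then the excluded discarded,
        # so exclusion does not shift the stream for later songs
        p_clip = np.clip(p, 1e-12, 1.0 - 1e-12)
        p_female = expit(logit(p_clip)[:, None] + delta[None, :])  # (songs, females)
        counts = rng.binomial(cfg.n_cycles, p_female)
        if not keep.any():
            raise EmptyCohortError(
                f"set {set_cfg.set_id!r}: all {cfg.n_females} females excluded"
            )
        for j, song in enumerate(songs):
            rate = counts[j, keep].mean() / cfg.n_cycles
            records.append(
                ResponseRecord(
                    song=song,
                    response_rate=float(rate),
                    n_females=int(keep.sum()),
                    n_cycles=cfg.n_cycles,
                    pos_label=set_cfg.positive,
                    neg_label=set_cfg.negative,
                )
            )
            p_map[song.id] = float(p[j])
            for f in range(cfg.n_females):
                per_female_rows.append(
                    {
                        "set_id": set_cfg.set_id,
                        "song_id": song.id,
                        "female": f,
                        "responses": int(counts[j, f]),
                        "excluded": bool(~keep[f]),
                    }
                )
    return SyntheticDataset(
        dataset=ResponseDataset(records),
        per_female=pd.DataFrame(per_female_rows),
        excluded_females=excluded,
        truth=cfg.truth,
        p_truth=p_map,
    )


def expected_exclusion_fraction(
    n_cycles: int, control_response_prob: float, exclusion_threshold: int
) -> float:
    """Closed-form P(female excluded) = 1 - BinomCDF(threshold; n, p)."""
    from scipy.stats import binom

    return float(binom.sf(exclusion_threshold, n_cycles, control_response_prob))


def recovery_report(
    result: CrossValResult | FitResult,
    truth: DDMParams,
    dataset: ResponseDataset | None = None,
    flat_tol: float = 0.01,
    coverage_tol: float = 0.2,
) -> pd.DataFrame:
    """Score fitted parameters against the generating truth.

    One row per parameter with truth, fitted mean (over folds, if a
    cross-validation result), SD, bias, relative error, and coverage (the
    fraction of folds whose estimate lies within ``coverage_tol`` relative
    error of the truth).  theta_minus is
    identifiable only up to a lower bound: if a dataset is supplied and the
    fitted solution sits on the flat shelf — deepening theta_minus by a
    further 50% at the fitted parameters changes no song's predicted
    probability by more than ``flat_tol`` — its row is flagged
    ``bounded_only`` instead of biased.  Permutation-invariant to fold order.
    """
    if isinstance(result, CrossValResult):
        frames = [f.params for f in result.folds]
    else:
        frames = [result.params]
    names: list[str] = sorted(
        {lab for p in frames for lab in p.weights}
    ) + ["sigma", "theta_plus", "theta_minus"]

    def value(params: DDMParams, name: str) -> float:
        if name in ("sigma", "theta_plus", "theta_minus"):
            return float(getattr(params, name))
        return float(params.weights.get(name, np.nan))

    rows = []
    for name in names:
        vals = np.array([value(p, name) for p in frames], dtype=float)
        tv = value(truth, name)
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        bias = mean - tv
        rel = abs(bias) / abs(tv) if tv != 0.0 else np.nan
        flag = ""
        if np.isnan(mean):
            flag = "unconstrained"
        elif name == "theta_minus" and dataset is not None:
            wmap = {
                lab: float(np.nanmean([p.weights.get(lab, np.nan) for p in frames]))
                for lab in {l for p in frames for l in p.weights}
            }
            if all(np.isfinite(v) for v in wmap.values()):
                base = DDMParams(
                    weights=wmap,
                    sigma=float(np.mean([p.sigma for p in frames])),
                    theta_plus=float(np.mean([p.theta_plus for p in frames])),
                    theta_minus=mean,
                )
                deeper = DDMParams(
                    weights=wmap, sigma=base.sigma,
                    theta_plus=base.theta_plus, theta_minus=1.5 * mean,
                )
                dp = predict_probabilities(dataset, base) - predict_probabilities(
                    dataset, deeper
                )
                if np.max(np.abs(dp)) < flat_tol:
                    flag = "bounded_only"
        if tv != 0.0:
            coverage = float(np.mean(np.abs(vals - tv) / abs(tv) <= coverage_tol))
        else:
            coverage = np.nan
        rows.append(
            {
                "parameter": name,
                "truth": tv,
                "fitted_mean": mean,
                "fitted_sd": sd,
                "bias": bias,
                "relative_error": rel,
                "coverage": coverage,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
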