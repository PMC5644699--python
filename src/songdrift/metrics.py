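"""Derived decision-dynamics quantities per stimulus set.

Summaries of the fitted model: the balance of negative vs positive weights
(omega-/omega+), how many consecutive subunits of one type suffice to fix a
decision without noise, the raw |theta/omega| threshold ratios, the
noise-to-signal ratios sigma/|omega|, and the decomposition of first-passage
mass over the thirds of a song.

Two threshold-distance conventions are exposed deliberately: the integer
count of subunits needed for a *strict* crossing (``subunits_to_threshold``)
and the raw dimensionless ratio |theta|/|omega| (``threshold_ratio``); for
the block subunit (weight 1) the latter equals the threshold itself.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import DDMParams, FirstPassageProfile
from .errors import UndefinedRatioError, UnreachableThresholdError


def weight_ratio(omega_neg: float, omega_pos: float) -> float:
    """omega-/omega+ — how strongly negative evidence outweighs positive."""
    if omega_pos == 0.0:
        raise UndefinedRatioError("omega_pos is zero")
    return omega_neg / omega_pos


def subunits_to_threshold(omega: float, theta: float) -> int:
    """Smallest k with k*|omega| strictly beyond |theta| (noise-free)."""
    if omega == 0.0:
        raise UndefinedRatioError("omega is zero")
    if math.copysign(1.0, omega) != math.copysign(1.0, theta):
        raise UnreachableThresholdError(
            f"omega={omega} can never reach theta={theta}"
        )
    return int(math.floor(abs(theta) / abs(omega))) + 1


def threshold_ratio(omega: float, theta: float) -> float:
    """|theta| / |omega| — threshold distance in units of one subunit's drift."""
    if omega == 0.0:
        raise UndefinedRatioError("omega is zero")
    return abs(theta) / abs(omega)


def noise_to_signal(sigma: float, omega: float) -> float:
    """sigma / |omega| — per-step noise relative to one subunit's drift."""
    if omega == 0.0:
        raise UndefinedRatioError("omega is zero")
    if sigma < 0.0:
        raise ValueError("sigma must be >= 0")
    return sigma / abs(omega)


@dataclass(frozen=True)
class SetMetrics:
    """Derived quantities for one stimulus set (a positive/negative pair)."""

    set_id: str
    omega_ratio: float
    n_to_lower: int
    n_to_upper: int | None  # None if the positive drift cannot reach theta+ in a song
    threshold_ratio_lower: float
    threshold_ratio_upper: float
    nsr_negative: float
    nsr_positive: float


def set_metrics(
    set_id: str,
    omega_neg: float,
    omega_pos: float,
    params: DDMParams,
) -> SetMetrics:
    """All per-set ratio summaries from a fitted parameter set."""
    try:
        n_up = subunits_to_threshold(omega_pos, params.theta_plus)
    except UnreachableThresholdError:
        n_up = None
    return SetMetrics(
        set_id=set_id,
        omega_ratio=weight_ratio(omega_neg, omega_pos),
        n_to_lower=subunits_to_threshold(omega_neg, params.theta_minus),
        n_to_upper=n_up,
        threshold_ratio_lower=threshold_ratio(omega_neg, params.theta_minus),
        threshold_ratio_upper=threshold_ratio(omega_pos, params.theta_plus),
        nsr_negative=noise_to_signal(params.sigma, omega_neg),
        nsr_positive=noise_to_signal(params.sigma, omega_pos),
    )


def set_metrics_table(
    pairs: dict[str, tuple[str, str]], params: DDMParams, round_to: int | None = None
) -> pd.DataFrame:
    """Tabulate per-set metrics for ``{set_id: (positive, negative)}`` pairs.

    ``round_to=1`` mirrors the one-decimal reporting convention of summary
    tables; machine output keeps full precision by default.
    """
    rows = []
    for set_id, (pos, neg) in pairs.items():
        m = set_metrics(set_id, params.weights[neg], params.weights[pos], params)
        rows.append(
            {
                "set_id": set_id,
                "pos_label": pos,
                "neg_label": neg,
                "omega_pos": params.weights[pos],
                "omega_neg": params.weights[neg],
                "omega_ratio": m.omega_ratio,
                "n_to_lower": m.n_to_lower,
                "n_to_upper": m.n_to_upper,
                "threshold_ratio_lower": m.threshold_ratio_lower,
                "threshold_ratio_upper": m.threshold_ratio_upper,
                "nsr_negative": m.nsr_negative,
                "nsr_positive": m.nsr_positive,
            }
        )
    df = pd.DataFrame(rows)
    if round_to is not None:
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].round(round_to)
    return df


@dataclass(frozen=True)
class ThirdsDecomposition:
    """First-passage mass per third of the song plus non-crosser masses."""

    p_upper_thirds: np.ndarray  # length 3
    p_lower_thirds: np.ndarray
    p_end_respond: float
    p_end_reject: float

    def total(self) -> float:
        return float(
            self.p_upper_thirds.sum()
            + self.p_lower_thirds.sum()
            + self.p_end_respond
            + self.p_end_reject
        )


def thirds_decomposition(profile: FirstPassageProfile) -> ThirdsDecomposition:
    """Sum first-passage masses over the first/second/last third of the song."""
    L = profile.n_steps
    if L % 3 != 0:
        raise ValueError(f"song length {L} is not divisible by 3")
    third = L // 3
    up = profile.p_upper.reshape(3, third).sum(axis=1)
    low = profile.p_lower.reshape(3, third).sum(axis=1)
    return ThirdsDecomposition(up, low, profile.p_end_respond, profile.p_end_reject)
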