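"""Discrete-step drift-diffusion model of the female response decision.

Each subunit of a song contributes a signed weight omega to an evidence
integrator; at every subunit step, Gaussian noise with standard deviation
sigma is added together with the drift.  The evidence starts at 0 and
accumulates perfectly (no leak).  A decision is fixed irreversibly the first
time the evidence strictly exceeds the upper threshold theta_plus (respond)
or falls strictly below the lower threshold theta_minus (reject); after a
crossing the evidence is clamped at the threshold.  If no threshold has been
crossed by the song's end, the response is given by the sign of the
integrated evidence (respond iff E_L > 0; the tie E_L = 0 has measure zero
under noise and maps to reject).

The model's clock is the subunit index: one noisy increment per subunit,
regardless of the subunit's physical duration.

Two backends compute response probabilities and first-passage profiles:

* Monte-Carlo (``response_probability_mc``) — vectorised simulation.
* Density propagation (``response_probability_exact``) — the evidence
  density is propagated over a bin grid spanning the unabsorbed interval
  (theta_minus, theta_plus); mass leaving the interval through either
  Gaussian tail is accumulated as absorbed per step.  Deterministic, used as
  the fitting objective and as the independent oracle for the simulator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .errors import UnknownLabelError
from .stimuli import SongModel

BLOCK_LABELS = ("block", "block76ms")


@dataclass(frozen=True)
class DDMParams:
    """Subunit weights and integrator parameters.

    ``weights`` maps subunit labels to evidence increments per subunit.  The
    standard block subunit anchors the scale: its weight is fixed at +1.0
    and is validated here when present.  ``sigma`` is the SD of the per-step
    Gaussian noise; ``theta_plus``/``theta_minus`` the absorbing thresholds.
    """

    weights: Mapping[str, float]
    sigma: float
    theta_plus: float
    theta_minus: float

    def __post_init__(self) -> None:
        if not (self.theta_minus < 0.0 < self.theta_plus):
            raise ValueError("need theta_minus < 0 < theta_plus")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")
        for lab in BLOCK_LABELS:
            w = self.weights.get(lab)
            if w is not None and not np.isnan(w) and w != 1.0:
                raise ValueError(f"{lab} weight is fixed at 1.0, got {w}")

    def step_weights(self, song: SongModel | Sequence[str]) -> np.ndarray:
        labels = song.subunits if isinstance(song, SongModel) else tuple(song)
        try:
            return np.array([self.weights[lab] for lab in labels], dtype=float)
        except KeyError as exc:
            raise UnknownLabelError(*exc.args) from None


@dataclass(frozen=True)
class DynamicsConfig:
    """Settings for the stochastic and density backends."""

    n_reps: int = 50_000
    seed: int = 0
    grid_bins_per_sigma: int = 20
    max_bins: int = 4000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.grid_bins_per_sigma < 1 or self.max_bins < 2:
            raise ValueError("grid resolution settings must be positive")


@dataclass(frozen=True)
class Trajectory:
    """One (noise-free or single-trial) evidence path, clamped after absorption."""

    evidence: np.ndarray  # E_0..E_L
    absorbed_at: int | None  # 1-based step of first crossing, or None
    crossed: str  # 'upper' | 'lower' | 'none'
    outcome: str  # 'respond' | 'reject'


@dataclass(frozen=True)
class DecisionOutcome:
    outcome: str  # 'respond' | 'reject'
    crossed: str  # 'upper' | 'lower' | 'none'
    step: int  # absorption step (1-based), or L if no crossing


@dataclass(frozen=True)
class FirstPassageProfile:
    """Per-step threshold-crossing masses plus terminal sign-rule masses."""

    p_upper: np.ndarray  # length L, P(first cross upper at step k)
    p_lower: np.ndarray
    p_end_respond: float  # no crossing, E_L > 0
    p_end_reject: float  # no crossing, E_L <= 0
    backend: str

    @property
    def n_steps(self) -> int:
        return len(self.p_upper)

    def total(self) -> float:
        return float(
            self.p_upper.sum() + self.p_lower.sum() + self.p_end_respond + self.p_end_reject
        )

    @property
    def p_respond(self) -> float:
        return float(self.p_upper.sum() + self.p_end_respond)


# ---------------------------------------------------------------------------
# deterministic and Monte-Carlo backends
# ---------------------------------------------------------------------------

def _outcome_from_path(E: np.ndarray, theta_plus: float, theta_minus: float):
    """First strict crossing along a cumulative path; returns clamped copy."""
    absorbed_at = None
    crossed = "none"
    E = E.copy()
    for k in range(1, len(E)):
        if E[k] > theta_plus:
            absorbed_at, crossed = k, "upper"
            E[k:] = theta_plus
            break
        if E[k] < theta_minus:
            absorbed_at, crossed = k, "lower"
            E[k:] = theta_minus
            break
    if crossed == "upper":
        outcome = "respond"
    elif crossed == "lower":
        outcome = "reject"
    else:
        outcome = "respond" if E[-1] > 0 else "reject"
    return E, absorbed_at, crossed, outcome


def integrate_deterministic(song: SongModel, params: DDMParams) -> Trajectory:
    """Noise-free integration: E_k = E_{k-1} + omega(subunit_k), clamped."""
    w = params.step_weights(song)
    E = np.concatenate([[0.0], np.cumsum(w)])
    E, absorbed_at, crossed, outcome = _outcome_from_path(
        E, params.theta_plus, params.theta_minus
    )
    return Trajectory(E, absorbed_at, crossed, outcome)


def simulate_trial(
    song: SongModel, params: DDMParams, rng: np.random.Generator | int
) -> DecisionOutcome:
    """One noisy trial; deterministic given the generator state."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    w = params.step_weights(song)
    steps = w + params.sigma * rng.standard_normal(len(w))
    E = np.concatenate([[0.0], np.cumsum(steps)])
    _, absorbed_at, crossed, outcome = _outcome_from_path(
        E, params.theta_plus, params.theta_minus
    )
    return DecisionOutcome(outcome, crossed, absorbed_at if absorbed_at else len(w))


def _simulate_batch(
    w: np.ndarray,
    params: DDMParams,
    n_reps: int,
    rng: np.random.Generator,
    record_mean: bool = False,
):
    """Vectorised simulation of n_reps trials of one song.

    Returns (crossed, step, E_final, mean_trace) where crossed is +1/-1/0,
    step the 1-based absorption step (0 if none) and mean_trace the mean
    clamped evidence per step (length L+1) if requested.
    """
    L = len(w)
    E = np.zeros(n_reps)
    crossed = np.zeros(n_reps, dtype=np.int8)
    step = np.zeros(n_reps, dtype=np.int32)
    active = np.ones(n_reps, dtype=bool)
    mean_trace = np.zeros(L + 1) if record_mean else None
    thp, thm, sigma = params.theta_plus, params.theta_minus, params.sigma
    for k in range(L):
        idx = np.nonzero(active)[0]
        if len(idx):
            E[idx] += w[k] + sigma * rng.standard_normal(len(idx))
            up = idx[E[idx] > thp]
            lo = idx[E[idx] < thm]
            crossed[up], crossed[lo] = 1, -1
            step[up] = k + 1
            step[lo] = k + 1
            E[up] = thp  # clamp absorbed paths at their threshold
            E[lo] = thm
            active[up] = False
            active[lo] = False
        if record_mean:
            mean_trace[k + 1] = E.mean()
    return crossed, step, E, mean_trace


def response_probability_mc(
    song: SongModel, params: DDMParams, cfg: DynamicsConfig = DynamicsConfig()
) -> tuple[float, float]:
    """Monte-Carlo response probability and its binomial standard error."""
    w = params.step_weights(song)
    if params.sigma == 0.0:
        p = 1.0 if integrate_deterministic(song, params).outcome == "respond" else 0.0
        return p, 0.0
    rng = np.random.default_rng(cfg.seed)
    crossed, _, E, _ = _simulate_batch(w, params, cfg.n_reps, rng)
    respond = (crossed == 1) | ((crossed == 0) & (E > 0))
    p = float(respond.mean())
    se = float(np.sqrt(p * (1.0 - p) / cfg.n_reps))
    return p, se


# ---------------------------------------------------------------------------
# density-propagation backend
# ---------------------------------------------------------------------------

def _grid(theta_minus: float, theta_plus: float, sigma: float,
          bins_per_sigma: int, max_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges/centers over (theta_minus, theta_plus), with 0 as an edge."""
    h = sigma / bins_per_sigma
    n_dn = max(1, int(np.ceil(-theta_minus / h)))
    n_up = max(1, int(np.ceil(theta_plus / h)))
    if n_dn + n_up > max_bins:
        scale = max_bins / (n_dn + n_up)
        n_dn = max(1, int(n_dn * scale))
        n_up = max(1, int(n_up * scale))
    edges = np.concatenate(
        [np.linspace(theta_minus, 0.0, n_dn + 1), np.linspace(0.0, theta_plus, n_up + 1)[1:]]
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


@dataclass(frozen=True)
class PropagationResult:
    """Per-step absorbed masses and terminal densities for a batch of songs."""

    absorbed_upper: np.ndarray  # (n_songs, L)
    absorbed_lower: np.ndarray
    p_end_respond: np.ndarray  # (n_songs,)
    p_end_reject: np.ndarray
    mean_clamped: np.ndarray | None  # (n_songs, L+1) if recorded

    @property
    def p_respond(self) -> np.ndarray:
        return self.absorbed_upper.sum(axis=1) + self.p_end_respond


def propagate_density(
    label_seqs: np.ndarray,
    label_weights: np.ndarray,
    sigma: float,
    theta_plus: float,
    theta_minus: float,
    bins_per_sigma: int = 20,
    max_bins: int = 4000,
    record_mean: bool = False,
) -> PropagationResult:
    """Propagate the evidence density for a batch of songs sharing a grid.

    ``label_seqs`` is an (n_songs, L) integer array indexing into
    ``label_weights``.  Each step shifts the density by the subunit's weight,
    convolves with the Gaussian noise kernel (midpoint rule over the bin
    grid) and books mass beyond either threshold as absorbed; the absorbing
    tails use exact Gaussian CDFs, so single-step probabilities are exact.
    """
    if sigma <= 0.0:
        raise ValueError("density propagation requires sigma > 0; "
                         "use integrate_deterministic for the noise-free model")
    seqs = np.atleast_2d(np.asarray(label_seqs, dtype=np.intp))
    n, L = seqs.shape
    edges, centers = _grid(theta_minus, theta_plus, sigma, bins_per_sigma, max_bins)
    nb = len(centers)
    used = np.unique(seqs)
    T: dict[int, np.ndarray] = {}
    a_up: dict[int, np.ndarray] = {}
    a_low: dict[int, np.ndarray] = {}
    init: dict[int, tuple[np.ndarray, float, float]] = {}
    for lab in used:
        wlab = label_weights[lab]
        z = (edges[None, :] - centers[:, None] - wlab) / sigma
        C = ndtr(z)
        T[lab] = np.diff(C, axis=1)
        a_low[lab] = np.ascontiguousarray(C[:, 0])
        a_up[lab] = np.ascontiguousarray(1.0 - C[:, -1])
        C0 = ndtr((edges - wlab) / sigma)
        init[lab] = (np.diff(C0), float(C0[0]), float(1.0 - C0[-1]))

    D = np.zeros((n, nb))
    Aup = np.zeros((n, L))
    Alow = np.zeros((n, L))
    M = np.zeros((n, L + 1)) if record_mean else None
    for lab in np.unique(seqs[:, 0]):
        rows = np.nonzero(seqs[:, 0] == lab)[0]
        d0, al, au = init[lab]
        D[rows] = d0
        Alow[rows, 0] = al
        Aup[rows, 0] = au
    for k in range(1, L):
        col = seqs[:, k]
        for lab in np.unique(col):
            rows = np.nonzero(col == lab)[0]
            sub = D[rows]
            Aup[rows, k] = sub @ a_up[lab]
            Alow[rows, k] = sub @ a_low[lab]
            D[rows] = sub @ T[lab]
        if record_mean:
            M[:, k + 1] = D @ centers
    if record_mean:
        # redo step-1 contribution and add clamped threshold mass
        M[:, 1] = np.nan  # filled below
        M_first = np.zeros(n)
        for lab in np.unique(seqs[:, 0]):
            rows = np.nonzero(seqs[:, 0] == lab)[0]
            M_first[rows] = init[lab][0] @ centers
        M[:, 1] = M_first
        cum_up = np.cumsum(Aup, axis=1)
        cum_low = np.cumsum(Alow, axis=1)
        M[:, 1:] += theta_plus * cum_up + theta_minus * cum_low
    upper_bins = centers > 0.0
    p_end_respond = D[:, upper_bins].sum(axis=1)
    p_end_reject = D[:, ~upper_bins].sum(axis=1)
    return PropagationResult(Aup, Alow, p_end_respond, p_end_reject, M)


def _song_seq(song: SongModel, params: DDMParams) -> tuple[np.ndarray, np.ndarray]:
    labels = sorted(set(song.subunits))
    weights = np.array([params.weights.get(lab, np.nan) for lab in labels])
    if np.isnan(weights).any():
        missing = [lab for lab, w in zip(labels, weights) if np.isnan(w)]
        raise UnknownLabelError(*missing)
    index = {lab: i for i, lab in enumerate(labels)}
    seq = np.array([[index[lab] for lab in song.subunits]], dtype=np.intp)
    return seq, weights


def response_probability_exact(
    song: SongModel, params: DDMParams, cfg: DynamicsConfig = DynamicsConfig()
) -> float:
    """Response probability by density propagation (deterministic)."""
    seq, weights = _song_seq(song, params)
    res = propagate_density(
        seq, weights, params.sigma, params.theta_plus, params.theta_minus,
        cfg.grid_bins_per_sigma, cfg.max_bins,
    )
    return float(res.p_respond[0])


def first_passage_profile(
    song: SongModel,
    params: DDMParams,
    cfg: DynamicsConfig = DynamicsConfig(),
    backend: str = "exact",
) -> FirstPassageProfile:
    """Per-step crossing probabilities plus terminal sign-rule masses."""
    L = len(song)
    if params.sigma == 0.0:
        traj = integrate_deterministic(song, params)
        p_upper = np.zeros(L)
        p_lower = np.zeros(L)
        end_r = end_j = 0.0
        if traj.crossed == "upper":
            p_upper[traj.absorbed_at - 1] = 1.0
        elif traj.crossed == "lower":
            p_lower[traj.absorbed_at - 1] = 1.0
        elif traj.outcome == "respond":
            end_r = 1.0
        else:
            end_j = 1.0
        return FirstPassageProfile(p_upper, p_lower, end_r, end_j, "deterministic")
    if backend == "exact":
        seq, weights = _song_seq(song, params)
        res = propagate_density(
            seq, weights, params.sigma, params.theta_plus, params.theta_minus,
            cfg.grid_bins_per_sigma, cfg.max_bins,
        )
        return FirstPassageProfile(
            res.absorbed_upper[0], res.absorbed_lower[0],
            float(res.p_end_respond[0]), float(res.p_end_reject[0]), "exact",
        )
    if backend == "mc":
        w = params.step_weights(song)
        rng = np.random.default_rng(cfg.seed)
        crossed, step, E, _ = _simulate_batch(w, params, cfg.n_reps, rng)
        p_upper = np.bincount(step[crossed == 1], minlength=L + 1)[1:] / cfg.n_reps
        p_lower = np.bincount(step[crossed == -1], minlength=L + 1)[1:] / cfg.n_reps
        none = crossed == 0
        end_r = float(np.mean(none & (E > 0)))
        end_j = float(np.mean(none & (E <= 0)))
        return FirstPassageProfile(p_upper, p_lower, end_r, end_j, "mc")
    raise ValueError(f"unknown backend {backend!r}")


def mean_trajectory(
    song: SongModel,
    params: DDMParams,
    cfg: DynamicsConfig = DynamicsConfig(),
    backend: str = "mc",
) -> np.ndarray:
    """Mean clamped evidence per step (E_0..E_L), averaging absorbed paths
    at their threshold value.  Default backend is Monte-Carlo with
    ``cfg.n_reps`` repetitions; the density backend is deterministic."""
    if params.sigma == 0.0:
        return integrate_deterministic(song, params).evidence
    if backend == "mc":
        w = params.step_weights(song)
        rng = np.random.default_rng(cfg.seed)
        _, _, _, trace = _simulate_batch(w, params, cfg.n_reps, rng, record_mean=True)
        return trace
    if backend == "exact":
        seq, weights = _song_seq(song, params)
        res = propagate_density(
            seq, weights, params.sigma, params.theta_plus, params.theta_minus,
            cfg.grid_bins_per_sigma, cfg.max_bins, record_mean=True,
        )
        return res.mean_clamped[0]
    raise ValueError(f"unknown backend {backend!r}")
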