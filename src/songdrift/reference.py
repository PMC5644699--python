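"""Reference parameter values and the standard stimulus-set layout.

``REFERENCE_PARAMS`` holds the mean fitted subunit weights and integrator
parameters for the C. biguttulus playback paradigm (block weight anchored at
+1.0): strongly negative weights for the two heterospecific subunits
(dorsatus-like and mollis-like), graded negative weights for conspecific-range
deviations, and small positive weights for the onset-accentuated subunits,
with per-step noise sigma = 142 between thresholds +420 and -803.  These
values serve as the ground truth for synthetic cohorts and recovery studies.
"""
from __future__ import annotations

from .ddm import DDMParams
from .stimuli import StimulusSetConfig

REFERENCE_WEIGHTS: dict[str, float] = {
    "dorsatus": -82.0,
    "mollis": -87.0,
    "gap": -55.0,
    "offset8dB": -51.0,
    "pause4ms": -53.0,
    "onset3dB_pause4ms": -40.0,
    "onset9dB": 15.0,
    "accent_offset": -34.0,
    "accent_onset": 7.0,
    "block": 1.0,
    "block76ms": 1.0,
}

REFERENCE_SIGMA = 142.0
REFERENCE_THETA_PLUS = 420.0
REFERENCE_THETA_MINUS = -803.0

REFERENCE_PARAMS = DDMParams(
    weights=REFERENCE_WEIGHTS,
    sigma=REFERENCE_SIGMA,
    theta_plus=REFERENCE_THETA_PLUS,
    theta_minus=REFERENCE_THETA_MINUS,
)

#: The seven stimulus sets: set_id -> (positive_label, negative_label).
SET_PAIRS: dict[str, tuple[str, str]] = {
    "dorsatus": ("block76ms", "dorsatus"),
    "mollis": ("block", "mollis"),
    "gap": ("block", "gap"),
    "offset8dB": ("block", "offset8dB"),
    "pause4ms": ("block", "pause4ms"),
    "onset": ("onset9dB", "onset3dB_pause4ms"),
    "accent": ("accent_onset", "accent_offset"),
}


def reference_stimulus_sets(
    n_songs: int = 35, length: int = 33, seed: int = 0
) -> list[StimulusSetConfig]:
    """One StimulusSetConfig per standard subunit pair (deterministic seeds)."""
    return [
        StimulusSetConfig(
            set_id=set_id,
            positive=pos,
            negative=neg,
            n_songs=n_songs,
            length=length,
            seed=seed + i,
        )
        for i, (set_id, (pos, neg)) in enumerate(SET_PAIRS.items())
    ]
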