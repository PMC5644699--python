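"""Song-model stimuli for grasshopper playback experiments.

Chorthippus biguttulus males sing sequences of stereotyped noise "syllables"
separated by short pauses; a syllable+pause unit is a *subunit*.  Playback
song models are built from exactly two subunit types per stimulus set — one
attractive ("positive") and one unattractive ("negative") — arranged in
mixtures over a fixed song length (33 subunits by default).  This module
encodes the subunit catalogue (timing and sound level of each segment),
assembles song models from placement patterns, and renders piecewise-constant
amplitude envelopes for inspection.

Only envelope timing/levels are modelled; no audio is synthesised.  Time is
integer milliseconds; the decision model's clock is the subunit index.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidSpecError, UnknownLabelError

#: Distinguished level for pauses/gaps. Not a dB value; never used in arithmetic.
SILENT = None

#: Default syllable plateau level, dB SPL.
PLATEAU_DB = 64.0

DEFAULT_SONG_LENGTH = 33


@dataclass(frozen=True)
class Segment:
    """One constant-level stretch of a subunit envelope."""

    duration_ms: int
    level_db: float | None  # None == SILENT

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise InvalidSpecError("segment duration must be > 0 ms")


@dataclass(frozen=True)
class SubunitSpec:
    """Timing/level description of one song subunit.

    ``role`` is the subunit's valence within its stimulus set: ``"positive"``
    subunits are the attractive member of the pair, ``"negative"`` the
    unattractive one.
    """

    name: str
    segments: tuple[Segment, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("positive", "negative"):
            raise InvalidSpecError(f"role must be positive|negative, got {self.role!r}")


def subunit_duration(spec: SubunitSpec) -> int:
    """Total duration of a subunit in ms (sum of its segment durations)."""
    if not spec.segments:
        raise InvalidSpecError(f"subunit {spec.name!r} has no segments")
    return sum(seg.duration_ms for seg in spec.segments)


def _seg(dur: int, level: float | None) -> Segment:
    return Segment(duration_ms=dur, level_db=level)


def default_catalog(gap_count: int = 2, gap_ms: int = 2) -> dict[str, SubunitSpec]:
    """The standard subunit catalogue.

    Negative (unattractive) subunits
      * ``dorsatus`` — mimics C. dorsatus: four 8-ms noise pulses separated by
        three 6-ms gaps, followed by a 40-ms pause (90 ms).
      * ``mollis`` — mimics C. mollis: 120-ms syllable + 120-ms silent pause.
      * ``gap`` — 72-ms syllable interrupted by silent gaps (default two 2-ms
        gaps) + 12-ms pause; emulates gap stimuli from earlier work, where the
        exact gap layout is not printed.
      * ``offset8dB`` — 72-ms syllable + 12-ms "shallow" pause at 56 dB
        (only 8 dB below the 64-dB plateau).
      * ``pause4ms`` — 72-ms syllable + very short 4-ms silent pause.
      * ``onset3dB_pause4ms`` — 72-ms syllable with a weak 3-dB, 10-ms onset
        accent (67 dB) + 4-ms silent pause; the short pause renders it
        unattractive despite the onset.
      * ``accent_offset`` — 70-dB plateau with an 82-dB, 10-ms accent at the
        syllable *end* (62–72 ms) + 12-ms pause at 58 dB (12-dB offset).

    Positive (attractive) subunits
      * ``block`` — the standard stimulus: 72-ms syllable + 12-ms pause.
      * ``block76ms`` — block variant paired with dorsatus: 76-ms syllable +
        14-ms pause, equalising subunit durations (90 ms).
      * ``onset9dB`` — 72-ms syllable with a 9-dB, 10-ms onset accent
        (73 dB) + 12-ms pause; onset accentuation correlates with male
        condition in natural songs.
      * ``accent_onset`` — time-reversed accent_offset: 82-dB accent in the
        first 10 ms of a 70-dB syllable + 12-ms pause at 58 dB.
    """
    if gap_count < 1 or gap_ms < 1:
        raise ConfigError("gap_count and gap_ms must be >= 1")
    # split the 72-ms plateau into gap_count+1 sound stretches around the gaps
    sound_total = 72 - gap_count * gap_ms
    if sound_total <= gap_count:
        raise ConfigError("gaps leave no room for sound in the 72-ms syllable")
    base = sound_total // (gap_count + 1)
    rests = sound_total - base * (gap_count + 1)
    gap_segments: list[Segment] = []
    for i in range(gap_count + 1):
        dur = base + (1 if i < rests else 0)
        gap_segments.append(_seg(dur, PLATEAU_DB))
        if i < gap_count:
            gap_segments.append(_seg(gap_ms, SILENT))
    gap_segments.append(_seg(12, SILENT))

    dorsatus_segments: list[Segment] = []
    for i in range(4):
        dorsatus_segments.append(_seg(8, PLATEAU_DB))
        dorsatus_segments.append(_seg(6 if i < 3 else 40, SILENT))

    cat = {
        "dorsatus": SubunitSpec("dorsatus", tuple(dorsatus_segments), "negative"),
        "mollis": SubunitSpec(
            "mollis", (_seg(120, PLATEAU_DB), _seg(120, SILENT)), "negative"
        ),
        "gap": SubunitSpec("gap", tuple(gap_segments), "negative"),
        "offset8dB": SubunitSpec(
            "offset8dB", (_seg(72, PLATEAU_DB), _seg(12, 56.0)), "negative"
        ),
        "pause4ms": SubunitSpec(
            "pause4ms", (_seg(72, PLATEAU_DB), _seg(4, SILENT)), "negative"
        ),
        "onset3dB_pause4ms": SubunitSpec(
            "onset3dB_pause4ms",
            (_seg(10, 67.0), _seg(62, PLATEAU_DB), _seg(4, SILENT)),
            "negative",
        ),
        "accent_offset": SubunitSpec(
            "accent_offset",
            (_seg(62, 70.0), _seg(10, 82.0), _seg(12, 58.0)),
            "negative",
        ),
        "block": SubunitSpec(
            "block", (_seg(72, PLATEAU_DB), _seg(12, SILENT)), "positive"
        ),
        "block76ms": SubunitSpec(
            "block76ms", (_seg(76, PLATEAU_DB), _seg(14, SILENT)), "positive"
        ),
        "onset9dB": SubunitSpec(
            "onset9dB",
            (_seg(10, 73.0), _seg(62, PLATEAU_DB), _seg(12, SILENT)),
            "positive",
        ),
        "accent_onset": SubunitSpec(
            "accent_onset",
            (_seg(10, 82.0), _seg(62, 70.0), _seg(12, 58.0)),
            "positive",
        ),
    }
    return cat


@dataclass(frozen=True)
class SongModel:
    """An ordered sequence of subunit labels forming one playback song."""

    id: str
    subunits: tuple[str, ...]
    set_id: str

    def __len__(self) -> int:
        return len(self.subunits)


def song_duration(song: SongModel, catalog: dict[str, SubunitSpec]) -> int:
    """Total song duration in ms."""
    total = 0
    for label in song.subunits:
        if label not in catalog:
            raise UnknownLabelError(label)
        total += subunit_duration(catalog[label])
    return total


# ---------------------------------------------------------------------------
# placement patterns
# ---------------------------------------------------------------------------

_BLOCK_KINDS = ("block-first", "block-middle", "block-last")


def parse_pattern(pattern: str) -> tuple[str, float | None]:
    """Parse a placement descriptor into (kind, proportion).

    Supported descriptors::

        pure-positive            all positive subunits
        pure-negative            all negative subunits
        switch-at-11             positive first third, then negative
        switch-at-11-reversed    negative first third, then positive
        uniform-random:<p>       round(p*L) negatives at random positions
        block-first:<p>          round(p*L) negatives as a leading block
        block-middle:<p>         ... centred block
        block-last:<p>           ... trailing block
    """
    if not isinstance(pattern, str):
        raise ConfigError(f"pattern descriptor must be a string, got {pattern!r}")
    head, _, tail = pattern.partition(":")
    if head in ("pure-positive", "pure-negative", "switch-at-11", "switch-at-11-reversed"):
        if tail:
            raise ConfigError(f"pattern {head!r} takes no proportion")
        return head, None
    if head == "uniform-random" or head in _BLOCK_KINDS:
        try:
            p = float(tail)
        except ValueError:
            raise ConfigError(f"malformed proportion in pattern {pattern!r}") from None
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"proportion must lie in [0, 1], got {p}")
        return head, p
    raise ConfigError(f"unknown pattern descriptor {pattern!r}")


def _negative_count(p: float, length: int) -> int:
    return int(math.floor(p * length + 0.5))


def build_song(
    pattern: str,
    pair: tuple[str, str],
    length: int = DEFAULT_SONG_LENGTH,
    seed: int = 0,
    song_id: str | None = None,
    set_id: str = "set",
) -> SongModel:
    """Assemble one song from a placement descriptor.

    ``pair`` is ``(positive_label, negative_label)``.  Deterministic given
    ``(pattern, seed)``; only ``uniform-random`` consumes randomness.  The
    switch patterns flip valence after the first third of the song
    (11 subunits at the default length of 33).
    """
    if length < 1:
        raise ConfigError("song length must be >= 1")
    pos, neg = pair
    kind, p = parse_pattern(pattern)
    if kind == "pure-positive":
        labels = [pos] * length
    elif kind == "pure-negative":
        labels = [neg] * length
    elif kind in ("switch-at-11", "switch-at-11-reversed"):
        third = int(round(length / 3))
        first, rest = (pos, neg) if kind == "switch-at-11" else (neg, pos)
        labels = [first] * third + [rest] * (length - third)
    else:
        n_neg = _negative_count(p, length)
        labels = [pos] * length
        if kind == "uniform-random":
            rng = np.random.default_rng(seed)
            for i in rng.choice(length, size=n_neg, replace=False):
                labels[i] = neg
        else:
            start = {
                "block-first": 0,
                "block-middle": (length - n_neg) // 2,
                "block-last": length - n_neg,
            }[kind]
            for i in range(start, start + n_neg):
                labels[i] = neg
    return SongModel(
        id=song_id if song_id is not None else f"{set_id}-{pattern}",
        subunits=tuple(labels),
        set_id=set_id,
    )


def default_patterns(n_songs: int = 35) -> list[str]:
    """A deterministic family of placement descriptors for one stimulus set.

    Mirrors the experimental design: both pure songs, both valence-switch
    songs, blocked negative thirds, and a sweep of uniformly placed negative
    proportions spanning 0–100%.
    """
    if n_songs < 2:
        raise ConfigError("a stimulus set needs at least the two pure songs")
    base = [
        "pure-positive",
        "pure-negative",
        "switch-at-11",
        "switch-at-11-reversed",
        "block-first:0.3333",
        "block-middle:0.3333",
        "block-last:0.3333",
        "block-first:0.6667",
        "block-middle:0.6667",
        "block-last:0.6667",
    ]
    patterns = base[:n_songs]
    n_extra = n_songs - len(patterns)
    if n_extra > 0:
        props = np.linspace(0.0, 1.0, n_extra + 2)[1:-1]
        patterns += [f"uniform-random:{p:.4f}" for p in props]
    return patterns


@dataclass(frozen=True)
class StimulusSetConfig:
    """Configuration of one stimulus set (a positive/negative subunit pair)."""

    set_id: str
    positive: str
    negative: str
    n_songs: int = 35
    length: int = DEFAULT_SONG_LENGTH
    sequence_patterns: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_songs < 2:
            raise ConfigError("n_songs must be >= 2")


def build_stimulus_set(
    cfg: StimulusSetConfig, catalog: dict[str, SubunitSpec] | None = None
) -> list[SongModel]:
    """Assemble the full song list for one stimulus set.

    Returns ``cfg.n_songs`` songs (the default pattern family always includes
    both pure songs); reproducible from ``cfg.seed``.
    """
    if catalog is not None:
        for label in (cfg.positive, cfg.negative):
            if label not in catalog:
                raise UnknownLabelError(label)
    patterns = (
        list(cfg.sequence_patterns)
        if cfg.sequence_patterns is not None
        else default_patterns(cfg.n_songs)
    )
    if len(patterns) != cfg.n_songs:
        raise ConfigError(
            f"{cfg.set_id}: {len(patterns)} patterns for n_songs={cfg.n_songs}"
        )
    root = np.random.SeedSequence(cfg.seed)
    songs: list[SongModel] = []
    seen: set[str] = set()
    for i, pattern in enumerate(patterns):
        child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        song = build_song(
            pattern,
            (cfg.positive, cfg.negative),
            length=cfg.length,
            seed=child_seed,
            song_id=f"{cfg.set_id}-{i:02d}-{pattern}",
            set_id=cfg.set_id,
        )
        if song.id in seen:
            raise ConfigError(f"duplicate song id {song.id!r}")
        seen.add(song.id)
        songs.append(song)
    return songs


# ---------------------------------------------------------------------------
# envelopes and tables
# ---------------------------------------------------------------------------

def render_envelope(
    song: SongModel, catalog: dict[str, SubunitSpec], dt: float = 1.0
) -> pd.DataFrame:
    """Sample the song's piecewise-constant amplitude envelope.

    Returns a DataFrame with columns ``t_ms`` and ``level_db``; silent
    stretches are NaN (SILENT is a distinguished level, not -inf).  Sampled at
    ``t = 0, dt, 2*dt, ...`` over the song's total duration.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    bounds: list[float] = [0.0]
    levels: list[float] = []
    for label in song.subunits:
        if label not in catalog:
            raise UnknownLabelError(label)
        for seg in catalog[label].segments:
            bounds.append(bounds[-1] + seg.duration_ms)
            levels.append(np.nan if seg.level_db is None else seg.level_db)
    total = bounds[-1]
    t = np.arange(0.0, total, dt)
    if len(levels) == 0:
        return pd.DataFrame({"t_ms": t, "level_db": np.array([], dtype=float)})
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(levels) - 1)
    return pd.DataFrame({"t_ms": t, "level_db": np.asarray(levels)[idx]})


def songs_to_frame(
    songs: list[SongModel], catalog: dict[str, SubunitSpec]
) -> pd.DataFrame:
    """Tabulate songs: one row per song with a P/N valence string."""
    rows = []
    for song in songs:
        seq = "".join(
            "P" if catalog[label].role == "positive" else "N" for label in song.subunits
        )
        labels = {catalog[label].role: label for label in song.subunits}
        rows.append(
            {
                "song_id": song.id,
                "set_id": song.set_id,
                "sequence": seq,
                "pos_label": labels.get("positive", ""),
                "neg_label": labels.get("negative", ""),
                "duration_ms": song_duration(song, catalog),
            }
        )
    return pd.DataFrame(rows)
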