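"""Behavioral response datasets: per-song response rates with trial structure.

The observable fitted by the model is, per song model, the fraction of
stimulus presentations that elicited a female response song, averaged over
the females of a cohort (typically 12-22 females x 18 presentation cycles).
Datasets round-trip through a delimited table whose ``sequence`` column is a
P/N valence string plus the two subunit labels of the set's pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigError
from .stimuli import SongModel


@dataclass(frozen=True)
class ResponseRecord:
    song: SongModel
    response_rate: float
    n_females: int
    n_cycles: int = 18
    pos_label: str = ""
    neg_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_rate <= 1.0:
            raise ValueError("response_rate must lie in [0, 1]")
        if self.n_females < 1 or self.n_cycles < 1:
            raise ValueError("n_females and n_cycles must be >= 1")


@dataclass
class ResponseDataset:
    records: list[ResponseRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def set_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.song.set_id, None)
        return list(seen)

    def subset(self, keep: Iterable[int]) -> "ResponseDataset":
        keep = list(keep)
        return ResponseDataset([self.records[i] for i in keep])

    def for_set(self, set_id: str) -> "ResponseDataset":
        return ResponseDataset([r for r in self.records if r.song.set_id == set_id])

    def labels(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.update(r.song.subunits)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            pos, neg = r.pos_label, r.neg_label
            if not (pos or neg):
                raise ConfigError(
                    f"record {r.song.id!r} lacks pair labels; cannot serialise"
                )
            seq = "".join("P" if lab == pos else "N" for lab in r.song.subunits)
            rows.append(
                {
                    "song_id": r.song.id,
                    "set_id": r.song.set_id,
                    "sequence": seq,
                    "pos_label": pos,
                    "neg_label": neg,
                    "response_rate": r.response_rate,
                    "n_females": r.n_females,
                    "n_cycles": r.n_cycles,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseDataset":
        records = []
        for row in df.itertuples(index=False):
            pos = "" if pd.isna(row.pos_label) else str(row.pos_label)
            neg = "" if pd.isna(row.neg_label) else str(row.neg_label)
            labels = tuple(pos if c == "P" else neg for c in str(row.sequence))
            if "" in labels:
                raise ConfigError(f"song {row.song_id!r}: missing pair label")
            song = SongModel(id=str(row.song_id), subunits=labels, set_id=str(row.set_id))
            records.append(
                ResponseRecord(
                    song=song,
                    response_rate=float(row.response_rate),
                    n_females=int(row.n_females),
                    n_cycles=int(row.n_cycles),
                    pos_label=pos,
                    neg_label=neg,
                )
            )
        return cls(records)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResponseDataset":
        return cls.from_frame(pd.read_csv(path))
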