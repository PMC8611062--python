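"""Preprocessing: raw stress/puff event tables -> chunked minute-level dataset.

The pipeline mirrors how minute-level sensor markers are prepared for
system identification:

1. round event timestamps to the nearest minute (averaging colliding stress
   probabilities),
2. linearly interpolate short (<= 2 min) gaps in the stress series,
3. delimit each smoking episode with a sliding 5-minute / 4-puff window and
   write its minutes into the binary smoking column,
4. split the series into maximal gap-free chunks and drop chunks shorter
   than 5 minutes.

Stress probabilities live in [0, 1]; smoking is binary; missing minutes are
NaN in the stress column and undefined in the smoking column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    EmptyInputError,
    InputError,
    InvalidEpisodeError,
    ParameterError,
)

__all__ = [
    "RawEventTable",
    "MinuteSeries",
    "Chunk",
    "ChunkedDataset",
    "to_minute_grid",
    "interpolate_short_gaps",
    "delimit_smoking_episode",
    "apply_smoking_episodes",
    "make_chunks",
    "preprocess_participant",
    "read_stress_csv",
    "read_puffs_csv",
    "write_chunks_csv",
    "read_chunks_csv",
]

EPISODE_WINDOW_MINUTES = 5
EPISODE_MIN_PUFFS = 4


@dataclass(frozen=True)
class RawEventTable:
    """Raw per-participant event tables in Unix-epoch seconds."""

    participant_id: str
    stress_rows: list[tuple[int, float]]
    puff_rows: list[tuple[int, list[int]]]  # (episode start epoch, puff epochs)


@dataclass
class MinuteSeries:
    """Minute-indexed stress/smoking series; NaN stress marks a missing minute.

    ``minute_index`` counts minutes from the participant's first (rounded)
    sample.  The smoking column is only meaningful where stress is present.
    """

    participant_id: str
    minute_index: np.ndarray
    stress: np.ndarray
    smoking: np.ndarray

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.stress)

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(
            self.participant_id,
            self.minute_index.copy(),
            self.stress.copy(),
            self.smoking.copy(),
        )


@dataclass(frozen=True)
class Chunk:
    """A maximal run of consecutive non-missing minutes."""

    chunk_id: int
    start_minute: int
    u: np.ndarray  # stress input, [0, 1]
    s: np.ndarray  # binary smoking output

    @property
    def length(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class ChunkedDataset:
    """Retained chunks for one participant plus their summary statistics."""

    participant_id: str
    chunks: tuple[Chunk, ...]

    @property
    def N_ch(self) -> int:
        return len(self.chunks)

    @property
    def N_l(self) -> float:
        """Mean retained chunk length in minutes (unrounded)."""
        return float(np.mean([c.length for c in self.chunks]))

    @property
    def total_minutes(self) -> int:
        return int(sum(c.length for c in self.chunks))

    def chunk(self, chunk_id: int) -> Chunk:
        for c in self.chunks:
            if c.chunk_id == chunk_id:
                return c
        raise KeyError(f"no chunk with id {chunk_id}")


def _round_minute(epoch_seconds: int) -> int:
    # nearest minute, half-up; sub-minute offsets collapse onto one sample
    return int((int(epoch_seconds) + 30) // 60)


def to_minute_grid(raw: RawEventTable) -> MinuteSeries:
    """Round stress samples to the nearest minute and place them on a dense grid.

    Two or more samples landing on the same minute are averaged.  The grid
    spans the first to the last rounded minute; minutes with no sample are
    missing (NaN).  Smoking is initialized to 0 wherever stress is present.
    """
    if not raw.stress_rows:
        raise EmptyInputError(f"no stress samples for participant {raw.participant_id}")
    epochs = np.array([e for e, _ in raw.stress_rows], dtype=np.int64)
    probs = np.array([v for _, v in raw.stress_rows], dtype=float)
    if np.any(epochs < 0):
        raise InputError("epoch timestamps must be nonnegative")
    if np.any((probs < 0.0) | (probs > 1.0)) or np.any(~np.isfinite(probs)):
        raise InputError("stress probabilities must lie in [0, 1]")

    minutes = (epochs + 30) // 60
    origin = int(minutes.min())
    rel = minutes - origin
    n = int(rel.max()) + 1

    stress = np.full(n, np.nan)
    counts = np.zeros(n)
    sums = np.zeros(n)
    np.add.at(sums, rel, probs)
    np.add.at(counts, rel, 1.0)
    observed = counts > 0
    stress[observed] = sums[observed] / counts[observed]

    smoking = np.zeros(n, dtype=np.int8)
    return MinuteSeries(
        participant_id=raw.participant_id,
        minute_index=np.arange(n, dtype=np.int64),
        stress=stress,
        smoking=smoking,
    )


def interpolate_short_gaps(series: MinuteSeries, max_gap: int = 2) -> MinuteSeries:
    """Linearly interpolate missing stress runs of length <= ``max_gap``.

    Only gaps flanked by observed values on both sides are filled; longer
    gaps carry too little information and stay missing.  Observed values are
    never altered, so the operation is idempotent.
    """
    if max_gap < 0:
        raise ParameterError("max_gap must be nonnegative")
    out = series.copy()
    stress = out.stress
    missing = np.isnan(stress)
    n = stress.size
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run = j - i
        if run <= max_gap and i > 0 and j < n:
            left, right = stress[i - 1], stress[j]
            for k in range(run):
                frac = (k + 1) / (run + 1)
                stress[i + k] = left + frac * (right - left)
            out.smoking[i:j] = 0  # interpolated minutes default to non-smoking
        i = j
    return out


def delimit_smoking_episode(
    start_minute: int, puff_minutes: list[int]
) -> tuple[int, list[int]]:
    """Extend a smoking episode with a sliding 5-minute window of >= 4 puffs.

    Windows ``W_i = [start+i, start+i+5)`` advance one minute at a time;
    extension stops at the first window containing fewer than four puffs.
    The episode ends at the largest puff minute inside any qualifying window,
    and every minute from ``start_minute`` to that end is a smoking minute.
    """
    puffs = np.asarray(sorted(puff_minutes), dtype=np.int64)
    if puffs.size == 0:
        raise InvalidEpisodeError("episode has no puffs")

    def _count(lo: int) -> int:
        return int(np.sum((puffs >= lo) & (puffs < lo + EPISODE_WINDOW_MINUTES)))

    if _count(start_minute) < EPISODE_MIN_PUFFS:
        raise InvalidEpisodeError(
            f"episode at minute {start_minute} has fewer than "
            f"{EPISODE_MIN_PUFFS} puffs in its first {EPISODE_WINDOW_MINUTES}-min window"
        )

    end = start_minute
    i = 0
    while _count(start_minute + i) >= EPISODE_MIN_PUFFS:
        lo = start_minute + i
        in_window = puffs[(puffs >= lo) & (puffs < lo + EPISODE_WINDOW_MINUTES)]
        end = max(end, int(in_window.max()))
        i += 1
    return end, list(range(start_minute, end + 1))


def apply_smoking_episodes(
    series: MinuteSeries,
    episodes: list[tuple[int, list[int]]],
    origin_minute: int = 0,
) -> MinuteSeries:
    """Write delimited episode minutes into the smoking column (OR-combined).

    ``episodes`` holds (start_minute, puff_minutes) in absolute minutes;
    ``origin_minute`` is the absolute minute of the series' index 0.  Smoking
    minutes falling into missing-stress gaps are discarded with the gap: the
    chunked dataset follows stress availability.
    """
    out = series.copy()
    n = out.stress.size
    for start, puffs in episodes:
        _, smoking_minutes = delimit_smoking_episode(start, puffs)
        for m in smoking_minutes:
            rel = m - origin_minute
            if 0 <= rel < n and not np.isnan(out.stress[rel]):
                out.smoking[rel] = 1
    return out


def make_chunks(series: MinuteSeries, min_length: int = 5) -> ChunkedDataset:
    """Split a series into maximal gap-free chunks, dropping short ones.

    Chunks shorter than ``min_length`` minutes carry too little dynamical
    information and are excluded; chunk ids number the retained chunks from 1.
    """
    if min_length < 1:
        raise ParameterError("min_length must be >= 1")
    present = ~np.isnan(series.stress)
    chunks: list[Chunk] = []
    n = present.size
    i = 0
    cid = 0
    while i < n:
        if not present[i]:
            i += 1
            continue
        j = i
        while j < n and present[j]:
            j += 1
        if j - i >= min_length:
            cid += 1
            chunks.append(
                Chunk(
                    chunk_id=cid,
                    start_minute=int(series.minute_index[i]),
                    u=series.stress[i:j].copy(),
                    s=series.smoking[i:j].astype(np.int8),
                )
            )
        i = j
    if not chunks:
        raise EmptyDatasetError(
            f"no chunk of length >= {min_length} for participant {series.participant_id}"
        )
    return ChunkedDataset(participant_id=series.participant_id, chunks=tuple(chunks))


# ---------------------------------------------------------------------------
# File-level pipeline


def read_stress_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp_unix_s", "stress_probability"}
    if not required.issubset(df.columns):
        raise InputError(f"stress table must have columns {sorted(required)}")
    return df


def read_puffs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "episode_start_unix_s", "puff_unix_s"}
    if not required.issubset(df.columns):
        raise InputError(f"puff table must have columns {sorted(required)}")
    return df


def preprocess_participant(
    stress_df: pd.DataFrame,
    puffs_df: pd.DataFrame,
    participant_id: str,
    max_gap: int = 2,
    min_chunk: int = 5,
) -> tuple[ChunkedDataset, dict]:
    """Run the full pipeline for one participant; returns (dataset, report)."""
    srows = stress_df[stress_df["participant_id"].astype(str) == str(participant_id)]
    if srows.empty:
        raise EmptyInputError(f"no stress rows for participant {participant_id}")
    raw = RawEventTable(
        participant_id=str(participant_id),
        stress_rows=list(
            zip(srows["timestamp_unix_s"].astype(int), srows["stress_probability"].astype(float))
        ),
        puff_rows=[],
    )
    series = to_minute_grid(raw)
    origin = _round_minute(int(srows["timestamp_unix_s"].min()))
    series = interpolate_short_gaps(series, max_gap=max_gap)

    prows = puffs_df[puffs_df["participant_id"].astype(str) == str(participant_id)]
    episodes = []
    for start_epoch, grp in prows.groupby("episode_start_unix_s"):
        start_min = _round_minute(int(start_epoch))
        puff_mins = [_round_minute(int(e)) for e in grp["puff_unix_s"]]
        episodes.append((start_min, puff_mins))
    series = apply_smoking_episodes(series, episodes, origin_minute=origin)

    dataset = make_chunks(series, min_length=min_chunk)

    present = ~np.isnan(series.stress)
    dropped = []
    i, n = 0, present.size
    while i < n:
        if present[i]:
            j = i
            while j < n and present[j]:
                j += 1
            if j - i < min_chunk:
                dropped.append({"start_minute": int(i), "length": int(j - i)})
            i = j
        else:
            i += 1
    report = {
        "participant_id": str(participant_id),
        "N_ch": dataset.N_ch,
        "N_l": dataset.N_l,
        "total_minutes": dataset.total_minutes,
        "dropped_runs": dropped,
    }
    return dataset, report


def write_chunks_csv(datasets: list[ChunkedDataset], path, sidecar_path=None) -> None:
    rows = []
    for ds in datasets:
        for c in ds.chunks:
            for m in range(c.length):
                rows.append(
                    {
                        "participant_id": ds.participant_id,
                        "chunk_id": c.chunk_id,
                        "minute": c.start_minute + m,
                        "stress": c.u[m],
                        "smoking": int(c.s[m]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar_path is not None:
        meta = {
            ds.participant_id: {"N_ch": ds.N_ch, "N_l": ds.N_l, "total_minutes": ds.total_minutes}
            for ds in datasets
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_chunks_csv(path, participant_id: str | None = None) -> ChunkedDataset:
    df = pd.read_csv(path)
    if participant_id is None:
        ids = df["participant_id"].astype(str).unique()
        if len(ids) != 1:
            raise InputError("chunks file has several participants; pass participant_id")
        participant_id = ids[0]
    df = df[df["participant_id"].astype(str) == str(participant_id)]
    if df.empty:
        raise EmptyInputError(f"no chunks for participant {participant_id}")
    chunks = []
    for cid, grp in df.groupby("chunk_id"):
        grp = grp.sort_values("minute")
        chunks.append(
            Chunk(
                chunk_id=int(cid),
                start_minute=int(grp["minute"].iloc[0]),
                u=grp["stress"].to_numpy(dtype=float),
                s=grp["smoking"].to_numpy(dtype=np.int8),
            )
        )
    chunks.sort(key=lambda c: c.chunk_id)
    return ChunkedDataset(participant_id=str(participant_id), chunks=tuple(chunks))
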