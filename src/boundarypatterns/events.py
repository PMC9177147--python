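"""Experiment timelines and window arithmetic.

The experiment has two phases: *encoding* (subjects watch 10 short movies,
each preceded by a 6 s title scene, split over two scanning runs) and
*recall* (subjects freely recount the movies in an order of their choosing,
with spontaneous pauses between movies). All analyses are built from mean
spatial activation patterns inside fixed windows placed relative to movie
onsets and offsets, shifted forward to account for the hemodynamic delay.

Conventions used throughout the package:

* times are seconds on the *run clock*: acquisition of volume 1 = 0 s;
* TR indices are 0-based and windows are half-open ``[start, end)``;
* a TR belongs to a window iff its acquisition onset falls inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHASES = ("encoding", "recall")
EVENT_KINDS = ("movie", "title", "within_event_boundary", "pause")

#: Encoding stimulus presentation starts 3 s after the first volume of each
#: run; stimulus-clock times must be converted explicitly with
#: :func:`stimulus_to_run_clock`.
STIMULUS_START_S = 3.0

EVENT_COLUMNS = ["subject", "phase", "run", "movie_id", "kind", "onset_s", "offset_s"]


def stimulus_to_run_clock(t_s: float) -> float:
    """Convert an encoding stimulus-clock time to the scanner run clock."""
    return t_s + STIMULUS_START_S


@dataclass(frozen=True)
class WindowSpec:
    """Boundary/non-boundary window geometry.

    Parameters
    ----------
    shift_s:
        Forward shift applied to every window to account for the
        hemodynamic response delay. Default 4.5 s.
    duration_s:
        Window length. Default 15 s; a 4.5 s variant is used for
        control analyses.
    """

    shift_s: float = 4.5
    duration_s: float = 15.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shift_s) and math.isfinite(self.duration_s)):
            raise ValueError("window parameters must be finite")
        if self.shift_s < 0:
            raise ValueError("shift_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


#: The default 15 s analysis window, shifted 4.5 s.
DEFAULT_WINDOW = WindowSpec()
#: The short-window control variant (4.5 s windows, same shift).
SHORT_WINDOW = WindowSpec(shift_s=4.5, duration_s=4.5)


@dataclass
class RunData:
    """One scanning run: a vertex x TR matrix plus acquisition metadata.

    ``trim_offset_s`` records how much initial acquisition time was
    discarded upstream: column 0 of ``data`` was acquired at
    ``trim_offset_s`` seconds on the run clock. Event times always stay on
    the run clock, so trimming never rewrites the event table.
    """

    subject_id: str
    phase: str
    run: int
    data: np.ndarray
    vertex_parcel: np.ndarray
    tr_s: float = 1.5
    trim_offset_s: float = 0.0
    vertex_area_mm2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D vertex x TR matrix")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.run < 1:
            raise ValueError("run index is 1-based")
        if np.isnan(self.data).any():
            raise ValueError("run data contains NaNs")
        self.vertex_parcel = np.asarray(self.vertex_parcel)
        if self.vertex_parcel.shape != (self.data.shape[0],):
            raise ValueError("vertex_parcel length must equal n_vertices")
        if self.trim_offset_s < 0:
            raise ValueError("trim_offset_s must be non-negative")
        k = self.trim_offset_s / self.tr_s
        if abs(k - round(k)) > 1e-9:
            raise ValueError("trim_offset_s must be a multiple of tr_s")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    def region_vertices(self, parcels: Iterable[int]) -> np.ndarray:
        """Indices of vertices whose parcel label is in ``parcels``."""
        idx = np.flatnonzero(np.isin(self.vertex_parcel, list(parcels)))
        if idx.size == 0:
            raise ValueError("region contains no vertices")
        return idx


class EventTable:
    """Timestamped experiment events for one or more subjects.

    Thin wrapper around a pandas DataFrame with columns
    ``(subject, phase, run, movie_id, kind, onset_s, offset_s)``.
    Interval events (movie, title, pause) carry an ``offset_s``; point
    events (within-movie boundaries) leave it NaN.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)[EVENT_COLUMNS].copy()
        self.validate()

    def validate(self) -> None:
        df = self.df
        bad_kind = ~df["kind"].isin(EVENT_KINDS)
        if bad_kind.any():
            row = int(np.flatnonzero(bad_kind.to_numpy())[0])
            raise ValueError(
                f"row {row}: unknown event kind {df['kind'].iloc[row]!r}"
            )
        bad_phase = ~df["phase"].isin(PHASES)
        if bad_phase.any():
            row = int(np.flatnonzero(bad_phase.to_numpy())[0])
            raise ValueError(f"row {row}: unknown phase {df['phase'].iloc[row]!r}")
        interval = df["kind"] != "within_event_boundary"
        iv = df[interval]
        if not (iv["offset_s"] > iv["onset_s"]).all():
            raise ValueError("interval events must have offset_s > onset_s")
        # movie intervals must not overlap within a (subject, phase, run)
        movies = df[df["kind"] == "movie"]
        for key, grp in movies.groupby(["subject", "phase", "run"]):
            g = grp.sort_values("onset_s")
            if (g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping movie intervals in {key}")

    # -- selectors -------------------------------------------------------
    def subjects(self) -> list[str]:
        return sorted(self.df["subject"].unique())

    def select(self, subject=None, phase=None, run=None, kind=None) -> pd.DataFrame:
        df = self.df
        if subject is not None:
            df = df[df["subject"] == subject]
        if phase is not None:
            df = df[df["phase"] == phase]
        if run is not None:
            df = df[df["run"] == run]
        if kind is not None:
            df = df[df["kind"] == kind]
        return df

    def movies(self, subject, phase, run=None) -> pd.DataFrame:
        return self.select(subject, phase, run, "movie").sort_values("onset_s")

    def titles(self, subject, run=None) -> pd.DataFrame:
        return self.select(subject, "encoding", run, "title").sort_values("onset_s")

    def within_boundaries(self, subject) -> pd.DataFrame:
        return self.select(subject, "encoding", None, "within_event_boundary")

    def pauses(self, subject) -> pd.DataFrame:
        return self.select(subject, "recall", None, "pause")

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)


def seconds_to_tr_range(start_s: float, end_s: float, run: RunData) -> range:
    """TR indices whose acquisition onset lies in ``[start_s, end_s)``.

    The returned half-open ``range`` is clipped to ``[0, n_trs)`` and may
    be empty.
    """
    if not (math.isfinite(start_s) and math.isfinite(end_s)):
        raise ValueError("window bounds must be finite")
    if start_s >= end_s:
        raise ValueError("start_s must precede end_s")
    # TR k onset = trim_offset_s + k * tr_s; epsilon guards float noise on
    # the exact-grid-alignment case.
    lo = math.ceil((start_s - run.trim_offset_s) / run.tr_s - 1e-9)
    hi = math.ceil((end_s - run.trim_offset_s) / run.tr_s - 1e-9)
    lo = max(lo, 0)
    hi = min(hi, run.n_trs)
    if hi <= lo:
        return range(0, 0)
    return range(lo, hi)


def boundary_window(offset_s: float, spec: WindowSpec = DEFAULT_WINDOW) -> tuple[float, float]:
    """Post-offset boundary window ``[offset + shift, offset + shift + dur)``."""
    if not math.isfinite(offset_s):
        raise ValueError("offset_s must be finite")
    start = offset_s + spec.shift_s
    return (start, start + spec.duration_s)


def middle_window(
    onset_s: float, offset_s: float, spec: WindowSpec = DEFAULT_WINDOW
) -> tuple[float, float]:
    """Non-boundary window: ``duration_s`` centered at the item midpoint,
    then shifted forward by ``shift_s``."""
    if not (math.isfinite(onset_s) and math.isfinite(offset_s)):
        raise ValueError("onset/offset must be finite")
    if offset_s - onset_s < spec.duration_s:
        raise ValueError(
            f"item [{onset_s}, {offset_s}) shorter than the "
            f"{spec.duration_s} s window"
        )
    mid = 0.5 * (onset_s + offset_s)
    start = mid - spec.duration_s / 2.0 + spec.shift_s
    return (start, start + spec.duration_s)


def extract_mean_pattern(
    run: RunData, tr_range: range, vertices: np.ndarray | None = None
) -> np.ndarray:
    """Mean spatial pattern across the TRs in ``tr_range``.

    Raises if the range is empty after clipping (the caller names the
    offending event in its own message).
    """
    if len(tr_range) == 0:
        raise ValueError("empty TR range: window lies outside the run")
    block = run.data[:, tr_range.start : tr_range.stop]
    if vertices is not None:
        block = block[vertices]
    # accumulate in float64 even for float32-stored runs
    return block.mean(axis=1, dtype=np.float64)
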