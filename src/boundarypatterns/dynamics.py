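"""Time-locked pattern dynamics around movie onsets and offsets.

For each movie we extract the spatial pattern at every TR on a grid from
30 s before to 60 s after the locking event (onset or offset of the
watched/recalled movie; 61 points at TR = 1.5 s), average across movies,
and then correlate the resulting pattern time series across time points
(within or between phases) to form time-time correlation matrices.
No hemodynamic shift is applied here: time 0 is the true stimulus or
behaviour time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventTable, RunData, seconds_to_tr_range
from .stats import bonferroni_mask

T_MIN_S = -30.0
T_MAX_S = 60.0


@dataclass
class TimeLockedSeries:
    """Mean peri-boundary pattern time series for one subject/region.

    ``patterns`` is (n_grid, n_vertices); grid points where no movie
    contributed (outside the run for all movies) are NaN rows with
    ``valid_counts`` 0.
    """

    lock: str
    phase: str
    times_s: np.ndarray
    patterns: np.ndarray
    valid_counts: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.valid_counts > 0


def timelocked_grid(tr_s: float = 1.5) -> np.ndarray:
    return np.arange(T_MIN_S, T_MAX_S + tr_s / 2, tr_s)


def timelocked_pattern_series(
    runs: dict,
    events: EventTable,
    lock: str = "offset",
    phase: str = "recall",
    region: tuple | None = None,
    subject: str | None = None,
) -> TimeLockedSeries:
    """Average peri-onset/offset pattern time series across movies.

    Grid points falling outside the run for a particular movie are
    skipped for that movie (its contribution count is decremented);
    movies are weighted equally regardless of duration.
    """
    if lock not in ("onset", "offset"):
        raise ValueError("lock must be 'onset' or 'offset'")
    if subject is None:
        subjects = {k[0] for k in runs}
        if len(subjects) != 1:
            raise ValueError("pass subject= when runs span multiple subjects")
        subject = subjects.pop()

    srun = {k: v for k, v in runs.items() if k[0] == subject and k[1] == phase}
    if not srun:
        raise ValueError(f"no {phase} runs for subject {subject}")
    any_run = next(iter(srun.values()))
    tr = any_run.tr_s
    grid = timelocked_grid(tr)
    vid = any_run.region_vertices(region) if region is not None else np.arange(
        any_run.n_vertices
    )

    acc = np.zeros((grid.size, vid.size))
    cnt = np.zeros(grid.size, dtype=int)
    for (subj, ph, run_no), run in srun.items():
        mv = events.movies(subject, phase, run_no)
        for _, row in mv.iterrows():
            anchor = row["onset_s"] if lock == "onset" else row["offset_s"]
            for gi, tau in enumerate(grid):
                t = anchor + tau
                rng = seconds_to_tr_range(t, t + tr, run)
                if len(rng) == 0:
                    continue
                acc[gi] += run.data[np.ix_(vid, [rng.start])][:, 0]
                cnt[gi] += 1
    patterns = np.full((grid.size, vid.size), np.nan)
    nz = cnt > 0
    patterns[nz] = acc[nz] / cnt[nz, np.newaxis]
    return TimeLockedSeries(
        lock=lock, phase=phase, times_s=grid, patterns=patterns, valid_counts=cnt
    )


def timetime_matrix(series_a: TimeLockedSeries, series_b: TimeLockedSeries) -> np.ndarray:
    """Pearson correlation between every pair of time points of two
    pattern time series; cells involving invalid grid points are NaN."""
    A, B = series_a.patterns, series_b.patterns
    if A.shape[1] != B.shape[1]:
        raise ValueError("series must share the vertex dimension")
    n = A.shape[0]
    out = np.full((n, len(B)), np.nan)
    va, vb = series_a.valid, series_b.valid
    Az = A[va] - A[va].mean(axis=1, keepdims=True)
    Bz = B[vb] - B[vb].mean(axis=1, keepdims=True)
    Az /= np.linalg.norm(Az, axis=1, keepdims=True)
    Bz /= np.linalg.norm(Bz, axis=1, keepdims=True)
    out[np.ix_(va, vb)] = Az @ Bz.T
    return out


def group_timetime_significance(
    matrices: list[np.ndarray], alpha: float = 0.05
):
    """Cell-wise two-tailed one-sample t-test across subjects with
    Bonferroni correction over all testable cells.

    A cell is testable when every subject has a value there; the
    Bonferroni denominator is the count of testable cells. Returns
    (significant mask, t map, p map).
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects")
    stack = np.stack(matrices)
    testable = ~np.isnan(stack).any(axis=0)
    n = stack.shape[0]
    t_map = np.full(stack.shape[1:], np.nan)
    p_map = np.full(stack.shape[1:], np.nan)
    sig = np.zeros(stack.shape[1:], dtype=bool)
    idx = np.flatnonzero(testable.ravel())
    if idx.size == 0:
        return sig, t_map, p_map
    vals = stack.reshape(n, -1)[:, idx]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    ok = sd > 0
    from scipy import stats as sps

    t = np.full(idx.size, np.nan)
    p = np.full(idx.size, np.nan)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), n - 1)
    t_map.ravel()[idx] = t
    p_map.ravel()[idx] = p
    m = idx.size
    rej = np.zeros(idx.size, dtype=bool)
    rej[ok] = p[ok] < alpha / m
    sig.ravel()[idx] = rej
    return sig, t_map, p_map
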