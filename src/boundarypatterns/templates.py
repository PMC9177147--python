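"""Within-movie event-boundary templates vs between-movie boundary templates.

Coarse within-movie scene boundaries (supplied by human coders in the
real experiment, planted by the generator here) are compared with the
between-movie boundary pattern: for each subject we average the
post-boundary window patterns into templates and correlate them.
Boundaries within the first 45 s of a movie are excluded to avoid
carry-over from the preceding between-movie boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    EventTable,
    WindowSpec,
    DEFAULT_WINDOW,
    boundary_window,
    middle_window,
    seconds_to_tr_range,
    extract_mean_pattern,
)
from .stats import GroupTestResult, one_sample_t, paired_t

EXCLUSION_S = 45.0


@dataclass
class TemplateSet:
    """Per-subject boundary templates over a region.

    ``between_encoding`` / ``between_recall``: mean over the 10 movie
    offset-window patterns of each phase. ``within``: mean over retained
    within-movie event-boundary window patterns (encoding only).
    """

    subject_id: str
    between_encoding: np.ndarray
    between_recall: np.ndarray
    within: np.ndarray
    retained_boundaries: pd.DataFrame


def select_within_boundaries(
    events: EventTable, subject: str, exclusion_s: float = EXCLUSION_S
) -> pd.DataFrame:
    """Within-movie boundaries at least ``exclusion_s`` into their movie.

    A boundary exactly at the threshold is retained (>= convention).
    Returns a frame with columns (run, movie_id, onset_s, rel_s).
    """
    wb = events.within_boundaries(subject)
    out = []
    for _, row in wb.iterrows():
        mv = events.movies(subject, "encoding", int(row["run"]))
        mine = mv[
            (mv["movie_id"] == row["movie_id"])
            & (mv["onset_s"] <= row["onset_s"])
            & (row["onset_s"] < mv["offset_s"])
        ]
        if mine.empty:
            raise ValueError(
                f"within-movie boundary at {row['onset_s']} s has no "
                "containing movie interval"
            )
        rel = row["onset_s"] - float(mine["onset_s"].iloc[0])
        if rel >= exclusion_s:
            out.append(
                {
                    "run": int(row["run"]),
                    "movie_id": int(row["movie_id"]),
                    "onset_s": float(row["onset_s"]),
                    "rel_s": rel,
                }
            )
    return pd.DataFrame(out, columns=["run", "movie_id", "onset_s", "rel_s"])


def _window_pattern(run, t0, t1, vid, what):
    rng = seconds_to_tr_range(t0, t1, run)
    if len(rng) == 0:
        raise ValueError(f"empty window for {what}")
    return extract_mean_pattern(run, rng, vid)


def build_templates(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    region: tuple | None = None,
    subject: str | None = None,
    exclusion_s: float = EXCLUSION_S,
) -> TemplateSet:
    """Two-stage averaging: mean over TRs within each post-boundary
    window, then mean across boundaries (within-movie) or movies
    (between-movie, per phase)."""
    if subject is None:
        subjects = {k[0] for k in runs}
        if len(subjects) != 1:
            raise ValueError("pass subject= when runs span multiple subjects")
        subject = subjects.pop()
    srun = {k: v for k, v in runs.items() if k[0] == subject}
    any_run = next(iter(srun.values()))
    vid = any_run.region_vertices(region) if region is not None else None

    between = {"encoding": [], "recall": []}
    for (subj, phase, run_no), run in srun.items():
        for _, row in events.movies(subject, phase, run_no).iterrows():
            t0, t1 = boundary_window(row["offset_s"], spec)
            between[phase].append(
                _window_pattern(run, t0, t1, vid, f"movie {row['movie_id']} offset")
            )

    retained = select_within_boundaries(events, subject, exclusion_s)
    if retained.empty:
        raise ValueError(f"no retained within-movie boundaries for {subject}")
    within = []
    for _, row in retained.iterrows():
        run = srun[(subject, "encoding", int(row["run"]))]
        t0, t1 = boundary_window(row["onset_s"], spec)
        within.append(
            _window_pattern(run, t0, t1, vid, f"within-boundary at {row['onset_s']} s")
        )

    return TemplateSet(
        subject_id=subject,
        between_encoding=np.mean(between["encoding"], axis=0),
        between_recall=np.mean(between["recall"], axis=0),
        within=np.mean(within, axis=0),
        retained_boundaries=retained,
    )


def _corr(x, y):
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant template: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class TemplateSimilarity:
    """Group comparison of template correlations.

    ``orange``: encoding-between vs recall-between templates (cross-phase
    consistency of the between-movie boundary pattern). ``green``:
    encoding within-movie template vs recall between-movie template.
    """

    orange_r: np.ndarray
    green_r: np.ndarray
    orange_stats: GroupTestResult
    green_stats: GroupTestResult


def template_similarity(template_sets: list[TemplateSet]) -> TemplateSimilarity:
    orange = np.array(
        [_corr(ts.between_encoding, ts.between_recall) for ts in template_sets]
    )
    green = np.array(
        [_corr(ts.within, ts.between_recall) for ts in template_sets]
    )
    return TemplateSimilarity(
        orange_r=orange,
        green_r=green,
        orange_stats=one_sample_t(orange),
        green_stats=one_sample_t(green),
    )


def intervals_overlap(a: tuple, b: tuple) -> bool:
    """Nonzero intersection of two half-open intervals."""
    return a[0] < b[1] and b[0] < a[1]


def within_movie_consistency(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    region: tuple | None = None,
    exclusion_s: float = EXCLUSION_S,
):
    """Consistency of within-movie boundary patterns during encoding.

    Per subject: (i) mean between-movie Pearson r across retained
    within-movie boundary patterns; (ii) mean between-movie r between
    within-movie boundary patterns and mid-movie non-boundary patterns,
    excluding non-boundary windows that overlap any retained boundary
    window. Returns per-subject arrays and group tests (one-sample on
    (i); paired (i) vs (ii)).
    """
    subjects = sorted({k[0] for k in runs})
    cons, cross = [], []
    for subject in subjects:
        srun = {k: v for k, v in runs.items() if k[0] == subject}
        any_run = next(iter(srun.values()))
        vid = any_run.region_vertices(region) if region is not None else None

        retained = select_within_boundaries(events, subject, exclusion_s)
        if retained.empty:
            raise ValueError(f"no retained within-movie boundaries for {subject}")
        b_patterns, b_movies, b_windows = [], [], []
        for _, row in retained.iterrows():
            run = srun[(subject, "encoding", int(row["run"]))]
            w = boundary_window(row["onset_s"], spec)
            b_patterns.append(
                _window_pattern(run, w[0], w[1], vid, "within-boundary")
            )
            b_movies.append(int(row["movie_id"]))
            b_windows.append((int(row["run"]), w))

        nb_patterns, nb_movies = [], []
        for (subj, phase, run_no), run in srun.items():
            if phase != "encoding":
                continue
            for _, row in events.movies(subject, "encoding", run_no).iterrows():
                w = middle_window(row["onset_s"], row["offset_s"], spec)
                if any(
                    r == run_no and intervals_overlap(w, bw)
                    for r, bw in b_windows
                ):
                    continue
                nb_patterns.append(
                    _window_pattern(run, w[0], w[1], vid, "non-boundary")
                )
                nb_movies.append(int(row["movie_id"]))

        rs = [
            _corr(b_patterns[i], b_patterns[j])
            for i in range(len(b_patterns))
            for j in range(i + 1, len(b_patterns))
            if b_movies[i] != b_movies[j]
        ]
        if not rs:
            raise ValueError(f"no valid between-movie boundary pairs for {subject}")
        cons.append(np.mean(rs))
        rx = [
            _corr(b, n)
            for b, bm in zip(b_patterns, b_movies)
            for n, nm in zip(nb_patterns, nb_movies)
            if bm != nm
        ]
        if not rx:
            raise ValueError(f"no boundary/non-boundary pairs for {subject}")
        cross.append(np.mean(rx))

    cons = np.asarray(cons)
    cross = np.asarray(cross)
    return {
        "consistency_r": cons,
        "cross_r": cross,
        "consistency_stats": one_sample_t(cons),
        "paired_stats": paired_t(cons, cross),
    }
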