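"""Boundary-pattern similarity: pattern sets, between-movie correlations,
conjunction maps, and the visual-feature control contrast.

For each subject, region, movie (1-10), phase (encoding/recall) and
condition (boundary = post-offset window, non-boundary = mid-movie
window) we extract one mean spatial pattern, then correlate patterns
across movies, conditions and phases (Pearson). "Between-movie" always
means movie i vs movie j with i != j: 45 unordered pairs within a phase,
90 ordered pairs across phases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .events import (
    EventTable,
    RunData,
    WindowSpec,
    DEFAULT_WINDOW,
    boundary_window,
    middle_window,
    seconds_to_tr_range,
    extract_mean_pattern,
)
from .stats import one_sample_t, paired_t, bonferroni_mask

CONDITIONS = ("boundary", "nonboundary")


@dataclass
class PatternSet:
    """Mean spatial patterns per (phase, movie, condition) for one subject.

    ``patterns`` maps ``(phase, movie_id, condition)`` to a vertex vector
    over the region; cells a subject never recalled are listed in
    ``missing`` instead.
    """

    subject_id: str
    region: tuple
    patterns: dict
    missing: list = field(default_factory=list)

    def get(self, phase: str, movie_id: int, condition: str):
        return self.patterns.get((phase, movie_id, condition))

    def movies_present(self, phase: str, condition: str) -> list[int]:
        return sorted(
            m for (ph, m, c) in self.patterns if ph == phase and c == condition
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x.std()
    ys = y.std()
    if xs == 0 or ys == 0:
        raise ValueError("Pearson correlation undefined for constant pattern")
    return float(np.corrcoef(x, y)[0, 1])


def subject_runs(runs: dict, subject: str) -> dict:
    return {k: v for k, v in runs.items() if k[0] == subject}


def build_pattern_set(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    region: tuple | None = None,
    subject: str | None = None,
) -> PatternSet:
    """Extract the (up to) 40 condition patterns for one subject.

    ``runs`` maps ``(subject, phase, run)`` to preprocessed RunData;
    ``region`` is a tuple of parcel labels (None = all vertices).
    Movies missing from the recall event table are recorded, not errors.
    """
    if subject is None:
        subjects = {k[0] for k in runs}
        if len(subjects) != 1:
            raise ValueError("pass subject= when runs span multiple subjects")
        subject = subjects.pop()
    srun = subject_runs(runs, subject)
    if not srun:
        raise ValueError(f"no runs for subject {subject}")
    any_run = next(iter(srun.values()))
    vid = any_run.region_vertices(region) if region is not None else None

    patterns = {}
    missing = []
    for phase in ("encoding", "recall"):
        present = set()
        for (subj, ph, run_no), run in srun.items():
            if ph != phase:
                continue
            mv = events.movies(subject, phase, run_no)
            for _, row in mv.iterrows():
                m = int(row["movie_id"])
                present.add(m)
                for cond in CONDITIONS:
                    if cond == "boundary":
                        win = boundary_window(row["offset_s"], spec)
                    else:
                        win = middle_window(row["onset_s"], row["offset_s"], spec)
                    rng = seconds_to_tr_range(win[0], win[1], run)
                    if len(rng) == 0:
                        raise ValueError(
                            f"empty {cond} window for movie {m} "
                            f"({subject}, {phase}, run {run_no})"
                        )
                    patterns[(phase, m, cond)] = extract_mean_pattern(run, rng, vid)
        for m in range(1, 11):
            if m not in present:
                for cond in CONDITIONS:
                    missing.append((phase, m, cond))
    return PatternSet(
        subject_id=subject,
        region=tuple(region) if region is not None else (),
        patterns=patterns,
        missing=missing,
    )


def between_movie_pairs(movies_a, movies_b, ordered: bool):
    """Movie index pairs entering a between-movie average.

    Within-phase comparisons use unordered pairs (45 for 10 movies);
    cross-phase comparisons use all ordered pairs i != j (90).
    """
    if ordered:
        return [(i, j) for i in movies_a for j in movies_b if i != j]
    return [(i, j) for i, j in itertools.combinations(sorted(movies_a), 2)]


def mean_between_movie_similarity(
    ps: PatternSet,
    phase_pair: tuple = ("recall", "recall"),
    condition: str = "boundary",
    condition_b: str | None = None,
) -> float:
    """Mean pairwise between-movie Pearson r for one subject.

    ``phase_pair`` selects within-phase (e.g. ``("recall", "recall")``,
    45 unordered pairs) or cross-phase (``("encoding", "recall")``, 90
    ordered pairs). ``condition_b`` lets the second pattern of each pair
    come from a different condition (used by the visual control).
    """
    pa, pb = phase_pair
    cb = condition if condition_b is None else condition_b
    cross = pa != pb or cb != condition
    ma = ps.movies_present(pa, condition)
    mb = ps.movies_present(pb, cb)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need at least 2 movies per phase")
    pairs = between_movie_pairs(ma, mb, ordered=cross)
    rs = [
        _pearson(ps.get(pa, i, condition), ps.get(pb, j, cb)) for i, j in pairs
    ]
    return float(np.mean(rs))


@dataclass
class ParcelSimilarity:
    """Per-subject mean between-movie similarities for every parcel.

    ``a``/``b``: recall-recall boundary / non-boundary (Fig 2-style blue
    quantities); ``c``/``d``: encoding-recall boundary / non-boundary
    (red quantities). Shapes are (n_subjects, n_parcels).
    """

    parcels: tuple
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    subjects: tuple


def _pair_rows(ps: PatternSet, row: dict, phase_pair, cond_a, cond_b):
    """Row-index arrays into a stacked cell matrix for a between-movie
    pair average (unordered within phase/condition, ordered otherwise)."""
    pa, pb = phase_pair
    ma = ps.movies_present(pa, cond_a)
    mb = ps.movies_present(pb, cond_b)
    ordered = pa != pb or cond_a != cond_b
    pairs = between_movie_pairs(ma, mb, ordered=ordered)
    ia = np.array([row[(pa, i, cond_a)] for i, _ in pairs])
    ja = np.array([row[(pb, j, cond_b)] for _, j in pairs])
    return ia, ja


def parcelwise_similarity(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    parcels: tuple | None = None,
) -> ParcelSimilarity:
    """The four between-movie similarity quantities for every subject and
    parcel.

    One whole-brain pattern extraction per subject, then a single
    cell-by-cell correlation matrix per (subject, parcel) from which the
    pair averages are read out.
    """
    subjects = sorted({k[0] for k in runs})
    any_run = next(iter(runs.values()))
    if parcels is None:
        parcels = tuple(sorted(np.unique(any_run.vertex_parcel).tolist()))
    vidx = {p: np.flatnonzero(any_run.vertex_parcel == p) for p in parcels}

    quantities = {
        "a": (("recall", "recall"), "boundary", "boundary"),
        "b": (("recall", "recall"), "nonboundary", "nonboundary"),
        "c": (("encoding", "recall"), "boundary", "boundary"),
        "d": (("encoding", "recall"), "nonboundary", "nonboundary"),
    }
    out = {q: np.full((len(subjects), len(parcels)), np.nan) for q in quantities}
    for si, subject in enumerate(subjects):
        ps = build_pattern_set(runs, events, spec, region=None, subject=subject)
        keys = [k for k in ps.patterns]
        row = {k: i for i, k in enumerate(keys)}
        X = np.stack([ps.patterns[k] for k in keys])
        idx = {
            q: _pair_rows(ps, row, pair, ca, cb)
            for q, (pair, ca, cb) in quantities.items()
        }
        for pi, p in enumerate(parcels):
            C = np.corrcoef(X[:, vidx[p]])
            for q, (ia, ja) in idx.items():
                out[q][si, pi] = C[ia, ja].mean()
    return ParcelSimilarity(
        parcels=tuple(parcels),
        a=out["a"],
        b=out["b"],
        c=out["c"],
        d=out["d"],
        subjects=tuple(subjects),
    )


def conjunction_map(
    boundary_r: np.ndarray,
    nonboundary_r: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Parcels with (i) positive boundary similarity and (ii) boundary >
    non-boundary similarity, both Bonferroni-corrected across parcels.

    Inputs are (n_subjects, n_parcels) per-subject mean correlations;
    both tests are two-tailed, with the mask restricted to the positive
    direction as in the published maps.
    """
    boundary_r = np.asarray(boundary_r, dtype=float)
    nonboundary_r = np.asarray(nonboundary_r, dtype=float)
    if boundary_r.shape != nonboundary_r.shape or boundary_r.ndim != 2:
        raise ValueError("expected matching (n_subjects, n_parcels) arrays")
    if boundary_r.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n_parcels = boundary_r.shape[1]
    t1 = np.empty(n_parcels)
    p1 = np.empty(n_parcels)
    t2 = np.empty(n_parcels)
    p2 = np.empty(n_parcels)
    for j in range(n_parcels):
        r1 = one_sample_t(boundary_r[:, j])
        r2 = paired_t(boundary_r[:, j], nonboundary_r[:, j])
        t1[j], p1[j] = r1.t_stat, r1.p_two_tailed
        t2[j], p2[j] = r2.t_stat, r2.p_two_tailed
    pos = (t1 > 0) & (t2 > 0)
    return bonferroni_mask(p1, alpha) & bonferroni_mask(p2, alpha) & pos


# Fig 3A-style ordering of the 40 condition cells
CONDITION_ORDER = [
    (phase, cond, m)
    for phase in ("encoding", "recall")
    for cond in CONDITIONS
    for m in range(1, 11)
]


def full_condition_matrix(pattern_sets: list[PatternSet]) -> np.ndarray:
    """Group-average 40x40 pattern-correlation matrix.

    Rows/columns follow :data:`CONDITION_ORDER` (phase, condition, movie).
    Cells are averaged over subjects that have both patterns; the
    diagonal is exactly 1 and the matrix is symmetric.
    """
    n = len(CONDITION_ORDER)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for ps in pattern_sets:
        vecs = []
        for phase, cond, m in CONDITION_ORDER:
            vecs.append(ps.get(phase, m, cond))
        for i in range(n):
            if vecs[i] is None:
                continue
            for j in range(i, n):
                if vecs[j] is None:
                    continue
                r = 1.0 if i == j else _pearson(vecs[i], vecs[j])
                acc[i, j] += r
                cnt[i, j] += 1
    with np.errstate(invalid="ignore"):
        mat = acc / cnt
    iu = np.triu_indices(n, 1)
    mat[(iu[1], iu[0])] = mat[iu]
    return mat


def visual_control_contrast(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    parcels: tuple | None = None,
    alpha: float = 0.05,
):
    """Shared-visual-features control: is enc-boundary x rec-boundary
    similarity greater than enc-boundary x rec-non-boundary similarity?

    Returns (t, p, mask) over parcels; the mask is Bonferroni-corrected,
    positive direction. Recall visual input is identical in both
    conditions, so a positive contrast cannot be explained by low-level
    visual features shared at boundaries.
    """
    subjects = sorted({k[0] for k in runs})
    any_run = next(iter(runs.values()))
    if parcels is None:
        parcels = tuple(sorted(np.unique(any_run.vertex_parcel).tolist()))
    vidx = {p: np.flatnonzero(any_run.vertex_parcel == p) for p in parcels}
    bb = np.zeros((len(subjects), len(parcels)))
    bn = np.zeros((len(subjects), len(parcels)))
    for si, subject in enumerate(subjects):
        ps = build_pattern_set(runs, events, spec, region=None, subject=subject)
        keys = [k for k in ps.patterns]
        row = {k: i for i, k in enumerate(keys)}
        X = np.stack([ps.patterns[k] for k in keys])
        i_bb, j_bb = _pair_rows(ps, row, ("encoding", "recall"), "boundary", "boundary")
        i_bn, j_bn = _pair_rows(
            ps, row, ("encoding", "recall"), "boundary", "nonboundary"
        )
        for pi, p in enumerate(parcels):
            C = np.corrcoef(X[:, vidx[p]])
            bb[si, pi] = C[i_bb, j_bb].mean()
            bn[si, pi] = C[i_bn, j_bn].mean()
    t = np.empty(len(parcels))
    p_val = np.empty(len(parcels))
    for j in range(len(parcels)):
        res = paired_t(bb[:, j], bn[:, j])
        t[j], p_val[j] = res.t_stat, res.p_two_tailed
    mask = bonferroni_mask(p_val, alpha) & (t > 0)
    return t, p_val, mask
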