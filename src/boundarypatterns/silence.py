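"""Audio/silence confound controls.

Two analyses test whether the generalized boundary pattern merely
reflects the absence of sound: (1) correlate the mean activation pattern
of within-movie silent moments during encoding with the recall
between-movie boundary template; (2) correlate the audio-amplitude time
course with the time course of similarity between the recall boundary
template and each encoding time point. Both exclude the first 45 s of
each movie, so between-movie boundary carry-over cannot masquerade as a
silence response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import (
    EventTable,
    RunData,
    WindowSpec,
    DEFAULT_WINDOW,
    seconds_to_tr_range,
)
from .stats import GroupTestResult, one_sample_t

EXCLUSION_S = 45.0


@dataclass
class SilenceMask:
    """Silent within-movie TRs of one encoding run.

    ``threshold_value`` is the mean (processed or raw) envelope over
    title-scene TRs; a within-movie TR counts as silent when its
    envelope is <= that threshold and it lies at least 45 s past the
    movie onset.
    """

    run: int
    tr_indices: np.ndarray
    threshold_value: float
    envelope: np.ndarray


def silence_timepoints(
    envelope: np.ndarray,
    run: RunData,
    events: EventTable,
    exclusion_s: float = EXCLUSION_S,
) -> SilenceMask:
    """Classify silent TRs of one encoding run.

    ``envelope`` must be aligned to the run's (possibly trimmed) TRs —
    typically the HRF-convolved z-scored regressor, optionally the raw
    per-TR amplitude.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.shape != (run.n_trs,):
        raise ValueError("envelope is not aligned to the run's TRs")
    subject = run.subject_id
    titles = events.titles(subject, run.run)
    title_trs: list[int] = []
    for _, row in titles.iterrows():
        title_trs.extend(seconds_to_tr_range(row["onset_s"], row["offset_s"], run))
    if not title_trs:
        raise ValueError("no title TRs in run: cannot form silence threshold")
    threshold = float(envelope[title_trs].mean())

    movie_trs: list[int] = []
    for _, row in events.movies(subject, "encoding", run.run).iterrows():
        movie_trs.extend(
            seconds_to_tr_range(row["onset_s"] + exclusion_s, row["offset_s"], run)
        )
    movie_trs_arr = np.array(sorted(set(movie_trs)), dtype=int)
    silent = movie_trs_arr[envelope[movie_trs_arr] <= threshold]
    return SilenceMask(
        run=run.run, tr_indices=silent, threshold_value=threshold, envelope=envelope
    )


def silence_pattern_correlation(
    runs: dict,
    masks: dict,
    recall_between_template: dict,
    region: tuple | None = None,
) -> tuple[np.ndarray, GroupTestResult]:
    """Correlate each subject's mean silent-moment pattern (encoding)
    with their recall between-movie boundary template.

    ``masks`` maps encoding run number -> SilenceMask (shared across
    subjects: all subjects heard the same soundtrack);
    ``recall_between_template`` maps subject -> template vector over the
    same region. Returns per-subject r and the group one-sample test.
    """
    subjects = sorted({k[0] for k in runs})
    rs = []
    for subject in subjects:
        blocks = []
        for (subj, phase, run_no), run in runs.items():
            if subj != subject or phase != "encoding":
                continue
            mask = masks[run_no]
            if mask.tr_indices.size == 0:
                raise ValueError(f"empty silence mask for run {run_no}")
            vid = (
                run.region_vertices(region)
                if region is not None
                else np.arange(run.n_vertices)
            )
            blocks.append(run.data[np.ix_(vid, mask.tr_indices)])
        if not blocks:
            raise ValueError(f"no encoding runs for subject {subject}")
        silent_pattern = np.concatenate(blocks, axis=1).mean(axis=1, dtype=np.float64)
        template = recall_between_template[subject]
        if silent_pattern.std() == 0 or np.asarray(template).std() == 0:
            raise ValueError("constant pattern: correlation undefined")
        rs.append(float(np.corrcoef(silent_pattern, template)[0, 1]))
    rs = np.asarray(rs)
    return rs, one_sample_t(rs) if rs.size >= 2 else None


def amplitude_similarity_correlation(
    runs: dict,
    envelopes: dict,
    recall_between_template: dict,
    events: EventTable,
    region: tuple | None = None,
    exclusion_s: float = EXCLUSION_S,
) -> tuple[np.ndarray, GroupTestResult]:
    """Correlate the audio-amplitude time course with the time course of
    template-to-data pattern similarity during encoding.

    For every within-movie TR (beyond 45 s from the movie onset) we
    correlate that TR's spatial pattern with the subject's recall
    boundary template, then correlate the resulting similarity time
    course with the (processed) audio envelope at the same TRs.
    """
    subjects = sorted({k[0] for k in runs})
    rs = []
    for subject in subjects:
        sim_tc, env_tc = [], []
        for (subj, phase, run_no), run in runs.items():
            if subj != subject or phase != "encoding":
                continue
            env = np.asarray(envelopes[run_no], dtype=float)
            if env.shape != (run.n_trs,):
                raise ValueError("envelope is not aligned to the run's TRs")
            vid = (
                run.region_vertices(region)
                if region is not None
                else np.arange(run.n_vertices)
            )
            template = np.asarray(recall_between_template[subject], dtype=float)
            tz = template - template.mean()
            tz /= np.linalg.norm(tz)
            trs: list[int] = []
            for _, row in events.movies(subject, "encoding", run_no).iterrows():
                trs.extend(
                    seconds_to_tr_range(
                        row["onset_s"] + exclusion_s, row["offset_s"], run
                    )
                )
            trs_arr = np.array(sorted(set(trs)), dtype=int)
            X = run.data[np.ix_(vid, trs_arr)].astype(np.float64)
            Xz = X - X.mean(axis=0, keepdims=True)
            norms = np.linalg.norm(Xz, axis=0)
            if (norms == 0).any():
                raise ValueError("constant spatial pattern in similarity time course")
            sim_tc.append(tz @ (Xz / norms))
            env_tc.append(env[trs_arr])
        sim = np.concatenate(sim_tc)
        envc = np.concatenate(env_tc)
        if sim.size < 3:
            raise ValueError("fewer than 3 usable TRs")
        rs.append(float(np.corrcoef(sim, envc)[0, 1]))
    rs = np.asarray(rs)
    return rs, one_sample_t(rs) if rs.size >= 2 else None
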