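"""Synthetic movie-encoding / free-recall experiments with known ground truth.

The generator emulates the study design the analyses assume: 15 subjects
watch 10 movies (2.15-7.75 min, each preceded by a 6 s silent title scene)
across two encoding runs, then freely recall them in a subject-specific
order separated by spontaneous pauses (lognormal, mean ~9.3 s, SD ~16.8 s).

The latent signal is a sum of planted spatial patterns gated by boxcar
state time series, convolved with a double-gamma HRF, plus white noise:

* a *content* pattern per movie, active while the movie is watched or
  recalled (all parcels);
* a shared *boundary* pattern, active for ``boundary_dwell_s`` after every
  movie offset in both phases, restricted to ``boundary_parcels``;
* a *within-movie event* pattern at coarse scene boundaries during
  encoding, restricted to ``boundary_parcels`` and constructed to have an
  exact target Pearson correlation with the boundary pattern;
* a *silence* pattern in ``aud_parcels``, active whenever the encoding
  audio envelope is zero (titles, planted dips, padding) and during
  recall pauses (speech gaps) — the auditory confound the silence
  controls are designed to detect.

All patterns are zero-mean and unit-norm over their supporting vertices,
so planted Pearson correlations are exact. A single master seed drives
deterministically split generator streams; the same config and seed
reproduce the experiment bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventTable, RunData, STIMULUS_START_S
from .preprocess import double_gamma_hrf, convolve_hrf, preprocess_run

#: 10 movie durations (s), evenly spaced inside the study's 2.15-7.75 min
#: range, snapped to the 1.5 s TR grid.
DEFAULT_MOVIE_DURATIONS_S = tuple(129.0 + 36.0 * k for k in range(10))


@dataclass(frozen=True)
class GroundTruthConfig:
    """Generative parameters of a synthetic experiment.

    Amplitudes are in z units relative to ``noise_sd``; the key
    signal-to-noise knob for the boundary analyses is
    ``amp_boundary / noise_sd`` (default 0.5).
    """

    n_subjects: int = 15
    n_parcels: int = 40
    vertices_per_parcel: int = 20
    movie_durations_s: tuple = DEFAULT_MOVIE_DURATIONS_S
    title_s: float = 6.0
    tr_s: float = 1.5
    pad_s: float = 66.0
    recall_frac: float = 0.5
    recall_start_s: float = 9.0
    pause_mean_s: float = 9.3
    pause_sd_s: float = 16.8
    pause_max_s: float = 60.0
    amp_boundary: float = 0.5
    amp_content: float = 1.0
    amp_event: float = 0.5
    amp_silence_aud: float = 0.5
    #: uniform activation change (z units, may be negative) added to every
    #: boundary-parcel vertex during boundary periods; drives the
    #: univariate boundary-vs-non-boundary contrast
    boundary_shift: float = 0.0
    corr_event_boundary: float = -0.3
    noise_sd: float = 1.0
    boundary_dwell_s: float = 15.0
    event_dwell_s: float = 15.0
    n_event_boundaries: tuple = (2, 4)
    n_boundary_parcels: int = 4
    n_aud_parcels: int = 4
    envelope_base: float = 1.0
    envelope_jitter: float = 0.2
    dip_len_tr: int = 3
    dip_frac: float = 0.6
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.movie_durations_s) != 10:
            raise ValueError("exactly 10 movie durations are required")
        if min(self.movie_durations_s) <= 0:
            raise ValueError("movie durations must be positive")
        for name in ("amp_boundary", "amp_content", "amp_event", "amp_silence_aud"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.corr_event_boundary) > 1:
            raise ValueError("|corr_event_boundary| must be <= 1")
        if self.n_boundary_parcels + self.n_aud_parcels > self.n_parcels:
            raise ValueError("planted parcel sets exceed the parcel count")

    @property
    def n_vertices(self) -> int:
        return self.n_parcels * self.vertices_per_parcel

    @property
    def boundary_parcels(self) -> tuple:
        return tuple(range(self.n_boundary_parcels))

    @property
    def aud_parcels(self) -> tuple:
        return tuple(
            range(self.n_boundary_parcels, self.n_boundary_parcels + self.n_aud_parcels)
        )

    @property
    def null_parcels(self) -> tuple:
        return tuple(range(self.n_boundary_parcels + self.n_aud_parcels, self.n_parcels))


@dataclass
class GroundTruth:
    """Planted patterns and parcel assignments of a synthetic experiment."""

    pattern_boundary: np.ndarray
    pattern_event: np.ndarray
    pattern_silence: np.ndarray
    pattern_movies: np.ndarray  # 10 x n_vertices
    boundary_parcels: tuple
    aud_parcels: tuple
    null_parcels: tuple
    dip_trs: dict  # encoding run -> list of raw TR indices set to zero
    config: GroundTruthConfig


@dataclass
class SyntheticExperiment:
    """A complete generated experiment.

    ``runs`` maps ``(subject_id, phase, run)`` to raw (untrimmed,
    unfiltered) RunData; ``envelopes`` maps each encoding run number to
    its raw per-TR audio amplitude series (shared across subjects, since
    all subjects watched the same stimuli).
    """

    runs: dict
    events: EventTable
    envelopes: dict
    truth: GroundTruth

    def subject_ids(self) -> list[str]:
        return sorted({k[0] for k in self.runs})


# -- helpers -------------------------------------------------------------


def _unit_pattern(rng: np.random.Generator, size: int) -> np.ndarray:
    v = rng.standard_normal(size)
    v -= v.mean()
    return v / np.linalg.norm(v)


def _correlated_pattern(
    rng: np.random.Generator, base: np.ndarray, rho: float
) -> np.ndarray:
    """Zero-mean unit-norm vector with exact Pearson correlation ``rho``
    to ``base`` (itself zero-mean unit-norm), via Gram-Schmidt mixing."""
    g = rng.standard_normal(base.size)
    g -= g.mean()
    g -= (g @ base) * base
    g /= np.linalg.norm(g)
    return rho * base + np.sqrt(1.0 - rho**2) * g


def _snap_tr(t: float, tr_s: float) -> float:
    return round(t / tr_s) * tr_s


def sample_pauses(
    rng: np.random.Generator, n: int, mean_s: float, sd_s: float, max_s: float
) -> np.ndarray:
    """Lognormal pause durations with the requested mean/SD, truncated to
    [0, max_s] by resampling. The strong positive skew (SD >> mean)
    matches spontaneous inter-movie recall gaps."""
    sigma2 = np.log(1.0 + (sd_s / mean_s) ** 2)
    mu = np.log(mean_s) - sigma2 / 2.0
    out = np.empty(n)
    for i in range(n):
        d = rng.lognormal(mu, np.sqrt(sigma2))
        while d > max_s:
            d = rng.lognormal(mu, np.sqrt(sigma2))
        out[i] = d
    return out


def _intervals_to_mask(intervals, n_trs: int, tr_s: float) -> np.ndarray:
    """Boolean per-TR mask of TRs whose onset falls in any interval."""
    mask = np.zeros(n_trs, dtype=bool)
    onsets = np.arange(n_trs) * tr_s
    for lo, hi in intervals:
        mask |= (onsets >= lo - 1e-9) & (onsets < hi - 1e-9)
    return mask


# -- timeline construction ------------------------------------------------


def _encoding_timeline(config: GroundTruthConfig):
    """Shared encoding timeline: per run, lists of title/movie intervals
    on the run clock, plus run length in TRs."""
    runs = {}
    movie_ids = {1: list(range(1, 6)), 2: list(range(6, 11))}
    for run, ids in movie_ids.items():
        t = STIMULUS_START_S
        titles, movies = [], []
        for m in ids:
            dur = config.movie_durations_s[m - 1]
            titles.append((m, t, t + config.title_s))
            movies.append((m, t + config.title_s, t + config.title_s + dur))
            t = t + config.title_s + dur
        total = t + config.pad_s
        n_trs = int(np.ceil(total / config.tr_s - 1e-9))
        runs[run] = {"titles": titles, "movies": movies, "n_trs": n_trs}
    return runs


def _sample_event_boundaries(config: GroundTruthConfig, rng: np.random.Generator):
    """Within-movie coarse boundary times (movie-relative, s), shared
    across subjects since all subjects watched the same stimuli."""
    lo_n, hi_n = config.n_event_boundaries
    out = {}
    for m in range(1, 11):
        dur = config.movie_durations_s[m - 1]
        n_b = int(rng.integers(lo_n, hi_n + 1))
        lo, hi = 30.0, dur - 30.0
        if hi <= lo:
            times = np.full(n_b, dur / 2.0)
        else:
            times = np.sort(rng.uniform(lo, hi, n_b))
        out[m] = [_snap_tr(t, config.tr_s) for t in times]
    return out


def _recall_timeline(config: GroundTruthConfig, rng: np.random.Generator):
    """One subject's recall timeline: movie intervals, pauses, run length."""
    order = rng.permutation(np.arange(1, 11))
    pauses = sample_pauses(
        rng, 9, config.pause_mean_s, config.pause_sd_s, config.pause_max_s
    )
    t = config.recall_start_s
    movies, pause_iv = [], []
    for i, m in enumerate(order):
        dur = _snap_tr(config.recall_frac * config.movie_durations_s[m - 1], config.tr_s)
        movies.append((int(m), t, t + dur))
        t += dur
        if i < 9:
            p = _snap_tr(pauses[i], config.tr_s)
            if p > 0:  # a sub-TR pause snaps to zero: movies abut directly
                pause_iv.append((t, t + p))
                t += p
    total = t + config.pad_s
    n_trs = int(np.ceil(total / config.tr_s - 1e-9))
    return movies, pause_iv, n_trs


# -- audio envelope --------------------------------------------------------


def generate_audio_envelope(
    config: GroundTruthConfig,
    enc_timeline: dict,
    run: int,
    rng: np.random.Generator,
):
    """Raw per-TR audio amplitude for one encoding run.

    Zero during titles, pre-stimulus time and end padding; positive with
    mild TR-to-TR jitter during movies; with one planted silent dip
    (``dip_len_tr`` TRs set to 0) per movie, placed ``dip_frac`` of the
    way through the movie (always beyond the 45 s exclusion zone for the
    default durations). Returns (envelope, dip TR indices).
    """
    info = enc_timeline[run]
    n_trs = info["n_trs"]
    env = np.zeros(n_trs)
    dips = []
    tr = config.tr_s
    for m, lo, hi in info["movies"]:
        k = _intervals_to_mask([(lo, hi)], n_trs, tr)
        env[k] = config.envelope_base + rng.uniform(
            -config.envelope_jitter, config.envelope_jitter, int(k.sum())
        )
        dip_t = lo + config.dip_frac * (hi - lo)
        k0 = int(np.ceil(dip_t / tr - 1e-9))
        dip_idx = list(range(k0, min(k0 + config.dip_len_tr, n_trs)))
        env[dip_idx] = 0.0
        dips.extend(dip_idx)
    return env, dips


# -- main generator --------------------------------------------------------


def generate_experiment(
    config: GroundTruthConfig, preprocess: bool = False, zscore: bool = True
) -> SyntheticExperiment:
    """Generate a full synthetic experiment.

    With ``preprocess=True`` each run is trimmed, high-pass filtered and
    z-scored (the standard pipeline) as soon as it is built, which keeps
    the peak memory footprint at one raw run; by default raw runs are
    returned so the preprocessing stage itself can be tested.
    """

    def _finish(run: RunData) -> RunData:
        return preprocess_run(run, zscore=zscore) if preprocess else run

    ss = np.random.SeedSequence(config.seed)
    (ss_pat, ss_evt, ss_env, ss_subj) = ss.spawn(4)
    rng_pat = np.random.default_rng(ss_pat)
    rng_evt = np.random.default_rng(ss_evt)
    rng_env = np.random.default_rng(ss_env)

    V = config.n_vertices
    vertex_parcel = np.repeat(np.arange(config.n_parcels), config.vertices_per_parcel)
    bound_idx = np.flatnonzero(np.isin(vertex_parcel, config.boundary_parcels))
    aud_idx = np.flatnonzero(np.isin(vertex_parcel, config.aud_parcels))

    # planted patterns (zero-mean, unit-norm over their support)
    p_bound = np.zeros(V)
    p_bound[bound_idx] = _unit_pattern(rng_pat, bound_idx.size)
    p_evt = np.zeros(V)
    p_evt[bound_idx] = _correlated_pattern(
        rng_pat, p_bound[bound_idx], config.corr_event_boundary
    )
    p_sil = np.zeros(V)
    p_sil[aud_idx] = _unit_pattern(rng_pat, aud_idx.size)
    p_movies = np.stack([_unit_pattern(rng_pat, V) for _ in range(10)])
    u_bound = np.zeros(V)
    u_bound[bound_idx] = 1.0  # uniform shift carrier for boundary_shift

    enc_tl = _encoding_timeline(config)
    evt_boundaries = _sample_event_boundaries(config, rng_evt)

    envelopes, dip_trs = {}, {}
    for run in (1, 2):
        envelopes[run], dip_trs[run] = generate_audio_envelope(
            config, enc_tl, run, rng_env
        )

    hrf = double_gamma_hrf(config.tr_s)
    tr = config.tr_s

    rows = []
    runs = {}
    subj_seeds = ss_subj.spawn(config.n_subjects)
    for s in range(config.n_subjects):
        subject = f"sub-{s + 1:02d}"
        rng_s = np.random.default_rng(subj_seeds[s])

        # ---- encoding runs (shared timeline, subject-specific noise)
        for run in (1, 2):
            info = enc_tl[run]
            n_trs = info["n_trs"]
            states, patterns, amps = [], [], []
            for m, lo, hi in info["movies"]:
                states.append(_intervals_to_mask([(lo, hi)], n_trs, tr))
                patterns.append(p_movies[m - 1])
                amps.append(config.amp_content)
            offsets = [(hi, hi + config.boundary_dwell_s) for _, _, hi in info["movies"]]
            bound_state = _intervals_to_mask(offsets, n_trs, tr)
            states.append(bound_state)
            patterns.append(p_bound)
            amps.append(config.amp_boundary)
            if config.boundary_shift != 0:
                states.append(bound_state)
                patterns.append(u_bound)
                amps.append(config.boundary_shift)
            evt_iv = []
            for m, lo, hi in info["movies"]:
                for b in evt_boundaries[m]:
                    evt_iv.append((lo + b, lo + b + config.event_dwell_s))
            states.append(_intervals_to_mask(evt_iv, n_trs, tr))
            patterns.append(p_evt)
            amps.append(config.amp_event)
            states.append(envelopes[run] == 0)
            patterns.append(p_sil)
            amps.append(config.amp_silence_aud)

            data = _assemble_run(states, patterns, amps, hrf, rng_s, config, n_trs)
            runs[(subject, "encoding", run)] = _finish(
                RunData(
                    subject_id=subject,
                    phase="encoding",
                    run=run,
                    data=data,
                    vertex_parcel=vertex_parcel,
                    tr_s=tr,
                    vertex_area_mm2=np.full(V, 4.0),
                )
            )
            for m, lo, hi in info["titles"]:
                rows.append((subject, "encoding", run, m, "title", lo, hi))
            for m, lo, hi in info["movies"]:
                rows.append((subject, "encoding", run, m, "movie", lo, hi))
                for b in evt_boundaries[m]:
                    rows.append(
                        (subject, "encoding", run, m, "within_event_boundary",
                         lo + b, np.nan)
                    )

        # ---- recall run (subject-specific order and pauses)
        movies, pauses, n_trs = _recall_timeline(config, rng_s)
        states, patterns, amps = [], [], []
        movie_iv = [(lo, hi) for _, lo, hi in movies]
        for m, lo, hi in movies:
            states.append(_intervals_to_mask([(lo, hi)], n_trs, tr))
            patterns.append(p_movies[m - 1])
            amps.append(config.amp_content)
        offsets = [(hi, hi + config.boundary_dwell_s) for _, _, hi in movies]
        bound_state = _intervals_to_mask(offsets, n_trs, tr)
        states.append(bound_state)
        patterns.append(p_bound)
        amps.append(config.amp_boundary)
        if config.boundary_shift != 0:
            states.append(bound_state)
            patterns.append(u_bound)
            amps.append(config.boundary_shift)
        # silence during every speech gap: pre-recall, inter-movie pauses,
        # and the tail after the last recalled movie
        silent = ~_intervals_to_mask(movie_iv, n_trs, tr)
        states.append(silent)
        patterns.append(p_sil)
        amps.append(config.amp_silence_aud)

        data = _assemble_run(states, patterns, amps, hrf, rng_s, config, n_trs)
        runs[(subject, "recall", 1)] = _finish(
            RunData(
                subject_id=subject,
                phase="recall",
                run=1,
                data=data,
                vertex_parcel=vertex_parcel,
                tr_s=tr,
                vertex_area_mm2=np.full(V, 4.0),
            )
        )
        for m, lo, hi in movies:
            rows.append((subject, "recall", 1, m, "movie", lo, hi))
        for lo, hi in pauses:
            rows.append((subject, "recall", 1, 0, "pause", lo, hi))

    events = EventTable(
        pd.DataFrame(
            rows,
            columns=["subject", "phase", "run", "movie_id", "kind", "onset_s", "offset_s"],
        )
    )
    truth = GroundTruth(
        pattern_boundary=p_bound,
        pattern_event=p_evt,
        pattern_silence=p_sil,
        pattern_movies=p_movies,
        boundary_parcels=config.boundary_parcels,
        aud_parcels=config.aud_parcels,
        null_parcels=config.null_parcels,
        dip_trs=dip_trs,
        config=config,
    )
    return SyntheticExperiment(
        runs=runs, events=events, envelopes=envelopes, truth=truth
    )


def _assemble_run(states, patterns, amps, hrf, rng, config, n_trs):
    """latent = sum_e amp_e * p_e outer conv(s_e); plus white noise.

    Run matrices are stored at ``config.dtype`` (float32 by default) to
    keep a full 15-subject experiment comfortably in memory; window
    averaging and all correlations accumulate in float64 downstream.
    """
    dtype = np.dtype(config.dtype)
    S = np.stack([np.asarray(s, dtype=float) for s in states])
    Sc = convolve_hrf(S, hrf).astype(dtype)
    P = (np.stack(patterns).T * np.asarray(amps)).astype(dtype)  # V x n_states
    data = P @ Sc
    if config.noise_sd > 0:
        if dtype == np.float32:
            noise = rng.standard_normal((config.n_vertices, n_trs), dtype=np.float32)
        else:
            noise = rng.standard_normal((config.n_vertices, n_trs))
        data += (noise * config.noise_sd).astype(dtype)
    return data


def preprocess_experiment(
    exp: SyntheticExperiment, cutoff_s: float = 140.0, zscore: bool = True
) -> SyntheticExperiment:
    """Apply trim -> high-pass -> z-score to every run of an experiment."""
    runs = {
        key: preprocess_run(run, cutoff_s=cutoff_s, zscore=zscore)
        for key, run in exp.runs.items()
    }
    return SyntheticExperiment(
        runs=runs, events=exp.events, envelopes=exp.envelopes, truth=exp.truth
    )
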