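"""Temporal preprocessing: volume trimming, high-pass filtering, run-wise
z-scoring, and construction of the audio-amplitude nuisance regressor.

Spatial preprocessing (motion correction, surface resampling, smoothing)
is assumed to have happened upstream; this module only handles the
per-run temporal steps that the pattern analyses depend on.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .events import RunData

#: Initial volumes discarded from each run (acquisition stabilisation and
#: the pre-stimulus period): 5 for encoding runs, 3 for recall runs.
TRIM_VOLUMES = {"encoding": 5, "recall": 3}


def double_gamma_hrf(
    tr_s: float = 1.5,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_disp_s: float = 1.0,
    undershoot_disp_s: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled at the TR.

    Difference of two gamma densities (peak ~6 s, undershoot ~16 s),
    normalized to unit peak. Returned as a 1-D kernel for causal
    convolution with TR-resolution designs.
    """
    t = np.arange(0, length_s + tr_s / 2, tr_s)
    peak = sps.gamma.pdf(t, peak_delay_s / peak_disp_s, scale=peak_disp_s)
    under = sps.gamma.pdf(
        t, undershoot_delay_s / undershoot_disp_s, scale=undershoot_disp_s
    )
    h = peak - under / peak_undershoot_ratio
    return h / h.max()


def convolve_hrf(series: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Causal convolution along the last axis, truncated to input length."""
    series = np.asarray(series, dtype=float)
    full = spsig.fftconvolve(series, hrf[np.newaxis, :] if series.ndim == 2 else hrf, axes=-1)
    return full[..., : series.shape[-1]]


def trim_initial_volumes(run: RunData) -> RunData:
    """Drop the initial volumes of a run (5 encoding / 3 recall).

    Event times are untouched: the run clock is preserved by advancing
    ``trim_offset_s``. Refuses to trim twice.
    """
    if run.trim_offset_s != 0:
        raise ValueError("run already trimmed (trim_offset_s != 0)")
    k = TRIM_VOLUMES[run.phase]
    if run.n_trs <= k:
        raise ValueError(f"run has only {run.n_trs} TRs; cannot trim {k}")
    return dataclasses.replace(
        run, data=run.data[:, k:].copy(), trim_offset_s=k * run.tr_s
    )


def dct_basis(n_trs: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Orthonormal DCT-II drift basis up to frequency 1/cutoff_s.

    Column k is cos(pi * k * (t + 0.5) / N); k = 0 is the constant term.
    Includes every k with k / (2 * N * tr_s) <= 1 / cutoff_s.
    """
    n_basis = int(math.floor(2.0 * n_trs * tr_s / cutoff_s)) + 1
    t = np.arange(n_trs)
    B = np.cos(np.pi * np.outer(t + 0.5, np.arange(n_basis)) / n_trs)
    Q, _ = np.linalg.qr(B)
    return Q


def highpass_dct(run: RunData, cutoff_s: float = 140.0) -> RunData:
    """Remove slow drifts by regressing out a DCT basis (cutoff 140 s).

    The mean (k = 0 term) is removed together with the drift terms; the
    output is orthogonal to the removed basis.
    """
    if cutoff_s <= 2 * run.tr_s:
        raise ValueError("cutoff_s must exceed the Nyquist period 2*tr_s")
    if run.n_trs < 8:
        raise ValueError("run too short for drift removal")
    Q = dct_basis(run.n_trs, run.tr_s, cutoff_s).astype(run.data.dtype, copy=False)
    resid = run.data - (run.data @ Q) @ Q.T
    return dataclasses.replace(run, data=resid)


def zscore_run(run: RunData) -> RunData:
    """Z-score each vertex's time series within the run (mean 0, SD 1)."""
    mu = run.data.mean(axis=1, keepdims=True)
    sd = run.data.std(axis=1, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance vertices cannot be z-scored: {zero.tolist()[:10]}"
        )
    return dataclasses.replace(run, data=(run.data - mu) / sd)


def preprocess_run(
    run: RunData, cutoff_s: float = 140.0, zscore: bool = True
) -> RunData:
    """trim -> high-pass -> z-score, the standard per-run pipeline."""
    out = highpass_dct(trim_initial_volumes(run), cutoff_s)
    return zscore_run(out) if zscore else out


# -- audio amplitude regressor ------------------------------------------


def hilbert_envelope(audio: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude |analytic signal| of a mono waveform."""
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("expected a single-channel waveform")
    return np.abs(spsig.hilbert(audio))


def bin_envelope_to_trs(
    envelope: np.ndarray, sr: float, n_trs: int, tr_s: float, start_s: float = 0.0
) -> np.ndarray:
    """Average the sample-rate envelope within each TR acquisition bin.

    ``start_s`` is the run-clock time of the first envelope sample.
    TR bins not covered by the audio are set to 0 (silence).
    """
    if sr <= 0:
        raise ValueError("sampling rate must be positive")
    out = np.zeros(n_trs)
    for k in range(n_trs):
        lo = int(round((k * tr_s - start_s) * sr))
        hi = int(round(((k + 1) * tr_s - start_s) * sr))
        lo = max(lo, 0)
        hi = min(hi, envelope.size)
        if hi > lo:
            out[k] = envelope[lo:hi].mean()
    return out


def envelope_regressor(
    envelope_tr: np.ndarray,
    hrf: np.ndarray,
    trim_volumes: int = 0,
) -> np.ndarray:
    """HRF-convolve and z-score a per-TR amplitude series.

    Convolution happens on the full (untrimmed) series so that early TRs
    carry the correct history; the first ``trim_volumes`` samples are then
    dropped to align with a trimmed run, and the result is z-scored over
    the remaining time points.
    """
    env = np.asarray(envelope_tr, dtype=float)
    conv = convolve_hrf(env, hrf)[trim_volumes:]
    sd = conv.std()
    if sd == 0:
        raise ValueError("constant envelope regressor cannot be z-scored")
    return (conv - conv.mean()) / sd


def audio_envelope_regressor(
    audio: np.ndarray,
    sr: float,
    run: RunData,
    stimulus_start_s: float = 0.0,
) -> np.ndarray:
    """Full audio-confound pipeline for one encoding run.

    |Hilbert analytic signal| -> per-TR mean -> double-gamma HRF
    convolution -> z-score; the output has one value per (trimmed) TR of
    ``run``.
    """
    env = hilbert_envelope(audio)
    trim = int(round(run.trim_offset_s / run.tr_s))
    n_raw = run.n_trs + trim
    env_tr = bin_envelope_to_trs(env, sr, n_raw, run.tr_s, start_s=stimulus_start_s)
    hrf = double_gamma_hrf(run.tr_s)
    return envelope_regressor(env_tr, hrf, trim_volumes=trim)
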