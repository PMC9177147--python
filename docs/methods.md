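# Methods

This note documents the analysis model implemented by `boundarypatterns`,
the synthetic experiment its tests run against, and the numerical and
design choices a maintainer should know about.

## The analysis problem

In a naturalistic memory experiment, subjects watch a series of ten short
audiovisual movies (encoding) and later recount them aloud in an order of
their own choosing (free spoken recall), both inside the scanner. The
transition from recalling one movie to the next is an *internally
generated* boundary between mental contexts: nothing on the screen
changes. The package asks whether a stereotyped multi-vertex activation
pattern appears after such boundaries, whether it generalizes across
movie contents and across the encoding/recall tasks, how it unfolds in
time around onsets and offsets, whether it resembles the pattern at
*within*-movie scene boundaries, and whether it can be explained away by
silence or audio-amplitude confounds.

All analyses operate on mean spatial patterns inside fixed windows:

* **boundary pattern** of a movie: mean pattern over `[offset + 4.5 s,
  offset + 19.5 s)` (a 15 s window shifted forward 4.5 s for the
  hemodynamic delay; a 4.5 s variant is available for controls);
* **non-boundary pattern**: the same-length window centered on the
  temporal midpoint of the movie, shifted the same way;
* **pattern similarity**: Pearson correlation between two spatial
  patterns over the vertices of a parcel or ROI.

Between-movie similarity averages all movie pairs i ≠ j: 45 unordered
pairs within a phase, 90 ordered pairs across encoding and recall.
Group inference is by two-tailed one-sample or paired t-tests across
subjects, reported with Cohen's d_z = t/√n and a 95% Student CI of the
mean. Whole-brain maps are corrected with Bonferroni across parcels
(strict p < α/m) or Benjamini–Hochberg FDR across vertices (step-up with
non-strict ≤, as originally defined). A *conjunction map* marks parcels
that pass both corrected tests: positive boundary similarity AND
boundary > non-boundary similarity.

## Window and clock conventions

TR indices are 0-based; all windows are half-open `[start, end)`; a TR
belongs to a window iff its acquisition onset falls inside the window.
Volume 1 of each run acquires at t = 0 on the *run clock*; encoding
stimuli start 3 s later, and conversion between the two clocks is always
explicit (`stimulus_to_run_clock`). Trimming initial volumes (5 for
encoding runs, 3 for recall runs) never rewrites event times: the run
keeps a `trim_offset_s` so window arithmetic stays on the run clock.
Windows that extend past a movie into the following title scene or pause
are used as-is, mirroring the fixed-window design; clipping happens only
at run boundaries. The "middle 15 s" is anchored on the midpoint of the
item, a documented choice; no sub-TR interpolation is performed anywhere.

## Preprocessing

Per run: trim initial volumes → regress out a DCT-II drift basis up to
1/140 s⁻¹ (an orthonormal cosine basis including the constant term;
deterministic and edge-stable, unlike an IIR filter) → z-score each
vertex's time series within the run. Z-scoring before pattern
correlation is harmless (Pearson is affine-invariant per vertex) but
fixes the units of univariate effects.

The audio confound regressor is |Hilbert analytic signal| of the mono
waveform → mean within each TR bin → convolution with a double-gamma HRF
→ z-score across time. The HRF uses peak delay 6 s, undershoot delay
16 s, unit dispersions, peak:undershoot ratio 6, 32 s length, unit peak;
the family is standard and the exact parameters are a documented default.
Convolution is applied to the untrimmed series and trimmed afterwards so
early TRs carry the correct stimulus history.

## Silence controls

Silent moments during encoding are within-movie TRs whose processed
envelope is ≤ the mean envelope over title-scene TRs, excluding the
first 45 s of every movie (so carry-over from the preceding between-movie
boundary cannot masquerade as a silence response). The threshold is
computed on the HRF-convolved z-scored regressor by default, with a
raw-envelope option; title TRs near the trimmed run start contribute to
the threshold like any others. The mean silent-moment pattern is
correlated with the recall between-movie boundary template per subject,
separately for an auditory-cortex ROI and the boundary ROI. A second
control correlates the amplitude time course with the time course of
template-to-data pattern similarity over the same within-movie TRs.

## Boundary templates

Within-movie scene boundaries are inputs (human-coded in real data,
planted by the generator). Boundaries within the first 45 s of their
movie are excluded; a boundary exactly at 45 s is retained (≥
convention). Templates are two-stage averages: mean over TRs within each
post-boundary window, then mean across boundaries or movies. The
within-movie consistency analysis excludes non-boundary windows that
overlap any retained boundary window by any nonzero amount (the interval
intersection rule).

## The synthetic experiment

The generator emulates the study design so every downstream stage is
testable without data: 15 subjects; 10 movies with durations evenly
spaced over 129–453 s (inside the 2.15–7.75 min range of the real
stimuli), snapped to the 1.5 s TR grid; a 6 s silent title before each
movie; two encoding runs of five movies each, stimuli starting 3 s into
the run; one recall run per subject with a random movie order, recall
durations half the movie duration, and inter-movie pauses drawn from a
lognormal with mean 9.3 s and SD 16.8 s truncated to [0, 60] s (the
strong positive skew matches SD ≫ mean; the true pause distribution is
unknown beyond these two moments). Sub-TR pauses snap to zero, so some
recall transitions have no pause — as in real recall.

The latent signal is a sum of spatial patterns gated by boxcar states,
convolved with the double-gamma HRF, plus white Gaussian noise, then
(optionally, default on) passed through the standard preprocessing:

| effect | pattern support | active when | default amplitude |
|---|---|---|---|
| content (per movie) | all parcels | while the movie is watched or recalled | 1.0 |
| boundary | 4 "boundary" parcels | 15 s after every movie offset, both phases | 0.5 |
| within-movie event | boundary parcels | 15 s after each planted scene boundary (encoding) | 0.5 |
| silence | 4 "auditory" parcels | encoding TRs with zero envelope; recall speech gaps | 0.5 |
| uniform boundary shift | boundary parcels | boundary periods | 0 (off) |

Noise SD defaults to 1.0, so the key signal-to-noise knob for the
boundary analyses is amp_boundary/noise_sd = 0.5. Patterns are zero-mean
unit-norm Gaussian vectors on their support; the within-movie event
pattern is built by Gram–Schmidt mixing to have an *exact* Pearson
correlation of −0.3 with the boundary pattern (matching the sign and
scale of the published within-vs-between dissociation). The remaining 32
parcels carry only content and noise and serve as the specificity
control. The uniform shift drives the univariate contrast and is off by
default. The latent boundary state lasting 15 s is a documented knob;
the data constrain only the post-HRF window.

Scene boundaries are planted 2–4 per movie, uniformly in
[30 s, duration − 30 s], shared across subjects (properties of the
stimuli). The audio envelope is zero during titles, pre-stimulus time
and padding, positive with ±20% TR jitter during movies, with one 3-TR
silent dip per movie at 60% of its duration — always past the 45 s
exclusion, so the silence classifier should recover exactly the dips.
Each run ends with 66 s of padding so that offset-locked windows and the
−30…+60 s peri-boundary grid stay inside the run for every movie.

A single master seed drives deterministically split RNG streams
(patterns, event times, envelope, per-subject timelines and noise);
the same config reproduces every matrix bit-for-bit. Run matrices are
stored as float32 for memory economy; all window averages and
correlations accumulate in float64.

What the generator does **not** emulate: autocorrelated physiological
noise, motion artifacts, subject-specific HRFs, semantic structure
shared between movies, partial or disordered recall, and spatial noise
correlations within parcels. Passing tests therefore demonstrate that
the analysis code recovers the phenomena it targets when they are
present and stays calibrated when they are absent — not that the
phenomena exist in any real dataset.

## Inference details and degenerate inputs

* Constant patterns make Pearson correlation undefined and raise
  immediately, as do zero-variance vertices at the z-scoring step.
* The univariate map needs a vertex adjacency for its minimum-area
  filter (16 mm² by default); synthetic data default to parcel-clique
  adjacency (no mesh exists) with 4 mm² per vertex, and components are
  formed among same-signed significant vertices.
* Time–time matrices test only cells where every subject has a value;
  the Bonferroni denominator is the count of testable cells
  (conservative and explicit). Grid points outside a run are skipped
  per movie, weighting the remaining movies equally.
* Cross-phase between-movie averages use all 90 ordered pairs; a
  45-pair unordered variant would estimate the same quantity with
  slightly more variance (within-phase averaging is unordered by
  symmetry).
* Group inference is on raw mean correlations, matching how the
  quantities are reported (CIs in r units); Fisher-z transforming
  first changes none of the qualitative conclusions at these effect
  sizes.

## Problem sizes used in tests

The acceptance suite runs the full 15-subject pipeline at 40 parcels ×
20 vertices over 20 seeds for each stochastic property (pattern
recovery, null calibration, sign dissociation, silence dissociation);
unit tests use a structurally identical scaled-down experiment (4
subjects, 12 parcels, 90–225 s movies) chosen to exercise every code
path quickly. The planted-recovery thresholds (≥95% of planted parcels
recovered, ≤5% of null parcels flagged, qualitative sign patterns in
≥95% of seeds) are properties of the method at the stated
signal-to-noise ratio, not fitted quantities.

## Known limitations

* The pipeline analyzes complete recall (every movie recalled once);
  missing recalls are carried through pattern bookkeeping but the
  group statistics assume complete per-subject cells.
* Real-data ingestion (GIFTI) converts to the internal container and is
  exercised only lightly; the deposited dataset is not required or
  downloaded.
* The silence analysis in the boundary ROI inherits a small positive
  bias from shared movie-content carry-over in both the silent-moment
  pattern and the recall boundary template — visible in synthetic runs
  as a group-mean r of roughly +0.03 and consistent with the weak
  positive trend the real experiment reports for that ROI.
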