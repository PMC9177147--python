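# boundarypatterns

Analysis pipeline for **boundary-locked activation patterns** in
naturalistic fMRI experiments where subjects watch a series of short
movies (encoding) and then freely recount them aloud (recall). The
transitions between recalled movies are internally generated boundaries
between mental contexts; this package measures whether a stereotyped
spatial activation pattern follows such boundaries, whether it
generalizes across movie contents and across the encoding/recall tasks,
how it unfolds in time, how it relates to within-movie scene boundaries,
and whether silence or audio-amplitude confounds can explain it.

It is aimed at cognitive-neuroscience researchers doing multivariate
pattern (RSA-style) analyses on surface-sampled BOLD data, and ships a
fully specified synthetic-experiment generator so that every stage of
the pipeline is testable end-to-end without downloading any data.

## The core quantities

For each subject, parcel, movie *m* and phase, with TR = 1.5 s:

* boundary pattern: mean spatial pattern over `[offset_m + 4.5 s, offset_m + 19.5 s)`
* non-boundary pattern: mean pattern over the middle 15 s of the movie,
  shifted forward 4.5 s for the hemodynamic delay

and the pattern-similarity statistics

* *a* — mean Pearson r between boundary patterns of different movies
  within recall (45 unordered pairs)
* *b* — the same for non-boundary patterns
* *c*, *d* — the same across encoding and recall (90 ordered pairs)

Group inference uses two-tailed one-sample/paired t-tests across
subjects with Cohen's d_z = t/√n and 95% CIs; maps are corrected with
Bonferroni across parcels or Benjamini–Hochberg FDR across vertices,
and a **conjunction map** marks parcels with both significantly positive
boundary similarity and boundary > non-boundary similarity. Further
stages compute peri-boundary time–time correlation matrices
(−30…+60 s, 61×61 cells, Bonferroni over testable cells),
within-movie vs between-movie boundary templates, and silence/audio
controls built on a Hilbert-envelope → HRF-convolution → z-score
regressor. See `docs/methods.md` for the full model and conventions.

## Worked example

```python
from boundarypatterns import GroundTruthConfig, generate_experiment
from boundarypatterns.similarity import (
    build_pattern_set, mean_between_movie_similarity,
)
from boundarypatterns.stats import one_sample_t

# 15 synthetic subjects, 10 movies, 40 parcels; a shared boundary
# pattern is planted in 4 parcels at half the noise amplitude
exp = generate_experiment(GroundTruthConfig(seed=1), preprocess=True)

roi = exp.truth.boundary_parcels        # the planted "PMC-like" ROI
a = [
    mean_between_movie_similarity(
        build_pattern_set(exp.runs, exp.events, region=roi, subject=s),
        ("recall", "recall"), "boundary",
    )
    for s in exp.subject_ids()
]
res = one_sample_t(a)
print(f"recall-recall boundary similarity: mean r = {res.mean:.3f}, "
      f"t({res.df}) = {res.t_stat:.2f}, d_z = {res.d_z:.2f}")
```

Output:

```
recall-recall boundary similarity: mean r = 0.195, t(14) = 26.45, d_z = 6.83
```

A mean between-movie correlation of ~0.2 with t(14) ≈ 26 says that
whenever this synthetic subject population transitions between recalled
movies, the same spatial pattern reappears in the planted ROI —
regardless of which movie just ended. The same quantity computed for
non-boundary patterns is ≈ 0 (no shared mid-movie pattern), and the
cross-phase version (*c*) is positive, i.e. the pattern generalizes
from watching to recalling.

The command-line interface runs whole stages:

```bash
boundarypatterns report --seed 1 --outdir results/
```

writes per-stage TSVs (univariate map, per-parcel similarities and
conjunction masks, the 40×40 condition matrix, time–time matrices,
template and silence-control correlations) plus `summary.json` with the
headline group statistics, the seed, and a config hash.

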