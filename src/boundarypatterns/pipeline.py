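"""End-to-end pipeline driver: simulate -> preprocess -> analyses -> report.

The pipeline operates on a synthetic experiment (or a previously saved
dataset directory) and writes one TSV/JSON bundle per stage plus a
summary JSON capturing the headline group statistics, the seed, and a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import WindowSpec, DEFAULT_WINDOW, SHORT_WINDOW
from .synth import GroundTruthConfig, generate_experiment, preprocess_experiment
from .preprocess import double_gamma_hrf, envelope_regressor, TRIM_VOLUMES
from .univariate import (
    subject_boundary_contrast,
    group_univariate_map,
    parcel_clique_adjacency,
)
from .similarity import (
    parcelwise_similarity,
    conjunction_map,
    build_pattern_set,
    full_condition_matrix,
    mean_between_movie_similarity,
)
from .dynamics import (
    timelocked_pattern_series,
    timetime_matrix,
    group_timetime_significance,
)
from .templates import build_templates, template_similarity
from .silence import (
    silence_timepoints,
    silence_pattern_correlation,
    amplitude_similarity_correlation,
)
from .stats import one_sample_t, paired_t
from .io import save_experiment, write_group_map_tsv

ALL_STAGES = (
    "simulate",
    "preprocess",
    "univariate",
    "similarity",
    "temporal",
    "templates",
    "silence",
    "report",
)


@dataclass
class PipelineConfig:
    """Everything a full pipeline run consumes.

    ``boundary_roi`` / ``aud_roi`` are parcel label lists (the PMC and
    auditory-cortex analogs); None means "use the generator's planted
    sets".
    """

    seed: int = 0
    outdir: str = "results"
    synth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    window_shift_s: float = 4.5
    window_duration_s: float = 15.0
    alpha: float = 0.05
    fdr_q: float = 0.05
    min_area_mm2: float = 16.0
    highpass_cutoff_s: float = 140.0
    boundary_roi: tuple | None = None
    aud_roi: tuple | None = None
    stages: tuple = ALL_STAGES
    save_dataset: bool = False

    @property
    def window(self) -> WindowSpec:
        return WindowSpec(self.window_shift_s, self.window_duration_s)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        synth = d.pop("synth", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__ and k != "synth"})
        if synth is not None:
            synth["movie_durations_s"] = tuple(synth["movie_durations_s"])
            synth["n_event_boundaries"] = tuple(synth["n_event_boundaries"])
            cfg = dataclasses.replace(cfg, synth=GroundTruthConfig(**synth))
        for name in ("stages", "boundary_roi", "aud_roi"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                cfg = dataclasses.replace(cfg, **{name: tuple(v)})
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        d.pop("save_dataset", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; any stage failure aborts with
    the stage name. Returns the results bundle (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, results, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ValueError(f"stage '{stage}' needs '{key}' from an earlier stage")
    return state[key]


def _stage_simulate(config, state, results, outdir):
    synth = dataclasses.replace(config.synth, seed=config.seed)
    exp = generate_experiment(synth)
    state["raw"] = exp
    results["n_subjects"] = synth.n_subjects
    results["n_parcels"] = synth.n_parcels
    if config.save_dataset:
        save_experiment(exp, outdir / "dataset")


def _stage_preprocess(config, state, results, outdir):
    exp = _require(state, "raw", "preprocess")
    proc = preprocess_experiment(exp, cutoff_s=config.highpass_cutoff_s)
    state["exp"] = proc
    hrf = double_gamma_hrf(exp.truth.config.tr_s)
    state["regressors"] = {
        run_no: envelope_regressor(env, hrf, TRIM_VOLUMES["encoding"])
        for run_no, env in exp.envelopes.items()
    }
    state["rois"] = {
        "boundary": tuple(config.boundary_roi or exp.truth.boundary_parcels),
        "aud": tuple(config.aud_roi or exp.truth.aud_parcels),
    }


def _stage_univariate(config, state, results, outdir):
    exp = _require(state, "exp", "univariate")
    subjects = exp.subject_ids()
    contrasts = np.stack(
        [
            subject_boundary_contrast(exp.runs, exp.events, config.window, subject=s)
            for s in subjects
        ]
    )
    any_run = next(iter(exp.runs.values()))
    gmap = group_univariate_map(
        contrasts,
        q=config.fdr_q,
        min_area_mm2=config.min_area_mm2,
        adjacency=parcel_clique_adjacency(any_run.vertex_parcel),
        vertex_area_mm2=any_run.vertex_area_mm2,
    )
    write_group_map_tsv(outdir / "univariate_map.tsv", gmap, any_run.vertex_parcel)
    results["univariate"] = {
        "n_significant_vertices": int(gmap.significant.sum()),
        "frac_significant": float(gmap.significant.mean()),
    }
    state["univariate_map"] = gmap


def _stage_similarity(config, state, results, outdir):
    exp = _require(state, "exp", "similarity")
    sim = parcelwise_similarity(exp.runs, exp.events, config.window)
    state["parcel_similarity"] = sim
    mask_recall = conjunction_map(sim.a, sim.b, config.alpha)
    mask_cross = conjunction_map(sim.c, sim.d, config.alpha)
    pd.DataFrame(
        {
            "parcel": sim.parcels,
            "a_recall_boundary": sim.a.mean(axis=0),
            "b_recall_nonboundary": sim.b.mean(axis=0),
            "c_cross_boundary": sim.c.mean(axis=0),
            "d_cross_nonboundary": sim.d.mean(axis=0),
            "conjunction_recall": mask_recall.astype(int),
            "conjunction_cross": mask_cross.astype(int),
        }
    ).to_csv(outdir / "parcel_similarity.tsv", sep="\t", index=False)

    roi = state["rois"]["boundary"]
    pattern_sets = [
        build_pattern_set(exp.runs, exp.events, config.window, region=roi, subject=s)
        for s in exp.subject_ids()
    ]
    state["roi_pattern_sets"] = pattern_sets
    per = {
        "a": [mean_between_movie_similarity(ps, ("recall", "recall"), "boundary") for ps in pattern_sets],
        "b": [mean_between_movie_similarity(ps, ("recall", "recall"), "nonboundary") for ps in pattern_sets],
        "c": [mean_between_movie_similarity(ps, ("encoding", "recall"), "boundary") for ps in pattern_sets],
        "d": [mean_between_movie_similarity(ps, ("encoding", "recall"), "nonboundary") for ps in pattern_sets],
    }
    roi_stats = {
        "recall_boundary": one_sample_t(per["a"]).as_dict(),
        "recall_nonboundary": one_sample_t(per["b"]).as_dict(),
        "cross_boundary": one_sample_t(per["c"]).as_dict(),
        "cross_nonboundary": one_sample_t(per["d"]).as_dict(),
        "recall_boundary_vs_nonboundary": paired_t(per["a"], per["b"]).as_dict(),
    }
    mat = full_condition_matrix(pattern_sets)
    np.savetxt(outdir / "condition_matrix.tsv", mat, delimiter="\t")
    truth = exp.truth
    results["similarity"] = {
        "conjunction_recall_parcels": [int(p) for p in np.array(sim.parcels)[mask_recall]],
        "conjunction_cross_parcels": [int(p) for p in np.array(sim.parcels)[mask_cross]],
        "planted_boundary_parcels": list(truth.boundary_parcels),
        "planted_aud_parcels": list(truth.aud_parcels),
        "null_parcels": list(truth.null_parcels),
        "roi_stats": roi_stats,
    }


def _stage_temporal(config, state, results, outdir):
    exp = _require(state, "exp", "temporal")
    roi = state["rois"]["boundary"]
    mats = []
    for s in exp.subject_ids():
        enc = timelocked_pattern_series(
            exp.runs, exp.events, "offset", "encoding", region=roi, subject=s
        )
        rec = timelocked_pattern_series(
            exp.runs, exp.events, "offset", "recall", region=roi, subject=s
        )
        mats.append(timetime_matrix(enc, rec))
    sig, t_map, _ = group_timetime_significance(mats, config.alpha)
    mean_mat = np.nanmean(np.stack(mats), axis=0)
    np.savetxt(outdir / "timetime_offset_enc_rec.tsv", mean_mat, delimiter="\t")
    np.savetxt(
        outdir / "timetime_offset_enc_rec_sig.tsv", sig.astype(int), delimiter="\t", fmt="%d"
    )
    results["temporal"] = {
        "n_significant_cells": int(sig.sum()),
        "n_testable_cells": int((~np.isnan(t_map)).sum()),
    }
    state["timetime_sig"] = sig


def _stage_templates(config, state, results, outdir):
    exp = _require(state, "exp", "templates")
    roi = state["rois"]["boundary"]
    tsets = [
        build_templates(exp.runs, exp.events, config.window, region=roi, subject=s)
        for s in exp.subject_ids()
    ]
    state["template_sets"] = tsets
    ts = template_similarity(tsets)
    pd.DataFrame(
        {
            "subject": exp.subject_ids(),
            "orange_between_between_r": ts.orange_r,
            "green_within_between_r": ts.green_r,
        }
    ).to_csv(outdir / "template_similarity.tsv", sep="\t", index=False)
    results["templates"] = {
        "orange": ts.orange_stats.as_dict(),
        "green": ts.green_stats.as_dict(),
    }


def _stage_silence(config, state, results, outdir):
    exp = _require(state, "exp", "silence")
    regressors = state["regressors"]
    subjects = exp.subject_ids()
    masks = {}
    for run_no, reg in regressors.items():
        run = exp.runs[(subjects[0], "encoding", run_no)]
        masks[run_no] = silence_timepoints(reg, run, exp.events)
    out = {}
    for roi_name in ("aud", "boundary"):
        roi = state["rois"][roi_name]
        templates = {
            s: build_templates(exp.runs, exp.events, config.window, region=roi, subject=s).between_recall
            for s in subjects
        }
        rs, stats_ = silence_pattern_correlation(exp.runs, masks, templates, region=roi)
        ra, stats_a = amplitude_similarity_correlation(
            exp.runs, regressors, templates, exp.events, region=roi
        )
        out[roi_name] = {
            "silence_r": stats_.as_dict(),
            "amplitude_r": stats_a.as_dict(),
            "per_subject_silence_r": rs.tolist(),
            "per_subject_amplitude_r": ra.tolist(),
        }
    pd.DataFrame(
        {
            "subject": subjects,
            "aud_silence_r": out["aud"]["per_subject_silence_r"],
            "boundary_roi_silence_r": out["boundary"]["per_subject_silence_r"],
            "aud_amplitude_r": out["aud"]["per_subject_amplitude_r"],
            "boundary_roi_amplitude_r": out["boundary"]["per_subject_amplitude_r"],
        }
    ).to_csv(outdir / "silence_controls.tsv", sep="\t", index=False)
    results["silence"] = {
        k: {"silence_r": v["silence_r"], "amplitude_r": v["amplitude_r"]}
        for k, v in out.items()
    }


def _stage_report(config, state, results, outdir):
    (outdir / "summary.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "univariate": _stage_univariate,
    "similarity": _stage_similarity,
    "temporal": _stage_temporal,
    "templates": _stage_templates,
    "silence": _stage_silence,
    "report": _stage_report,
}
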