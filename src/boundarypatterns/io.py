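"""Dataset container: HDF5 run matrices + TSV events + JSON sidecar.

Layout of a dataset directory::

    container.h5          one group per (subject, phase, run) holding the
                          vertex x TR matrix and acquisition metadata;
                          root-level vertex_parcel / vertex_area_mm2
    events.tsv            the event table (see events.EventTable)
    envelope_run<k>.tsv   raw per-TR audio amplitude per encoding run
    dataset.json          schema version and free-form metadata
    truth.json            (synthetic data only) planted parcel sets + config

Real surface-sampled data (GIFTI) can be converted into this container
with :func:`gifti_to_rundata`; the analyses never read imaging formats
directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventTable, RunData
from .synth import SyntheticExperiment, GroundTruthConfig

SCHEMA_VERSION = 1


def save_experiment(exp: SyntheticExperiment, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    any_run = next(iter(exp.runs.values()))
    with h5py.File(outdir / "container.h5", "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("vertex_parcel", data=any_run.vertex_parcel)
        if any_run.vertex_area_mm2 is not None:
            f.create_dataset("vertex_area_mm2", data=any_run.vertex_area_mm2)
        for (subject, phase, run_no), run in exp.runs.items():
            g = f.create_group(f"{subject}/{phase}/run-{run_no}")
            g.create_dataset("data", data=run.data)
            g.attrs["tr_s"] = run.tr_s
            g.attrs["trim_offset_s"] = run.trim_offset_s
    exp.events.to_tsv(outdir / "events.tsv")
    for run_no, env in exp.envelopes.items():
        pd.DataFrame(
            {"time_s": np.arange(env.size) * any_run.tr_s, "amplitude": env}
        ).to_csv(outdir / f"envelope_run{run_no}.tsv", sep="\t", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_vertices": int(any_run.n_vertices),
        "tr_s": any_run.tr_s,
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=2))
    truth = {
        "boundary_parcels": list(exp.truth.boundary_parcels),
        "aud_parcels": list(exp.truth.aud_parcels),
        "null_parcels": list(exp.truth.null_parcels),
        "dip_trs": {str(k): list(map(int, v)) for k, v in exp.truth.dip_trs.items()},
        "config": dataclasses.asdict(exp.truth.config),
        "patterns": {
            "boundary": exp.truth.pattern_boundary.tolist(),
            "event": exp.truth.pattern_event.tolist(),
            "silence": exp.truth.pattern_silence.tolist(),
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
    return outdir


def load_dataset(path):
    """Load a dataset directory -> (runs, events, envelopes, meta).

    Validates the schema version, label-array lengths, NaN-freeness and
    event-table invariants; errors name the offending field or row.
    """
    path = Path(path)
    meta_path = path / "dataset.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} missing: not a dataset directory")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema_version mismatch: got {meta.get('schema_version')}, "
            f"expected {SCHEMA_VERSION}"
        )
    events = EventTable.from_tsv(path / "events.tsv")
    runs = {}
    with h5py.File(path / "container.h5", "r") as f:
        vertex_parcel = f["vertex_parcel"][()]
        area = f["vertex_area_mm2"][()] if "vertex_area_mm2" in f else None
        for subject in f:
            if not isinstance(f[subject], h5py.Group):
                continue
            for phase in f[subject]:
                for run_name in f[subject][phase]:
                    g = f[subject][phase][run_name]
                    run_no = int(run_name.split("-")[1])
                    data = g["data"][()]
                    if data.shape[0] != vertex_parcel.shape[0]:
                        raise ValueError(
                            f"vertex_parcel length {vertex_parcel.shape[0]} != "
                            f"n_vertices {data.shape[0]} in {subject}/{phase}"
                        )
                    runs[(subject, phase, run_no)] = RunData(
                        subject_id=subject,
                        phase=phase,
                        run=run_no,
                        data=data,
                        vertex_parcel=vertex_parcel,
                        tr_s=float(g.attrs["tr_s"]),
                        trim_offset_s=float(g.attrs["trim_offset_s"]),
                        vertex_area_mm2=area,
                    )
    envelopes = {}
    for env_path in sorted(path.glob("envelope_run*.tsv")):
        run_no = int(env_path.stem.replace("envelope_run", ""))
        envelopes[run_no] = pd.read_csv(env_path, sep="\t")["amplitude"].to_numpy()
    truth_path = path / "truth.json"
    if truth_path.exists():
        meta["truth"] = json.loads(truth_path.read_text())
    return runs, events, envelopes, meta


def gifti_to_rundata(
    func_paths, subject_id, phase, run, vertex_parcel, tr_s=1.5
) -> RunData:
    """Optional ingestion path for real surface-sampled data.

    ``func_paths`` are GIFTI functional files (one per hemisphere) whose
    darrays are time points; they are stacked vertex-wise. Requires
    nibabel.
    """
    import nibabel as nib  # optional dependency

    mats = []
    for p in func_paths:
        img = nib.load(str(p))
        mats.append(np.stack([d.data for d in img.darrays], axis=1))
    data = np.concatenate(mats, axis=0)
    return RunData(
        subject_id=subject_id,
        phase=phase,
        run=run,
        data=data,
        vertex_parcel=np.asarray(vertex_parcel),
        tr_s=tr_s,
    )


def write_group_map_tsv(path, map_result, vertex_parcel=None) -> None:
    """Write a GroupStatMap as TSV (vertex, parcel, effect, t, p, significant)."""
    df = pd.DataFrame(
        {
            "vertex": np.arange(map_result.effect.size),
            "effect": map_result.effect,
            "t": map_result.t_stat,
            "p": map_result.p_two_tailed,
            "significant": map_result.significant.astype(int),
        }
    )
    if vertex_parcel is not None:
        df.insert(1, "parcel", vertex_parcel)
    df.to_csv(path, sep="\t", index=False)
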