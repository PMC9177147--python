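"""Vertex-wise univariate boundary response during recall.

Contrasts mean activation in the 15 s following each recalled movie's
offset against the middle 15 s of the movie (both shifted 4.5 s), then
performs a group one-sample t-test per vertex with Benjamini-Hochberg
FDR control and a minimum-surface-area component filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
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
from .stats import vectorized_one_sample_t, bh_mask


@dataclass
class GroupStatMap:
    effect: np.ndarray
    t_stat: np.ndarray
    p_two_tailed: np.ndarray
    significant: np.ndarray
    sign: np.ndarray


def subject_boundary_contrast(
    runs: dict,
    events: EventTable,
    spec: WindowSpec = DEFAULT_WINDOW,
    subject: str | None = None,
    phase: str = "recall",
) -> np.ndarray:
    """Per-vertex boundary minus non-boundary mean activation for one
    subject: average over TRs within each window, then over movies."""
    if subject is None:
        subjects = {k[0] for k in runs}
        if len(subjects) != 1:
            raise ValueError("pass subject= when runs span multiple subjects")
        subject = subjects.pop()
    bounds, middles = [], []
    for (subj, ph, run_no), run in runs.items():
        if subj != subject or ph != phase:
            continue
        for _, row in events.movies(subject, phase, run_no).iterrows():
            m = int(row["movie_id"])
            bw = boundary_window(row["offset_s"], spec)
            mw = middle_window(row["onset_s"], row["offset_s"], spec)
            br = seconds_to_tr_range(bw[0], bw[1], run)
            mr = seconds_to_tr_range(mw[0], mw[1], run)
            if len(br) == 0 or len(mr) == 0:
                raise ValueError(f"empty window for movie {m} of {subject}")
            bounds.append(extract_mean_pattern(run, br))
            middles.append(extract_mean_pattern(run, mr))
    if not bounds:
        raise ValueError(f"no recalled movies for subject {subject}")
    return np.mean(bounds, axis=0) - np.mean(middles, axis=0)


def parcel_clique_adjacency(vertex_parcel: np.ndarray) -> list[tuple[int, int]]:
    """Default adjacency for data without a mesh: every parcel is a clique."""
    edges = []
    for p in np.unique(vertex_parcel):
        idx = np.flatnonzero(vertex_parcel == p)
        edges.extend(
            (int(idx[i]), int(idx[j]))
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
        )
    return edges


def group_univariate_map(
    contrasts: np.ndarray,
    q: float = 0.05,
    min_area_mm2: float = 16.0,
    adjacency: list | None = None,
    vertex_area_mm2: np.ndarray | None = None,
) -> GroupStatMap:
    """Group inference on stacked per-subject contrasts (subjects x
    vertices): two-tailed t against zero, BH across vertices, then
    removal of connected components of same-signed significant vertices
    whose summed surface area falls below ``min_area_mm2``."""
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.ndim != 2 or contrasts.shape[0] < 2:
        raise ValueError("need a subjects x vertices array with >= 2 subjects")
    t, p, effect = vectorized_one_sample_t(contrasts)
    sig = bh_mask(p, q)
    sign = np.sign(t).astype(int)

    if min_area_mm2 > 0 and sig.any():
        if adjacency is None:
            raise ValueError("min_area_mm2 > 0 requires a vertex adjacency")
        n_vertices = contrasts.shape[1]
        area = (
            np.ones(n_vertices)
            if vertex_area_mm2 is None
            else np.asarray(vertex_area_mm2, dtype=float)
        )
        g = nx.Graph()
        g.add_nodes_from(np.flatnonzero(sig).tolist())
        for u, v in adjacency:
            if sig[u] and sig[v] and sign[u] == sign[v]:
                g.add_edge(u, v)
        for comp in nx.connected_components(g):
            comp = list(comp)
            if area[comp].sum() < min_area_mm2:
                sig[comp] = False
    return GroupStatMap(
        effect=effect, t_stat=t, p_two_tailed=p, significant=sig, sign=sign
    )
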