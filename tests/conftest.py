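import numpy as np
import pytest

from boundarypatterns.events import RunData
from boundarypatterns.synth import GroundTruthConfig, generate_experiment

#: a scaled-down experiment for fast unit tests: shorter movies, fewer
#: subjects/vertices, but the same structure (10 movies, 2 encoding runs,
#: titles, pauses, within-movie boundaries, audio dips)
TINY = GroundTruthConfig(
    n_subjects=4,
    n_parcels=12,
    vertices_per_parcel=10,
    movie_durations_s=tuple(90.0 + 15.0 * k for k in range(10)),
    recall_frac=0.6,
    seed=1234,
)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_exp():
    """Raw (unpreprocessed) tiny experiment."""
    return generate_experiment(TINY)


@pytest.fixture(scope="session")
def tiny_proc():
    """Preprocessed tiny experiment (trim + high-pass + z-score)."""
    return generate_experiment(TINY, preprocess=True)


def make_run(
    data,
    phase="recall",
    tr_s=1.5,
    trim_offset_s=0.0,
    subject="sub-01",
    run=1,
    n_parcels=1,
):
    """Hand-built RunData for oracle tests (float64)."""
    data = np.asarray(data, dtype=float)
    n_vertices = data.shape[0]
    per = max(n_vertices // n_parcels, 1)
    parcels = np.minimum(np.arange(n_vertices) // per, n_parcels - 1)
    return RunData(
        subject_id=subject,
        phase=phase,
        run=run,
        data=data,
        vertex_parcel=parcels,
        tr_s=tr_s,
        trim_offset_s=trim_offset_s,
    )
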