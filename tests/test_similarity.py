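"""Pattern sets, between-movie similarity, conjunction logic."""

import dataclasses
import itertools

import numpy as np
import pytest

from boundarypatterns.events import DEFAULT_WINDOW
from boundarypatterns.synth import generate_experiment
from boundarypatterns.similarity import (
    PatternSet,
    build_pattern_set,
    between_movie_pairs,
    mean_between_movie_similarity,
    parcelwise_similarity,
    conjunction_map,
    full_condition_matrix,
    visual_control_contrast,
    CONDITION_ORDER,
)
from conftest import TINY


@pytest.fixture(scope="module")
def pattern_sets(tiny_proc):
    return [
        build_pattern_set(
            tiny_proc.runs, tiny_proc.events, DEFAULT_WINDOW,
            region=tiny_proc.truth.boundary_parcels, subject=s,
        )
        for s in tiny_proc.subject_ids()
    ]


class TestBuildPatternSet:
    def test_complete_subject_has_40_patterns(self, pattern_sets):
        for ps in pattern_sets:
            assert len(ps.patterns) == 40  # 10 movies x 2 phases x 2 conditions
            assert not ps.missing

    def test_missing_recalls_recorded_not_fatal(self, tiny_proc):
        s = tiny_proc.subject_ids()[0]
        ev = tiny_proc.events
        pruned = ev.df[
            ~(
                (ev.df["subject"] == s)
                & (ev.df["phase"] == "recall")
                & (ev.df["kind"] == "movie")
                & (ev.df["movie_id"].isin([3, 7]))
            )
        ]
        from boundarypatterns.events import EventTable

        ps = build_pattern_set(
            tiny_proc.runs, EventTable(pruned), DEFAULT_WINDOW,
            region=tiny_proc.truth.boundary_parcels, subject=s,
        )
        assert len(ps.patterns) == 36
        assert ("recall", 3, "boundary") in ps.missing

    def test_empty_region_rejected(self, tiny_proc):
        with pytest.raises(ValueError, match="no vertices"):
            build_pattern_set(
                tiny_proc.runs, tiny_proc.events, DEFAULT_WINDOW,
                region=(999,), subject=tiny_proc.subject_ids()[0],
            )


class TestPairCounts:
    def test_within_phase_45_unordered(self):
        pairs = between_movie_pairs(range(1, 11), range(1, 11), ordered=False)
        assert len(pairs) == 45

    def test_cross_phase_90_ordered(self):
        pairs = between_movie_pairs(range(1, 11), range(1, 11), ordered=True)
        assert len(pairs) == 90
        assert all(i != j for i, j in pairs)


class TestMeanSimilarity:
    def test_matches_brute_force_double_loop(self, pattern_sets):
        """Oracle equivalence: the averaged pair correlations equal an
        explicit double loop to 1e-12."""
        ps = pattern_sets[0]
        got = mean_between_movie_similarity(ps, ("recall", "recall"), "boundary")
        rs = []
        for i in range(1, 11):
            for j in range(i + 1, 11):
                a = ps.get("recall", i, "boundary")
                b = ps.get("recall", j, "boundary")
                rs.append(np.corrcoef(a, b)[0, 1])
        assert len(rs) == 45
        assert got == pytest.approx(np.mean(rs), abs=1e-12)

        got_x = mean_between_movie_similarity(ps, ("encoding", "recall"), "boundary")
        rs_x = [
            np.corrcoef(ps.get("encoding", i, "boundary"),
                        ps.get("recall", j, "boundary"))[0, 1]
            for i in range(1, 11) for j in range(1, 11) if i != j
        ]
        assert len(rs_x) == 90
        assert got_x == pytest.approx(np.mean(rs_x), abs=1e-12)

    def test_identical_patterns_give_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        patterns = {
            (ph, m, "boundary"): v.copy()
            for ph in ("encoding", "recall")
            for m in range(1, 11)
        }
        ps = PatternSet("sub-x", (), patterns)
        assert mean_between_movie_similarity(
            ps, ("recall", "recall"), "boundary"
        ) == pytest.approx(1.0)

    def test_constant_pattern_rejected(self):
        patterns = {
            ("recall", m, "boundary"): np.zeros(10) for m in range(1, 11)
        }
        ps = PatternSet("sub-x", (), patterns)
        with pytest.raises(ValueError, match="constant"):
            mean_between_movie_similarity(ps, ("recall", "recall"), "boundary")

    def test_scaling_invariance(self, tiny_proc):
        """Pearson similarity ignores global scaling of a subject's data."""
        s = tiny_proc.subject_ids()[0]
        runs = {k: v for k, v in tiny_proc.runs.items() if k[0] == s}
        scaled = {
            k: dataclasses.replace(v, data=v.data * 3.7) for k, v in runs.items()
        }
        roi = tiny_proc.truth.boundary_parcels
        a = build_pattern_set(runs, tiny_proc.events, DEFAULT_WINDOW, region=roi)
        b = build_pattern_set(scaled, tiny_proc.events, DEFAULT_WINDOW, region=roi)
        for pair in (("recall", "recall"), ("encoding", "recall")):
            assert mean_between_movie_similarity(a, pair, "boundary") == pytest.approx(
                mean_between_movie_similarity(b, pair, "boundary"), abs=1e-6
            )


class TestParcelwise:
    def test_matches_per_roi_computation(self, tiny_proc):
        sim = parcelwise_similarity(tiny_proc.runs, tiny_proc.events)
        s0 = tiny_proc.subject_ids()[0]
        for parcel in (0, 5, 11):
            ps = build_pattern_set(
                tiny_proc.runs, tiny_proc.events, DEFAULT_WINDOW,
                region=(parcel,), subject=s0,
            )
            pi = sim.parcels.index(parcel)
            assert sim.a[0, pi] == pytest.approx(
                mean_between_movie_similarity(ps, ("recall", "recall"), "boundary"),
                abs=1e-9,
            )
            assert sim.c[0, pi] == pytest.approx(
                mean_between_movie_similarity(ps, ("encoding", "recall"), "boundary"),
                abs=1e-9,
            )

    def test_boundary_exceeds_nonboundary_in_planted_parcels(self, tiny_proc):
        sim = parcelwise_similarity(tiny_proc.runs, tiny_proc.events)
        planted = list(tiny_proc.truth.boundary_parcels)
        assert sim.a[:, planted].mean() > sim.b[:, planted].mean() + 0.05


class TestConjunction:
    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            conjunction_map(np.ones((1, 5)), np.zeros((1, 5)))

    def test_positive_and_greater_required(self):
        rng = np.random.default_rng(1)
        n_sub, n_parcel = 12, 6
        a = rng.normal(0.0, 0.01, (n_sub, n_parcel))
        b = rng.normal(0.0, 0.01, (n_sub, n_parcel))
        a[:, 0] += 0.5          # positive and > b -> flagged
        a[:, 1] -= 0.5          # strongly negative -> never flagged
        b[:, 2] += 0.5          # b > a with a null -> not flagged
        mask = conjunction_map(a, b)
        assert mask[0]
        assert not mask[1] and not mask[2]
        assert not mask[3:].any()

    def test_bonferroni_denominator_is_parcel_count(self):
        """A parcel at p slightly above alpha/m fails, below passes."""
        from scipy import stats as sps

        n_sub, m = 15, 400
        t_edge = sps.t.isf(0.05 / m / 2, n_sub - 1)
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1.0, n_sub)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
        a = np.tile(base[:, None], (1, m)) * 0.01
        a[:, 0] = base * 0.01 + 0.01 * (t_edge + 0.2) / np.sqrt(n_sub)
        a[:, 1] = base * 0.01 + 0.01 * (t_edge - 0.2) / np.sqrt(n_sub)
        b = np.zeros((n_sub, m))
        mask = conjunction_map(a, b)
        assert mask[0] and not mask[1]


class TestFullConditionMatrix:
    def test_shape_diagonal_symmetry(self, pattern_sets):
        mat = full_condition_matrix(pattern_sets)
        assert mat.shape == (40, 40)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T, atol=1e-12)
        assert len(CONDITION_ORDER) == 40

    def test_boundary_block_elevated_for_planted_region(self, pattern_sets):
        mat = full_condition_matrix(pattern_sets)
        idx = {key: k for k, key in enumerate(CONDITION_ORDER)}
        bb = [
            mat[idx[("recall", "boundary", i)], idx[("recall", "boundary", j)]]
            for i, j in itertools.combinations(range(1, 11), 2)
        ]
        nn = [
            mat[idx[("recall", "nonboundary", i)], idx[("recall", "nonboundary", j)]]
            for i, j in itertools.combinations(range(1, 11), 2)
        ]
        assert np.mean(bb) > np.mean(nn) + 0.05


class TestVisualControl:
    def test_planted_region_positive_null_absent(self, tiny_proc):
        t, p, mask = visual_control_contrast(tiny_proc.runs, tiny_proc.events)
        planted = list(tiny_proc.truth.boundary_parcels)
        null = list(tiny_proc.truth.null_parcels)
        assert t[planted].min() > 0
        assert mask[planted].any()
        assert not mask[null].any()
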