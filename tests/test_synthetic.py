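import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_pearson
from hypercoev.dynamics import edge_time_series, network_sequence
from hypercoev.hypergraph import edge_edge_correlation
from hypercoev.prep import bandpass
from hypercoev.synthetic import (
    PlantedDesign,
    PlantedGroup,
    TaskBlock,
    generate_edge_level,
    generate_fd_trace,
    generate_region_level,
    generate_region_size_table,
)


def design(groups, n_nodes=8, noise_sd=0.2, seed=0, n_windows=20):
    return PlantedDesign(
        n_nodes=n_nodes,
        tasks=(TaskBlock("a", 2.0, n_windows), TaskBlock("b", 2.5, n_windows)),
        groups=groups,
        noise_sd=noise_sd,
        seed=seed,
    )


class TestDesignValidation:
    def test_amplitude_bounds(self):
        with pytest.raises(ValueError, match="amplitude"):
            PlantedGroup(edges=((0, 1),), amplitude=1.2)

    def test_node_out_of_range(self):
        g = PlantedGroup(edges=((0, 9),), amplitude=0.5)
        with pytest.raises(ValueError, match="node"):
            design((g,), n_nodes=8)

    def test_pairs_normalized_unordered(self):
        g = PlantedGroup(edges=((3, 1),), amplitude=0.5)
        assert g.edges == ((1, 3),)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PlantedGroup(edges=((2, 2),), amplitude=0.5)

    def test_min_windows(self):
        with pytest.raises(ValueError, match="windows"):
            PlantedDesign(n_nodes=4, tasks=(TaskBlock("a", 2.0, 1),),
                          groups=(), noise_sd=0.1)


class TestEdgeLevel:
    def test_zero_noise_members_identical(self):
        g = PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=1.0)
        ets, truth = generate_edge_level(design((g,), noise_sd=0.0))
        rows = truth.member_rows[0]
        for i, j in itertools.combinations(rows, 2):
            np.testing.assert_allclose(ets.weights[i], ets.weights[j])
            assert brute_pearson(ets.weights[i], ets.weights[j]) == pytest.approx(1.0)

    def test_null_case_rows_independent(self):
        g = PlantedGroup(edges=((0, 1), (2, 3)), amplitude=0.0)
        ets, truth = generate_edge_level(
            design((g,), noise_sd=0.3, n_windows=400)
        )
        rows = truth.member_rows[0]
        assert abs(brute_pearson(ets.weights[rows[0]], ets.weights[rows[1]])) < 0.12

    def test_within_group_exceeds_between_group_correlation(self):
        g = PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=0.9)
        ets, truth = generate_edge_level(design((g,), noise_sd=0.3, seed=7))
        rows = truth.member_rows[0]
        others = [r for r in range(ets.n_edges) if r not in rows]
        within = np.mean([
            brute_pearson(ets.weights[i], ets.weights[j])
            for i, j in itertools.combinations(rows, 2)
        ])
        between = np.mean([
            brute_pearson(ets.weights[i], ets.weights[j])
            for i in rows for j in others[:10]
        ])
        assert within > between

    def test_weights_inside_unit_interval(self):
        g = PlantedGroup(edges=((0, 1),), amplitude=1.0,
                         task_levels={"a": 1.0, "b": -1.0})
        ets, _ = generate_edge_level(design((g,), noise_sd=0.5))
        assert (np.abs(ets.weights) < 1.0).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_deterministic_given_seed(self, seed):
        g = PlantedGroup(edges=((0, 1), (2, 3)), amplitude=0.7, task="a")
        d = design((g,), seed=seed, n_windows=5)
        a, _ = generate_edge_level(d)
        b, _ = generate_edge_level(d)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_explicit_edge_subset(self):
        g = PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=1.0)
        ets, truth = generate_edge_level(
            design((g,), noise_sd=0.0),
            edges=[(0, 1), (2, 3), (4, 5), (6, 7)],
        )
        assert ets.n_edges == 4
        assert truth.member_rows[0] == [0, 1, 2]


class TestRegionLevel:
    def test_zero_noise_pair_weight_one_in_active_windows(self):
        d = PlantedDesign(
            n_nodes=4, tasks=(TaskBlock("t", 2.0, 6),),
            groups=(PlantedGroup(edges=((0, 1),), amplitude=1.0),),
            noise_sd=0.0, seed=3,
        )
        runs, _ = generate_region_level(d)
        with pytest.warns(UserWarning):  # nodes 2, 3 are flat at zero noise
            ets = edge_time_series(network_sequence(runs))
        np.testing.assert_allclose(ets.weights[ets.row_of(0, 1)], 1.0, atol=1e-9)

    def test_task_restricted_group_correlates_within_its_task(self):
        g = PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=0.95, task="a")
        d = design((g,), n_nodes=10, noise_sd=0.2, seed=5, n_windows=12)
        runs, truth = generate_region_level(d)
        runs = [bandpass(r) for r in runs]
        ets = edge_time_series(network_sequence(runs))
        rows = truth.member_rows[0]
        def mean_corr(cols):
            return np.mean([
                brute_pearson(ets.weights[i, cols], ets.weights[j, cols])
                for i, j in itertools.combinations(rows, 2)
            ])
        in_task = mean_corr(ets.task_windows("a"))
        out_task = mean_corr(ets.task_windows("b"))
        assert in_task > out_task + 0.2

    def test_byte_identical_given_seed(self):
        g = PlantedGroup(edges=((0, 1),), amplitude=0.8)
        d = design((g,), n_nodes=5, seed=11, n_windows=4)
        a, _ = generate_region_level(d)
        b, _ = generate_region_level(d)
        for ra, rb in zip(a, b):
            assert ra.data.tobytes() == rb.data.tobytes()
            assert ra.fd.tobytes() == rb.fd.tobytes()

    def test_window_too_short_rejected(self):
        d = PlantedDesign(n_nodes=4, tasks=(TaskBlock("t", 25.0, 3),),
                          groups=(), noise_sd=0.1)
        with pytest.raises(ValueError, match="short"):
            generate_region_level(d)

    def test_samples_per_window_match_study_trs(self):
        d = design((), n_nodes=4, n_windows=4)
        runs, _ = generate_region_level(d)
        assert runs[0].n_samples == 4 * 30   # TR 2.0 -> 30 per 60 s window
        assert runs[1].n_samples == 4 * 24   # TR 2.5 -> 24


class TestFdTrace:
    def test_zero_mean_gives_zero_trace(self):
        np.testing.assert_array_equal(generate_fd_trace(50, 0.0, 1), 0.0)

    def test_mean_within_five_percent(self):
        trace = generate_fd_trace(100, 0.3, 1)
        assert (trace >= 0).all()
        assert 0.285 <= trace.mean() <= 0.315

    def test_low_motion_trace_survives_exclusion_rule(self):
        trace = generate_fd_trace(100, 0.2, 2)
        assert trace.mean() < 0.25

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_fd_trace(0, 0.1, 1)
        with pytest.raises(ValueError):
            generate_fd_trace(10, -0.5, 1)


class TestRegionSizeTable:
    def test_deterministic(self):
        a = generate_region_size_table(4, 6, seed=3)
        b = generate_region_size_table(4, 6, seed=3)
        assert a.equals(b)

    def test_outlier_cv_flagged_by_rule(self):
        from hypercoev.atlas import coefficient_of_variation

        df = generate_region_size_table(12, 9, outlier_spec={2: {"cv": 0.5}},
                                        seed=1)
        fine = df[df["scale"] == "fine"]
        cv = fine.groupby("region")["voxels"].apply(
            lambda s: coefficient_of_variation(s.to_numpy())
        )
        assert cv["fine_002"] > 0.30
        assert (cv.drop("fine_002") < 0.30).all()

    def test_parent_pointers_form_two_scales(self):
        df = generate_region_size_table(3, 7, seed=0)
        fine = df[df["scale"] == "fine"]
        coarse = df[df["scale"] == "coarse"]
        assert fine["parent"].notna().all()
        assert coarse["parent"].isna().all()
        assert set(fine["parent"]) <= set(coarse["region"])

    def test_zero_subject_outlier(self):
        df = generate_region_size_table(3, 4, outlier_spec={1: {"zero_subject": 2}},
                                        seed=0)
        row = df[(df["region"] == "fine_001") & (df["subject"] == "sub02")]
        assert (row["voxels"] == 0).all()
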