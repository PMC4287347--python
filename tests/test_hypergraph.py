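import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_bh, brute_components, brute_pearson
from hypercoev.dynamics import EdgeTimeSeriesMatrix, edge_pairs
from hypercoev.hypergraph import (
    BinarizedEdgeMatrix,
    EdgeEdgeCorrelation,
    edge_edge_correlation,
    extract_hyperedges,
    fdr_binarize,
    hyperedge_node_degree,
    hyperedge_size,
    size_distribution,
)


def ets_from_weights(weights, n_nodes=None, tasks=None):
    weights = np.asarray(weights, dtype=float)
    e, w = weights.shape
    if n_nodes is None:
        n_nodes = 3
        while n_nodes * (n_nodes - 1) // 2 < e:
            n_nodes += 1
    pairs = edge_pairs(n_nodes)[:e]
    tasks = np.asarray(["t"] * w if tasks is None else tasks)
    return EdgeTimeSeriesMatrix(weights=weights, pairs=pairs,
                                window_tasks=tasks, n_nodes=n_nodes)


class TestEdgeEdgeCorrelation:
    def test_identical_and_affine_rows(self):
        ets = ets_from_weights(np.asarray([[0.1, 0.2, 0.3, 0.4],
                                           [0.1, 0.2, 0.3, 0.4],
                                           [0.2, 0.4, 0.6, 0.8]]))
        c = edge_edge_correlation(ets)
        assert c.r[0, 1] == pytest.approx(1.0)
        assert c.p[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert c.r[0, 2] == pytest.approx(1.0)  # affine relation

    def test_hand_example_against_brute_force(self):
        a = [1, 0, 2, 1, 3]
        b = [0, 1, 1, 2, 2]
        c = edge_edge_correlation(ets_from_weights(np.asarray([a, b]) / 10.0))
        expected_r = brute_pearson(a, b)
        assert c.r[0, 1] == pytest.approx(expected_r, abs=1e-12)
        t = expected_r * np.sqrt(3 / (1 - expected_r**2))
        expected_p = 2 * stats.t.sf(abs(t), df=3)
        assert c.p[0, 1] == pytest.approx(expected_p, rel=1e-10)

    def test_matches_scipy_pearsonr_on_random_instances(self, rng):
        # the p-value oracle: scipy's pearsonr on many small instances
        for _ in range(400):
            w = int(rng.integers(5, 12))
            x = rng.standard_normal((2, w))
            c = edge_edge_correlation(ets_from_weights(x))
            r_ref, p_ref = stats.pearsonr(x[0], x[1])
            assert c.r[0, 1] == pytest.approx(r_ref, abs=1e-12)
            assert c.p[0, 1] == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_constant_row_gets_zero_r_unit_p(self, rng):
        x = rng.standard_normal((3, 8))
        x[1] = 0.5
        c = edge_edge_correlation(ets_from_weights(x))
        assert c.r[1, 0] == 0.0 and c.p[1, 0] == 1.0
        assert c.r[1, 1] == 1.0  # diagonal convention

    def test_block_size_does_not_change_result(self, rng):
        x = rng.standard_normal((20, 10))
        full = edge_edge_correlation(ets_from_weights(x), block_size=4096)
        blocked = edge_edge_correlation(ets_from_weights(x), block_size=3)
        np.testing.assert_allclose(full.r, blocked.r, atol=1e-14)

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="4 windows"):
            edge_edge_correlation(ets_from_weights(rng.standard_normal((3, 3))))


class TestFdrBinarize:
    def build(self, pvals):
        pvals = np.asarray(pvals)
        e = pvals.shape[0]
        return EdgeEdgeCorrelation(
            r=np.ones((e, e)) * 0.5, p=pvals, n_windows=10,
            pairs=edge_pairs(e + 1)[:e], n_nodes=e + 1,
        )

    def sym_p(self, upper):
        m = len(upper)
        e = int((1 + np.sqrt(1 + 8 * m)) / 2)
        p = np.zeros((e, e))
        p[np.triu_indices(e, 1)] = upper
        return p + p.T

    def test_all_unit_p_gives_empty(self):
        b = fdr_binarize(self.build(self.sym_p([1.0, 1.0, 1.0])))
        assert b.b.sum() == 0

    def test_bh_hand_cases(self):
        # {0.001, 0.2, 0.9}: only 0.001 survives the 0.0167/0.0333/0.05 stairs
        b = fdr_binarize(self.build(self.sym_p([0.001, 0.2, 0.9])), q=0.05)
        assert b.b[np.triu_indices(3, 1)].tolist() == [1, 0, 0]
        # {0.01, 0.02, 0.03}: all survive because 0.03 <= 0.05 * 3/3
        b = fdr_binarize(self.build(self.sym_p([0.01, 0.02, 0.03])), q=0.05)
        assert b.b[np.triu_indices(3, 1)].tolist() == [1, 1, 1]

    def test_agrees_with_sort_and_scan_oracle(self, rng):
        for _ in range(1000):
            m = int(rng.integers(3, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            e = int((1 + np.sqrt(1 + 8 * m)) / 2)
            if e * (e - 1) // 2 != m:
                continue
            b = fdr_binarize(self.build(self.sym_p(p)), q=q)
            got = b.b[np.triu_indices(e, 1)].astype(bool)
            np.testing.assert_array_equal(got, brute_bh(p, q))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=3),
           st.floats(min_value=0.01, max_value=0.3))
    def test_bh_property_matches_oracle(self, pvals, q):
        b = fdr_binarize(self.build(self.sym_p(pvals)), q=q)
        got = b.b[np.triu_indices(3, 1)].astype(bool)
        np.testing.assert_array_equal(got, brute_bh(pvals, q))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=45)
        c = self.build(self.sym_p(p))
        b_strict = fdr_binarize(c, q=0.01).b
        b_loose = fdr_binarize(c, q=0.10).b
        assert ((b_strict == 1) <= (b_loose == 1)).all()

    @pytest.mark.parametrize("q", [0.0, 1.0, 1.5, -0.1])
    def test_invalid_q_rejected(self, q):
        with pytest.raises(ValueError, match="outside"):
            fdr_binarize(self.build(self.sym_p([0.5, 0.5, 0.5])), q=q)


class TestExtractHyperedges:
    def binarized(self, links, e, n_nodes=None):
        b = np.zeros((e, e), dtype=np.uint8)
        for i, j in links:
            b[i, j] = b[j, i] = 1
        n_nodes = n_nodes or (e + 1)
        return BinarizedEdgeMatrix(b=b, q=0.05, alternative="two-sided",
                                   pairs=edge_pairs(n_nodes)[:e], n_nodes=n_nodes)

    def test_chain_forms_single_hyperedge_with_singleton(self):
        # three cross-linked edges on six nodes plus one unlinked edge
        pairs = np.asarray([[0, 1], [2, 3], [4, 5], [6, 7]])
        bm = self.binarized([(0, 1), (1, 2)], e=4, n_nodes=8)
        bm.pairs = pairs
        hg = extract_hyperedges(bm)
        assert hg.hyperedges == (frozenset({0, 1, 2}),)
        assert hyperedge_size(hg.hyperedges[0]) == 3
        assert hg.nodes_of(hg.hyperedges[0]) == frozenset(range(6))
        assert hg.singletons == frozenset({3})

    def test_empty_matrix_all_singletons(self):
        hg = extract_hyperedges(self.binarized([], e=5))
        assert hg.hyperedges == ()
        assert hg.singletons == frozenset(range(5))

    def test_two_disjoint_pairs(self):
        hg = extract_hyperedges(self.binarized([(0, 1), (2, 3)], e=5))
        assert sorted(sorted(h) for h in hg.hyperedges) == [[0, 1], [2, 3]]
        assert hg.singletons == frozenset({4})

    def test_partition_property_random(self, rng):
        for _ in range(50):
            e = 30
            b = (rng.uniform(size=(e, e)) < 0.05).astype(np.uint8)
            b = np.triu(b, 1)
            b = b + b.T
            hg = extract_hyperedges(
                BinarizedEdgeMatrix(b=b, q=0.05, alternative="two-sided",
                                    pairs=edge_pairs(9)[:e], n_nodes=9)
            )
            seen = set(hg.singletons)
            total = len(hg.singletons)
            for h in hg.hyperedges:
                assert len(h) >= 2
                assert not (h & seen)
                seen |= h
                total += len(h)
            assert total == e and seen == set(range(e))

    def test_agrees_with_transitive_closure_oracle(self, rng):
        for _ in range(300):
            e = 50
            b = (rng.uniform(size=(e, e)) < rng.uniform(0.005, 0.08)).astype(np.uint8)
            b = np.triu(b, 1)
            b = b + b.T
            bm = BinarizedEdgeMatrix(b=b, q=0.05, alternative="two-sided",
                                     pairs=edge_pairs(11)[:e], n_nodes=11)
            hg = extract_hyperedges(bm)
            labels = brute_components(b)
            mine = hg.membership()
            # same partition: each oracle component is one hyperedge/singleton
            for lab in np.unique(labels):
                members = np.flatnonzero(labels == lab)
                assert len(set(mine[members].tolist())) == 1
                if members.size == 1:
                    assert mine[members[0]] == -1


class TestDiagnostics:
    def hg(self, hyperedges, e=6, n_nodes=6):
        from hypercoev.hypergraph import Hypergraph

        members = frozenset().union(*hyperedges) if hyperedges else frozenset()
        return Hypergraph(
            hyperedges=tuple(frozenset(h) for h in hyperedges),
            singletons=frozenset(range(e)) - members,
            pairs=edge_pairs(n_nodes)[:e],
            n_nodes=n_nodes,
        )

    def test_node_degree_single_hypergraph(self):
        # edges (0,1) and (1,2) in one hyperedge: nodes 0, 1, 2 get degree 1
        hg = self.hg([{0, 1}], e=3, n_nodes=3)  # rows 0=(0,1), 1=(0,2)
        deg = hyperedge_node_degree([hg], 3)
        assert deg.tolist() == [1, 1, 1]

    def test_node_degree_additivity_over_subjects(self, rng):
        hgs = [self.hg([{0, 1}, {3, 4}]), self.hg([{0, 2}])]
        combined = hyperedge_node_degree(hgs, 6)
        summed = sum(hyperedge_node_degree([h], 6) for h in hgs)
        np.testing.assert_array_equal(combined, summed)

    def test_size_distribution_cumulative(self):
        hgs = [self.hg([{0, 1}, {2, 3, 4, 5}], e=6),
               self.hg([{0, 1}], e=6)]
        # pooled sizes {2, 4, 2} -> >=2: 3, >=4: 1
        df = size_distribution(hgs)
        assert df.set_index("size")["count_at_least"].to_dict() == {2: 3, 4: 1}
        assert (np.diff(df["count_at_least"]) <= 0).all()

    def test_size_distribution_empty(self):
        assert size_distribution([]).empty

    def test_singleton_size_one(self):
        assert hyperedge_size({7}) == 1
        with pytest.raises(ValueError):
            hyperedge_size(set())
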