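import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hrrgcn as h
from hrrgcn.hrrnet import WEIGHT_TABLE, cutoff_weight


def _matrix(values, ids=None, arrays=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return h.ExpressionMatrix(
        ids or [f"PS{i:03d}" for i in range(n)],
        arrays or [f"A{j:02d}" for j in range(m)],
        values,
    )


class TestPearson:
    def test_identical_and_opposite_rows(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        m = _matrix([x, x, -x])
        r = h.pearson_correlation(m).r
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1/3, sd_x = sd_y = sqrt(2/3)  =>  r = 0.5
        m = _matrix([[1, 2, 3], [1, 3, 2], [2, 2, 3]])
        r = h.pearson_correlation(m).r
        assert r[0, 1] == pytest.approx(0.5)

    def test_symmetry_exact(self, small_matrix):
        r = h.pearson_correlation(small_matrix).r
        assert (r == r.T).all()

    def test_zero_variance_row_rejected(self):
        m = _matrix([[1, 1, 1, 1], [1, 2, 3, 4]], ids=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            h.pearson_correlation(m)


class TestRanks:
    def test_ordering_by_decreasing_r(self):
        ids = ["A", "B", "C", "D"]
        r = np.array(
            [
                [1.0, 0.9, 0.5, 0.7],
                [0.9, 1.0, 0.1, 0.2],
                [0.5, 0.1, 1.0, 0.3],
                [0.7, 0.2, 0.3, 1.0],
            ]
        )
        rk = h.correlation_to_ranks(h.CorrelationMatrix(ids, r)).rank
        assert rk[0, 1] == 1 and rk[0, 3] == 2 and rk[0, 2] == 3

    def test_ties_broken_by_ascending_identifier(self):
        ids = ["A", "C", "B"]  # deliberately not in lexicographic order
        r = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.2], [0.7, 0.2, 1.0]])
        rk = h.correlation_to_ranks(h.CorrelationMatrix(ids, r)).rank
        # B < C lexicographically, so B gets the smaller rank
        assert rk[0, 2] == 1 and rk[0, 1] == 2

    def test_rows_are_permutations(self, small_matrix):
        rk = h.correlation_to_ranks(h.pearson_correlation(small_matrix)).rank
        n = small_matrix.n_probesets
        for i in range(n):
            row = np.delete(rk[i], i)
            assert sorted(row) == list(range(1, n))
            assert rk[i, i] == 0


class TestHRR:
    def test_formula_on_directional_ranks(self):
        ids = list("ABCDE")
        rank = np.array(
            [
                [0, 1, 2, 3, 4],
                [4, 0, 1, 2, 3],
                [1, 2, 0, 3, 4],
                [1, 2, 3, 0, 4],
                [1, 2, 3, 4, 0],
            ]
        )
        net = h.hrr_matrix(h.RankMatrix(ids, rank))
        assert net.hrr[0, 1] == 4  # max(rank(A,B)=1, rank(B,A)=4)
        assert net.hrr[0, 2] == 2  # max(2, 1)
        assert (net.hrr == net.hrr.T).all()
        assert (net.hrr >= np.maximum(rank, rank.T)).all()

    def test_mutual_best_partners_give_hrr_one(self):
        # two near-duplicate genes are each other's rank-1 partner
        rng = np.random.default_rng(12)
        base = rng.normal(size=10)
        values = rng.normal(size=(20, 10))
        values[3] = base + rng.normal(0, 0.01, 10)
        values[7] = base + rng.normal(0, 0.01, 10)
        net = h.hrr_network(_matrix(values))
        assert net.hrr[3, 7] == 1

    def test_mutual_best_partners_fixed_point(self, small_matrix):
        net = h.hrr_network(small_matrix)
        assert net.hrr.min() >= 0
        off = net.hrr[~np.eye(net.n, dtype=bool)]
        assert off.min() >= 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n, m = 400, 12
        em = _matrix(rng.normal(size=(n, m)))
        net = h.hrr_network(em)
        # independent oracle: per-gene sorted correlation lists, double loop
        r = np.corrcoef(em.values)
        ranks = {}
        for i in range(n):
            order = sorted(
                (j for j in range(n) if j != i),
                key=lambda j: (-r[i, j], em.probeset_ids[j]),
            )
            ranks[i] = {j: pos + 1 for pos, j in enumerate(order)}
        for i in range(0, n, 7):  # sampled rows, full columns
            for j in range(n):
                if i == j:
                    continue
                assert net.hrr[i, j] == max(ranks[i][j], ranks[j][i])

    @pytest.mark.parametrize("block", [1, 3, 17, None])
    def test_chunked_equals_dense(self, block):
        rng = np.random.default_rng(5)
        em = _matrix(rng.normal(size=(60, 8)))
        dense = h.hrr_matrix(
            h.correlation_to_ranks(h.pearson_correlation(em))
        )
        chunked = h.hrr_network(em, block_size=block)
        np.testing.assert_array_equal(dense.hrr, chunked.hrr)
        np.testing.assert_array_equal(dense.rank, chunked.rank)

    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
        gene=st.integers(min_value=0, max_value=29),
    )
    def test_per_gene_affine_invariance(self, a, b, gene):
        """x -> a*x + b (a > 0) on any gene leaves r, ranks and HRR unchanged."""
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 10))
        em = _matrix(values)
        transformed = values.copy()
        transformed[gene] = a * transformed[gene] + b
        em2 = _matrix(transformed)
        n1, n2 = h.hrr_network(em), h.hrr_network(em2)
        np.testing.assert_array_equal(n1.hrr, n2.hrr)
        np.testing.assert_array_equal(n1.rank, n2.rank)


class TestGuideClusters:
    def test_cluster_width_caps_at_n_minus_one(self):
        rng = np.random.default_rng(3)
        em = _matrix(rng.normal(size=(50, 8)))
        clusters = h.guide_clusters(h.hrr_network(em), k=100)
        assert len(clusters) == 50
        assert all(len(c) == 49 for c in clusters)

    def test_members_sorted_by_ascending_hrr_and_guide_excluded(self):
        rng = np.random.default_rng(4)
        em = _matrix(rng.normal(size=(40, 10)))
        for c in h.guide_clusters(h.hrr_network(em), k=10):
            assert list(c.hrr_values) == sorted(c.hrr_values)
            assert c.guide not in c.member_ids
            assert len(c) == 10

    def test_membership_may_be_asymmetric(self):
        rng = np.random.default_rng(6)
        em = _matrix(rng.normal(size=(60, 8)))
        clusters = {c.guide: set(c.member_ids) for c in
                    h.guide_clusters(h.hrr_network(em), k=5)}
        asym = [
            (g, m) for g, members in clusters.items()
            for m in members if g not in clusters[m]
        ]
        assert asym, "expected at least one one-sided top-k membership"

    def test_invalid_k_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            h.guide_clusters(h.hrr_network(small_matrix), k=0)


class TestThresholdNetwork:
    def test_printed_weight_table_verbatim(self):
        for cutoff, weight in WEIGHT_TABLE.items():
            assert cutoff_weight(cutoff) == weight

    def test_closed_form_for_unlisted_cutoffs(self):
        assert cutoff_weight(15) == pytest.approx(1.0 / 10)
        assert cutoff_weight(25) == pytest.approx(1.0 / 20)

    def test_uniform_weight_on_edges(self):
        rng = np.random.default_rng(8)
        em = _matrix(rng.normal(size=(80, 10)))
        el = h.threshold_network(h.hrr_network(em), 30)
        assert set(el.edges["weight"]) == {0.04}
        assert (el.edges["hrr"] <= 30).all()

    def test_cutoff_two_on_three_genes_by_enumeration(self):
        em = _matrix([[1, 2, 3, 5], [1.1, 2, 3.2, 4.9], [3, 1, 4, 1.5]])
        net = h.hrr_network(em)
        el = h.threshold_network(net, 2)
        expected = {
            (i, j)
            for i in range(3)
            for j in range(i + 1, 3)
            if max(net.rank[i, j], net.rank[j, i]) <= 2
        }
        got = {
            (em.probeset_ids.index(a), em.probeset_ids.index(b))
            for a, b in zip(el.edges["probeset_a"], el.edges["probeset_b"])
        }
        assert got == expected

    def test_cutoff_bounds(self, small_matrix):
        net = h.hrr_network(small_matrix)
        with pytest.raises(ValueError):
            h.threshold_network(net, 1)
        with pytest.raises(ValueError):
            h.threshold_network(net, small_matrix.n_probesets)

    def test_pairs_lexicographic_and_isolated_reported(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(30, 10))
        values[0] = rng.normal(size=10) * 0.001 + values[1] * 0  # unrelated gene
        em = _matrix(values)
        el = h.threshold_network(h.hrr_network(em), 3)
        assert (el.edges["probeset_a"] < el.edges["probeset_b"]).all()
        assert set(el.isolated) | set(el.edges["probeset_a"]) | set(
            el.edges["probeset_b"]
        ) == set(em.probeset_ids)

    def test_graphml_and_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        em = _matrix(rng.normal(size=(20, 8)))
        el = h.threshold_network(h.hrr_network(em), 10)
        p = tmp_path / "edges.tsv"
        from hrrgcn.hrrnet import load_edges, write_edges, write_graphml

        write_edges(el, p)
        back = load_edges(p)
        pd.testing.assert_frame_equal(back, el.edges)
        write_graphml(el, tmp_path / "net.graphml")
        import networkx as nx

        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == len(el.edges)
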