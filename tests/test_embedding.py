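import numpy as np
import pandas as pd
import pytest

from matte import ExpressionMatrix
from matte.embedding import (
    EmbeddingMatrix,
    build_pcc_graph,
    compute_rdc,
    compute_rde,
    mix_embeddings,
    reduce_dim,
    spectral_embed,
)
from matte.errors import AlignmentError, DegenerateGraphError, DimensionalityError


def expr_from(values, prefix="S"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i}" for i in range(values.shape[0])],
            columns=[f"{prefix}{i}" for i in range(values.shape[1])],
        ),
        unit="arbitrary",
    )


def brute_force_rde(means):
    n = len(means)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            out[a, b] = abs(means[a] - means[b])
    return out


class TestRde:
    def test_two_instance_means(self):
        # per-instance means 1 (gene in p1) and 3 (same gene in p2)
        e1 = expr_from([[1.0, 1.0]], "A")
        e2 = expr_from([[3.0, 3.0]], "B")
        emb = compute_rde(e1, e2)
        np.testing.assert_allclose(emb.coords, [[0, 2], [2, 0]])
        assert emb.instances == [("G0", "p1"), ("G0", "p2")]

    def test_matches_independent_double_loop(self, rng):
        e1 = expr_from(rng.normal(size=(6, 9)), "A")
        e2 = expr_from(rng.normal(size=(6, 9)), "B")
        emb = compute_rde(e1, e2)
        means = np.concatenate(
            [e1.values.mean(axis=1).to_numpy(), e2.values.mean(axis=1).to_numpy()]
        )
        np.testing.assert_allclose(emb.coords, brute_force_rde(means), atol=1e-12)

    def test_global_shift_invariance(self, rng):
        e1 = expr_from(rng.normal(size=(5, 7)), "A")
        e2 = expr_from(rng.normal(size=(5, 7)), "B")
        base = compute_rde(e1, e2).coords
        shifted = compute_rde(
            expr_from(e1.values.to_numpy() + 10.0, "A"),
            expr_from(e2.values.to_numpy() + 10.0, "B"),
        ).coords
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_metric_properties(self, rng):
        e1 = expr_from(rng.normal(size=(8, 5)), "A")
        e2 = expr_from(rng.normal(size=(8, 5)), "B")
        r = compute_rde(e1, e2).coords
        np.testing.assert_allclose(r, r.T)
        assert (np.diag(r) == 0).all() and (r >= 0).all()
        n = r.shape[0]
        idx = rng.integers(0, n, size=(50, 3))
        for a, b, c in idx:
            assert r[a, c] <= r[a, b] + r[b, c] + 1e-12

    def test_gene_list_mismatch_rejected(self, rng):
        e1 = expr_from(rng.normal(size=(3, 4)), "A")
        e2 = expr_from(rng.normal(size=(3, 4)), "B")
        e2.values.index = ["G0", "G1", "X"]
        with pytest.raises(AlignmentError):
            compute_rde(e1, e2)


class TestPccGraph:
    def test_perfect_and_anti_correlation(self):
        g = build_pcc_graph(expr_from([[1, 2, 3], [2, 4, 6], [3, 2, 1]]))
        assert g.adjacency[0, 1] == pytest.approx(1.0)
        assert g.adjacency[0, 2] == pytest.approx(1.0)  # |PCC| folds sign
        assert (np.diag(g.adjacency) == 0).all()

    def test_matches_pairwise_loop(self, rng):
        x = rng.normal(size=(5, 50))
        g = build_pcc_graph(expr_from(x))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = xi @ xj / np.sqrt((xi @ xi) * (xj @ xj))
                assert g.adjacency[i, j] == pytest.approx(abs(r), abs=1e-10)
        np.testing.assert_allclose(g.degree, g.adjacency.sum(axis=1))

    def test_constant_gene_gets_zero_edges_with_warning(self, rng):
        x = rng.normal(size=(3, 10))
        x[1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            g = build_pcc_graph(expr_from(x))
        assert g.adjacency[1].sum() == 0 or g.degree[1] == 0


class TestSpectralEmbed:
    @staticmethod
    def laplacian(graph):
        dinv = 1 / np.sqrt(graph.degree)
        return np.eye(len(graph.nodes)) - dinv[:, None] * graph.adjacency * dinv

    def test_complete_graph_eigenvalues(self):
        # perfectly correlated triple -> complete unit-weight graph on 3 nodes
        base = np.array([1.0, 2.0, 5.0, 3.0])
        g = build_pcc_graph(expr_from([base, 2 * base, base + 1]))
        vals = np.linalg.eigvalsh(self.laplacian(g))
        np.testing.assert_allclose(sorted(vals), [0, 1.5, 1.5], atol=1e-8)

    def test_eigenvalue_bounds_and_components(self, rng):
        # two perfectly-correlated blocks that are independent of each other
        t = rng.normal(size=30)
        u = rng.normal(size=30)
        u -= (u @ t) / (t @ t) * t  # orthogonalize -> exactly zero correlation
        t, u = t - t.mean(), u - u.mean()
        u -= (u @ t) / (t @ t) * t
        x = np.vstack([t, 2 * t, u, 3 * u])
        g = build_pcc_graph(expr_from(x))
        vals = np.linalg.eigvalsh(self.laplacian(g))
        assert vals.min() > -1e-9 and vals.max() < 2 + 1e-9
        # two connected components -> eigenvalue 0 with multiplicity 2
        assert (np.abs(vals) < 1e-8).sum() == 2

    def test_isolated_node_is_an_error(self, rng):
        x = rng.normal(size=(3, 10))
        x[2] = 7.0  # constant -> degree 0
        with pytest.warns(UserWarning):
            g = build_pcc_graph(expr_from(x))
        with pytest.raises(DegenerateGraphError, match="G2"):
            spectral_embed(g, 2)

    def test_sign_convention_and_shape(self, rng):
        g = build_pcc_graph(expr_from(rng.normal(size=(10, 40))))
        coords = spectral_embed(g, 4)
        assert coords.shape == (10, 4)
        for j in range(4):
            assert coords[np.argmax(np.abs(coords[:, j])), j] > 0
        with pytest.raises(DimensionalityError):
            spectral_embed(g, 10)


class TestRdc:
    def test_identical_phenotypes_collapse(self, rng):
        x = rng.normal(size=(8, 30))
        emb = compute_rdc(expr_from(x, "A"), expr_from(x, "B"), d=3)
        ng = 8
        np.testing.assert_allclose(emb.coords[:ng], emb.coords[ng:], atol=1e-9)

    def test_sample_order_invariance(self, rng):
        x1, x2 = rng.normal(size=(6, 25)), rng.normal(size=(6, 25))
        base = compute_rdc(expr_from(x1, "A"), expr_from(x2, "B"), d=3).coords
        perm = rng.permutation(25)
        shuffled = compute_rdc(
            expr_from(x1[:, perm], "A"), expr_from(x2, "B"), d=3
        ).coords
        np.testing.assert_allclose(shuffled, base, atol=1e-8)

    def test_swapped_block_genes_move_farther(self, rng):
        # two co-expression blocks; genes 0-4 swap block membership in p2
        ns, ng = 200, 20
        f1, f2 = rng.normal(size=ns), rng.normal(size=ns)
        noise = 0.3
        block = np.array([0] * 10 + [1] * 10)
        block_swapped = block.copy()
        block_swapped[:5] = 1  # genes 0-4 move from block 0 to block 1
        def draw(memb):
            return np.vstack(
                [
                    (f1 if m == 0 else f2) + noise * rng.normal(size=ns)
                    for m in memb
                ]
            )
        emb = compute_rdc(
            expr_from(draw(block), "A"), expr_from(draw(block_swapped), "B"), d=2
        )
        d_inst = np.linalg.norm(emb.coords[:ng] - emb.coords[ng:], axis=1)
        assert d_inst[:5].min() > d_inst[5:].max()


class TestReduceDim:
    def test_rank_one_keeps_single_component(self, rng):
        row = rng.normal(size=6)
        coords = np.outer(rng.normal(size=10), row)
        emb = EmbeddingMatrix([(f"G{i}", "p1") for i in range(10)], coords, "RDE")
        out = reduce_dim(emb, 0.99)
        assert out.coords.shape[1] == 1

    def test_full_rank_projection_is_isometry(self, rng):
        coords = rng.normal(size=(12, 5))
        emb = EmbeddingMatrix([(f"G{i}", "p1") for i in range(12)], coords, "RDE")
        out = reduce_dim(emb, 5)
        def pdist(m):
            return np.linalg.norm(m[:, None] - m[None, :], axis=-1)
        np.testing.assert_allclose(pdist(out.coords), pdist(coords), atol=1e-8)

    def test_identical_rows_stay_identical(self, rng):
        coords = rng.normal(size=(6, 4))
        coords[3] = coords[0]
        emb = EmbeddingMatrix([(f"G{i}", "p1") for i in range(6)], coords, "RDE")
        out = reduce_dim(emb, 2)
        np.testing.assert_allclose(out.coords[3], out.coords[0], atol=1e-10)

    def test_overlarge_request_clips_to_rank(self, rng):
        row = rng.normal(size=6)
        coords = np.outer(rng.normal(size=8), row)
        emb = EmbeddingMatrix([(f"G{i}", "p1") for i in range(8)], coords, "RDE")
        with pytest.warns(UserWarning, match="rank"):
            out = reduce_dim(emb, 5)
        assert out.coords.shape[1] == 1


class TestMix:
    def test_blocks_standardized_to_unit_variance(self, rng):
        a = EmbeddingMatrix([("G0", "p1"), ("G0", "p2")], rng.normal(size=(2, 3)) * 100, "RDE")
        b = EmbeddingMatrix([("G0", "p1"), ("G0", "p2")], rng.normal(size=(2, 4)), "RDC")
        mixed = mix_embeddings(a, b)
        assert mixed.coords.shape == (2, 7)
        x = mixed.coords - mixed.coords.mean(axis=0)
        np.testing.assert_allclose(x[:, :3].var(axis=0).sum(), 1.0)
        np.testing.assert_allclose(x[:, 3:].var(axis=0).sum(), 1.0)
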