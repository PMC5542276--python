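"""Fixed-point ranking checked against a direct linear-system solution."""

import numpy as np
import pytest
from scipy import stats

from dirgenerank import (
    dirgenerank,
    ks_rank_enrichment,
    select_signature,
    signature_size,
)
from dirgenerank.network import DependencyEdge, DependencyNetwork
from dirgenerank.survival import GeneStability


def random_digraph(rng, n, p_edge=0.15):
    """Random edge list (modulator, dependent) with no self-loops."""
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p_edge:
                edges.append((f"g{i:02d}", f"g{j:02d}"))
    return edges


def to_network(edges):
    return DependencyNetwork(
        [DependencyEdge(s, t, 0.1, 0.01) for s, t in edges], alpha=0.05, n_perm=0
    )


def linear_solve_oracle(edges, imp_raw, d, degree_mode="row"):
    """Solve r = (1-d) imp + d M r directly (dense linear algebra)."""
    genes = sorted({g for e in edges for g in e})
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    w = np.zeros((n, n))
    for s, t in edges:  # edge s -> t means "t depends on s": w[t, s] = 1
        w[idx[t], idx[s]] = 1.0
    deg = w.sum(axis=1) if degree_mode == "row" else w.sum(axis=0)
    inv = np.divide(1.0, deg, out=np.zeros(n), where=deg > 0)
    m = w.T @ np.diag(inv)
    imp = np.array([imp_raw.get(g, 0.0) for g in genes])
    imp = imp / imp.sum() if imp.sum() > 0 else np.full(n, 1.0 / n)
    r = np.linalg.solve(np.eye(n) - d * m, (1 - d) * imp)
    return genes, r


class TestDirgenerank:
    @pytest.mark.parametrize("n,seed", [(5, 0), (10, 1), (20, 2), (35, 3), (50, 4)])
    @pytest.mark.parametrize("degree_mode", ["row", "literal"])
    def test_matches_linear_solve(self, n, seed, degree_mode):
        rng = np.random.default_rng(seed)
        edges = random_digraph(rng, n)
        imp_raw = {f"g{i:02d}": float(rng.integers(0, 400)) for i in range(n)}
        res = dirgenerank(to_network(edges), imp_raw, d=0.7, eps=1e-12,
                          degree_mode=degree_mode)
        genes, r_exact = linear_solve_oracle(edges, imp_raw, 0.7, degree_mode)
        assert res.gene_ids == genes
        np.testing.assert_allclose(res.r, r_exact, atol=1e-8)

    def test_five_node_planted_graph(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "a"), ("e", "d")]
        imp = {g: v for g, v in zip("abcde", [5.0, 1.0, 1.0, 2.0, 1.0])}
        res = dirgenerank(to_network(edges), imp, d=0.7, eps=1e-12)
        genes, r_exact = linear_solve_oracle(edges, imp, 0.7)
        np.testing.assert_allclose(res.r, r_exact, atol=1e-8)

    def test_d_zero_returns_normalized_importance(self):
        edges = [("a", "b"), ("b", "c")]
        res = dirgenerank(to_network(edges), {"a": 2.0, "b": 1.0, "c": 1.0}, d=0.0)
        np.testing.assert_allclose(res.r, [0.5, 0.25, 0.25])
        assert res.n_iter == 1

    def test_mutually_dependent_equal_importance_symmetric(self):
        edges = [("a", "b"), ("b", "a")]
        res = dirgenerank(to_network(edges), {"a": 3.0, "b": 3.0}, d=0.7)
        assert res.r[0] == pytest.approx(res.r[1], rel=1e-10)

    def test_importance_rescaling_preserves_order_and_values(self):
        rng = np.random.default_rng(6)
        edges = random_digraph(rng, 15)
        imp = {f"g{i:02d}": float(rng.integers(1, 100)) for i in range(15)}
        scaled = {g: 17.0 * v for g, v in imp.items()}
        r1 = dirgenerank(to_network(edges), imp, d=0.7, eps=1e-12)
        r2 = dirgenerank(to_network(edges), scaled, d=0.7, eps=1e-12)
        np.testing.assert_allclose(r1.r, r2.r, rtol=1e-9)

    def test_mass_conservation_in_row_mode(self):
        # one distribution step conserves the total mass of distributing genes
        rng = np.random.default_rng(8)
        edges = random_digraph(rng, 12)
        genes = sorted({g for e in edges for g in e})
        idx = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        w = np.zeros((n, n))
        for s, t in edges:
            w[idx[t], idx[s]] = 1.0
        deg = w.sum(axis=1)
        r = rng.random(n)
        inv = np.divide(1.0, deg, out=np.zeros(n), where=deg > 0)
        distributed = (w.T @ (r * inv)).sum()
        assert distributed == pytest.approx(r[deg > 0].sum(), rel=1e-12)

    def test_invalid_damping_rejected(self):
        edges = [("a", "b")]
        for d in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                dirgenerank(to_network(edges), {"a": 1.0, "b": 1.0}, d=d)


class TestSelectSignature:
    def test_one_percent_of_3995_is_40(self):
        assert signature_size(3995, 0.01) == 40

    def test_minimum_one_gene(self):
        assert signature_size(100, 0.01) == 1

    def test_selection_and_signs(self):
        edges = [("a", "b"), ("c", "b"), ("c", "a"), ("d", "a")]
        stab = [
            GeneStability("a", 10, 0.5, 10),
            GeneStability("b", 8, -0.2, 10),
            GeneStability("c", 2, 0.1, 10),
            GeneStability("d", 0, -0.9, 10),
        ]
        res = dirgenerank(to_network(edges), stab, d=0.5)
        sig = select_signature(res, stab, fraction=0.5)
        assert len(sig.genes) == 2
        assert set(sig.positive_genes()) | set(sig.negative_genes()) == set(sig.genes)

    def test_boundary_tie_broken_by_gene_id(self):
        # no edges between b and c: equal importance, deterministic order
        edges = [("a", "b"), ("a", "c")]
        imp = {"a": 1.0, "b": 1.0, "c": 1.0}
        res = dirgenerank(to_network(edges), imp, d=0.7)
        assert res.r[1] == pytest.approx(res.r[2])
        sig = select_signature(res, {"a": 0.0, "b": 0.0, "c": 0.0}, fraction=2 / 3)
        assert sig.genes[-1] == "b"  # tie at the cut: ascending ID wins


class TestKsRankEnrichment:
    def test_top_signature_extreme_p(self):
        ranked = [f"g{i}" for i in range(1000)]
        p = ks_rank_enrichment(ranked[:20], ranked)
        assert p < 1e-6

    def test_full_list_is_exactly_uniform(self):
        ranked = [f"g{i}" for i in range(50)]
        assert ks_rank_enrichment(ranked, ranked) == pytest.approx(1.0)

    def test_calibration_under_random_signatures(self):
        rng = np.random.default_rng(13)
        ranked = [f"g{i}" for i in range(500)]
        hits = 0
        reps = 1000
        for _ in range(reps):
            sig = [ranked[i] for i in rng.choice(500, 20, replace=False)]
            hits += ks_rank_enrichment(sig, ranked) <= 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_disjoint_signature_rejected(self):
        with pytest.raises(ValueError):
            ks_rank_enrichment(["x"], ["a", "b"])
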