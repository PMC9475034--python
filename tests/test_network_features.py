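import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from psnfuse.network_features import (
    CENTRALITY_NAMES,
    FeatureConfig,
    assemble_features,
    compute_centralities,
    default_k_grid,
    encode_membership,
    iterative_measure,
    sbm_modules,
    sbm_objective,
    select_k_by_silhouette,
    spectral_modules,
)
from psnfuse.psn import PSN
from psnfuse.synthetic_data import planted_block_affinity
from conftest import random_affinity


def col(matrix, name):
    return matrix[:, CENTRALITY_NAMES.index(name)]


class TestCentralities:
    def test_k4_symmetry_closed_forms(self, k4_psn):
        c = compute_centralities(k4_psn)
        assert np.allclose(col(c, "weighted_degree"), 3.0)
        assert np.allclose(col(c, "pagerank"), 0.25)
        assert np.allclose(col(c, "clustering"), 1.0)
        assert np.allclose(col(c, "iterative_weighted_degree"), 3.0)

    def test_path_graph_load_enumerated(self, p3_psn):
        # all shortest paths in P3 pass through the centre
        c = compute_centralities(p3_psn)
        assert col(c, "load")[1] == pytest.approx(1.0)
        assert col(c, "load")[0] == pytest.approx(0.0)
        assert col(c, "load")[2] == pytest.approx(0.0)

    def test_hits_authority_equals_hub_undirected(self):
        a = random_affinity(7, seed=0)
        c = compute_centralities(PSN(affinity=a, patient_ids=np.arange(7)))
        assert np.allclose(col(c, "hits_authority"), col(c, "hits_hub"))

    def test_thirteen_columns_and_permutation_equivariance(self):
        a = random_affinity(8, seed=1)
        c = compute_centralities(PSN(affinity=a, patient_ids=np.arange(8)))
        assert c.shape == (8, 13)
        perm = np.random.default_rng(2).permutation(8)
        cp = compute_centralities(PSN(affinity=a[np.ix_(perm, perm)], patient_ids=np.arange(8)))
        assert np.allclose(cp, c[perm], atol=1e-6)

    def test_disconnected_graph_raises(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            compute_centralities(PSN(affinity=a, patient_ids=np.arange(4)))


def brute_force_peeling(a, base):
    """Independent peeling oracle on an affinity matrix (plain loops)."""
    n = a.shape[0]
    alive = list(range(n))
    scores = {}
    g_full = nx.from_numpy_array(a)
    while alive:
        vals = {}
        sub = g_full.subgraph(alive)
        if base == "weighted_degree":
            for u in alive:
                vals[u] = sum(a[u, v] for v in alive if v != u and a[u, v] > 0)
        else:
            vals = nx.clustering(sub, weight="weight")
        mn = min(vals.values())
        drop = [u for u in alive if vals[u] <= mn + 1e-9]
        for u in drop:
            scores[u] = vals[u]
            alive.remove(u)
    return scores


class TestIterativeMeasures:
    def test_star_graph_peeling_by_hand(self, star_psn):
        scores = iterative_measure(star_psn, base="weighted_degree")
        # leaves (degree 1) are removed first; hub is scored on the residual
        assert all(scores[u] == pytest.approx(1.0) for u in range(1, 5))
        assert scores[0] == pytest.approx(0.0)  # hub alone after leaves go

    @pytest.mark.parametrize("base", ["weighted_degree", "clustering"])
    def test_matches_brute_force_oracle_on_random_battery(self, base):
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 9))
            a = random_affinity(n, seed=seed + 100)
            # sparsify some edges to vary structure
            mask = rng.random((n, n)) < 0.3
            mask = mask | mask.T
            a[mask] = 0.0
            np.fill_diagonal(a, 0.0)
            got = iterative_measure(nx.from_numpy_array(a), base=base)
            want = brute_force_peeling(a, base)
            for u in range(n):
                assert got[u] == pytest.approx(want[u], abs=1e-8), (seed, u)


class TestModules:
    def test_disconnected_cliques_split_exactly(self):
        a = np.zeros((8, 8))
        a[:4, :4] = 1.0
        a[4:, 4:] = 1.0
        np.fill_diagonal(a, 0.0)
        for fn in (spectral_modules, sbm_modules):
            labels = fn(a, 2, seed=0)
            assert adjusted_rand_score([0] * 4 + [1] * 4, labels) == 1.0

    @pytest.mark.parametrize("k", [2, 3])
    def test_planted_blocks_recovered(self, k):
        a, truth = planted_block_affinity(60, k, within=0.9, between=0.1, seed=4)
        assert adjusted_rand_score(truth, spectral_modules(a, k, seed=1)) == 1.0
        assert adjusted_rand_score(truth, sbm_modules(a, k, seed=1)) == 1.0

    def test_determinism(self):
        a, _ = planted_block_affinity(30, 3, seed=2)
        assert np.array_equal(spectral_modules(a, 3, 5), spectral_modules(a, 3, 5))
        assert np.array_equal(sbm_modules(a, 3, 5), sbm_modules(a, 3, 5))

    def test_sbm_greedy_never_decreases_objective(self):
        a = random_affinity(25, seed=9)
        init = spectral_modules(a, 4, seed=3)
        final = sbm_modules(a, 4, seed=3)
        assert sbm_objective(a, final, 4) >= sbm_objective(a, init, 4) - 1e-9

    def test_k_out_of_range(self):
        a = random_affinity(5, seed=0)
        for bad in (1, 5):
            with pytest.raises(ValueError):
                spectral_modules(a, bad, seed=0)


class TestSilhouetteSelection:
    def test_singleton_grid(self):
        a, _ = planted_block_affinity(20, 2, seed=0)
        k, labels = select_k_by_silhouette(a, "spectral", [2], seed=0)
        assert k == 2 and len(labels) == 20

    def test_three_blocks_selected_from_grid(self):
        a, truth = planted_block_affinity(60, 3, seed=5)
        k, labels = select_k_by_silhouette(a, "spectral", range(2, 7), seed=1)
        assert k == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tie_goes_to_smaller_k(self, monkeypatch):
        # force exact score ties: the smallest k must win
        import psnfuse.network_features as nf

        monkeypatch.setattr(nf, "silhouette_score", lambda *a, **kw: 0.5)
        a, _ = planted_block_affinity(20, 2, seed=1)
        k, _ = select_k_by_silhouette(a, "spectral", [2, 3, 4], seed=0)
        assert k == 2


class TestMembershipAndAssembly:
    def test_one_hot_example(self):
        got = encode_membership([0, 1, 0], 2)
        assert np.array_equal(got, [[1, 0], [0, 1], [1, 0]])
        assert np.array_equal(encode_membership([0, 0, 0], 1), [[1], [1], [1]])
        with pytest.raises(ValueError):
            encode_membership([0, 2], 2)

    def test_assembled_table_shape_and_row_sums(self):
        a, _ = planted_block_affinity(30, 3, within=0.9, between=0.1, seed=6)
        psn = PSN(affinity=a, patient_ids=np.array([f"P{i}" for i in range(30)], object))
        table = assemble_features(psn, FeatureConfig(k_grid=(2, 3, 4), seed=0, refine=False))
        n_mod = table.values.shape[1] - 13
        assert [m for m in table.column_meta[:13]] == [
            f"centrality:{n}" for n in CENTRALITY_NAMES
        ]
        # two one-hot blocks concatenated: every row sums to 2
        assert np.allclose(table.modularity_block.sum(axis=1), 2.0)
        assert n_mod >= 4  # at least k=2 per algorithm

    def test_default_k_grid_is_geometric(self):
        assert default_k_grid(60) == (2, 4, 8, 16)
        assert default_k_grid(5) == (2,)
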