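import itertools

import numpy as np
import pytest

from germdecon.clustering import (
    METHODS,
    ClusteringError,
    bootstrap_support,
    cophenetic_correlation,
    hierarchical_tree,
    select_linkage_method,
)
from germdecon.gower import DissimilarityMatrix, GowerConfig, gd_matrix
from germdecon.synthetic_data import SimulationConfig, simulate_collection


def dm_from_square(ids, gd):
    gd = np.asarray(gd, dtype=float)
    return DissimilarityMatrix(list(ids), gd,
                               np.full(gd.shape, 100, dtype=np.int64))


def lance_williams(dist, method):
    """Independent naive Lance-Williams agglomeration (full-matrix update,
    merge the globally closest pair each round).  Returns merge heights and
    a full cophenetic matrix."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    active = list(range(n))
    members = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    d = d.copy()
    np.fill_diagonal(d, np.inf)
    working = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n
    while len(active) > 1:
        (i, j), h = min(working.items(), key=lambda kv: kv[1])
        heights.append(h)
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = h
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dik = working[tuple(sorted((i, k)))]
            djk = working[tuple(sorted((j, k)))]
            nk = sizes[k]
            if method == "average":
                val = (ni * dik + nj * djk) / (ni + nj)
            elif method == "ward_d":
                val = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            else:
                raise ValueError(method)
            working[tuple(sorted((new, k)))] = val
        for key in [key for key in working if i in key or j in key]:
            del working[key]
        members[new] = members[i] + members[j]
        sizes[new] = ni + nj
        active = [a for a in active if a not in (i, j)] + [new]
    return np.array(heights), coph


class TestHierarchicalTree:
    def test_two_leaves_single_merge(self):
        dm = dm_from_square(["A", "B"], [[0, 0.3], [0.3, 0]])
        tree = hierarchical_tree(dm, "average")
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.3)

    def test_three_leaf_upgma_hand_worked(self):
        # ultrametric: d(A,B)=0.2, d(A,C)=d(B,C)=0.5
        dm = dm_from_square(["A", "B", "C"],
                            [[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]])
        tree = hierarchical_tree(dm, "average")
        assert sorted(tree.heights.round(12)) == [0.2, 0.5]

    def test_unknown_method_rejected(self):
        dm = dm_from_square(["A", "B"], [[0, 0.3], [0.3, 0]])
        with pytest.raises(ClusteringError):
            hierarchical_tree(dm, "upgma_typo")

    def test_undefined_entries_rejected(self):
        gd = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(Exception):
            hierarchical_tree(dm_from_square(["A", "B"], gd), "average")

    @pytest.mark.parametrize("method", ["average", "ward_d"])
    def test_matches_independent_lance_williams(self, method):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 4))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = dm_from_square([f"L{i}" for i in range(10)], dist)
        tree = hierarchical_tree(dm, method)
        heights, coph = lance_williams(dist, method)
        np.testing.assert_allclose(np.sort(tree.heights), np.sort(heights),
                                   rtol=1e-10)
        from scipy.spatial.distance import squareform
        np.testing.assert_allclose(tree.cophenetic_distances(),
                                   squareform(coph), rtol=1e-10)

    def test_upgma_heights_monotone(self, structured_diploid):
        gm, _ = structured_diploid
        tree = hierarchical_tree(gd_matrix(gm), "average")
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_cophenetic_matrix_is_ultrametric_for_monotone_methods(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = dm_from_square([f"L{i}" for i in range(8)], dist)
        for method in ("average", "complete", "single"):
            from scipy.spatial.distance import squareform
            coph = squareform(hierarchical_tree(dm, method).cophenetic_distances())
            for i, j, k in itertools.permutations(range(8), 3):
                assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_one(self):
        dm = dm_from_square(["A", "B", "C"],
                            [[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]])
        tree = hierarchical_tree(dm, "average")
        assert cophenetic_correlation(dm, tree) == pytest.approx(1.0)

    def test_four_leaf_brute_force(self):
        gd = np.array([[0.0, 0.1, 0.4, 0.5],
                       [0.1, 0.0, 0.45, 0.42],
                       [0.4, 0.45, 0.0, 0.2],
                       [0.5, 0.42, 0.2, 0.0]])
        dm = dm_from_square(list("ABCD"), gd)
        tree = hierarchical_tree(dm, "average")
        # brute force: LCA merge height per pair from the clade sets
        clades = tree.clades()
        heights = tree.heights
        n = 4
        coph = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                for k, clade in enumerate(clades):
                    if i in clade and j in clade:
                        coph[i, j] = coph[j, i] = heights[k]
                        break
        from scipy.spatial.distance import squareform
        from scipy.stats import pearsonr
        expect = pearsonr(squareform(gd, checks=False), squareform(coph))[0]
        assert cophenetic_correlation(dm, tree) == pytest.approx(expect, abs=1e-12)

    def test_constant_matrix_undefined(self):
        dm = dm_from_square(["A", "B", "C"],
                            np.array([[0, .3, .3], [.3, 0, .3], [.3, .3, 0]]))
        tree = hierarchical_tree(dm, "average")
        with pytest.raises(ClusteringError, match="zero variance"):
            cophenetic_correlation(dm, tree)


class TestMethodSelection:
    def test_average_wins_on_clock_like_structure(self, structured_diploid):
        gm, _ = structured_diploid
        sel = select_linkage_method(gm, n_boot=25, seed=0)
        assert sel.winner == "average"
        assert sel.mean_ccc["average"] == max(sel.mean_ccc.values())

    def test_single_method_list(self, structured_diploid):
        gm, _ = structured_diploid
        sel = select_linkage_method(gm, methods=["complete"], n_boot=5, seed=0)
        assert sel.winner == "complete"

    def test_same_seed_reproduces(self, structured_diploid):
        gm, _ = structured_diploid
        a = select_linkage_method(gm, methods=["average", "single"], n_boot=10, seed=3)
        b = select_linkage_method(gm, methods=["average", "single"], n_boot=10, seed=3)
        assert a.mean_ccc == b.mean_ccc and a.winner == b.winner

    def test_bad_inputs(self, structured_diploid):
        gm, _ = structured_diploid
        with pytest.raises(ClusteringError):
            select_linkage_method(gm, methods=[], n_boot=5)
        with pytest.raises(ClusteringError):
            select_linkage_method(gm, n_boot=0)


class TestBootstrapSupport:
    def test_exact_clone_clade_fully_supported(self):
        cfg = SimulationConfig(seed=61, n_snps=400, n_subpops=2,
                               n_genotypes_per_subpop=4, default_ploidy=2,
                               clone_copies={"G001": 2},
                               intra_library_miscall=0.0,
                               inter_library_miscall=0.0, missing_rate=0.0)
        gm, _ = simulate_collection(cfg)
        st = bootstrap_support(gm, method="average", n_boot=40, seed=0)
        clades = st.tree.clades()
        idx = {a: k for k, a in enumerate(st.tree.ids)}
        pair = frozenset([idx["G001.1"], idx["G001.2"]])
        k = clades.index(pair)
        assert st.support[k] == 1.0

    def test_divergent_subpopulation_split_highly_supported(self):
        cfg = SimulationConfig(seed=62, n_snps=800, n_subpops=2, fst=0.45,
                               n_genotypes_per_subpop=5, default_ploidy=2)
        gm, truth = simulate_collection(cfg)
        st = bootstrap_support(gm, method="average", n_boot=60, seed=0)
        pop0 = frozenset(i for i, a in enumerate(st.tree.ids)
                         if truth.genotype_subpop[truth.clone_map[a]] == 0)
        clades = st.tree.clades()
        assert pop0 in clades or frozenset(range(len(st.tree.ids))) - pop0 in clades
        k = clades.index(pop0 if pop0 in clades else
                         frozenset(range(len(st.tree.ids))) - pop0)
        assert st.support[k] >= 0.95

    def test_zero_bootstraps_rejected(self, structured_diploid):
        gm, _ = structured_diploid
        with pytest.raises(ClusteringError):
            bootstrap_support(gm, n_boot=0)

    def test_newick_export_parses(self, structured_diploid):
        import io

        from Bio import Phylo

        gm, _ = structured_diploid
        st = bootstrap_support(gm, method="average", n_boot=10, seed=1)
        nwk = st.tree.to_newick(st.support)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(st.tree.ids)
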