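"""Hierarchical clustering over GD with method selection and bootstrap support.

The eight agglomeration rules of R's hclust are exposed under their hclust
names (ward_d, ward_d2, single, complete, average/UPGMA, mcquitty/WPGMA,
median/WPGMC, centroid/UPGMC), backed by scipy's linkage.  The two Ward
conventions are related by ward_d(d) = ward_d2(sqrt(d)) with squared merge
heights, which is how ward_d is realized here.

Method choice follows the cophenetic correlation coefficient (CCC): the
Pearson correlation between the input dissimilarities and the tree's
cophenetic distances, bootstrapped by resampling SNP columns with
replacement and recomputing the GD matrix.  Clade stability on the chosen
tree is reported as plain bootstrap proportions: the fraction of
SNP-resampled trees containing the same leaf clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .genotypes import GenotypeMatrix
from .gower import DissimilarityMatrix, GowerConfig, _restrict, _state_matrix, gd_matrix_from_states

METHODS = ("ward_d", "ward_d2", "single", "complete", "average",
           "mcquitty", "median", "centroid")

_SCIPY_NAME = {"average": "average", "single": "single", "complete": "complete",
               "mcquitty": "weighted", "median": "median", "centroid": "centroid",
               "ward_d2": "ward"}


class ClusteringError(ValueError):
    pass


@dataclass
class LinkageTree:
    """Merge sequence in scipy linkage form plus leaf ids and method name."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    ids: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed matrix of lowest-common-merge heights."""
        return hierarchy.cophenet(self.linkage)

    def clades(self) -> list[frozenset[int]]:
        """Leaf-index set of every internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self, support: np.ndarray | None = None) -> str:
        """Newick string: branch lengths from merge-height differences,
        optional internal-node labels (support percentages)."""
        root = hierarchy.to_tree(self.linkage)
        clade_height = {}

        def height(node):
            return 0.0 if node.is_leaf() else node.dist

        def rec(node, parent_h):
            bl = max(parent_h - height(node), 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{bl:.6g}"
            label = ""
            if support is not None:
                k = node.id - self.n_leaves
                if 0 <= k < len(support):
                    label = f"{100 * support[k]:.0f}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f"{label}:{bl:.6g}")

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        label = ""
        if support is not None:
            label = f"{100 * support[-1]:.0f}"
        return f"({left},{right}){label};"


@dataclass
class MethodSelection:
    methods: list[str]
    mean_ccc: dict[str, float]
    sd_ccc: dict[str, float]
    winner: str


@dataclass
class SupportedTree:
    tree: LinkageTree
    support: np.ndarray  # per internal node, in [0,1], merge order
    n_boot: int


def hierarchical_tree(dm: DissimilarityMatrix, method: str = "average") -> LinkageTree:
    if method not in METHODS:
        raise ClusteringError(f"unknown linkage method {method!r}; choose from {METHODS}")
    condensed = dm.to_condensed()
    if method == "ward_d":
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        Z = hierarchy.linkage(condensed, method=_SCIPY_NAME[method])
    return LinkageTree(Z, list(dm.ids), method)


def cophenetic_correlation(dm: DissimilarityMatrix, tree: LinkageTree) -> float:
    """Pearson correlation between input GDs and cophenetic distances."""
    if list(dm.ids) != tree.ids:
        raise ClusteringError("tree and matrix cover different accession sets")
    orig = dm.to_condensed()
    coph = tree.cophenetic_distances()
    if np.std(orig) == 0 or np.std(coph) == 0:
        raise ClusteringError("zero variance: cophenetic correlation undefined")
    return float(pearsonr(orig, coph)[0])


def _bootstrap_dms(gm: GenotypeMatrix, cfg: GowerConfig, n_boot: int, seed: int):
    """Yield GD matrices from SNP-column resamples (missing pairs rejected:
    resampling keeps every pair co-genotyped somewhere in practice)."""
    sub = _restrict(gm, cfg)
    state = _state_matrix(sub, cfg)
    rng = np.random.default_rng(seed)
    m = state.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        yield gd_matrix_from_states(state[:, cols], sub.accession_ids)


def select_linkage_method(gm: GenotypeMatrix, cfg: GowerConfig | None = None,
                          methods: Sequence[str] = METHODS, n_boot: int = 100,
                          seed: int = 0) -> MethodSelection:
    """Bootstrap CCC distributions per linkage method; winner = max mean CCC."""
    if gm.n_accessions < 2:
        raise ClusteringError("need at least 2 accessions")
    if not methods:
        raise ClusteringError("empty method list")
    if n_boot < 1:
        raise ClusteringError("n_boot must be >= 1")
    cfg = cfg or GowerConfig()
    ccc: dict[str, list[float]] = {m: [] for m in methods}
    for bdm in _bootstrap_dms(gm, cfg, n_boot, seed):
        for m in methods:
            tree = hierarchical_tree(bdm, m)
            try:
                ccc[m].append(cophenetic_correlation(bdm, tree))
            except ClusteringError:
                pass  # degenerate resample
    mean = {m: float(np.mean(v)) if v else float("nan") for m, v in ccc.items()}
    sd = {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for m, v in ccc.items()}
    winner = max(methods, key=lambda m: (np.nan_to_num(mean[m], nan=-np.inf), m))
    return MethodSelection(list(methods), mean, sd, winner)


def bootstrap_support(gm: GenotypeMatrix, cfg: GowerConfig | None = None,
                      method: str = "average", n_boot: int = 1000,
                      seed: int = 0) -> SupportedTree:
    """Clade bootstrap proportions on the reference tree.

    Support of an internal node = fraction of SNP-resampled trees whose
    clade set contains the same leaf set.
    """
    if n_boot < 1:
        raise ClusteringError("n_boot must be >= 1")
    cfg = cfg or GowerConfig()
    from .gower import gd_matrix

    ref_dm = gd_matrix(gm, cfg)
    ref_tree = hierarchical_tree(ref_dm, method)
    ref_clades = ref_tree.clades()
    counts = np.zeros(len(ref_clades))
    for bdm in _bootstrap_dms(gm, cfg, n_boot, seed):
        boot_clades = set(hierarchical_tree(bdm, method).clades())
        for k, clade in enumerate(ref_clades):
            if clade in boot_clades:
                counts[k] += 1
    return SupportedTree(ref_tree, counts / n_boot, n_boot)
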