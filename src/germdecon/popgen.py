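"""Ordination, cluster-number selection, AMOVA, and diversity statistics.

These analyses run on the redundancy-culled genotype set (one
representative per unique genotype).  Genotypes enter as dosage fractions
(dosage/ploidy), putting mixed ploidies on one scale.

* PCA: mean-imputed, column-centered (optionally unit-scaled) dosage
  fractions, eigen-decomposed; scores and per-axis variance percentages.
* K selection: K-means over the principal components explaining a target
  share of variance, scored by BIC(K) = n ln(WSS_K/n) + K ln(n); the
  chosen K is the smallest K attaining the minimum BIC before the curve
  turns upward.
* AMOVA: allele-level hierarchical analysis of molecular variance.  Each
  accession contributes `ploidy` binary allele copies per locus, so sums
  of squares decompose among groups / among genotypes within groups /
  within genotypes; variance components come from the standard nested
  expected-mean-square coefficients, and per-stratum p-values from
  permutation (genotypes among groups; allele copies among genotypes
  within groups).
* Diversity: effective allele number, observed and unbiased expected
  heterozygosity, F_IS, MAF spectrum, mean GD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix
from .gower import GowerConfig, gd_matrix


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    ids: list[str]
    scores: np.ndarray       # (N, n_axes)
    pct_variance: np.ndarray  # per axis, non-increasing, sums <= 100

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k+1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def pca_genotypes(gm: GenotypeMatrix, scale: bool = False,
                  max_axes: int | None = None) -> PCAResult:
    """PCA of the dosage-fraction matrix with per-SNP mean imputation."""
    if gm.n_accessions < 2 or gm.n_snps < 2:
        raise PopgenError("need at least 2 accessions and 2 SNPs")
    f = gm.dosage_fraction()
    all_missing = np.isnan(f).all(axis=0)
    if all_missing.any():
        raise PopgenError(f"{int(all_missing.sum())} SNP columns are entirely missing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(f, axis=0)
    idx = np.where(np.isnan(f))
    f[idx] = col_mean[idx[1]]
    f = f - f.mean(axis=0)
    if scale:
        sd = f.std(axis=0)
        f = f / np.where(sd > 0, sd, 1.0)
    n_axes = min(gm.n_accessions - 1, gm.n_snps)
    if max_axes is not None:
        n_axes = min(n_axes, max_axes)
    p = PCA(n_components=n_axes, svd_solver="full")
    scores = p.fit_transform(f)
    return PCAResult(gm.accession_ids, scores, 100.0 * p.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# K selection by BIC

@dataclass
class KSelection:
    k_values: list[int]
    bic: dict[int, float]
    chosen_k: int
    assignments: dict[str, int]


def select_k_bic(pca: PCAResult, k_range: Sequence[int] = range(2, 11),
                 retained_variance: float = 0.9, seed: int = 0,
                 n_init: int = 10) -> KSelection:
    """K-means over the leading PCs, K chosen by minimum BIC.

    BIC(K) = n ln(WSS_K / n) + K ln(n) (the find.clusters convention);
    ties on the minimum resolve to the smallest K, and a non-decreasing
    curve therefore returns the smallest evaluated K.
    """
    k_values = sorted(int(k) for k in k_range)
    n = len(pca.ids)
    if not k_values:
        raise PopgenError("empty K range")
    if k_values[0] < 1 or k_values[-1] > n - 1:
        raise PopgenError(f"K range {k_values[0]}..{k_values[-1]} outside 1..{n-1}")
    cum = np.cumsum(pca.pct_variance) / np.sum(pca.pct_variance)
    n_axes = int(np.searchsorted(cum, retained_variance) + 1)
    X = pca.scores[:, :n_axes]
    bic: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wss = max(float(km.inertia_), 1e-12)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        labels[k] = km.labels_
    best = min(bic.values())
    chosen = min(k for k in k_values if bic[k] == best)
    return KSelection(k_values, bic, chosen,
                      dict(zip(pca.ids, (int(v) for v in labels[chosen]))))


# ---------------------------------------------------------------------------
# AMOVA

@dataclass
class AmovaStratum:
    df: float
    ss: float
    ms: float
    var: float
    var_pct: float
    p_value: float = float("nan")
    truncated: bool = False


@dataclass
class AmovaTable:
    among_groups: AmovaStratum
    among_genotypes: AmovaStratum
    within_genotypes: AmovaStratum
    fst: float
    n_permutations: int = 0
    renormalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in [("Among Groups", self.among_groups),
                        ("Among Genotypes", self.among_genotypes),
                        ("Within Genotypes", self.within_genotypes)]:
            rows.append(dict(source=name, df=s.df, SS=s.ss, MS=s.ms,
                             p_value=s.p_value, Var=s.var, Var_pct=s.var_pct))
        return pd.DataFrame(rows).set_index("source")


def _amova_ss(d0: np.ndarray, typed: np.ndarray, pl: np.ndarray,
              group_ind: np.ndarray) -> tuple[float, float, float]:
    """Summed-over-loci sums of squares (among groups, among accessions
    within groups, within accessions) for binary allele copies.

    d0: (I, M) dosages with missing as 0; typed: (I, M) bool; pl: (I,)
    ploidies; group_ind: (I, G) one-hot group membership.
    """
    pl_col = pl[:, None].astype(float)
    n_l = (typed * pl_col).sum(axis=0)            # allele copies per locus
    T_l = d0.sum(axis=0)
    use = n_l > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_within = (d0 * (pl_col - d0) / pl_col * typed).sum(axis=0)
        n_il = group_ind.T @ (typed * pl_col)     # (G, M)
        T_il = group_ind.T @ d0
        grp_term = np.where(n_il > 0, T_il ** 2 / np.maximum(n_il, 1e-300), 0.0).sum(axis=0)
        acc_term = (np.where(typed, d0 ** 2, 0.0) / pl_col).sum(axis=0)
        tot_term = np.where(n_l > 0, T_l ** 2 / np.maximum(n_l, 1e-300), 0.0)
    ss_a = (grp_term - tot_term)[use].sum()
    ss_b = (acc_term - grp_term)[use].sum()
    ss_w = ss_within[use].sum()
    return float(ss_a), float(ss_b), float(ss_w)


def _components(ss_a, ss_b, ss_w, df_a, df_b, df_w, coef_a, coef_b, coef_c):
    ms_a, ms_b, ms_w = ss_a / df_a, ss_b / df_b, ss_w / df_w
    var_w = ms_w
    var_b = (ms_b - var_w) / coef_a
    var_a = (ms_a - var_w - coef_b * var_b) / coef_c
    return (ms_a, ms_b, ms_w), (var_a, var_b, var_w)


def amova(gm: GenotypeMatrix, grouping: Mapping[str, str], n_perm: int = 999,
          seed: int = 0, permute_alleles: bool = True) -> AmovaTable:
    """Hierarchical AMOVA of allele-frequency variance.

    ``grouping`` maps every accession id to a group label.  Negative
    variance components are truncated to zero (flagged) and percentages
    renormalized.  F_ST = among-group component / total.  The
    among-groups p-value permutes genotypes among groups; the other two
    strata redistribute allele copies among genotypes within groups,
    which ``permute_alleles=False`` skips (their p-values stay NaN).
    """
    ids = gm.accession_ids
    missing_assign = [a for a in ids if a not in grouping]
    if missing_assign:
        raise PopgenError(f"accessions without a group: {missing_assign}")
    labels = [grouping[a] for a in ids]
    group_names = sorted(set(labels))
    g = len(group_names)
    if g < 2:
        raise PopgenError("need at least 2 groups")
    sizes = pd.Series(labels).value_counts()
    if (sizes < 2).any():
        warnings.warn("group(s) with a single genotype: among-genotype df collapses there")

    I = gm.n_accessions
    pl = gm.ploidy.astype(float)
    typed = ~gm.missing_mask
    d0 = np.where(typed, gm.dosage, 0).astype(float)
    gi = np.array([group_names.index(l) for l in labels])
    group_ind = np.eye(g)[gi]

    df_a, df_b, df_w = g - 1.0, float(I - g), float((pl - 1).sum())
    n = pl.sum()
    n_i = group_ind.T @ pl
    sum_nij2_over_ni = float((((group_ind * pl[:, None]) ** 2).sum(axis=0) / n_i).sum())
    coef_a = (n - sum_nij2_over_ni) / df_b
    coef_b = (sum_nij2_over_ni - (pl ** 2).sum() / n) / df_a
    coef_c = (n - (n_i ** 2).sum() / n) / df_a

    ss_a, ss_b, ss_w = _amova_ss(d0, typed, pl, group_ind)
    (ms_a, ms_b, ms_w), (var_a, var_b, var_w) = _components(
        ss_a, ss_b, ss_w, df_a, df_b, df_w, coef_a, coef_b, coef_c)

    truncated = [v < 0 for v in (var_a, var_b, var_w)]
    var_a_t, var_b_t, var_w_t = (max(v, 0.0) for v in (var_a, var_b, var_w))
    total = var_a_t + var_b_t + var_w_t
    if total <= 0:
        pct = (0.0, 0.0, 0.0)
        fst = 0.0
    else:
        pct = tuple(100.0 * v / total for v in (var_a_t, var_b_t, var_w_t))
        fst = var_a_t / total

    p_a = p_b = p_w = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        # among groups: permute genotypes among groups
        count_a = 0
        for _ in range(n_perm):
            perm_ind = group_ind[rng.permutation(I)]
            pss_a, pss_b, pss_w = _amova_ss(d0, typed, pl, perm_ind)
            _, (pv_a, _, _) = _components(pss_a, pss_b, pss_w, df_a, df_b, df_w,
                                          coef_a, coef_b, coef_c)
            if pv_a >= var_a:
                count_a += 1
        p_a = (count_a + 1) / (n_perm + 1)
        # among/within genotypes: redistribute allele copies among the
        # genotypes of each group (multivariate hypergeometric per locus)
        count_b = 0
        count_w = 0
        M = gm.n_snps
        for _ in range(n_perm if permute_alleles else 0):
            d_perm = np.zeros_like(d0)
            for gidx in range(g):
                members = np.flatnonzero(gi == gidx)
                rem_T = d0[members].sum(axis=0)
                rem_n = (typed[members] * pl[members, None]).sum(axis=0)
                for a in members:
                    cap = np.where(typed[a], pl[a], 0).astype(np.int64)
                    ngood = rem_T.astype(np.int64)
                    nbad = np.maximum(rem_n.astype(np.int64) - ngood, 0)
                    draw = np.zeros(M, dtype=np.int64)
                    ok = cap > 0
                    if ok.any():
                        draw[ok] = rng.hypergeometric(np.maximum(ngood[ok], 0),
                                                      nbad[ok], cap[ok])
                    d_perm[a] = draw
                    rem_T = rem_T - draw
                    rem_n = rem_n - cap
            pss_a, pss_b, pss_w = _amova_ss(d_perm, typed, pl, group_ind)
            _, (_, pv_b, pv_w) = _components(pss_a, pss_b, pss_w, df_a, df_b, df_w,
                                             coef_a, coef_b, coef_c)
            if pv_b >= var_b:
                count_b += 1
            if pv_w >= var_w:
                count_w += 1
        if permute_alleles:
            p_b = (count_b + 1) / (n_perm + 1)
            p_w = (count_w + 1) / (n_perm + 1)

    return AmovaTable(
        among_groups=AmovaStratum(df_a, ss_a, ms_a, var_a_t, pct[0], p_a, truncated[0]),
        among_genotypes=AmovaStratum(df_b, ss_b, ms_b, var_b_t, pct[1], p_b, truncated[1]),
        within_genotypes=AmovaStratum(df_w, ss_w, ms_w, var_w_t, pct[2], p_w, truncated[2]),
        fst=float(fst),
        n_permutations=n_perm,
        renormalized=any(truncated),
    )


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversitySummary:
    n_accessions: int
    n_loci_used: int
    pct_maf_gt_0p1: float
    n_e: float
    h_o: float
    h_e: float
    mean_gd: float
    f_is: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def diversity_stats(gm: GenotypeMatrix,
                    population: Sequence[str] | None = None) -> DiversitySummary:
    """Per-population diversity: N_E, H_O, unbiased H_E, F_IS, MAF spectrum,
    mean pairwise GD.

    Allele frequencies come from dosage sums over ploidy-weighted copies;
    unbiased H_E carries the n_c/(n_c - 1) small-sample correction; F_IS is
    the mean of 1 - H_O/H_E over polymorphic loci.
    """
    sub = gm.select_accessions(list(population)) if population is not None else gm
    if sub.n_accessions == 0:
        raise PopgenError("empty population")
    pl = sub.ploidy.astype(float)[:, None]
    typed = ~sub.missing_mask
    d0 = np.where(typed, sub.dosage, 0).astype(float)
    n_c = (typed * pl).sum(axis=0)
    use = n_c > 1
    if not use.any():
        raise PopgenError("no locus with more than one allele copy")
    p = d0.sum(axis=0)[use] / n_c[use]
    q = 1.0 - p
    n_cu = n_c[use]
    n_e = 1.0 / (p ** 2 + q ** 2)
    h_e = (n_cu / (n_cu - 1.0)) * (1.0 - p ** 2 - q ** 2)
    het = sub.het_mask
    typed_u = typed[:, use]
    with np.errstate(invalid="ignore", divide="ignore"):
        h_o = np.where(typed_u.sum(axis=0) > 0,
                       het[:, use].sum(axis=0) / np.maximum(typed_u.sum(axis=0), 1), 0.0)
    poly = (p > 0) & (p < 1) & (h_e > 0)
    f_is = float(np.mean(1.0 - h_o[poly] / h_e[poly])) if poly.any() else float("nan")
    maf = np.minimum(p, q)
    if sub.n_accessions >= 2:
        dm = gd_matrix(sub, GowerConfig("collapsed"))
        tri = dm.gd[np.triu_indices(dm.n, 1)]
        mean_gd = float(np.nanmean(tri))
    else:
        mean_gd = float("nan")
    return DiversitySummary(
        n_accessions=sub.n_accessions,
        n_loci_used=int(use.sum()),
        pct_maf_gt_0p1=float(100.0 * (maf > 0.1).mean()),
        n_e=float(n_e.mean()),
        h_o=float(h_o.mean()),
        h_e=float(h_e.mean()),
        mean_gd=mean_gd,
        f_is=f_is,
    )
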