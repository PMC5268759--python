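"""Modified Gower dissimilarity (GD) between accessions.

For a pair of accessions the dissimilarity over m bi-allelic SNPs is

    GD(x, y) = 1 - sum_i(s_i * w_i) / sum_i(w_i)

where w_i = 1 when both accessions carry a genotype call at SNP i and
s_i scores identity-by-state.  Two codings of s are provided:

``collapsed``
    genotypes collapse to {hom-ref, het, hom-alt}: s = 1 for identical
    states, 0.5 for het vs either homozygote, 0 for opposite homozygotes.
    Valid across ploidies, which is why mixed-ploidy pairs use it.
``dosage``
    states are dosage fractions f = dosage/ploidy and s = 1 - |f_x - f_y|;
    on diploids this reproduces the collapsed scores exactly, and for
    tetraploids it splits the heterozygote class into the 3:1 / 1:1 / 1:3
    depth-ratio states, scoring cross-class heterozygotes by linear dosage
    distance (e.g. 3:1 vs 1:3 -> 0.5).
``diploidized``
    collapsed coding restricted to a caller-supplied subset of markers
    that behave diploidly inside a polyploid (het depth ratio ~ 1/ploidy),

Pairs with no co-genotyped SNP are reported as undefined (NaN), never
silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix


class GowerError(ValueError):
    pass


@dataclass
class GowerConfig:
    coding: str = "collapsed"
    diploidized_snp_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.coding not in ("collapsed", "dosage", "diploidized"):
            raise GowerError(f"unknown coding {self.coding!r}")
        if self.coding == "diploidized" and not self.diploidized_snp_ids:
            raise GowerError("diploidized coding requires a non-empty SNP subset")


@dataclass
class DissimilarityMatrix:
    """Pairwise GD values plus per-pair co-genotyped SNP counts."""

    ids: list[str]
    gd: np.ndarray          # (N, N) float, NaN where undefined
    pair_snp_counts: np.ndarray  # (N, N) int

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, accession_id: str) -> int:
        return self.ids.index(accession_id)

    def value(self, a: str, b: str) -> float:
        return float(self.gd[self.index(a), self.index(b)])

    def to_condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy convention); errors on
        undefined pairs, which have no meaningful distance."""
        if np.isnan(self.gd[np.triu_indices(self.n, 1)]).any():
            raise GowerError("dissimilarity matrix has undefined pairs")
        return squareform(self.gd, checks=False)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append((self.ids[i], self.ids[j], self.gd[i, j],
                             int(self.pair_snp_counts[i, j])))
        return pd.DataFrame(rows, columns=["accession_a", "accession_b", "gd", "n_snps"])

    def write_dual_triangle_csv(self, path: str | Path) -> None:
        """GD below the diagonal, co-genotyped SNP counts above it; the
        diagonal carries each accession's own typed-SNP count."""
        out = np.empty((self.n, self.n), dtype=object)
        for i in range(self.n):
            out[i, i] = int(self.pair_snp_counts[i, i])
            for j in range(i + 1, self.n):
                out[i, j] = int(self.pair_snp_counts[i, j])
                out[j, i] = "" if np.isnan(self.gd[j, i]) else round(float(self.gd[j, i]), 6)
        pd.DataFrame(out, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def read_dual_triangle_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        ids = list(df.index.astype(str))
        n = len(ids)
        gd = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=np.int64)
        raw = df.to_numpy()
        for i in range(n):
            counts[i, i] = int(float(raw[i, i]))
            for j in range(i + 1, n):
                counts[i, j] = counts[j, i] = int(float(raw[i, j]))
                v = raw[j, i]
                gd[i, j] = gd[j, i] = np.nan if (isinstance(v, float) and np.isnan(v)) else float(v)
        return cls(ids, gd, counts)


def _state_matrix(gm: GenotypeMatrix, cfg: GowerConfig) -> np.ndarray:
    """Per-cell IBS state with NaN at missing cells."""
    if cfg.coding == "dosage":
        if len(set(gm.ploidy)) > 1:
            raise GowerError("dosage coding requires uniform ploidy; "
                             "use collapsed coding for mixed-ploidy comparisons")
        return gm.dosage_fraction()
    # collapsed (and diploidized = collapsed on a subset handled upstream)
    pl = gm.ploidy[:, None]
    state = np.where(gm.dosage == 0, 0.0, np.where(gm.dosage == pl, 1.0, 0.5))
    state[gm.missing_mask] = np.nan
    return state


def _restrict(gm: GenotypeMatrix, cfg: GowerConfig) -> GenotypeMatrix:
    if cfg.coding == "diploidized":
        return gm.select_snps(list(cfg.diploidized_snp_ids))
    return gm


def gd_pair(gm: GenotypeMatrix, a: str, b: str,
            cfg: GowerConfig | None = None) -> tuple[float, int]:
    """GD between two accessions and the number of co-genotyped SNPs used."""
    cfg = cfg or GowerConfig()
    sub = _restrict(gm, cfg)
    state = _state_matrix(sub, cfg)
    xa, xb = state[sub.accession_index(a)], state[sub.accession_index(b)]
    w = ~np.isnan(xa) & ~np.isnan(xb)
    n_used = int(w.sum())
    if n_used == 0:
        return float("nan"), 0
    return float(np.abs(xa[w] - xb[w]).mean()), n_used


def gd_matrix(gm: GenotypeMatrix, cfg: GowerConfig | None = None) -> DissimilarityMatrix:
    """All-pairs GD with pairwise deletion of missing data (vectorized).

    Since both codings score s = 1 - |state_a - state_b|, the pair GD is
    the mean absolute state difference over co-genotyped SNPs; the state
    alphabet is small, so the sums factor into a few matrix products.
    """
    cfg = cfg or GowerConfig()
    if gm.n_accessions < 2:
        raise GowerError("need at least 2 accessions")
    sub = _restrict(gm, cfg)
    state = _state_matrix(sub, cfg)
    return gd_matrix_from_states(state, sub.accession_ids)


def gd_matrix_from_states(state: np.ndarray, ids: Sequence[str]) -> DissimilarityMatrix:
    """GD matrix from an (N, M) state matrix (NaN = missing)."""
    valid = ~np.isnan(state)
    levels = np.unique(state[valid])
    # indicator stack per state level
    A = [(np.nan_to_num(state, nan=np.inf) == u).astype(np.float64) for u in levels]
    V = valid.astype(np.float64)
    W = V @ V.T
    D = np.zeros_like(W)
    for ui, u in enumerate(levels):
        C = np.zeros_like(V)
        for vi, v in enumerate(levels):
            if vi != ui:
                C += abs(u - v) * A[vi]
        D += A[ui] @ C.T
    with np.errstate(invalid="ignore", divide="ignore"):
        gd = np.where(W > 0, D / np.maximum(W, 1e-300), np.nan)
    np.fill_diagonal(gd, np.where(np.diag(W) > 0, 0.0, np.nan))
    gd = 0.5 * (gd + gd.T)  # enforce exact symmetry against fp noise
    return DissimilarityMatrix(list(ids), gd, W.astype(np.int64))


def select_diploidized_snps(gm: GenotypeMatrix, target_ratio: float = 0.25,
                            tol: float = 0.05, min_het_accessions: int = 3) -> list[str]:
    """Markers behaving diploidly within tetraploids.

    A SNP is kept when, across heterozygous tetraploid accessions with
    depth, the mean heterozygous allele-depth ratio sits within ``tol`` of
    ``target_ratio`` or of ``1 - target_ratio`` with standard deviation at
    most ``tol``, supported by at least ``min_het_accessions`` accessions.
    """
    is4x = gm.ploidy == 4
    if not is4x.any():
        return []
    sub_idx = np.flatnonzero(is4x)
    het = gm.het_mask[sub_idx]
    total = gm.total_depth[sub_idx].astype(float)
    alt = gm.alt_depth[sub_idx].astype(float)
    use = het & (total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(use, alt / np.maximum(total, 1), np.nan)
    counts = use.sum(axis=0)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(np.where(use, ratio, np.nan), axis=0)
        sd = np.nanstd(np.where(use, ratio, np.nan), axis=0)
    near = (np.abs(mean - target_ratio) <= tol) | (np.abs(mean - (1 - target_ratio)) <= tol)
    keep = (counts >= min_het_accessions) & near & (sd <= tol)
    keep = np.nan_to_num(keep.astype(float)).astype(bool)
    return [s for s, k in zip(gm.snp_ids, keep) if k]
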