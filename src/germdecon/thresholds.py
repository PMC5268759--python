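"""Empirical redundancy thresholds (GD_99%).

Two accessions are declared the same genotype when their Gower
dissimilarity falls below a cutoff estimated from the GD distribution
among replicates of known-identical material:

* biological replicates — duplicate DNA preps within one GBS library and
  sequencing lane (sample-level noise only);
* technical replicates — duplicates split across library preparations and
  lanes (library and lane effects added, empirically ~6-7x larger GDs);
* in-silico read sub-sampling — binomial thinning of each accession's
  allele depths followed by re-calling, a replicate surrogate needing no
  extra wet-lab work.

When the replicate GDs pass a Shapiro-Wilk normality check the cutoff is
the one-sided 99th percentile of the fitted normal, mean + 2.3263 sd;
otherwise the empirical percentile is used.  For a species with no
replicates at all, a threshold is extrapolated by dividing its
read-subsampling cutoff by the cross-species subsampling:technical ratio.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .gower import DissimilarityMatrix, gd_matrix_from_states
from .synthetic_data import call_genotypes


class ThresholdError(ValueError):
    pass


@dataclass
class ReplicateGDSet:
    category: str  # biological | technical | subsampling
    gd_values: np.ndarray
    pair_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gd_values = np.asarray(self.gd_values, dtype=float)
        if (self.gd_values < 0).any():
            raise ThresholdError("negative GD in replicate set")


@dataclass
class ThresholdEstimate:
    category: str
    gd99: float
    method: str  # normal_percentile | empirical_percentile | extrapolated
    mean_gd: float = float("nan")
    sd_gd: float = float("nan")
    shapiro_W: float = float("nan")
    shapiro_p: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def replicate_gd_sets(dm: DissimilarityMatrix,
                      meta: pd.DataFrame) -> list[ReplicateGDSet]:
    """Pull replicate-pair GDs out of a dissimilarity matrix.

    Accessions sharing a non-empty ``replicate_group`` tag are replicates
    of one genotype; a pair sharing library and lane is biological,
    anything else technical.  Returns one pooled set per category present.
    """
    groups: dict[str, list[str]] = {}
    for acc, row in meta.iterrows():
        tag = row.get("replicate_group", "")
        if tag:
            groups.setdefault(str(tag), []).append(acc)
    values: dict[str, list[float]] = {"biological": [], "technical": []}
    labels: dict[str, list[tuple[str, str]]] = {"biological": [], "technical": []}
    for tag, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"replicate_group {tag!r} has a single member; skipped")
            continue
        for a, b in itertools.combinations(members, 2):
            same = (meta.loc[a, "library_id"] == meta.loc[b, "library_id"]
                    and meta.loc[a, "lane_id"] == meta.loc[b, "lane_id"])
            cat = "biological" if same else "technical"
            gd = dm.value(a, b)
            if np.isnan(gd):
                warnings.warn(f"replicate pair ({a}, {b}) has undefined GD; skipped")
                continue
            values[cat].append(gd)
            labels[cat].append((a, b))
    return [ReplicateGDSet(cat, np.array(values[cat]), labels[cat])
            for cat in ("biological", "technical") if values[cat]]


def subsample_depths(gm: GenotypeMatrix, accession: str, fraction: float = 0.5,
                     n_subsamples: int = 10, seed: int = 0,
                     min_call_depth: int = 6,
                     min_minor_reads: int = 3) -> list[np.ndarray]:
    """Replicate surrogate: binomially thin each allele's depth at ``fraction``
    (the with-replacement read-sampling approximation) and re-call.

    Returns ``n_subsamples`` dosage profiles for the accession.
    """
    i = gm.accession_index(accession)
    ref, alt = gm.ref_depth[i], gm.alt_depth[i]
    if (ref + alt).sum() == 0:
        raise ThresholdError(f"accession {accession!r} has no depth data")
    ploidy = int(gm.ploidy[i])
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_subsamples):
        if fraction >= 1.0:
            r, a = ref.copy(), alt.copy()
        else:
            r = rng.binomial(ref, fraction)
            a = rng.binomial(alt, fraction)
        d = call_genotypes(r, a, ploidy, min_call_depth, min_minor_reads)
        d[gm.dosage[i] == MISSING] = MISSING  # originally uncalled stays missing
        profiles.append(d)
    return profiles


def subsampling_gd_set(gm: GenotypeMatrix, accession: str, fraction: float = 0.5,
                       n_subsamples: int = 10, seed: int = 0,
                       **call_kwargs) -> ReplicateGDSet:
    """Pairwise collapsed-coding GDs among the sub-sample profiles
    (45 pairs for the default 10 sub-samples)."""
    profiles = subsample_depths(gm, accession, fraction, n_subsamples, seed,
                                **call_kwargs)
    ploidy = int(gm.ploidy[gm.accession_index(accession)])
    states = np.stack(profiles).astype(float)
    miss = states == MISSING
    states = np.where(states == 0, 0.0, np.where(states == ploidy, 1.0, 0.5))
    states[miss] = np.nan
    ids = [f"{accession}|sub{k+1}" for k in range(len(profiles))]
    dm = gd_matrix_from_states(states, ids)
    gds, labels = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        if not np.isnan(dm.gd[i, j]):
            gds.append(dm.gd[i, j])
            labels.append((ids[i], ids[j]))
    return ReplicateGDSet("subsampling", np.array(gds), labels)


Z_99 = float(stats.norm.ppf(0.99))  # 2.3263


def estimate_threshold(rset: ReplicateGDSet,
                       confidence: float = 0.99) -> ThresholdEstimate:
    """GD cutoff from a replicate GD distribution.

    Shapiro-Wilk p >= 0.05 -> one-sided normal percentile
    mean + z * sd; otherwise the empirical percentile at ``confidence``.
    """
    x = rset.gd_values
    if x.size < 3:
        raise ThresholdError(f"need >= 3 GD values, got {x.size}")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate replicate GD distribution (zero spread); "
                      "threshold equals the mean")
        return ThresholdEstimate(rset.category, gd99=mean, method="normal_percentile",
                                 mean_gd=mean, sd_gd=0.0)
    W, p = stats.shapiro(x)
    z = float(stats.norm.ppf(confidence))
    if p >= 0.05:
        gd99, method = mean + z * sd, "normal_percentile"
    else:
        gd99, method = float(np.quantile(x, confidence)), "empirical_percentile"
    return ThresholdEstimate(rset.category, gd99=float(gd99), method=method,
                             mean_gd=mean, sd_gd=sd,
                             shapiro_W=float(W), shapiro_p=float(p))


def extrapolate_threshold(readsample_gd99: float, ratio: float) -> ThresholdEstimate:
    """Threshold for a species without replicates: its read-subsampling
    GD_99% divided by the cross-species subsampling:technical ratio."""
    if not (0.0 < ratio <= 1.0):
        raise ThresholdError(f"ratio must lie in (0, 1], got {ratio}")
    return ThresholdEstimate("technical", gd99=float(readsample_gd99) / ratio,
                             method="extrapolated")


def estimate_ratio(per_species: Sequence[tuple[float, float]],
                   decimals: int | None = None) -> float:
    """Mean over species of (read-subsampling GD_99%) / (technical GD_99%)."""
    if not per_species:
        raise ThresholdError("need at least one species pair")
    ratios = []
    for sub99, tech99 in per_species:
        if tech99 == 0:
            raise ThresholdError("zero technical threshold in ratio estimate")
        ratios.append(sub99 / tech99)
    r = float(np.mean(ratios))
    return round(r, decimals) if decimals is not None else r
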