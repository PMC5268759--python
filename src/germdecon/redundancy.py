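"""Redundancy partitioning and collection-level reporting.

Accession pairs with GD at or below the GD_99% cutoff are joined by an
edge; connected components of that graph (single-linkage transitive
closure) with two or more members are redundancy groups, everything else
a singleton.  Each group gets a representative — the most read-abundant
member — and the partition feeds collection summaries (redundancy and
curation over-estimation percentages) plus passport-conflict flags:
usurpers (one name, several genotypes), synonyms (one genotype, several
names), and gender or species-label disagreement within a group.

Pairs with undefined GD are conservatively treated as distinct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .gower import DissimilarityMatrix


@dataclass
class RedundancyPartition:
    groups: list[set[str]]
    singletons: set[str]
    representatives: dict[int, str] = field(default_factory=dict)  # group index -> accession
    threshold_used: float = float("nan")
    max_intra_group_gd: float = float("nan")  # chaining diagnostic

    @property
    def n_unique(self) -> int:
        return len(self.groups) + len(self.singletons)

    @property
    def n_accessions(self) -> int:
        return sum(len(g) for g in self.groups) + len(self.singletons)

    def group_of(self, accession: str) -> set[str]:
        for g in self.groups:
            if accession in g:
                return g
        return {accession} if accession in self.singletons else set()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, g in enumerate(self.groups):
            rep = self.representatives.get(k, "")
            for a in sorted(g):
                rows.append(dict(accession_id=a, group=f"R{k+1:02d}",
                                 representative=rep, is_representative=a == rep))
        for a in sorted(self.singletons):
            rows.append(dict(accession_id=a, group="", representative=a,
                             is_representative=True))
        return pd.DataFrame(rows).set_index("accession_id")


@dataclass
class CollectionReport:
    n_analyzed: int
    n_unique: int
    redundancy_pct: float
    overestimation_pct: float
    conflict_flags: list["ConflictFlag"] = field(default_factory=list)


@dataclass
class ConflictFlag:
    kind: str  # usurper | synonym | gender_mismatch | species_mismatch
    detail: str
    accessions: list[str]


def redundancy_groups(dm: DissimilarityMatrix, gd99: float) -> RedundancyPartition:
    """Partition accessions at the given cutoff (connected components of
    the gd <= gd99 graph); undefined pairs contribute no edge."""
    if not np.isfinite(gd99):
        raise ValueError(f"threshold must be finite, got {gd99}")
    n = dm.n
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(dm.gd, nan=np.inf) <= gd99
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, set[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(dm.ids[i])
    multi = sorted((g for g in groups.values() if len(g) >= 2),
                   key=lambda g: min(g))
    singles = {next(iter(g)) for g in groups.values() if len(g) == 1}
    max_intra = float("nan")
    intra = [dm.value(a, b) for g in multi for a, b in itertools.combinations(sorted(g), 2)]
    intra = [v for v in intra if not np.isnan(v)]
    if intra:
        max_intra = float(max(intra))
    return RedundancyPartition(multi, singles, threshold_used=float(gd99),
                               max_intra_group_gd=max_intra)


def choose_representatives(partition: RedundancyPartition,
                           meta: pd.DataFrame) -> RedundancyPartition:
    """Representative = most read-abundant member (ties and missing read
    counts fall back to the lexicographically smallest accession id)."""
    reps = {}
    have_reads = "total_pe_reads" in meta.columns
    for k, group in enumerate(partition.groups):
        members = sorted(group)
        if have_reads:
            reads = meta.loc[members, "total_pe_reads"].fillna(0).to_numpy(dtype=np.int64)
            best = int(np.max(reads))
            candidates = [m for m, r in zip(members, reads) if r == best]
        else:
            import warnings
            warnings.warn("no read counts in passport; representatives chosen lexicographically")
            candidates = members
        reps[k] = min(candidates)
    partition.representatives = reps
    return partition


def collection_summary(n_analyzed: int, n_unique: int) -> CollectionReport:
    """Redundancy percentage 100*(N - U)/N and curation over-estimation
    100*(N/U - 1) for N analyzed vs U unique genotypes."""
    if not (1 <= n_unique <= n_analyzed):
        raise ValueError(f"need 1 <= n_unique <= n_analyzed, got {n_unique}/{n_analyzed}")
    return CollectionReport(
        n_analyzed=n_analyzed,
        n_unique=n_unique,
        redundancy_pct=100.0 * (n_analyzed - n_unique) / n_analyzed,
        overestimation_pct=100.0 * (n_analyzed / n_unique - 1.0),
    )


def flag_conflicts(partition: RedundancyPartition,
                   meta: pd.DataFrame) -> list[ConflictFlag]:
    """Passport conflicts exposed by the genotype partition."""
    flags: list[ConflictFlag] = []
    unit_of: dict[str, int] = {}
    for k, g in enumerate(partition.groups):
        for a in g:
            unit_of[a] = k
    for j, a in enumerate(sorted(partition.singletons)):
        unit_of[a] = len(partition.groups) + j

    # usurpers: one display name spanning different genetic units
    by_name: dict[str, list[str]] = {}
    for a in unit_of:
        name = str(meta.loc[a, "display_name"]) if a in meta.index else a
        by_name.setdefault(name, []).append(a)
    for name, accs in sorted(by_name.items()):
        units = {unit_of[a] for a in accs}
        if len(units) > 1:
            flags.append(ConflictFlag(
                "usurper",
                f"name {name!r} is shared by {len(units)} distinct genotypes",
                sorted(accs)))

    for k, g in enumerate(partition.groups):
        members = sorted(g)
        names = {str(meta.loc[a, "display_name"]) for a in members if a in meta.index}
        if len(names) > 1:
            flags.append(ConflictFlag(
                "synonym",
                f"group {k+1} holds one genotype under names {sorted(names)}",
                members))
        genders = {str(meta.loc[a, "observed_gender"]) for a in members if a in meta.index}
        genders |= {str(meta.loc[a, "reported_gender"]) for a in members if a in meta.index}
        genders.discard("unknown")
        if len(genders) > 1:
            flags.append(ConflictFlag(
                "gender_mismatch",
                f"group {k+1} mixes gender records {sorted(genders)}",
                members))
        species = {str(meta.loc[a, "species_label"]) for a in members if a in meta.index}
        species.discard("unknown")
        if len(species) > 1:
            flags.append(ConflictFlag(
                "species_mismatch",
                f"group {k+1} mixes species labels {sorted(species)}",
                members))
    return flags


def curation_shortlist(partition: RedundancyPartition) -> list[str]:
    """One representative per unique genotype."""
    reps = [partition.representatives.get(k, min(g))
            for k, g in enumerate(partition.groups)]
    return sorted(reps + sorted(partition.singletons))
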