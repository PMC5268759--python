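"""Synthetic germplasm collections with planted structure.

Generates a :class:`~germdecon.genotypes.GenotypeMatrix` with known ground
truth so every pipeline stage (ploidy inference, Gower dissimilarity,
redundancy thresholds, clustering, AMOVA) can be exercised offline:

* sub-populations diverged from a common ancestral allele-frequency pool
  by a Balding-Nichols draw parameterized by F_ST;
* founder genotypes with ploidy 2, 4, or 6 and binomially drawn dosages;
* clonal accession copies of founders, re-sampled through a replicate-error
  channel whose magnitude depends on library placement: copies prepared
  within one GBS library ("biological" replicates) perturb calls at the
  intra-library rate, copies split across libraries ("technical"
  replicates) at the larger inter-library rate;
* negative-binomial per-cell read depths with binomial allele-depth splits
  (so heterozygous depth ratios concentrate at the dosage fractions), and
  an explicit missing-call channel.

Replicate error is modeled post-call as a dosage perturbation, which makes
the channel directly calibratable against empirically observed replicate
dissimilarities (biological GD of order 1e-4..1e-3, technical GD roughly
6-7x larger).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, _default_snps

_LIBRARIES = ["L1", "L2", "L3"]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the collection generator; all rates are probabilities in [0,1].

    ``intra_library_miscall`` / ``inter_library_miscall`` are per-call
    genotype perturbation probabilities for biological vs technical
    replicate copies; their defaults put mean replicate dissimilarities at
    the magnitudes observed for GBS replicates (ratio 6.4).
    """

    n_subpops: int = 3
    fst: float = 0.15
    n_genotypes_per_subpop: int = 10
    clone_copies: Mapping[str, int] | None = None
    ploidy_map: Mapping[str, int] | None = None
    default_ploidy: int = 4
    n_snps: int = 2000
    mean_depth: float = 40.0
    depth_dispersion: float = 5.0
    seq_error_rate: float = 0.005
    intra_library_miscall: float = 0.0005
    inter_library_miscall: float = 0.0032
    missing_rate: float = 0.065
    diploidized_fraction: float = 0.13
    min_call_depth: int = 6
    min_minor_reads: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise SimulationError(f"fst must lie in (0,1), got {self.fst}")
        for name in ("seq_error_rate", "intra_library_miscall",
                     "inter_library_miscall", "missing_rate", "diploidized_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must lie in [0,1], got {v}")
        if self.seed is None:
            raise SimulationError("seed is mandatory for reproducibility")


@dataclass
class SimulationTruth:
    """Planted ground truth for parameter-recovery tests."""

    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray  # (n_subpops, n_snps)
    genotype_subpop: dict[str, int]
    clone_map: dict[str, str]  # accession_id -> founder genotype id
    ploidies: dict[str, int]
    diploidized_snp_ids: list[str] = field(default_factory=list)

    def clone_partition(self) -> dict[str, set[str]]:
        """Founder -> set of accession ids (the true redundancy partition)."""
        part: dict[str, set[str]] = {}
        for acc, g in self.clone_map.items():
            part.setdefault(g, set()).add(acc)
        return part

    def write_json(self, path: str | Path) -> None:
        payload = {
            "genotype_subpop": self.genotype_subpop,
            "clone_map": self.clone_map,
            "ploidies": self.ploidies,
            "diploidized_snp_ids": self.diploidized_snp_ids,
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "subpop_freqs": self.subpop_freqs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def call_genotypes(ref_depth, alt_depth, ploidy: int, min_call_depth: int = 6,
                   min_minor_reads: int = 3):
    """Depth-ratio genotype caller: dosage = round(ploidy * alt/total).

    Total depth below ``min_call_depth`` gives a missing call.  A
    heterozygous call additionally requires ``min_minor_reads`` reads of
    each allele, else it is rounded to the nearer homozygote.  Accepts
    scalars or arrays; returns int dosage(s) with -1 for missing.
    """
    if ploidy < 2:
        raise ValueError(f"ploidy must be >= 2, got {ploidy}")
    ref = np.asarray(ref_depth, dtype=np.int64)
    alt = np.asarray(alt_depth, dtype=np.int64)
    scalar = ref.ndim == 0
    ref, alt = np.atleast_1d(ref), np.atleast_1d(alt)
    total = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    dosage = np.clip(np.rint(ploidy * ratio).astype(np.int16), 0, ploidy)
    het = (dosage > 0) & (dosage < ploidy)
    weak = het & ((ref < min_minor_reads) | (alt < min_minor_reads))
    # nearer homozygote by depth ratio
    dosage[weak] = np.where(ratio[weak] >= 0.5, ploidy, 0)
    dosage[total < min_call_depth] = MISSING
    return int(dosage[0]) if scalar else dosage


def _perturb_dosage(dosage: np.ndarray, ploidy: int, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Replicate-error channel: with probability ``rate`` move a call by
    one dosage step (reflecting at 0 and ploidy)."""
    out = dosage.copy()
    hit = rng.random(out.shape) < rate
    if not hit.any():
        return out
    step = np.where(rng.random(out.shape) < 0.5, -1, 1)
    step = np.where(out == 0, 1, np.where(out == ploidy, -1, step))
    out[hit] = out[hit] + step[hit]
    return out


def simulate_collection(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a collection under ``cfg``; returns the matrix and its truth.

    Founder ids are ``G001``...; accession ids ``G001.1``, ``G001.2``...
    Founders with >= 2 copies alternate between biological replicate sets
    (all copies in the founder's home library) and technical sets (copies
    spread over libraries); ``replicate_group`` tags tie the copies back
    to one genotype.
    """
    rng = np.random.default_rng(cfg.seed)
    M = cfg.n_snps
    S = cfg.n_subpops
    founders = [f"G{k+1:03d}" for k in range(S * cfg.n_genotypes_per_subpop)]
    subpop_of = {g: k % S for k, g in enumerate(founders)}
    clone_copies = dict(cfg.clone_copies or {})
    for g in clone_copies:
        if g not in subpop_of:
            raise SimulationError(f"clone map references unknown founder {g!r}")
    ploidy_map = dict(cfg.ploidy_map or {})
    ploidies = {g: int(ploidy_map.get(g, cfg.default_ploidy)) for g in founders}

    # allele frequencies: ancestral pool + Balding-Nichols subpop draws
    p_anc = rng.uniform(0.05, 0.95, size=M)
    F = cfg.fst
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    subpop_freqs = np.stack([rng.beta(a, b) for _ in range(S)])

    diploidized = np.zeros(M, dtype=bool)
    n_dip = int(round(cfg.diploidized_fraction * M))
    if n_dip:
        diploidized[rng.choice(M, size=n_dip, replace=False)] = True

    founder_dosage: dict[str, np.ndarray] = {}
    for g in founders:
        p = subpop_freqs[subpop_of[g]]
        pl = ploidies[g]
        d = rng.binomial(pl, p).astype(np.int16)
        if pl > 2:
            # diploidized markers segregate within a single sub-genome:
            # at most two variable copies, the rest fixed reference
            d[diploidized] = rng.binomial(2, p[diploidized]).astype(np.int16)
        founder_dosage[g] = d

    # replicate sets: alternate biological / technical among cloned founders
    cloned = sorted(g for g, c in clone_copies.items() if c >= 2)
    technical = {g for k, g in enumerate(cloned) if k % 2 == 1}

    acc_rows = []
    dosage_rows, ref_rows, alt_rows = [], [], []
    clone_map: dict[str, str] = {}
    acc_ploidies: dict[str, int] = {}
    for k, g in enumerate(founders):
        home = _LIBRARIES[k % len(_LIBRARIES)]
        copies = max(1, int(clone_copies.get(g, 1)))
        for c in range(copies):
            acc = f"{g}.{c+1}"
            pl = ploidies[g]
            if g in technical:
                lib = _LIBRARIES[(k + c) % len(_LIBRARIES)]
                rate = cfg.inter_library_miscall
            else:
                lib = home
                rate = cfg.intra_library_miscall
            d = _perturb_dosage(founder_dosage[g], pl, rate, rng)
            # depths consistent with the call
            total = rng.negative_binomial(
                cfg.depth_dispersion,
                cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth),
                size=M,
            )
            total = np.maximum(total, cfg.min_call_depth)
            f = d / pl
            e = cfg.seq_error_rate
            alt = rng.binomial(total, f * (1 - e) + (1 - f) * e)
            ref = total - alt
            miss = rng.random(M) < cfg.missing_rate
            d = d.copy()
            d[miss] = MISSING
            ref, alt = ref.copy(), alt.copy()
            ref[miss] = 0
            alt[miss] = 0
            acc_rows.append(
                dict(accession_id=acc, display_name=acc, species_label="synthetic",
                     library_id=lib, lane_id=lib[-1],
                     total_pe_reads=int(rng.integers(1_000_000, 8_000_000)),
                     reported_gender=rng.choice(["female", "male"]),
                     observed_gender="unknown", ploidy=pl,
                     replicate_group=g if copies >= 2 else "")
            )
            dosage_rows.append(d)
            ref_rows.append(ref)
            alt_rows.append(alt)
            clone_map[acc] = g
            acc_ploidies[acc] = pl

    meta = pd.DataFrame(acc_rows).set_index("accession_id")
    snp_ids = [f"snp{j+1:05d}" for j in range(M)]
    snps = _default_snps(snp_ids)
    gm = GenotypeMatrix(np.stack(dosage_rows), np.stack(ref_rows), np.stack(alt_rows),
                        meta, snps)
    truth = SimulationTruth(
        ancestral_freqs=p_anc,
        subpop_freqs=subpop_freqs,
        genotype_subpop=subpop_of,
        clone_map=clone_map,
        ploidies=acc_ploidies,
        diploidized_snp_ids=[snp_ids[j] for j in np.flatnonzero(diploidized)],
    )
    return gm, truth
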