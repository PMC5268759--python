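"""End-to-end deconvolution pipeline.

Config-driven orchestration of the full workflow per species partition:
load -> ploidy inference -> GD matrix -> replicate thresholds ->
redundancy partition + conflict flags -> culled representative set ->
linkage-method selection -> bootstrap-supported tree -> PCA -> K
selection -> AMOVA -> diversity.  Every stage writes its table/tree under
the output directory and a top-level JSON summary collects the headline
numbers; all stochastic steps derive from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, gower, ploidy, popgen, redundancy, thresholds
from .genotypes import GenotypeMatrix, read_genotype_table, read_passport, read_vcf

log = logging.getLogger("germdecon")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genotype_path: str = ""
    genotype_format: str = "vcf"  # vcf | table
    passport_path: str | None = None
    simplex_only: bool = False
    species_column: str = "species_label"
    coding: str = "collapsed"
    confidence: float = 0.99
    subsample_fraction: float = 0.5
    n_subsamples: int = 10
    paper_compat_ratio: float | None = None  # fixed subsampling:technical ratio
    linkage_methods: Sequence[str] = clustering.METHODS
    ccc_bootstraps: int = 100
    support_bootstraps: int = 200
    k_range: Sequence[int] = tuple(range(2, 11))
    amova_permutations: int = 999
    min_maf: float = 0.0
    max_missing: float = 1.0
    seed: int = 0
    out_dir: str = "germdecon_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.genotype_path:
            raise PipelineError("config key 'genotype_path' is required")
        if not Path(self.genotype_path).exists():
            raise PipelineError(f"genotype_path does not exist: {self.genotype_path}")
        if self.passport_path and not Path(self.passport_path).exists():
            raise PipelineError(f"passport_path does not exist: {self.passport_path}")


def load_collection(cfg: PipelineConfig) -> GenotypeMatrix:
    passport = read_passport(cfg.passport_path) if cfg.passport_path else None
    if cfg.genotype_format == "vcf":
        return read_vcf(cfg.genotype_path, passport)
    if cfg.genotype_format == "table":
        return read_genotype_table(cfg.genotype_path, passport,
                                   simplex_only=cfg.simplex_only)
    raise PipelineError(f"unknown genotype_format {cfg.genotype_format!r}")


def _threshold_for(gm: GenotypeMatrix, dm: gower.DissimilarityMatrix,
                   cfg: PipelineConfig, seed: int) -> thresholds.ThresholdEstimate:
    """Technical-replicate threshold when replicates exist, else a
    read-subsampling threshold (extrapolated when a compat ratio is set)."""
    sets = thresholds.replicate_gd_sets(dm, gm.accessions)
    by_cat = {s.category: s for s in sets}
    for cat in ("technical", "biological"):
        if cat in by_cat and by_cat[cat].gd_values.size >= 3:
            est = thresholds.estimate_threshold(by_cat[cat], cfg.confidence)
            log.info("threshold from %s replicates: gd99=%.5f (%s)",
                     cat, est.gd99, est.method)
            return est
    # no replicates: subsample the most read-abundant accession
    acc = gm.accessions["total_pe_reads"].idxmax()
    rset = thresholds.subsampling_gd_set(gm, acc, cfg.subsample_fraction,
                                         cfg.n_subsamples, seed)
    est = thresholds.estimate_threshold(rset, cfg.confidence)
    if cfg.paper_compat_ratio:
        est = thresholds.extrapolate_threshold(est.gd99, cfg.paper_compat_ratio)
    log.info("threshold from read subsampling of %s: gd99=%.5f (%s)",
             acc, est.gd99, est.method)
    return est


def run_deconvolution(cfg: PipelineConfig,
                      gm: GenotypeMatrix | None = None) -> dict:
    """Run the whole pipeline per species; returns the summary dict.

    A pre-built matrix may be passed directly (e.g. from the simulator),
    bypassing file input.
    """
    cfg_out = Path(cfg.out_dir)
    cfg_out.mkdir(parents=True, exist_ok=True)
    if gm is None:
        cfg.validate()
        gm = load_collection(cfg)
    summary: dict = {"seed": cfg.seed, "species": {}}
    species = sorted(set(gm.accessions[cfg.species_column]))
    for sp in species:
        try:
            summary["species"][sp] = _run_species(gm, sp, cfg, cfg_out / str(sp))
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise PipelineError(f"stage failure in species {sp!r}: {exc}") from exc
    (cfg_out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run_species(gm_all: GenotypeMatrix, sp: str, cfg: PipelineConfig,
                 out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    ids = [a for a in gm_all.accession_ids
           if gm_all.accessions.loc[a, cfg.species_column] == sp]
    gm = gm_all.select_accessions(ids)
    res: dict = {"n_analyzed": gm.n_accessions, "n_snps": gm.n_snps}

    # ploidy
    calls = ploidy.call_ploidy_all(gm)
    gcfg = gower.GowerConfig(cfg.coding)
    dm = gower.gd_matrix(gm, gcfg)
    dm.write_dual_triangle_csv(out / "gd_dual_triangle.csv")
    undef = int(np.isnan(dm.gd[np.triu_indices(dm.n, 1)]).sum())
    if undef:
        log.warning("%d undefined GD pairs in %s", undef, sp)
    res["n_undefined_pairs"] = undef

    est = _threshold_for(gm, dm, cfg, cfg.seed)
    pd.DataFrame([est.to_dict()]).to_csv(out / "threshold.csv", index=False)
    part = redundancy.redundancy_groups(dm, est.gd99)
    part = redundancy.choose_representatives(part, gm.accessions)
    part.to_frame().to_csv(out / "redundancy_partition.csv")
    calls = ploidy.annotate_from_redundancy(calls, part.groups)
    ploidy.ploidy_table(calls).to_csv(out / "ploidy_calls.csv")
    flags = redundancy.flag_conflicts(part, gm.accessions)
    pd.DataFrame([f.__dict__ for f in flags]).to_csv(out / "conflicts.csv", index=False)
    report = redundancy.collection_summary(gm.n_accessions, part.n_unique)
    res.update(n_unique=part.n_unique,
               redundancy_pct=round(report.redundancy_pct, 1),
               overestimation_pct=round(report.overestimation_pct, 1),
               gd99=est.gd99, threshold_method=est.method,
               n_conflict_flags=len(flags))

    # culled set
    reps = redundancy.curation_shortlist(part)
    culled = gm.select_accessions(reps)
    if culled.n_accessions < 3:
        log.info("species %s: too few unique genotypes for structure analysis", sp)
        return res

    sel = clustering.select_linkage_method(culled, gcfg,
                                           methods=cfg.linkage_methods,
                                           n_boot=cfg.ccc_bootstraps, seed=cfg.seed)
    pd.DataFrame({"method": sel.methods,
                  "mean_ccc": [sel.mean_ccc[m] for m in sel.methods],
                  "sd_ccc": [sel.sd_ccc[m] for m in sel.methods]}
                 ).to_csv(out / "linkage_ccc.csv", index=False)
    stree = clustering.bootstrap_support(culled, gcfg, sel.winner,
                                         n_boot=cfg.support_bootstraps, seed=cfg.seed)
    (out / "tree.nwk").write_text(stree.tree.to_newick(stree.support) + "\n")
    res["linkage_method"] = sel.winner

    pca = popgen.pca_genotypes(culled)
    pca.to_frame().to_csv(out / "pca_scores.csv")
    res["pc1_pct"] = round(float(pca.pct_variance[0]), 2)
    kmax = min(max(cfg.k_range), culled.n_accessions - 1)
    krange = [k for k in cfg.k_range if k <= kmax]
    ksel = popgen.select_k_bic(pca, krange, seed=cfg.seed)
    res["chosen_k"] = ksel.chosen_k
    pd.DataFrame({"K": ksel.k_values,
                  "BIC": [ksel.bic[k] for k in ksel.k_values]}
                 ).to_csv(out / "bic.csv", index=False)

    if ksel.chosen_k >= 2:
        grouping = {a: f"K{v}" for a, v in ksel.assignments.items()}
        sizes = pd.Series(list(grouping.values())).value_counts()
        if (sizes >= 2).sum() >= 2:
            table = popgen.amova(culled, grouping,
                                 n_perm=cfg.amova_permutations, seed=cfg.seed)
            table.to_frame().to_csv(out / "amova.csv")
            res["fst"] = round(table.fst, 4)
            res["amova_within_pct"] = round(table.within_genotypes.var_pct, 1)
    div = popgen.diversity_stats(culled)
    pd.DataFrame([div.to_dict()]).to_csv(out / "diversity.csv", index=False)
    res["h_e"] = round(div.h_e, 3)
    res["f_is"] = round(div.f_is, 3)
    return res
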