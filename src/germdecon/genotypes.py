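"""Genotype-matrix data model and I/O.

The central object is :class:`GenotypeMatrix`: N accessions x M bi-allelic
SNPs, each cell carrying an alternate-allele dosage call (0..ploidy, or
missing) plus reference/alternate read depths.  Dosage divided by ploidy
("dosage fraction") is the universal genotype coordinate used downstream,
which keeps diploid, tetraploid, and hexaploid accessions on one scale.

Supported formats: VCF 4.x with per-sample GT and AD fields (read via
pysam, written as uncompressed text), and a documented TSV "genotype
table" dialect (one row per SNP, per-accession cells ``dosage:ref:alt``).
Accession passport metadata (species, library, lane, read counts,
replicate tags, gender) rides along as a pandas DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1

#: passport columns guaranteed to exist on GenotypeMatrix.accessions
META_COLUMNS = [
    "display_name",
    "species_label",
    "library_id",
    "lane_id",
    "total_pe_reads",
    "reported_gender",
    "observed_gender",
    "ploidy",
    "replicate_group",
]

SNP_COLUMNS = ["centroid_id", "position", "ref_allele", "alt_allele", "snps_in_centroid"]


class GenotypeDataError(ValueError):
    """Malformed or inconsistent genotype input."""


def _default_meta(accession_ids: Sequence[str], ploidy: int | Sequence[int] = 2) -> pd.DataFrame:
    n = len(accession_ids)
    ploidies = np.full(n, ploidy) if np.isscalar(ploidy) else np.asarray(ploidy)
    return pd.DataFrame(
        {
            "display_name": list(accession_ids),
            "species_label": ["unknown"] * n,
            "library_id": ["L1"] * n,
            "lane_id": ["1"] * n,
            "total_pe_reads": np.zeros(n, dtype=np.int64),
            "reported_gender": ["unknown"] * n,
            "observed_gender": ["unknown"] * n,
            "ploidy": ploidies.astype(np.int64),
            "replicate_group": [""] * n,
        },
        index=pd.Index(accession_ids, name="accession_id"),
    )


def _default_snps(snp_ids: Sequence[str]) -> pd.DataFrame:
    m = len(snp_ids)
    return pd.DataFrame(
        {
            "centroid_id": list(snp_ids),
            "position": np.arange(1, m + 1, dtype=np.int64),
            "ref_allele": ["A"] * m,
            "alt_allele": ["T"] * m,
            "snps_in_centroid": np.ones(m, dtype=np.int64),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


@dataclass
class CollectionSummary:
    """Table-1-style summary of a genotype matrix."""

    n_accessions: int
    n_snps: int
    mean_depth: float
    pct_depth_gt20: float
    pct_het: float
    pct_hom: float
    pct_missing: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage calls with allele depths.

    Attributes
    ----------
    dosage
        ``(N, M)`` int array of alternate-allele counts; ``MISSING`` (-1)
        marks cells without an assigned genotype.
    ref_depth, alt_depth
        ``(N, M)`` non-negative read-depth arrays.
    accessions
        passport DataFrame indexed by accession_id with META_COLUMNS.
    snps
        SNP DataFrame indexed by snp_id with SNP_COLUMNS.
    """

    dosage: np.ndarray
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    accessions: pd.DataFrame
    snps: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int32)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int32)
        if self.snps is None:
            self.snps = _default_snps([f"snp{j+1}" for j in range(self.dosage.shape[1])])
        if isinstance(self.accessions, (list, tuple)):
            self.accessions = _default_meta(list(self.accessions))
        n, m = self.dosage.shape
        if len(self.accessions) != n or len(self.snps) != m:
            raise GenotypeDataError(
                f"grid is {n}x{m} but metadata lists {len(self.accessions)} "
                f"accessions and {len(self.snps)} SNPs"
            )
        if self.ref_depth.shape != (n, m) or self.alt_depth.shape != (n, m):
            raise GenotypeDataError("depth grids must match the dosage grid shape")
        if not self.accessions.index.is_unique:
            raise GenotypeDataError("accession_id values must be unique")
        pl = self.ploidy[:, None]
        ok = self.dosage[self.dosage >= 0] <= np.broadcast_to(pl, self.dosage.shape)[self.dosage >= 0]
        if not np.all(ok):
            raise GenotypeDataError("dosage exceeds accession ploidy")

    # -- basic accessors -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def accession_ids(self) -> list[str]:
        return list(self.accessions.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def ploidy(self) -> np.ndarray:
        return self.accessions["ploidy"].to_numpy(dtype=np.int64)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def het_mask(self) -> np.ndarray:
        """Heterozygote = 0 < dosage < ploidy."""
        pl = self.ploidy[:, None]
        return (self.dosage > 0) & (self.dosage < pl)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def dosage_fraction(self) -> np.ndarray:
        """(N, M) float matrix of dosage/ploidy with NaN at missing cells."""
        f = self.dosage / self.ploidy[:, None]
        f[self.missing_mask] = np.nan
        return f

    def accession_index(self, accession_id: str) -> int:
        try:
            return int(self.accessions.index.get_loc(accession_id))
        except KeyError:
            raise KeyError(f"unknown accession {accession_id!r}") from None

    # -- subsetting ------------------------------------------------------
    def select_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accession_index(a) for a in ids]
        return GenotypeMatrix(
            self.dosage[idx], self.ref_depth[idx], self.alt_depth[idx],
            self.accessions.iloc[idx].copy(), self.snps.copy(),
        )

    def select_snps(self, snp_ids: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(snp_ids, np.ndarray) and snp_ids.dtype == bool:
            mask = snp_ids
        else:
            wanted = set(snp_ids)
            mask = np.array([s in wanted for s in self.snps.index])
        return GenotypeMatrix(
            self.dosage[:, mask], self.ref_depth[:, mask], self.alt_depth[:, mask],
            self.accessions.copy(), self.snps.loc[mask].copy(),
        )


# ---------------------------------------------------------------------------
# passport

def read_passport(path: str | Path) -> pd.DataFrame:
    """Read an accession passport CSV (S1-Table-style column semantics)."""
    df = pd.read_csv(path, dtype={"accession_id": str})
    if "accession_id" not in df.columns:
        raise GenotypeDataError("passport table needs an 'accession_id' column")
    df = df.set_index("accession_id")
    for col in META_COLUMNS:
        if col not in df.columns:
            df[col] = {"total_pe_reads": 0, "ploidy": 0}.get(col, "")
    df["replicate_group"] = df["replicate_group"].fillna("")
    return df[META_COLUMNS]


def _merge_passport(meta: pd.DataFrame, passport: pd.DataFrame | None, strict: bool) -> pd.DataFrame:
    if passport is None:
        return meta
    unknown = [a for a in meta.index if a not in passport.index]
    if unknown:
        msg = f"samples absent from passport: {unknown}"
        if strict:
            raise GenotypeDataError(msg)
        warnings.warn(msg)
    for col in META_COLUMNS:
        have = [a for a in meta.index if a in passport.index]
        if have:
            vals = passport.loc[have, col]
            meta.loc[have, col] = vals.values
    meta["ploidy"] = pd.to_numeric(meta["ploidy"]).astype(np.int64)
    meta["total_pe_reads"] = pd.to_numeric(meta["total_pe_reads"]).astype(np.int64)
    return meta


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, passport: pd.DataFrame | None = None,
             strict: bool = False) -> GenotypeMatrix:
    """Read a VCF with per-sample GT (any ploidy) and AD into a GenotypeMatrix.

    Dosage is the count of non-reference alleles in GT (``0/0/0/1`` -> 1 of
    ploidy 4); a missing GT becomes a missing call.  Multi-allelic records
    are rejected in strict mode, otherwise reduced to the most-supported
    alternate allele with a warning (calls carrying other alternates become
    missing).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    dosages: list[np.ndarray] = []
    refs: list[np.ndarray] = []
    alts: list[np.ndarray] = []
    snp_rows = []
    ploidy = np.zeros(len(samples), dtype=np.int64)
    warned_multi = False
    for rec in vf:
        alt_alleles = rec.alts or ()
        if len(alt_alleles) != 1:
            if strict:
                raise GenotypeDataError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            if len(alt_alleles) == 0:
                continue
            if not warned_multi:
                warnings.warn("multi-allelic records reduced to the major alternate allele")
                warned_multi = True
            ad_all = np.array([
                (rec.samples[s].get("AD") or (0,) * (len(alt_alleles) + 1))
                for s in samples
            ], dtype=float)
            ad_all = np.nan_to_num(ad_all)
            keep_alt = int(np.argmax(ad_all[:, 1:].sum(axis=0))) + 1
        else:
            keep_alt = 1
        d = np.full(len(samples), MISSING, dtype=np.int16)
        r = np.zeros(len(samples), dtype=np.int32)
        a = np.zeros(len(samples), dtype=np.int32)
        for k, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is not None and None not in gt and len(gt) > 0:
                if any(g not in (0, keep_alt) for g in gt):
                    d[k] = MISSING  # call involves a dropped alternate
                else:
                    d[k] = sum(1 for g in gt if g == keep_alt)
                ploidy[k] = max(ploidy[k], len(gt))
            ad = call.get("AD")
            if ad is not None:
                ad = [0 if x is None else x for x in ad]
                r[k] = ad[0]
                a[k] = ad[keep_alt] if len(ad) > keep_alt else 0
        dosages.append(d)
        refs.append(r)
        alts.append(a)
        snp_id = rec.id or f"{rec.chrom}_{rec.pos}"
        try:
            nsc = int(rec.info["NSC"])
        except (KeyError, ValueError):
            nsc = 1
        snp_rows.append(
            dict(snp_id=snp_id, centroid_id=rec.chrom, position=rec.pos,
                 ref_allele=rec.ref, alt_allele=alt_alleles[keep_alt - 1],
                 snps_in_centroid=nsc)
        )
    vf.close()
    if not snp_rows:
        raise GenotypeDataError(f"no usable biallelic records in {path}")
    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    ploidy[ploidy == 0] = 2
    meta = _default_meta(samples, ploidy)
    meta = _merge_passport(meta, passport, strict)
    return GenotypeMatrix(
        np.stack(dosages, axis=1), np.stack(refs, axis=1), np.stack(alts, axis=1),
        meta, snps,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT and AD (round-trips with read_vcf)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=NSC,Number=1,Type=Integer,Description="SNPs in source centroid">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for c in pd.unique(gm.snps["centroid_id"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        pl = gm.ploidy
        for j, (snp_id, row) in enumerate(gm.snps.iterrows()):
            pos = int(row["position"]) if pd.notna(row["position"]) else j + 1
            cells = []
            for i in range(gm.n_accessions):
                d = gm.dosage[i, j]
                if d == MISSING:
                    gt = "/".join(["."] * pl[i])
                else:
                    gt = "/".join(["0"] * (pl[i] - d) + ["1"] * d)
                cells.append(f"{gt}:{gm.ref_depth[i, j]},{gm.alt_depth[i, j]}")
            fh.write(
                f"{row['centroid_id']}\t{pos}\t{snp_id}\t{row['ref_allele']}\t"
                f"{row['alt_allele']}\t.\tPASS\tNSC={int(row['snps_in_centroid'])}\t"
                "GT:AD\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV genotype-table dialect

TABLE_FIXED = ["snp_id", "centroid_id", "position", "ref_allele", "alt_allele", "snps_in_centroid"]


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect: fixed SNP columns then one ``dosage:ref:alt``
    cell per accession (``.`` for a missing dosage)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_FIXED + gm.accession_ids) + "\n")
        for j, (snp_id, row) in enumerate(gm.snps.iterrows()):
            cells = []
            for i in range(gm.n_accessions):
                d = gm.dosage[i, j]
                ds = "." if d == MISSING else str(int(d))
                cells.append(f"{ds}:{gm.ref_depth[i, j]}:{gm.alt_depth[i, j]}")
            fixed = [snp_id, row["centroid_id"], str(int(row["position"])),
                     row["ref_allele"], row["alt_allele"], str(int(row["snps_in_centroid"]))]
            fh.write("\t".join(fixed + cells) + "\n")


def read_genotype_table(path: str | Path, passport: pd.DataFrame | None = None,
                        simplex_only: bool = False, strict: bool = False) -> GenotypeMatrix:
    """Read the TSV genotype-table dialect (see :func:`write_genotype_table`).

    With ``simplex_only`` SNPs from multi-SNP centroids are dropped, keeping
    only markers that are the lone polymorphism on their GBS fragment.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(TABLE_FIXED)] != TABLE_FIXED:
            raise GenotypeDataError("genotype table header does not match the documented dialect")
        acc_ids = header[len(TABLE_FIXED):]
        if len(set(acc_ids)) != len(acc_ids):
            raise GenotypeDataError("duplicate accession column name in genotype table")
        snp_rows, dosages, refs, alts = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeDataError(f"line {lineno}: expected {len(header)} columns, got {len(parts)}")
            nsc = int(parts[5])
            if simplex_only and nsc > 1:
                continue
            d = np.empty(len(acc_ids), dtype=np.int16)
            r = np.empty(len(acc_ids), dtype=np.int32)
            a = np.empty(len(acc_ids), dtype=np.int32)
            for k, cell in enumerate(parts[len(TABLE_FIXED):]):
                try:
                    ds, rs, as_ = cell.split(":")
                except ValueError:
                    raise GenotypeDataError(f"line {lineno}: malformed cell {cell!r}") from None
                d[k] = MISSING if ds == "." else int(ds)
                r[k], a[k] = int(rs), int(as_)
            snp_rows.append(dict(snp_id=parts[0], centroid_id=parts[1], position=int(parts[2]),
                                 ref_allele=parts[3], alt_allele=parts[4], snps_in_centroid=nsc))
            dosages.append(d)
            refs.append(r)
            alts.append(a)
    if not snp_rows:
        raise GenotypeDataError("no SNP rows retained from genotype table")
    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    dos = np.stack(dosages, axis=1)
    ploidy = np.maximum(dos.max(axis=1), 2)
    # even ploidy convention: odd maxima round up (dosage <= ploidy still holds)
    ploidy = ploidy + (ploidy % 2)
    meta = _default_meta(acc_ids, ploidy)
    meta = _merge_passport(meta, passport, strict)
    return GenotypeMatrix(dos, np.stack(refs, axis=1), np.stack(alts, axis=1), meta, snps)


# ---------------------------------------------------------------------------
# summaries and filters

def summarize_collection(gm: GenotypeMatrix, depth_cut: int = 20) -> CollectionSummary:
    """Percent het/hom/missing over all cells, mean depth over non-missing
    cells, and the share of SNPs with mean depth >= ``depth_cut``."""
    n_cells = gm.dosage.size
    if n_cells == 0:
        raise GenotypeDataError("empty genotype matrix")
    miss = gm.missing_mask
    het = gm.het_mask
    hom = (~miss) & (~het)
    pct_missing = 100.0 * miss.sum() / n_cells
    if miss.all():
        raise GenotypeDataError("all cells missing: mean depth undefined")
    depth = gm.total_depth.astype(float)
    mean_depth = float(depth[~miss].mean())
    with np.errstate(invalid="ignore"):
        snp_mean_depth = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(~miss, depth, np.nan).mean(axis=0, where=~miss),
            0.0,
        )
    return CollectionSummary(
        n_accessions=gm.n_accessions,
        n_snps=gm.n_snps,
        mean_depth=mean_depth,
        pct_depth_gt20=float(100.0 * (snp_mean_depth >= depth_cut).mean()),
        pct_het=float(100.0 * het.sum() / n_cells),
        pct_hom=float(100.0 * hom.sum() / n_cells),
        pct_missing=float(pct_missing),
    )


def filter_loci(gm: GenotypeMatrix, min_maf: float = 0.0, max_missing: float = 1.0,
                min_mean_depth: float = 0.0) -> GenotypeMatrix:
    """Drop SNPs failing minor-allele-frequency, missingness, or depth filters.

    Raises if nothing survives, naming the filter that removed the most loci.
    """
    f = gm.dosage_fraction()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(f, axis=0)
    p = np.nan_to_num(p, nan=0.0)
    maf = np.minimum(p, 1.0 - p)
    miss_frac = gm.missing_mask.mean(axis=0)
    miss = gm.missing_mask
    depth = gm.total_depth.astype(float)
    typed = (~miss).sum(axis=0)
    mean_depth = np.where(typed > 0, np.where(~miss, depth, 0).sum(axis=0) / np.maximum(typed, 1), 0.0)
    pass_maf = maf >= min_maf
    pass_miss = miss_frac <= max_missing
    pass_depth = mean_depth >= min_mean_depth
    keep = pass_maf & pass_miss & pass_depth
    if not keep.any():
        removed = {
            "min_maf": int((~pass_maf).sum()),
            "max_missing": int((~pass_miss).sum()),
            "min_mean_depth": int((~pass_depth).sum()),
        }
        binding = max(removed, key=removed.get)
        raise GenotypeDataError(f"all SNPs removed; binding filter: {binding} ({removed})")
    return gm.select_snps(keep)
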