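"""Ploidy inference from heterozygous allele-depth ratios.

At a heterozygous SNP the fraction of reads carrying the alternate allele
estimates the dosage fraction, so across many heterozygous loci the ratio
distribution is multimodal with modes at k/ploidy: one peak (0.5) for
diploids, three (0.25, 0.5, 0.75) for tetraploids, five (0.17, 0.33, 0.5,
0.67, 0.83) for hexaploids.  A Gaussian KDE over the ratios is scanned for
prominent local maxima and the peak set is matched against those
templates; ambiguous or data-poor accessions come back "unclear" /
"insufficient_data" rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .genotypes import GenotypeMatrix

TEMPLATES: dict[int, np.ndarray] = {
    2: np.array([0.5]),
    4: np.array([0.25, 0.5, 0.75]),
    6: np.array([1 / 6, 2 / 6, 0.5, 4 / 6, 5 / 6]),
}

#: mass near 0/1 is residual sequencing error, not a dosage class
EDGE_WINDOW = (0.05, 0.95)


class InsufficientDataError(ValueError):
    pass


@dataclass
class PloidyCall:
    accession_id: str
    n_het_loci_used: int
    peak_positions: list[float] = field(default_factory=list)
    inferred_ploidy: int | None = None
    status: str = "unclear"  # ok | unclear | insufficient_data
    source: str = "depth_ratios"  # or "redundancy" after annotation


def het_depth_ratios(gm: GenotypeMatrix, accession: str,
                     min_site_depth: int = 10) -> np.ndarray:
    """alt/(ref+alt) at heterozygous, non-missing sites with total depth
    >= ``min_site_depth``."""
    i = gm.accession_index(accession)
    het = gm.het_mask[i]
    total = gm.total_depth[i]
    use = het & (total >= min_site_depth) & (total > 0)
    return gm.alt_depth[i, use] / total[use]


#: default absolute kernel width; below half the spacing of hexaploid
#: dosage classes, so the five 6x modes stay resolved.  Rule-of-thumb
#: (Silverman/Scott) bandwidths assume unimodality and smear the ratio
#: modes together.
DEFAULT_BANDWIDTH = 0.025


def ratio_density(ratios: np.ndarray, bandwidth: float | None = None,
                  grid_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of depth ratios on a [0,1] grid.

    ``bandwidth`` is an absolute kernel standard deviation (default
    :data:`DEFAULT_BANDWIDTH`).
    """
    h = DEFAULT_BANDWIDTH if bandwidth is None else float(bandwidth)
    sd = float(np.std(ratios))
    kde = gaussian_kde(ratios, bw_method=h / sd if sd > 0 else None)
    grid = np.linspace(0.0, 1.0, grid_size)
    return grid, kde(grid)


def detect_ratio_peaks(ratios: np.ndarray, bandwidth: float | None = None,
                       min_prominence: float = 0.02,
                       min_het_loci: int = 100,
                       min_separation: float = 0.09) -> list[float]:
    """Prominent local maxima of the ratio KDE inside the edge window.

    Dosage classes are unevenly populated (extreme allele frequencies make
    single-copy heterozygotes far more common than balanced ones), so the
    prominence floor relative to the global maximum is deliberately low;
    maxima closer than ``min_separation`` — which is below the 1/6 spacing
    of hexaploid classes — are treated as one mode and the higher kept.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < min_het_loci:
        raise InsufficientDataError(
            f"{ratios.size} heterozygous ratios < required {min_het_loci}")
    grid, dens = ratio_density(ratios, bandwidth)
    idx, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    idx = [i for i in idx if EDGE_WINDOW[0] <= grid[i] <= EDGE_WINDOW[1]]
    merged: list[int] = []
    for i in idx:
        if merged and grid[i] - grid[merged[-1]] < min_separation:
            if dens[i] > dens[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return sorted(float(grid[i]) for i in merged)


def infer_ploidy(peaks: list[float], tol: float = 0.06) -> PloidyCall:
    """Match a peak list against the ploidy templates.

    A template is consistent when peaks and template positions pair off
    one-to-one within ``tol``; exactly one consistent template yields a
    call, anything else is unclear.
    """
    consistent = []
    for pl, template in TEMPLATES.items():
        if len(peaks) == len(template) and np.all(
                np.abs(np.sort(peaks) - template) <= tol):
            consistent.append(pl)
    call = PloidyCall("", 0, [float(p) for p in sorted(peaks)])
    if len(consistent) == 1:
        call.inferred_ploidy = consistent[0]
        call.status = "ok"
    return call


def call_ploidy(gm: GenotypeMatrix, accession: str, min_site_depth: int = 10,
                bandwidth: float | None = None, min_prominence: float = 0.02,
                min_het_loci: int = 100, tol: float = 0.06) -> PloidyCall:
    """het_depth_ratios -> detect_ratio_peaks -> infer_ploidy for one accession.

    A lone central peak is demoted to "unclear" when the density at 0.25
    and 0.75 reaches half the central density — possible tetraploid
    shoulders too weak to register as peaks.
    """
    ratios = het_depth_ratios(gm, accession, min_site_depth)
    try:
        peaks = detect_ratio_peaks(ratios, bandwidth, min_prominence, min_het_loci)
    except InsufficientDataError:
        return PloidyCall(accession, int(ratios.size), status="insufficient_data")
    call = infer_ploidy(peaks, tol)
    call.accession_id = accession
    call.n_het_loci_used = int(ratios.size)
    if call.inferred_ploidy == 2:
        grid, dens = ratio_density(ratios, bandwidth)
        side = max(dens[np.argmin(np.abs(grid - 0.25))],
                   dens[np.argmin(np.abs(grid - 0.75))])
        center = dens[np.argmin(np.abs(grid - 0.5))]
        if side >= 0.5 * center:
            call.inferred_ploidy = None
            call.status = "unclear"
    return call


def call_ploidy_all(gm: GenotypeMatrix, **kwargs) -> list[PloidyCall]:
    return [call_ploidy(gm, a, **kwargs) for a in gm.accession_ids]


def annotate_from_redundancy(calls: list[PloidyCall],
                             groups: list[set[str]]) -> list[PloidyCall]:
    """Let unclear/insufficient accessions inherit the consensus ploidy of
    an ok redundancy partner; never overwrites an ok call."""
    by_id = {c.accession_id: c for c in calls}
    for group in groups:
        ok = [by_id[a].inferred_ploidy for a in group
              if a in by_id and by_id[a].status == "ok"]
        if not ok:
            continue
        values, counts = np.unique(ok, return_counts=True)
        consensus = int(values[np.argmax(counts)])
        for a in group:
            c = by_id.get(a)
            if c is not None and c.status != "ok":
                c.inferred_ploidy = consensus
                c.status = "ok"
                c.source = "redundancy"
    return calls


def ploidy_table(calls: list[PloidyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(accession_id=c.accession_id, n_het_loci_used=c.n_het_loci_used,
              peaks=";".join(f"{p:.3f}" for p in c.peak_positions),
              inferred_ploidy=c.inferred_ploidy if c.inferred_ploidy else "",
              status=c.status, source=c.source)
         for c in calls]
    ).set_index("accession_id")


def plot_ratio_kde(gm: GenotypeMatrix, accession: str, path: str | Path,
                   min_site_depth: int = 10) -> None:
    """Per-accession histogram + KDE of heterozygous depth ratios (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ratios = het_depth_ratios(gm, accession, min_site_depth)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(ratios, bins=50, range=(0, 1), density=True, alpha=0.4)
    if ratios.size >= 2:
        grid, dens = ratio_density(ratios)
        ax.plot(grid, dens)
    ax.set_xlabel("alternate allele depth ratio")
    ax.set_ylabel("density")
    ax.set_title(accession)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
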