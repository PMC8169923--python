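"""Windowed genome scans.

Two complementary window geometries are used:

* **base-pair windows** for AFD-SNP density — 1 Mb windows advanced by
  200 kb from position 1 to the chromosome end; a window whose density of
  qualifying SNPs strictly exceeds ``min_density`` per Mb is flagged, and
  overlapping or book-ended flagged windows are merged into candidate
  regions;
* **SNP-count windows** for the expectation goodness-of-fit scan — 10
  consecutive SNPs advanced by 5, scoring each window by DFScore, the mean
  squared deviation of the two bulks' frequencies from their nearest
  admissible Mendelian value:

      DFScore = (1/2n) * sum_i [ (f_high_i - e_high_i)^2
                                 + (f_low_i - e_low_i)^2 ]

  where e is the nearest member of the bulk's expectation set
  (:mod:`bsascan.genetic_models`).  DFScore is zero exactly when every site
  in the window sits on an expectation value in both bulks; windows with
  DFScore <= ``dfscore_epsilon`` are flagged as *best* windows.  The raw
  within-window sample variances of each bulk's frequencies are reported
  alongside so the variance-near-zero reading of "best" is also available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .afd_stats import ScanParams
from .errors import InputError
from .genetic_models import ExpectationSet, nearest_deviation
from .sitetable_io import BulkSite, chrom_sort_key

__all__ = [
    "WindowScore",
    "Region",
    "density_scan",
    "merge_flagged_windows",
    "variance_scan",
    "triage_region_genes",
    "peak_position",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowScore:
    """One genomic window with its counts and scores.

    ``start``/``end`` are 1-based inclusive.  ``density`` is SNPs per Mb
    over the window's actual span.  ``dfscore``, ``var_high``, ``var_low``
    are populated only by the variance scan; ``partial`` marks a trailing
    variance-scan window with fewer than the nominal SNP count.
    """

    chrom: str
    start: int
    end: int
    n_snps: int
    density: float = 0.0
    dfscore: Optional[float] = None
    var_high: Optional[float] = None
    var_low: Optional[float] = None
    best: bool = False
    partial: bool = False


@dataclass
class Region:
    """A maximal run of merged flagged windows (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0  # peak window SNP count among the merged windows
    peak_density: float = 0.0
    group: str = ""

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def _group_sites(sites: Sequence[BulkSite]) -> List[Tuple[str, List[BulkSite]]]:
    """Group sorted sites by chromosome, preserving (chrom, pos) order."""
    groups: Dict[str, List[BulkSite]] = {}
    for s in sites:
        groups.setdefault(s.chrom, []).append(s)
    return sorted(groups.items(), key=lambda kv: chrom_sort_key(kv[0]))


def density_scan(
    sites: Sequence[BulkSite],
    params: ScanParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> List[WindowScore]:
    """Count qualifying sites in sliding base-pair windows.

    Windows of ``density_window_bp`` advance by ``density_step_bp`` starting
    at position 1; the final window is truncated at the chromosome end so
    the density always refers to the actual span.  ``sites`` should already
    be restricted to the qualifying (AFD-filtered) SNPs.

    Raises
    ------
    InputError
        If a site lies beyond its chromosome's declared length.
    """
    params = params or ScanParams()
    chrom_lengths = chrom_lengths or {}
    windows: List[WindowScore] = []
    for chrom, chrom_sites in _group_sites(sites):
        pos = np.asarray([s.pos for s in chrom_sites], dtype=np.int64)
        length = int(chrom_lengths.get(chrom, pos.max() if pos.size else 0))
        if pos.size and pos.max() > length:
            bad = chrom_sites[int(np.argmax(pos))]
            raise InputError(
                f"site {bad.chrom}:{bad.pos} lies beyond the declared "
                f"chromosome length {length}"
            )
        start = 1
        while start <= length:
            end = min(start + params.density_window_bp - 1, length)
            n = int(
                np.searchsorted(pos, end, side="right")
                - np.searchsorted(pos, start, side="left")
            )
            span = end - start + 1
            windows.append(
                WindowScore(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snps=n,
                    density=n * 1_000_000 / span,
                )
            )
            start += params.density_step_bp
    return windows


def merge_flagged_windows(
    windows: Sequence[WindowScore],
    min_density: float = 30.0,
    group: str = "",
) -> List[Region]:
    """Coalesce flagged windows (density strictly > ``min_density``) into regions.

    Overlapping or book-ended flagged windows on the same chromosome merge
    into a maximal region whose boundaries are the union of the member
    windows; ``peak_density`` and ``n_snps`` record the densest member.
    """
    flagged: Dict[str, List[WindowScore]] = {}
    for w in windows:
        if w.density > min_density:
            flagged.setdefault(w.chrom, []).append(w)

    regions: List[Region] = []
    for chrom in sorted(flagged, key=chrom_sort_key):
        current: Optional[Region] = None
        for w in sorted(flagged[chrom], key=lambda w: (w.start, w.end)):
            if current is not None and w.start <= current.end + 1:  # overlap or book-ended
                current.end = max(current.end, w.end)
                current.peak_density = max(current.peak_density, w.density)
                current.n_snps = max(current.n_snps, w.n_snps)
            else:
                current = Region(
                    chrom=chrom,
                    start=w.start,
                    end=w.end,
                    n_snps=w.n_snps,
                    peak_density=w.density,
                    group=group,
                )
                regions.append(current)
    return regions


def _sample_var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if x.size > 1 else 0.0


def variance_scan(
    sites: Sequence[BulkSite],
    params: ScanParams | None = None,
    exp_high: ExpectationSet | None = None,
    exp_low: ExpectationSet | None = None,
) -> List[WindowScore]:
    """Score SNP-count windows by deviation from the Mendelian expectations.

    Windows of ``var_window_snps`` consecutive sites advance by
    ``var_step_snps`` per chromosome; a trailing window with fewer sites is
    emitted with ``partial=True`` rather than dropped.  Requires both
    expectation sets; see module docstring for the DFScore formula.
    """
    params = params or ScanParams()
    if exp_high is None or exp_low is None:
        raise ValueError("variance_scan requires exp_high and exp_low expectation sets")

    out: List[WindowScore] = []
    w, step = params.var_window_snps, params.var_step_snps
    for chrom, chrom_sites in _group_sites(sites):
        n = len(chrom_sites)
        i = 0
        while i < n:
            chunk = chrom_sites[i : i + w]
            fh = np.asarray([s.f_high for s in chunk])
            fl = np.asarray([s.f_low for s in chunk])
            dev_h = np.asarray([nearest_deviation(f, exp_high)[1] for f in fh])
            dev_l = np.asarray([nearest_deviation(f, exp_low)[1] for f in fl])
            m = len(chunk)
            dfscore = float((dev_h**2).sum() + (dev_l**2).sum()) / (2 * m)
            out.append(
                WindowScore(
                    chrom=chrom,
                    start=chunk[0].pos,
                    end=chunk[-1].pos,
                    n_snps=m,
                    density=float("nan"),
                    dfscore=dfscore,
                    var_high=_sample_var(fh),
                    var_low=_sample_var(fl),
                    best=dfscore <= params.dfscore_epsilon,
                    partial=m < w,
                )
            )
            if i + w >= n:
                break
            i += step
    return out


def peak_position(positions, scores) -> float:
    """Location of a score peak, tie-aware.

    At a strongly linked locus the per-site statistic commonly *ties* at its
    maximum across a run of fully co-segregating markers; taking the first
    maximum would bias the peak toward the run's proximal edge.  The peak is
    therefore reported as the midpoint of the span of tied maximal sites —
    the center of the interval estimate.  Positions are assumed to lie on
    one chromosome.
    """
    positions = np.asarray(positions, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if positions.size == 0:
        raise ValueError("peak_position requires at least one site")
    tied = positions[scores == scores.max()]
    return float(0.5 * (tied.min() + tied.max()))


# expression triage classes
NOT_EXPRESSED = "not_expressed"
EXPRESSED = "expressed"
HIGHLY_EXPRESSED = "highly_expressed"

_LOG2_OFFSET = 1e-6  # keeps log2 of zero-expression genes finite and far below any cut


def triage_region_genes(
    tpm_table: pd.DataFrame,
    region: Region,
    gene_coords: Mapping[str, Tuple[str, int, int]],
    low_cut: float = 1.0,
    high_cut: float = 8.0,
) -> Dict[str, str]:
    """Classify the genes of a candidate region by expression level.

    Parameters
    ----------
    tpm_table : DataFrame
        Genes (index) x samples (columns) TPM values, >= 0.
    region : Region
        Candidate region; genes whose coordinates overlap it are triaged.
    gene_coords : mapping gene -> (chrom, start, end), 1-based inclusive.
    low_cut, high_cut : float
        Strict log2(TPM) cuts: a gene is ``not_expressed`` when its maximum
        over samples of log2(TPM) < ``low_cut`` (default 1, i.e. TPM 2),
        ``highly_expressed`` when the maximum > ``high_cut`` (default 8,
        TPM 256), otherwise ``expressed``.

    Genes in the table without coordinates are logged and skipped.
    """
    if (tpm_table.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    classes: Dict[str, str] = {}
    skipped = 0
    for gene in tpm_table.index:
        coords = gene_coords.get(gene)
        if coords is None:
            skipped += 1
            continue
        chrom, g_start, g_end = coords
        if str(chrom) != str(region.chrom) or g_start > region.end or g_end < region.start:
            continue
        max_log2 = math.log2(float(tpm_table.loc[gene].max()) + _LOG2_OFFSET)
        if max_log2 < low_cut:
            classes[gene] = NOT_EXPRESSED
        elif max_log2 > high_cut:
            classes[gene] = HIGHLY_EXPRESSED
        else:
            classes[gene] = EXPRESSED
    if skipped:
        logger.warning("triage: %d gene(s) lacked coordinates and were skipped", skipped)
    return classes
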