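"""VCF ingestion and tabular I/O.

Reads a multi-sample VCF, restricts to biallelic SNPs passing a quality
floor, and reduces each site to the two bulk alternate-allele frequencies
that every downstream statistic consumes.  Two frequency modes are offered:

* ``GT`` (default) — count alternate alleles among the called genotypes of
  the bulk's samples; missing genotypes are excluded from numerator and
  denominator alike.  This matches the design in which every extreme
  individual is sequenced and genotyped separately and the bulks are pooled
  in silico.
* ``AD`` — sum per-sample allelic depths across the bulk, for genuinely
  pooled sequencing; sites lacking the AD tag are skipped and tallied.

Coordinates are 1-based inside the toolkit (VCF convention); only the BED
writer converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Tuple, Union

import pandas as pd
from cyvcf2 import VCF

from .afd_stats import afd, power_afd
from .errors import ConfigurationError, InputError, InternalConsistencyError

__all__ = [
    "BulkSite",
    "BulkSpec",
    "read_bulk_sites",
    "write_site_table",
    "read_site_table",
    "write_regions",
    "chrom_sort_key",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class BulkSite:
    """One biallelic SNP with its per-bulk alternate-allele frequencies.

    ``n_high``/``n_low`` count the called alleles (GT mode) or summed read
    depth (AD mode) behind each frequency; sites with a fully missing bulk
    are never emitted.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    f_high: float
    f_low: float
    n_high: int
    n_low: int
    qual: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_high <= 1.0 and 0.0 <= self.f_low <= 1.0):
            raise ValueError(f"bulk frequencies must lie in [0, 1]: {self}")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError(f"each bulk needs at least one called allele: {self}")


@dataclass(frozen=True)
class BulkSpec:
    """A named bulk: the VCF sample IDs pooled for one phenotype extreme."""

    name: str
    samples: Tuple[str, ...]

    def __init__(self, name: str, samples: Iterable[str]) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "samples", tuple(samples))
        if not self.samples:
            raise ConfigurationError(f"bulk {self.name!r} has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise ConfigurationError(f"bulk {self.name!r} lists duplicate samples")


_natural_re = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str):
    """Natural-order key so chromosome '2' sorts before '10' and 'chr2' before 'chr10'."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _natural_re.split(str(chrom))
        if part != ""
    )


def _bulk_indices(vcf_samples: Sequence[str], spec: BulkSpec) -> List[int]:
    index = {s: i for i, s in enumerate(vcf_samples)}
    missing = [s for s in spec.samples if s not in index]
    if missing:
        raise ConfigurationError(
            f"bulk {spec.name!r} lists sample(s) absent from the VCF header: "
            + ", ".join(missing)
        )
    return [index[s] for s in spec.samples]


def _gt_frequency(genotypes, indices) -> Tuple[float, int]:
    """Alt-allele frequency and called-allele count over a bulk (GT mode)."""
    alt = 0
    called = 0
    for i in indices:
        for allele in genotypes[i][:-1]:  # last entry is the phased flag
            if allele < 0:  # missing
                continue
            called += 1
            if allele == 1:
                alt += 1
    return (alt / called if called else 0.0), called


def read_bulk_sites(
    vcf_source: Union[str, PathLike],
    high: BulkSpec,
    low: BulkSpec,
    af_mode: str = "GT",
    min_qual: float = 100.0,
    counts: dict | None = None,
) -> List[BulkSite]:
    """Read a VCF and return per-site bulk frequencies, sorted by (chrom, pos).

    Only biallelic SNPs with QUAL >= ``min_qual`` and at least one called
    allele (or read, in AD mode) per bulk are emitted.  Multiallelic
    records, indels, low-quality sites, AD-less sites (AD mode) and sites
    with a fully missing bulk are skipped and tallied both in the log and,
    if a ``counts`` dict is supplied, in place.

    Raises
    ------
    ConfigurationError
        If a bulk names a sample absent from the header, or the bulks overlap.
    InputError
        If positions decrease within a chromosome (unsorted VCF).
    """
    af_mode = af_mode.upper()
    if af_mode not in ("GT", "AD"):
        raise ConfigurationError(f"af_mode must be 'GT' or 'AD', got {af_mode!r}")
    overlap = set(high.samples) & set(low.samples)
    if overlap:
        raise ConfigurationError(
            "bulks must be disjoint; shared sample(s): " + ", ".join(sorted(overlap))
        )

    vcf = VCF(str(vcf_source))
    hi_idx = _bulk_indices(vcf.samples, high)
    lo_idx = _bulk_indices(vcf.samples, low)

    tally = {
        "records": 0,
        "multiallelic": 0,
        "indel": 0,
        "low_qual": 0,
        "missing_bulk": 0,
        "no_ad": 0,
        "emitted": 0,
    }
    sites: List[BulkSite] = []
    last: Tuple[str, int] | None = None
    for v in vcf:
        tally["records"] += 1
        if last is not None and v.CHROM == last[0] and v.POS < last[1]:
            raise InputError(
                f"VCF is not coordinate-sorted: {v.CHROM}:{v.POS} after {last[0]}:{last[1]}"
            )
        last = (v.CHROM, v.POS)
        if len(v.ALT) != 1:
            tally["multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            tally["indel"] += 1
            continue
        qual = v.QUAL if v.QUAL is not None else float("-inf")
        if qual < min_qual:
            tally["low_qual"] += 1
            continue

        if af_mode == "GT":
            genotypes = v.genotypes
            f_high, n_high = _gt_frequency(genotypes, hi_idx)
            f_low, n_low = _gt_frequency(genotypes, lo_idx)
        else:
            try:
                ad = v.format("AD")
            except KeyError:  # AD absent from the header entirely
                ad = None
            if ad is None:
                tally["no_ad"] += 1
                continue
            ad = ad.astype(float)
            ad[ad < 0] = 0  # missing encoded as negative sentinels
            hi = ad[hi_idx, :2]
            lo = ad[lo_idx, :2]
            n_high = int(hi.sum())
            n_low = int(lo.sum())
            f_high = float(hi[:, 1].sum()) / n_high if n_high else 0.0
            f_low = float(lo[:, 1].sum()) / n_low if n_low else 0.0

        if n_high < 1 or n_low < 1:
            tally["missing_bulk"] += 1
            continue
        tally["emitted"] += 1
        sites.append(
            BulkSite(
                chrom=v.CHROM,
                pos=v.POS,
                ref=ref,
                alt=alt,
                f_high=f_high,
                f_low=f_low,
                n_high=n_high,
                n_low=n_low,
                qual=float(qual) if qual != float("-inf") else float("nan"),
            )
        )

    sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos))
    logger.info(
        "VCF ingest: %(records)d records, %(emitted)d sites emitted; skipped "
        "%(multiallelic)d multiallelic, %(indel)d indel, %(low_qual)d low-qual, "
        "%(missing_bulk)d missing-bulk, %(no_ad)d without AD",
        tally,
    )
    if counts is not None:
        counts.update(tally)
    return sites


SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "f_high", "f_low", "afd", "power_afd")


def _as_text_handle(dest: Union[str, PathLike, IO[str]]):
    if isinstance(dest, (str, PathLike)):
        return open(dest, "w"), True
    return dest, False


def write_site_table(
    sites: Sequence[BulkSite],
    dest: Union[str, PathLike, IO[str]],
    power: float = 4.0,
) -> None:
    """Write the per-site statistics table as TSV.

    Columns: chrom, pos, ref, alt, f_high, f_low, afd, power_afd; all
    frequencies and statistics printed with 7 decimal places.
    """
    handle, close = _as_text_handle(dest)
    try:
        handle.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            a = afd(s.f_high, s.f_low)
            p = power_afd(s.f_high, s.f_low, power)
            handle.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                f"{s.f_high:.7f}\t{s.f_low:.7f}\t{a:.7f}\t{p:.7f}\n"
            )
    finally:
        if close:
            handle.close()


def read_site_table(source: Union[str, PathLike, IO[str]]) -> pd.DataFrame:
    """Read a site table written by :func:`write_site_table`."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"site table is missing column(s): {sorted(missing)}")
    return df


def write_regions(
    regions: Sequence,
    bed: Union[str, PathLike, IO[str]],
    tsv: Union[str, PathLike, IO[str], None] = None,
) -> None:
    """Write merged regions as BED (0-based half-open) and optionally TSV.

    The TSV keeps 1-based inclusive coordinates with columns group, chrom,
    start, end, n_snps, peak_density.

    Raises
    ------
    InternalConsistencyError
        If regions on one chromosome overlap or are unsorted.
    """
    by_chrom: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        prev_end = None
        for r in rs:
            if prev_end is not None and r.start <= prev_end:
                raise InternalConsistencyError(
                    f"regions on chromosome {chrom} overlap or are unsorted at {r.start}"
                )
            prev_end = r.end

    handle, close = _as_text_handle(bed)
    try:
        for r in regions:
            handle.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.group or 'region'}\t{r.peak_density:.4f}\n"
            )
    finally:
        if close:
            handle.close()

    if tsv is None:
        return
    handle, close = _as_text_handle(tsv)
    try:
        handle.write("group\tchrom\tstart\tend\tn_snps\tpeak_density\n")
        for r in regions:
            handle.write(
                f"{r.group}\t{r.chrom}\t{r.start}\t{r.end}\t{r.n_snps}\t{r.peak_density:.4f}\n"
            )
    finally:
        if close:
            handle.close()
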