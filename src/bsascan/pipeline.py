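"""End-to-end orchestration: ingest -> per-site stats -> filters -> scans -> writers.

:func:`run_scan` wires the library modules into the full genome scan and
writes the result bundle to an output directory:

* ``sites.tsv`` — every ingested biallelic SNP with f_high, f_low, AFD and
  PowerAFD (7 decimals);
* ``cmplot_sites.tsv`` — marker/chrom/pos/PowerAFD columns for external
  Manhattan plotting;
* ``density_windows.tsv`` — the sliding 1 Mb density windows over the
  AFD-filtered SNPs, with flags;
* ``regions.bed`` / ``regions.tsv`` — merged flagged windows (BED is
  0-based half-open, TSV 1-based inclusive);
* ``variance_windows.tsv`` — the 10-SNP expectation goodness-of-fit scan;
* ``summary.txt`` — the human-readable report of :func:`summarize`.

Outputs are deterministic functions of the input VCF and configuration;
partially written files are removed if any stage fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from cyvcf2 import VCF

from .afd_stats import ScanParams, afd, is_afd_snp, passes_afd_threshold, power_afd
from .errors import ConfigurationError
from .genetic_models import ExpectationSet, expectation_set
from .sitetable_io import (
    BulkSite,
    BulkSpec,
    chrom_sort_key,
    read_bulk_sites,
    write_regions,
    write_site_table,
)
from .window_scans import Region, WindowScore, density_scan, merge_flagged_windows, variance_scan

__all__ = ["RunConfig", "ResultBundle", "run_scan", "summarize", "default_roles"]

logger = logging.getLogger(__name__)

# default bulk roles per cross design (high bulk first)
_DEFAULT_ROLES = {
    "f2_intercross": ("dominant_bulk", "recessive_bulk"),
    "homozygous_bulks": ("high_bulk", "low_bulk"),
    "backcross": ("high_bulk", "low_bulk"),
}


def default_roles(design: str) -> Tuple[str, str]:
    """The conventional (high-bulk, low-bulk) expectation roles of a design."""
    try:
        return _DEFAULT_ROLES[design]
    except KeyError:
        raise ConfigurationError(
            f"unknown design {design!r}; choose from {sorted(_DEFAULT_ROLES)}"
        ) from None


@dataclass
class RunConfig:
    """Everything one genome scan needs.

    ``apply_band_filter`` / ``apply_afd_filter`` select which per-site
    filters define the AFD-SNP set fed to the density scan (both on by
    default); the variance scan always runs on the full site set, since its
    score already measures deviation from the genetic model.
    """

    vcf: str
    high: BulkSpec
    low: BulkSpec
    out_dir: str
    params: ScanParams = field(default_factory=ScanParams)
    design: str = "homozygous_bulks"
    high_role: Optional[str] = None
    low_role: Optional[str] = None
    af_mode: str = "GT"
    min_qual: float = 100.0
    group: str = ""  # label carried into the region outputs (e.g. F2 / F3)
    apply_band_filter: bool = True
    apply_afd_filter: bool = True
    chrom_lengths: Optional[Mapping[str, int]] = None

    def expectations(self) -> Tuple[ExpectationSet, ExpectationSet]:
        hi_role, lo_role = default_roles(self.design)
        return (
            expectation_set(self.design, self.high_role or hi_role),
            expectation_set(self.design, self.low_role or lo_role),
        )


@dataclass
class ResultBundle:
    """In-memory results of one scan plus the paths written."""

    sites: List[BulkSite]
    afd_sites: List[BulkSite]
    density_windows: List[WindowScore]
    regions: List[Region]
    variance_windows: List[WindowScore]
    stage_counts: Dict[str, int]
    params: ScanParams
    paths: Dict[str, Path] = field(default_factory=dict)


def _contig_lengths(vcf_path: str) -> Dict[str, int]:
    vcf = VCF(str(vcf_path))
    try:
        return {name: int(length) for name, length in zip(vcf.seqnames, vcf.seqlens)}
    except Exception:  # header lacks contig lengths
        return {}


def run_scan(config: RunConfig) -> ResultBundle:
    """Execute the full scan and write the result bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        counts: Dict[str, int] = {}
        sites = read_bulk_sites(
            config.vcf,
            config.high,
            config.low,
            af_mode=config.af_mode,
            min_qual=config.min_qual,
            counts=counts,
        )
        p = config.params
        afd_sites = [
            s
            for s in sites
            if (not config.apply_band_filter or is_afd_snp(s, p))
            and (not config.apply_afd_filter or passes_afd_threshold(s, p))
        ]
        stage_counts = {
            "vcf_records": counts.get("records", 0),
            "sites_ingested": len(sites),
            "afd_snps": len(afd_sites),
            **{k: counts.get(k, 0) for k in ("multiallelic", "indel", "low_qual", "missing_bulk", "no_ad")},
        }

        chrom_lengths = dict(config.chrom_lengths or _contig_lengths(config.vcf))
        windows = density_scan(afd_sites, p, chrom_lengths)
        regions = merge_flagged_windows(windows, p.min_density, group=config.group)
        exp_high, exp_low = config.expectations()
        var_windows = variance_scan(sites, p, exp_high, exp_low)

        bundle = ResultBundle(
            sites=sites,
            afd_sites=afd_sites,
            density_windows=windows,
            regions=regions,
            variance_windows=var_windows,
            stage_counts=stage_counts,
            params=p,
        )

        def path(name: str) -> Path:
            pth = out / name
            written.append(pth)
            bundle.paths[name] = pth
            return pth

        write_site_table(sites, path("sites.tsv"), power=p.power)
        with open(path("cmplot_sites.tsv"), "w") as fh:
            fh.write("marker\tchrom\tpos\tpower_afd\n")
            for i, s in enumerate(sites, 1):
                fh.write(
                    f"site_{i}\t{s.chrom}\t{s.pos}\t{power_afd(s.f_high, s.f_low, p.power):.7f}\n"
                )
        with open(path("density_windows.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tn_snps\tdensity\tflagged\n")
            for w in windows:
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{w.density:.4f}\t"
                    f"{int(w.density > p.min_density)}\n"
                )
        write_regions(regions, path("regions.bed"), path("regions.tsv"))
        with open(path("variance_windows.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tn_snps\tvar_high\tvar_low\tdfscore\tbest\tpartial\n")
            for w in var_windows:
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{w.var_high:.7f}\t"
                    f"{w.var_low:.7f}\t{w.dfscore:.7f}\t{int(w.best)}\t{int(w.partial)}\n"
                )
        with open(path("summary.txt"), "w") as fh:
            fh.write(summarize(bundle))
        return bundle
    except Exception:
        for pth in written:
            pth.unlink(missing_ok=True)
        logger.error("scan failed; removed %d partial output file(s)", len(written))
        raise


def summarize(bundle: ResultBundle, top_n: int = 20) -> str:
    """Human-readable report: stage counts, per-chromosome tallies, top loci.

    The top-locus table lists the strongest PowerAFD sites (descending, ties
    broken by chromosome and position) with the statistic at 7 decimals.
    """
    p = bundle.params
    lines: List[str] = ["# bsascan scan summary", ""]
    if not bundle.sites:
        lines.append("No sites ingested (zero sites).")
        return "\n".join(lines) + "\n"

    lines.append("## Stage counts")
    for key, val in bundle.stage_counts.items():
        lines.append(f"{key}\t{val}")
    lines.append("")

    chroms = sorted({s.chrom for s in bundle.sites}, key=chrom_sort_key)
    lines.append("## Per-chromosome")
    lines.append("chrom\tafd_snps\tflagged_windows\tregions")
    for c in chroms:
        n_afd = sum(1 for s in bundle.afd_sites if s.chrom == c)
        n_fw = sum(1 for w in bundle.density_windows if w.chrom == c and w.density > p.min_density)
        n_reg = sum(1 for r in bundle.regions if r.chrom == c)
        lines.append(f"{c}\t{n_afd}\t{n_fw}\t{n_reg}")
    lines.append("")

    scored = sorted(
        bundle.sites,
        key=lambda s: (-power_afd(s.f_high, s.f_low, p.power), chrom_sort_key(s.chrom), s.pos),
    )
    lines.append(f"## Top PowerAFD loci (power {p.power:g})")
    lines.append("chrom\tpos\tpower_afd")
    for s in scored[:top_n]:
        lines.append(f"{s.chrom}\t{s.pos}\t{power_afd(s.f_high, s.f_low, p.power):.7f}")
    return "\n".join(lines) + "\n"
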