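"""Shared fixtures: a minimal VCF text builder and small simulated crosses."""

from __future__ import annotations

from pathlib import Path

import pytest


def build_vcf_text(samples, rows, contigs=None, with_ad=False):
    """Render a minimal VCF 4.2 text.

    ``rows`` is a sequence of tuples (chrom, pos, ref, alt, qual, gts)
    where ``alt`` may be comma-joined for multiallelic records and each
    element of ``gts`` is a genotype string like ``0/1`` (optionally
    ``0/1:ad_ref,ad_alt`` when ``with_ad``).
    """
    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_ad:
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    fmt = "GT:AD" if with_ad else "GT"
    for chrom, pos, ref, alt, qual, gts in rows:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\t{fmt}\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def vcf_factory(tmp_path):
    """Write a VCF built by :func:`build_vcf_text` to a temp file, return its path."""
    counter = {"n": 0}

    def _make(samples, rows, contigs=None, with_ad=False) -> str:
        counter["n"] += 1
        path = tmp_path / f"test_{counter['n']}.vcf"
        path.write_text(build_vcf_text(samples, rows, contigs, with_ad))
        return str(path)

    return _make
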