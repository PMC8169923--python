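"""Synthetic backcross / F2 populations for end-to-end testing of the scans.

The simulator emulates the breeding design behind two-bulk BSA of a
quantitative trait in a hybrid cattle population: a low-trait dam breed is
crossed to a high-trait sire breed, and the F1 is either intercrossed
(F2 design) or repeatedly backcrossed to the sire breed.  Founders are fully
divergent (dam breed carries the reference allele at every marker, sire
breed the alternate), so every marker is informative.

Mechanics
---------
* **Meiosis** uses the Haldane map function at a uniform 1 cM/Mb: the
  recombination fraction between adjacent markers d bp apart is
  r = (1 - exp(-2 d x 1e-8)) / 2, crossovers independent across intervals.
* **Phenotype** is additive at a single biallelic QTL:
  y = effect x dosage + N(0, sigma_e^2), with sigma_e^2 set from the
  realized dosage variance so the QTL explains exactly h^2 of the
  phenotypic variance in expectation.
* **Bulks** are the ``bulk_size`` largest and smallest phenotypes, ties
  broken deterministically by individual index.
* **VCF emission** writes one sample per bulked individual with phased GT
  and, when ``depth`` > 0, an AD field drawn as Poisson(depth) reads per
  sample per site with binomial allele sampling — the standard pooled-seq
  noise model.  QUAL is set above the default ingestion floor.

A single integer seed drives three independent generator streams (pedigree,
phenotype noise, read depth) so components can be regenerated separately;
fixed seed means byte-identical VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import IO, List, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "Population",
    "simulate_cross",
    "select_bulks",
    "emit_vcf",
    "bulk_frequencies",
]

CM_PER_MB = 1.0  # uniform genetic map


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cross.

    Defaults describe the reference scenario used throughout the test
    suite: a single 100 Mb chromosome carrying 200 evenly spaced markers,
    one additive QTL at mid-chromosome explaining h2 = 0.8 of the
    phenotypic variance, 400 backcross progeny, bulks of 20, and 10x
    sequencing depth for the optional AD field.
    """

    n_chrom: int = 1
    chrom_length_bp: int = 100_000_000
    n_markers: int = 200  # per chromosome
    qtl_chrom: int = 1  # 1-based chromosome index
    qtl_pos_bp: int = 50_000_000
    qtl_effect: float = 1.0  # phenotype units per alt allele
    h2: float = 0.8
    design: str = "backcross"  # or "f2_intercross"
    n_backcross_gens: int = 1
    pop_size: int = 400
    bulk_size: int = 20
    depth: float = 10.0  # mean read depth for AD; 0 = GT-only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.qtl_chrom <= self.n_chrom:
            raise ConfigurationError(
                f"qtl_chrom {self.qtl_chrom} not among the {self.n_chrom} simulated chromosome(s)"
            )
        if not 1 <= self.qtl_pos_bp <= self.chrom_length_bp:
            raise ConfigurationError("qtl_pos_bp outside the simulated chromosome")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.h2 == 1.0 and self.qtl_effect == 0.0:
            raise ConfigurationError("h2 = 1 with zero QTL effect is contradictory")
        if self.bulk_size * 2 > self.pop_size:
            raise ConfigurationError("bulk_size must be <= pop_size / 2")
        if self.design not in ("backcross", "f2_intercross"):
            raise ConfigurationError(
                f"design must be 'backcross' or 'f2_intercross', got {self.design!r}"
            )
        if self.n_backcross_gens < 1:
            raise ConfigurationError("n_backcross_gens must be >= 1")
        if self.n_markers < 1 or self.n_chrom < 1:
            raise ConfigurationError("need at least one marker and one chromosome")


@dataclass
class Population:
    """Simulated cohort: phased genotypes, phenotypes, and the marker map.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with 0 = dam-breed
    (reference) allele and 1 = sire-breed (alternate) allele.  ``chrom`` and
    ``pos`` describe the loci (1-based chromosome index and bp position);
    ``qtl_index`` is the column of the causal locus.
    """

    haplotypes: np.ndarray
    phenotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    qtl_index: int
    config: SimConfig

    @property
    def dosage(self) -> np.ndarray:
        """Alt-allele dosage per individual per locus, in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)


def _marker_map(config: SimConfig) -> Tuple[np.ndarray, np.ndarray, int]:
    """Evenly spaced marker positions per chromosome, with the QTL inserted
    as a locus if no marker falls exactly on it."""
    chroms: List[int] = []
    poss: List[int] = []
    L, m = config.chrom_length_bp, config.n_markers
    spacing = L / m
    base = np.round((np.arange(m) + 0.5) * spacing).astype(np.int64)
    base = np.clip(base, 1, L)
    for c in range(1, config.n_chrom + 1):
        positions = list(base)
        if c == config.qtl_chrom and config.qtl_pos_bp not in positions:
            positions.append(config.qtl_pos_bp)
        positions = sorted(set(positions))
        chroms.extend([c] * len(positions))
        poss.extend(positions)
    chrom = np.asarray(chroms, dtype=np.int64)
    pos = np.asarray(poss, dtype=np.int64)
    qtl_index = int(np.flatnonzero((chrom == config.qtl_chrom) & (pos == config.qtl_pos_bp))[0])
    return chrom, pos, qtl_index


def _recomb_fractions(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Per-interval recombination fraction; 0.5 across chromosome breaks
    (independent assortment)."""
    d_bp = np.diff(pos).astype(float)
    d_morgan = d_bp * CM_PER_MB * 1e-8
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))  # Haldane
    r[np.diff(chrom) != 0] = 0.5
    return r


def _gametes(parents: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent row via vectorized meiosis.

    ``parents`` has shape (n, 2, M); returns (n, M).
    """
    n, _, m = parents.shape
    switch = np.empty((n, m), dtype=np.int8)
    switch[:, 0] = rng.integers(0, 2, size=n)  # which haplotype starts
    switch[:, 1:] = rng.random((n, m - 1)) < r if m > 1 else 0
    hap_choice = np.cumsum(switch, axis=1) % 2
    return np.take_along_axis(parents, hap_choice[:, None, :], axis=1)[:, 0, :]


def simulate_cross(config: SimConfig) -> Population:
    """Simulate the pedigree and phenotypes described by ``config``.

    Founder breeds are fixed for opposite alleles at every marker; the F1 is
    uniformly heterozygous.  ``backcross`` crosses each generation back to
    the (homozygous) sire breed ``n_backcross_gens`` times; ``f2_intercross``
    mates independent F1 gametes.  All randomness flows from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pedigree, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    chrom, pos, qtl_index = _marker_map(config)
    m = len(pos)
    r = _recomb_fractions(chrom, pos)
    n = config.pop_size

    f1 = np.zeros((n, 2, m), dtype=np.int8)
    f1[:, 1, :] = 1  # dam haplotype all-ref, sire haplotype all-alt

    if config.design == "f2_intercross":
        hap_a = _gametes(f1, r, rng_pedigree)
        hap_b = _gametes(f1, r, rng_pedigree)
        haplotypes = np.stack([hap_a, hap_b], axis=1)
    else:
        current = f1
        for _ in range(config.n_backcross_gens):
            seg = _gametes(current, r, rng_pedigree)  # segregating gamete
            sire = np.ones_like(seg)  # recurrent parent is homozygous alt
            current = np.stack([seg, sire], axis=1)
        haplotypes = current

    dosage_qtl = haplotypes[:, :, qtl_index].sum(axis=1).astype(float)
    genetic = config.qtl_effect * dosage_qtl
    var_g = float(np.var(genetic))
    if config.qtl_effect == 0.0 or var_g == 0.0 or config.h2 == 0.0:
        sigma_e = 1.0
    elif config.h2 == 1.0:
        sigma_e = 0.0
    else:
        sigma_e = float(np.sqrt(var_g * (1.0 - config.h2) / config.h2))
    phenotypes = genetic + rng_noise.normal(0.0, sigma_e, size=n)

    return Population(
        haplotypes=haplotypes,
        phenotypes=phenotypes,
        chrom=chrom,
        pos=pos,
        qtl_index=qtl_index,
        config=config,
    )


def select_bulks(pop: Population, bulk_size: int) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of the extreme-phenotype bulks.

    The high bulk takes the ``bulk_size`` largest phenotypes (ties broken by
    smaller individual index), then the low bulk takes the smallest among
    the remaining individuals, same tie-break.  Returned index arrays are
    sorted ascending.
    """
    n = len(pop.phenotypes)
    if 2 * bulk_size > n:
        raise ConfigurationError("2 x bulk_size exceeds the population size")
    idx = np.arange(n)
    # stable sort descending by phenotype keeps index order within ties
    desc = idx[np.argsort(-pop.phenotypes, kind="stable")]
    high = np.sort(desc[:bulk_size])
    remaining = np.setdiff1d(idx, high, assume_unique=True)
    asc = remaining[np.argsort(pop.phenotypes[remaining], kind="stable")]
    low = np.sort(asc[:bulk_size])
    return high, low


def bulk_frequencies(pop: Population, indices: Sequence[int]) -> np.ndarray:
    """True alt-allele frequency per locus over a bulk, from the genotypes."""
    sub = pop.haplotypes[np.asarray(indices, dtype=int)]
    return sub.sum(axis=(0, 1)) / (2.0 * len(indices))


def _sample_names(prefix: str, indices: Sequence[int]) -> List[str]:
    return [f"{prefix}{i:04d}" for i in indices]


def emit_vcf(
    pop: Population,
    high: Sequence[int],
    low: Sequence[int],
    config: SimConfig | None = None,
    dest: Union[str, PathLike, IO[str], None] = None,
) -> str:
    """Write the bulked individuals as a VCF 4.2 text stream.

    One sample per bulked individual (high bulk first, named ``H<idx>``,
    then ``L<idx>``), phased GT from the simulated haplotypes, REF ``A`` for
    the dam allele and ALT ``C`` for the sire allele, QUAL fixed at 200 so
    default quality filters pass.  When ``config.depth`` > 0 an AD field is
    added with Poisson read depth and binomial allele sampling.  Returns the
    VCF text; also writes it to ``dest`` when given.
    """
    config = config or pop.config
    ss = np.random.SeedSequence(config.seed)
    rng_depth = np.random.default_rng(ss.spawn(3)[2])

    high = np.asarray(high, dtype=int)
    low = np.asarray(low, dtype=int)
    order = np.concatenate([high, low])
    names = _sample_names("H", high) + _sample_names("L", low)
    haps = pop.haplotypes[order]  # (k, 2, M)
    n_samp, _, m = haps.shape

    with_ad = config.depth > 0
    if with_ad:
        depth = rng_depth.poisson(config.depth, size=(m, n_samp))
        p_alt = haps.sum(axis=1).T / 2.0  # (M, k)
        alt_reads = rng_depth.binomial(depth, p_alt)

    lines: List[str] = [
        "##fileformat=VCFv4.2",
        "##source=bsascan-cross-simulator",
    ]
    for c in range(1, config.n_chrom + 1):
        lines.append(f"##contig=<ID={c},length={config.chrom_length_bp}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_ad:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names))

    fmt = "GT:AD" if with_ad else "GT"
    for j in range(m):
        fields = [
            str(int(pop.chrom[j])),
            str(int(pop.pos[j])),
            ".",
            "A",
            "C",
            "200",
            "PASS",
            ".",
            fmt,
        ]
        for k in range(n_samp):
            gt = f"{haps[k, 0, j]}|{haps[k, 1, j]}"
            if with_ad:
                d, a = int(depth[j, k]), int(alt_reads[j, k])
                gt += f":{d - a},{a}"
            fields.append(gt)
        lines.append("\t".join(fields))
    text = "\n".join(lines) + "\n"

    if dest is not None:
        if isinstance(dest, (str, PathLike)):
            with open(dest, "w") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text
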