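# Methods

## The mapping model

Bulked-segregant analysis assumes a biallelic quantitative trait locus
(QTL) segregating in a cross between two divergent founder lines. Two
bulks are formed from the individuals with the most extreme phenotypes;
each bulk's alternate-allele frequency is estimated per site, either by
counting alleles across the bulk's called genotypes (`GT` mode, the
default — appropriate when every individual is sequenced separately and
pooled in silico) or by summing per-sample allelic depths (`AD` mode, for
physically pooled libraries). Selection on the phenotype distorts allele
frequencies only at loci linked to the trait, so the allele frequency
difference

    AFD_i = | f_H,i − f_L,i |

is near zero genome-wide and rises toward a causal locus. Raising it to
the fourth power, `PowerAFD = AFD⁴`, shrinks background noise (an AFD of
0.3 contributes 0.008) far more than linked signal (0.9 → 0.66) and is
the per-locus ranking statistic.

## Site filters

Two filters define the "AFD-SNP" set fed to the density scan, both with
inclusive thresholds:

* **informative band** — each bulk frequency must satisfy `f ≤ 0.45` or
  `f ≥ 0.55`: a bulk sitting near 0.5 carries no segregation signal. We
  apply the band to *both* bulks (each must deviate from 0.5); applying it
  to the AFD value instead is reachable through configuration.
* **AFD threshold** — `AFD ≥ 0.3`.

Ingestion keeps only biallelic SNPs with `QUAL ≥ 100` (configurable) and
at least one called allele per bulk. Multiallelic records are skipped
rather than split — the statistics are defined on a single alternate
frequency, and splitting would create dependent pseudo-sites. Indels are
excluded wholesale: hybrid F1 indel genotypes are prone to being
mis-called as homozygous, which corrupts AFD. Missing genotypes leave the
numerator and denominator together (unbiased frequency at reduced n); a
site is dropped only when a bulk has no called allele at all.

## Windowed scans

**Density scan.** 1 Mb windows advance by 200 kb from position 1 to the
chromosome end (the trailing window is truncated, and its density refers
to its actual span). A window is flagged when its AFD-SNP density strictly
exceeds 30 per Mb; overlapping or book-ended flagged windows merge into
maximal candidate regions. The 200 kb step (rather than a 1 Mb tiling)
lets region boundaries resolve to 200 kb while spanning several Mb.

**Expectation goodness-of-fit (DFScore).** Under a given cross design the
bulk frequencies at a tightly linked marker take one of a small set of
exact Mendelian values:

| design | role | admissible f |
|---|---|---|
| F2 intercross | dominant bulk | 1/3, 2/3 |
| F2 intercross | recessive bulk | 0, 1 |
| homozygous bulks | either | 0, 1 |
| backcross | either | 0, 1/2, 1 |

(The backcross row follows from one haplotype always coming from the
homozygous recurrent parent.) Expected values are stored as exact
rationals. In windows of 10 consecutive SNPs (step 5) the score is the
mean squared deviation from the nearest admissible value over both bulks:

    DFScore = (1/2n) Σ_i [ (f_H,i − ê_H,i)² + (f_L,i − ê_L,i)² ]

DFScore = 0 exactly when every site in the window sits on an expectation
in both bulks. Windows with `DFScore ≤ 0.0025` (root-mean deviation 0.05
frequency units; configurable) are flagged *best*. The within-window
sample variances of each bulk's frequencies are reported alongside, so
the alternative "variance near zero" reading of a best window is also
available. A trailing window with fewer than 10 SNPs is emitted and
marked partial rather than silently dropped. At a frequency equidistant
from two expectations the smaller expected value is chosen,
deterministically; the deviation is identical either way.

**Peak location.** The genome-wide peak of a per-site statistic is
reported as the midpoint of the span of tied maximal sites, not the first
maximum: in a backcross with a strong QTL, the causal site and its fully
co-segregating neighbours tie exactly (AFD = 0.5 over a multi-Mb run),
and a first-maximum rule would systematically hit the proximal edge of
the run. The midpoint is the centre of the interval estimate.

**Expression triage.** Genes overlapping a candidate region are classed
from a gene × sample TPM table by the maximum over samples of
`log2(TPM + 1e−6)` (the offset keeps zero-expression genes finite and far
below any cut): strictly below 1 → not expressed; strictly above 8 →
highly expressed; otherwise expressed. Inequalities are strict, so a gene
whose maximum is exactly TPM = 2 counts as expressed.

## The cross simulator

The simulator emulates the breeding design the scans assume — a
low-trait dam breed crossed to a high-trait sire breed, followed by an F1
intercross or by repeated backcrossing to the sire breed (as in
graded-up hybrid beef pedigrees) — with fully divergent founders, so
allele 1 marks the sire-breed haplotype everywhere.

* **Meiosis**: Haldane map function at a uniform 1 cM/Mb
  (`r = (1 − e^(−2d)) / 2`, d in Morgans), crossovers independent across
  intervals; the simplest standard choice.
* **Markers**: evenly spaced per chromosome; the QTL position is inserted
  as a genotyped locus if no marker falls on it.
* **Phenotype**: purely additive single QTL, `y = a·dosage + ε`,
  `ε ~ N(0, σ²)` with σ² set from the realized dosage variance so the QTL
  explains exactly h² of the phenotypic variance. With zero effect the
  noise SD defaults to 1 (a pure-noise trait); h² = 1 with zero effect is
  rejected as contradictory.
* **Bulks**: the `bulk_size` largest and smallest phenotypes; ties break
  deterministically by individual index (high bulk first).
* **Sequencing noise**: when a mean depth is set, per-sample per-site read
  depth is Poisson and alternate reads binomial in the genotype dosage —
  the standard pooled-seq model. GT fields are always exact.
* **Determinism**: one integer seed spawns three independent generator
  streams (pedigree, phenotype noise, depth), so a fixed seed yields
  byte-identical VCF output and components can be regenerated separately.

Reference scenario (the defaults, used by the test suite and the
acceptance script): one 100 Mb chromosome, 200 markers (0.5 Mb spacing),
QTL at 50 Mb with effect 1.0 and h² = 0.8, 400 backcross progeny, bulks
of 20, depth 10×. These sizes mirror a modest single-family livestock
mapping design — bulk allele counts of 40 give a per-site frequency SE of
about 0.08, which is what makes the fourth power worthwhile. Under this
scenario the PowerAFD peak lands within 5 Mb of the true QTL in ≈96% of
replicates (long-run, measured over 500 seeds), and matched null
simulations flag no density region.

### What the simulator does not model

Real demography (founder diversity within breeds, selection during
breeding), genotyping error beyond depth sampling, indels and
multiallelic variation, non-uniform recombination maps, polygenic
backgrounds (a multi-QTL configuration is possible but the default is a
single locus), and linkage disequilibrium inherited from the founder
populations. Passing tests therefore demonstrate that the statistics and
window machinery behave correctly under the idealized Mendelian model,
not that real data of a given size will localize a QTL equally well.

## Numerical choices

* Statistics are computed in double precision; 7-decimal rounding
  (round-half-even) applies only when tables are written, matching the
  reporting precision of per-locus hits.
* Expectation sets are exact `Fraction`s; 1/3 is never a decimal
  rounding.
* Density thresholds are strict (`> 30/Mb`), site filters inclusive
  (`≥ 0.3`, band edges included on the informative side), as printed.
* Sample variance uses the n−1 denominator and is defined as 0 for
  single-site windows.
* Chromosomes sort naturally (2 before 10) regardless of VCF header
  order; an unsorted VCF (positions decreasing within a chromosome) is an
  input error, not silently reordered.

## Known limitations

* `Region.n_snps` reports the densest member window's count, not the
  deduplicated union count over the merged span (peak density is the
  headline figure).
* The DFScore windowing is defined on SNP counts, so window genomic
  spans vary with local SNP density; scores are not comparable across
  windows of very different spans without care.
* AD-mode frequencies are read-sampling estimates; the exactness
  guarantees (round-trip identity, integer allele conservation) hold for
  GT mode only.
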