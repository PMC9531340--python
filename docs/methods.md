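# Methods

This note documents the models, parameter choices, and numerical conventions
behind `bulkmap`, and what the test suite does and does not establish.

## Study design being modelled

A recessive, monogenic mutant recovered from an EMS-mutagenized inbred line
is crossed to its wild-type progenitor; F2 plants with the mutant phenotype
are pooled ("the bulk") and sequenced together with both parents. Because
the bulk is fixed for the mutant haplotype at the causal locus, the
mutant-allele read fraction (SNP index) drifts from 0.5 toward 1.0 with
increasing linkage, and the causal interval appears as a high-index plateau.

## SNP filtration

Rules and boundary semantics (all depths are summed allele depths, AD, not
the DP field — the same reads the SNP index later uses):

| rule | predicate (fail condition) | default |
|------|----------------------------|---------|
| i    | parent depth < 3 or > 100; bulk depth < 5 or > 150 | inclusive-pass at the bounds |
| ii   | any sample GQ < 20 | GQ 20 passes; absent GQ treated as 99 |
| iii  | wild-type parent het or uncalled | — |
| iv   | bulk heterogeneous and all its alleles foreign to both parents | — |
| v    | parents not homozygous for different alleles | — |
| vi   | wild-type → mutant substitution not G→A / C→T | `ems_only` switch |

Attribution is first-failing-rule, which makes the report an exact partition
of the input (testable by conservation). Rule (iv) is provably vacuous on
biallelic records — a heterogeneous bulk then shows exactly {ref, alt},
which always intersects a non-missing parent genotype — but it is kept as an
explicit predicate so that inputs decomposed from multiallelic sites
exercise it. The EMS orientation in rule (vi) is defined by the parents'
homozygous alleles, not by VCF ref/alt polarity, so a site where the
reference genome happens to carry the mutant base is still classified
correctly.

Missing genotypes are kept as `missing` (and then removed by rule iii when
they affect the wild-type parent) rather than dropped at read time; a
`drop`-style policy can be emulated by filtering the record list before the
cascade.

## SNP index and window scan

The index of a site is mutant-allele reads over total bulk reads; sites with
zero bulk depth, or where the mutant parent is not homozygous, are excluded
with a logged count rather than imputed. No correction for sequencing error
is applied — the raw index is what gets smoothed and thresholded.

Window geometry defaults: **2 Mb window, 10 kb step, minimum 3 SNPs per
window, arithmetic-mean smoothing**. The source analysis does not state its
window parameters; these values are common MutMap practice and resolve
signal at the scale of a multi-megabase candidate interval while masking
windows too sparse to average meaningfully. All are configurable.

The **0.80 threshold** is applied to the smoothed track (matching the usual
presentation of an index plot with a dotted threshold line over a smoothed
curve); a `--raw` switch thresholds unsmoothed per-SNP indices instead.
Candidate regions are maximal runs of consecutive unmasked above-threshold
windows; their bounds are snapped inward to the first and last raw SNP in
the run's span, and the reported length is (end − start)/10⁶ Mb rounded to
two decimals. Regions are returned sorted by peak smoothed index, so the
first region is the mapping signal. Raising the threshold can only shrink
the called footprint (tested as a monotonicity property).

## Segregation statistics

Two-class 1-df goodness of fit. With the Yates continuity correction the
statistic is `Σ max(|Oᵢ − Eᵢ| − 0.5, 0)² / Eᵢ`; the floor at zero keeps the
exact-fit case at χ² = 0. The correction is **on by default** because the
corrected form is what reproduces the reference F2 and BC1 statistics this
package's tests pin down (321:89 vs 3:1 → 2.198; 18:20 vs 1:1 → 0.026; the
uncorrected values would be 2.371 and 0.105). P-values are the upper tail of
χ²(1) via scipy. The `SegregationTest` object carries the exact floating
statistic; 3-decimal rounding (the usual table format) happens only in
reports, because rounding before comparison can invert the
corrected ≤ uncorrected ordering at the 5×10⁻⁴ level.

Only two-class tests are supported (df = 1); multi-class heterogeneity
chi-squares are out of scope.

## Consequence annotation

A splice-region substitution is defined as one within the first or last
2 nt of an intron (the canonical GT donor / AG acceptor dinucleotides).
The model for such a hit is single-intron retention: exactly that intron is
left in the mature transcript; exon skipping, cryptic splice sites and
multi-intron effects are not modelled. The retained transcript is
re-translated from the annotated start codon; `frameshift` is true when the
retained length is not a multiple of 3. An in-frame, stop-free retained
intron therefore lengthens the protein without truncation, and the
transcript-length delta always equals the retained intron length (both are
tested invariants). Exonic substitutions are re-translated and classified by
comparing the mutant and wild-type products; a stop-loss (longer product) is
reported as missense, since EMS transitions essentially never remove stops
and a dedicated class was not warranted. Exonic positions outside the CDS
leave the protein unchanged and come out as synonymous.

Classification is deterministic and strand-symmetric: a gene and its
reverse-complement mirror yield identical classes and lengths (tested on
mirrored fixtures). Only single-nucleotide substitutions are supported —
EMS produces transitions.

## Synthetic data generator

What it emulates, and the defaults chosen where the design left them open:

- **Genome**: 2 chromosomes × 10 Mb, named A01/A02. Large enough for a
  multi-megabase candidate region and an unlinked control chromosome, small
  enough that a full run takes well under a second.
- **EMS density**: 5×10⁻⁶ per bp (~100 sites over 20 Mb), an
  order-of-magnitude convention for a single EMS line; site counts are
  Poisson(rate × genome size), positions uniform, every induced substitution
  G→A or C→T on the reference strand.
- **Cross and selection**: each bulk plant is two independent F1 gametes;
  crossovers follow a Poisson process along the chromosome (Haldane model,
  no interference; r = (1 − e^(−2d))/2) at 4 cM/Mb, a typical Brassica-scale
  recombination density. Plants are rejection-sampled until 30 are
  homozygous mutant at the causal locus — the bulk size of the modelled
  design.
- **Read sampling**: per-site Poisson depth (bulk 50×, parents 30×),
  binomial allele counts with symmetric per-base error 0.001, genotypes
  called by majority with a het call when the minor allele holds > 20% of
  reads — a simulator convention, not a claim about any production caller.
  GQ is synthesized at 99.
- **Background noise** (rate 1.5×10⁻⁶ per bp): parent-shared variants,
  residual wild-type heterozygosity, and non-transition mutant-specific
  sites, so rules (iii), (v) and (vi) do real work end to end. The
  wild-type-het class is given an independent Binomial(2N, 0.5) bulk
  frequency rather than full pedigree tracking; it exists to exercise the
  filter, not to model residual heterozygosity faithfully.

What passing tests on this generator do **not** show: performance on real
data with alignment artifacts, indels, multiallelic sites, mapping-quality
pathologies, structural variation, or reference bias — none of which are
simulated. The generator validates the statistical logic of the pipeline
(linkage expectations, selection, filtration, window scanning), not a
variant caller.

The bundled **synthetic gene** (`make_causal_gene`) reproduces the published
*architecture* of the mapped locus — seven exons and six introns, a 2517-bp
genomic span, a 1896-nt spliced CDS encoding 631 residues, and a 98-nt
second intron whose retention yields a 1994-nt transcript — with
seeded-random sequence content, since the real sequence is unpublished. Its
intron 2 carries an early in-frame stop after the donor so that retention
deterministically truncates the product (to 185 residues in this synthetic
sequence; the real allele's products are not reproducible without the real
sequence). A codon-aligned TGG in exon 4 provides the premature-stop
fixture.

## Numerical and interface conventions

- Coordinates are 1-based inclusive in every domain type; half-open
  conversions live inside the readers.
- VCF: v4.2, FORMAT `GT:AD:DP:GQ`, sample order wt_parent / mut_parent /
  bulk. Indel and multiallelic lines are dropped with a logged count by
  default (an `error` mode is available). Absent GQ is treated as 99 — the
  absence of an annotation should not silently delete data.
- All randomness flows through one `numpy.random.Generator` seeded from the
  run seed; a fixed seed reproduces every output byte-for-byte.
- The run report is a pure function of the stage outputs; every number in it
  can be recomputed by calling the stage functions on the written files.

## Problem sizes used in validation

The statistical acceptance checks use 1000-record randomized filter
fixtures, ≥ 1020 bulk chromosomes per recombination fraction for the
linkage-law checks (r ∈ {0, 0.1, 0.25, 0.5}, tolerance 3 standard errors),
100 seeded end-to-end simulations at study scale (30-plant bulk, 50× depth,
error 0.001) for causal-locus recovery, and 1000 random tables for the
Yates-bound property. These sizes make the full suite run in a few seconds
while keeping Monte-Carlo tolerances honest.

## Known limitations

- Single-transcript gene models only; no UTR-aware classes, no NMD
  prediction, no splice-strength scoring.
- No confidence bands on the SNP index under the null; region calling is a
  fixed-threshold rule by design.
- The filter cascade assumes exactly three sample roles; designs with two
  bulks (high/low) or without a mutant-parent sample are out of scope.
- Real-data scale counts (millions of raw SNPs) depend on upstream
  alignment and calling choices and are intentionally not reproduced here;
  the pipeline starts at the VCF.
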