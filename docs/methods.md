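# Methods

## The detection model

`mthet` treats heteroplasmy detection as a per-position decision problem on
a pileup of single-end reads aligned to a linearised mitochondrial
reference. There is no probabilistic genotype model: the method is a set of
hard filters and thresholds chosen for specificity on data of moderate,
uneven coverage (the mtDNA fraction of ChIP-seq experiments, typically
20–100×), where likelihood-based micro-heteroplasmy callers are
underpowered and error-model fitting is fragile.

Assumptions baked into the design:

- Reads are single-end and ungapped or nearly so; mate information, if
  present, is ignored. Indels are not called; reads with a deletion at a
  position simply contribute no entry to that column.
- The reference is treated as ground truth. Reference mismatch (e.g. a
  sample aligned to a related species' genome) shifts the major allele but
  not the minor-allele logic.
- The reference is consumed as linear. Reads spanning the circular origin
  junction are out of scope; the few dozen terminal positions consequently
  run at reduced depth.
- Sequencing errors are (i) mostly independent per base and rare enough
  that two independent same-base errors per strand at one site are
  improbable, and (ii) when location-specific, strongly strand-asymmetric.
  Assumption (ii) is what the two-reads-per-strand rule exploits.

## Pipeline and parameters

Preprocessing: experiments of one individual are merged (multiset union,
coordinate-sorted); duplicates — reads sharing (contig, start, strand,
aligned span) — are collapsed to the single copy with the highest MAPQ
(ties keep input order; the span can be dropped from the key via
`use_span=False`); reads with MAPQ ≥ `min_mapq` are extracted.

| parameter | default | units | role |
|---|---|---|---|
| `min_mapq` | 20 | Phred-scaled | discard ambiguously mapped reads (NUMT protection) |
| `min_base_quality` | 23 | Phred | filter 1: base at the position |
| `neighbor_window` | 5 | read bases/side | filter 2 window |
| `min_neighbor_quality` | 15 | Phred | filter 2: every existing neighbour |
| `min_depth` | 20 | reads | criterion 1 |
| `min_minor_fraction` | 0.15 | proportion of filtered depth | criterion 2 |
| `min_minor_per_strand` | 2 | reads | criterion 3, per strand |

All thresholds are inclusive lower bounds (“at least”). Two boundary
conventions deserve note, since prose descriptions of such filters are
often ambiguous by one unit: a base of quality exactly 23 is **kept**
(discard-if-below-23), and a minor fraction of exactly 15 % **passes**.
Both are configurable, and the fraction comparison uses exact rational
arithmetic (`count · denominator ≥ numerator · depth` with the threshold
parsed as a decimal fraction), so columns like 15/100 are decided exactly
rather than by floating-point rounding.

Neighbour qualities are taken in *read* coordinates (adjacent sequenced
bases), which is how quality strings are indexed and is robust to nearby
indels. At read ends only the neighbours that exist are evaluated: the
rule discards on low-quality neighbours, not absent ones.

The minor-fraction denominator is the full filtered depth, not
major+minor. Tie conventions: if two alleles tie for the top count the
reference allele (else the alphabetically smaller) is the major; if two
tie for second place, the candidate passing the strand criterion is
evaluated, and if both pass the alphabetically smaller is taken and the
tie flagged on the call. Reads carrying any other base are tallied as
`third_count`; a third allele is never promoted, so calls are strictly
biallelic. Every no-call carries a machine-readable list of failed
criteria (`depth`, `minor_fraction`, `strand`).

Low-complexity regions are **not** excluded from scanning: homopolymer
stretches are error-prone but also genuinely hypermutable, and the strand
and neighbour-quality filters are the defence instead. The five classical
human low-complexity intervals (66–71, 303–309, 514–523, 12418–12425,
16184–16193) ship as a ready-made region set for reporting, not masking.

Two depth notions are kept separate and never mixed: *coverage* (pre
quality-filter depth of the preprocessed alignment, the quantity a depth
utility reports; used for mean/SD and the coverage ratio = fraction of
positions with ≥ 20 reads) and the caller's *filtered depth*. Coverage SD
uses the n−1 sample denominator.

## Downstream analyses

- **Mutation spectrum**: each call contributes one count to its
  major→minor cell among the 12 directional substitution classes, oriented
  on the reference-forward strand (complementary classes are not
  collapsed). Ts = {A↔G, C↔T}; a zero-transversion spectrum reports the
  Ts/Tv ratio as undefined rather than infinite. Spectrum comparisons: a
  two-sided Fisher exact test on the [[Ts,Tv],[refTs,refTv]] table, and a
  Pearson χ² of the 12-cell spectrum against reference proportions scaled
  to the observed total (zero-expectation cells dropped; dof = cells − 1).
- **Consequence annotation**: overlap classes with precedence
  protein_coding > tRNA > rRNA > D_loop > other_intergenic; coding changes
  are translated under NCBI table 2 (vertebrate mitochondrial: TGA=Trp,
  ATA=Met, AGA/AGG=stop; overridable for non-vertebrates), handling
  reverse-strand CDS by reverse complement. This is a deliberately minimal
  single-nucleotide, single-CDS predictor — enough for the
  synonymous/nonsynonymous dichotomy, not a general effect predictor.
  Incomplete stop codons completed by polyadenylation are translated from
  genomic sequence as annotated.
- **Cross-species mapping**: a multiple alignment induces per species a
  strictly monotone bijection between ungapped positions and alignment
  columns; orthologous positions are the composition source → column →
  target. A target gap yields an explicit unmappable report, never a
  nearest-position guess; ambiguity characters count as non-gap. One MSA
  mechanism serves both the low-complexity-region counting and the
  disease-association transfer, keeping the package self-contained
  (no external liftover service).

## The simulator, and what it does not emulate

The generator produces coordinate-sorted ungapped single-end alignments:
uniform read starts on a linear reference (default 16,500 bp, 50 bp reads,
mean depth 60×), Gaussian Phred profile (mean 35, SD 3, floor 10, cap 41),
MAPQ 60, optional PCR duplicates (coordinate-identical copies with fresh
quality draws). Planted heteroplasmies are generative: each covering read
carries the minor allele with probability f (Bernoulli), split by the
configured strand balance b (forward-read probability 2fb, reverse
2f(1−b)), so realised minor counts are binomial around the target — the
same sampling noise real sequencing produces. Independent errors are
injected after planting (uniform among the other three bases), plus
optional one-strand error sites. Contamination mixes in
`round(fraction · n)` reads drawn from a diverged copy of the reference
(default 10 % substitution divergence), mapped at low MAPQ (default 10) to
mirror how cross-species reads align, with an option to give a
sub-fraction confident MAPQ to stress the caller. Everything is a pure
function of (config, seed); identical seeds give byte-identical SAM.

Not emulated: real indels and soft-clipping, ChIP enrichment structure,
NUMT cross-mapping, position-dependent quality decay along reads,
GC-coverage bias, and circular-junction reads. Passing tests on this
generator therefore demonstrate the decision logic and its operating
characteristics under the stated noise model — not robustness to
alignment artifacts, which the MAPQ filter only partially proxies.

A consequence of Bernoulli planting worth stating explicitly: at 60× the
detection probability of a variant planted at exactly the 0.15 threshold
is ~0.5, and at 0.20 it is ≈ 0.82 (binomial mass below the 15 % cut, plus
a small strand-rule loss), reaching ≈ 0.99 at 0.30. Pooled over planted
fractions {0.2, 0.3, 0.5} the measured sensitivity is 0.94 at the default
conditions. This is the method's true operating characteristic near
threshold, not an implementation defect; specificity is the design
priority, and error-only genomes (error rate ≤ 0.5 %) as well as
strand-confined error sites (up to 30 % of one strand) and 10 %
cross-species contamination all yield zero calls in the test and
acceptance suites.

Truth labels (`label_truth`) are expectation-based: a planted variant is
labelled callable when its expected depth, fraction and per-strand minor
counts clear the thresholds; configs whose expectations cannot satisfy the
strand rule, and plants identical to the reference base, are flagged with
warnings instead of being silently mislabelled.

## Problem sizes and numerical choices

The simulation-heavy suites run on shortened references — 1.0–1.2 kb at
the full 60× depth for the 50-genome brute-force equivalence, 100-seed
strand-bias and 250-genome sensitivity/specificity studies — since the
per-position decision rules are length-invariant; the contamination null
and the acceptance script use the full 16.5 kb genome. The vectorised
pileup engine (one pass over all positions, neighbour minima via a padded
sliding window) is verified position-by-position against a naive
O(reads × length) oracle, and the Fisher exact test against exhaustive
hypergeometric enumeration (all tables with row sums ≤ 16, plus sampled
larger margins).

Degenerate inputs: empty read sets scan to empty tables (not errors);
unanimous columns are fraction-criterion no-calls; constant inputs make
the coverage–heteroplasmy Pearson correlation undefined (returned as
`None`, never NaN-propagated); zero-transversion spectra have undefined
Ts/Tv.

## Known limitations

- No likelihood model: minor alleles below 15 % are invisible by design;
  thresholds trade sensitivity near the boundary for specificity.
- Strictly biallelic calls; true triallelic sites (not observed in
  practice) would surface only through `third_count`.
- No phasing: the number of distinct mtDNA haplotypes behind ≥ 2
  heteroplasmic positions in one individual is not identifiable from
  short single-end reads.
- The duplicate rule collapses natural coordinate collisions at high
  depth with fixed-length reads (~25 % of reads at 60×/50 bp/16.5 kb),
  deflating post-dedup depth; this mirrors the behaviour of classical
  single-end duplicate removal on real data.
- Consequence prediction ignores overlapping genes' second reading frames
  and tRNA/rRNA structural effects.
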