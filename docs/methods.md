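# Methods

This note documents the statistical models, parameter choices and design
decisions behind `clonsel`, and states what the synthetic-data tests do and
do not demonstrate about real data.

## Merged variant table

The unit of analysis is a transcriptome position with per-sample reference
and alternative read counts (bases at phred ≥ 20; alignment score ≥ 20 and
duplicate removal are upstream responsibilities of the aligner/pileup and
are only documented here). The merged table is the union over the pair of
all sites with ≥ 1 alternative read in either sample. Two conventions
matter downstream:

* **Missing ≠ zero.** A site absent from one sample's pileup is recorded
  with that sample's counts missing (NaN). Missing counts fail the depth
  filter; they are never treated as AAR = 0, which would fabricate
  evidence of absence.
* **Genotype estimate.** "Non-homozygous reference" is operationalized as
  alt_count ≥ 2 and AAR ≥ 0.05. Requiring two alternative reads means a
  lone sequencing error cannot create a genotype; the 5% floor keeps
  high-depth error accumulations out. These two values are this package's
  definition (upstream callers each have their own), exposed in
  `Thresholds`.
* The genotype rule is required in **at least one** sample, not both: a
  truly de-novo-appearing subclone mutation is hom-ref in the sensitive
  sample by construction, and demanding non-hom-ref in both would discard
  exactly the variants the analysis exists to find.

## Inclusion filter

The decision tree is evaluated in fixed order (genotype, depth, coding,
segmental duplication, evidence) and an audit trace records every rule's
verdict per variant. Points where the rules required interpretation:

* Depth is strict: `> 10` reads in both samples (configurable).
* "Coding" means `location_class == exonic` and not synonymous; splice-site
  variants are excluded under this conservative reading (configurable via
  the annotation's location classes).
* The three evidence branches are exhaustive: COSMIC-catalogued variants
  need 1000g CEU AF < 5% *if* a frequency is reported; novel variants
  (no 1000g CEU, no dbSNP) need SIFT *or* PolyPhen2-HDIV "deleterious";
  dbSNP-known variants absent from 1000g CEU need *both*. A variant
  present in 1000g CEU but not in COSMIC has no admitting branch and is
  excluded — population polymorphism without somatic evidence is treated
  as germline.
* PolyPhen2 "possibly_damaging" is not "deleterious".
* COSMIC membership is matched by position **and** allele by default; a
  position-only mode exists for annotation sources that only record
  positions.
* Unannotated merged-table records are excluded and counted separately
  ("unannotated"), never silently dropped.

## Clonal-selection test

For each included variant the two-sided Fisher exact p-value of
`[[ref_s, alt_s], [ref_r, alt_r]]` is computed by summing hypergeometric
point probabilities not exceeding the observed table's. Implementation
details:

* Point probabilities come from cached log-factorials (`scipy.special.gammaln`);
  the summation and tie handling are this package's own. Tables whose
  probability is within relative tolerance `1e-7` of the observed one
  count as ties and are included — the convention shared by standard
  implementations, and fixed here so results are reproducible to the digit.
  Degenerate margins give p = 1.
* The test suite verifies agreement with an exact big-integer enumeration
  (tolerance 1e-9 over all tables with total ≤ 60) and with
  `scipy.stats.fisher_exact` on random larger tables; scipy is an oracle,
  not the implementation.
* Classification: *selected_up/down* requires `p ≤ 10⁻³` **and**
  `|ΔAAR| ≥ 0.1` (a minimum effect size — a significant but tiny shift at
  high depth is not treated as clonal selection). Variants failing the
  selection call with AAR > 0.30 in both samples are *ancestral*; the rest
  *unclassified*. The categories are exclusive and exhaustive, and the
  caller applies a fixed per-variant alpha rather than an FDR: the
  selection alpha is an operating point of the screen, not an inference
  about the family of all variants.

## Regional ploidy / allelic imbalance

Expression-derived het-site AARs identify the *ratio* of parental allele
copies, not absolute copy number: a 6:2 region is indistinguishable from
3:1. The reported ploidy k is therefore the smallest consistent value
(m/k in lowest terms) — a deliberate, prominently stated caveat of the
whole approach.

The fit maximizes the mirrored binomial mixture log-likelihood
`Σᵢ log[½·Binom(altᵢ|depthᵢ, r) + ½·Binom(altᵢ|depthᵢ, 1−r)]` over
coprime candidate ratios with k ≤ 10 (up to "deca-ploidy"). The 50/50
mirror reflects unknown phase: either haplotype may carry the alternative
allele. Numerical and design choices:

* Because the mixture is exactly symmetric under r ↔ 1−r, the grid is
  restricted to r ≥ ½ and the reported m is oriented afterwards by the
  empirical mean AAR; mirroring the data (alt → depth−alt) therefore maps
  m → k−m and never changes k.
* A BIC-style penalty `½·ln(n)·(k−2)` treats the denominator as model
  complexity, so a fine ratio (say 5/9) must earn its keep against 1/2 on
  likelihood. Ties break toward smaller k, then toward the more balanced
  ratio.
* Site selection: depth ≥ 20 and AAR strictly inside (0.10, 0.90); and,
  when an annotation table is available, **dbSNP-identified sites only**.
  The restriction matters: somatic subclone variants have AARs that track
  clone fractions (≈ 0.35 at the default subclone fraction), and letting
  them into the pool biases the region fit toward spurious fine ratios.
  Germline polymorphisms are the correct substrate for allelic-imbalance
  estimation.
* Regions with fewer than 20 usable sites are reported as "no-call", not
  fitted.
* An optional beta-binomial likelihood (concentration parameter) is
  provided for overdispersed data; the default is pure binomial.
* The segment grid is fixed (BED input; the synthetic default uses
  cytoband-scale segments). Change-point segmentation is out of scope:
  the report compares band-level regions between samples, with "-"
  denoting absence of allelic imbalance.

This entire module is a re-design from the definition of regional ploidy
as "total number of parental alleles in large genomic regions"; the
original study's estimator was not published in reusable form, so exact
agreement with its real-data calls is not claimed — the tests demonstrate
parameter recovery on data generated under this module's own model.

## Differential expression

With one library per condition, the package uses the exact conditional
binomial test: given a gene's total count n, the sensitive count is
`Binomial(n, lib_s/(lib_s+lib_r))` under the null of equal relative
expression (two-sided by the same minimum-likelihood tie rule as the
Fisher test). This is the canonical replicate-free exact test and is fully
auditable; it is a stand-in chosen by this package, not a reconstruction
of any particular prior tool. DE calls require a pseudocount-protected
normalized fold change ≥ 2.5 in either direction and BH-adjusted
p ≤ 0.01 (BH via `statsmodels`, verified against a brute-force step-up to
1e-12). Genes with zero counts in both samples are excluded from testing
and from the BH denominator. Two caveats are intrinsic and documented
rather than patched:

* **The test sees only sampling noise.** Extra-Poisson (biological)
  variability between cultures cannot be estimated from n = 1 per
  condition; under realistic culture-to-culture dispersion the test is
  anticonservative and the FC ≥ 2.5 gate does most of the biological
  filtering. Passing null-control tests on the generator (see below)
  therefore demonstrates correctness of the statistic, not FDR control on
  real pairs.
* **Column-sum normalization carries composition bias.** When DE is
  asymmetric (more up- than down-regulation or vice versa), the DE signal
  itself shifts the library totals and hence every fold change (≈ 12% on
  the default synthetic plan). `call_de` accepts externally supplied
  library sizes; real analyses should prefer robust size factors.

## Read-overlap merging

Fragments shorter than twice the read length yield overlapping mates;
counting both mates double-counts overlap bases. Detection scans overlap
lengths from the longest possible downwards and accepts the first length
≥ `min_overlap` (default 10) whose mismatch fraction against
reverse-complement(R2) is ≤ `max_mismatch_rate` (default 0.1); `N`
matches nothing and counts as a mismatch. Orientation is assumed FR
(standard Illumina). In the merged overlap each base and quality is taken
from the mate with the higher phred (ties → R1), and the fragment is split
at `floor(len/2)` so every position is covered exactly once; the split
point is this package's choice (it balances downstream coverage), as is
the detection tolerance — neither is dictated by the upstream protocol.
Non-overlapping pairs pass through byte-identically. One identifiability
limit: in random sequence a longer spurious perfect overlap occasionally
exists (probability ≈ 4⁻ᴸ per extra candidate length), in which case no
detector can prefer the geometric truth; with 101 error-free fragments
this affects roughly one pair in ten runs.

## Synthetic-data generator

The generator emulates the study design end to end: an ancestral tumor
clone (fraction 1.0 by default), a resistant subclone absent before
treatment and at fraction 0.7 after (the published design reports neither
subclone fractions nor depths; these defaults are stand-ins chosen once),
regional allelic configurations per sample, and expression with planted
fold changes. Default conditions:

| Parameter | Default | Meaning |
|---|---|---|
| mean_depth / depth_dispersion | 100 / 5 | negative-binomial site depth (CV ≈ 0.46, emulating expression-dependent RNA-seq coverage) |
| resistant subclone fraction | 0.0 → 0.7 | sensitive → resistant sample |
| error_rate | 10⁻³ | alt reads at hom-ref sites (exercises the ≥ 1-alt table rule) |
| neutral segdup fraction | 0.10 | exercises the segmental-duplication exclusion |
| het sites per segment | 80 | substrate of the ploidy fit |
| expression NB size | 1000 | ≈ Poisson; sampling noise only (see above) |
| planted DE plan | 60 genes | folds 3/5/8 up, 1/3–1/8 down, one at 1/17 |

True AARs follow the clone algebra: `ancestral_fraction·m/k` for ancestral
variants, `f·½` for subclone-private variants in diploid regions,
`(1−f)·½` for variants carried by the displaced cells; germline het sites
sit at each sample's `m/k`. Alt counts are binomial at the true AAR
(error-rate for hom-ref sites). Truth rows carry both a *category*
(ancestral / selected_up / selected_down / neutral, always consistent with
the planted AARs — a germline site in a ploidy-divergent region is
genuinely a variant whose AAR shifts, and is labeled accordingly) and a
*source* (ancestral / subclone / germline_het / error) so recovery metrics
can separate mechanism from signature. All randomness flows from one
explicitly passed integer seed; identical seeds give byte-identical
outputs.

What the generator does **not** emulate — and hence what green tests do
not show about real data: spliced alignment and mapping bias,
base-quality miscalibration, indel representation ambiguity, stromal
contamination, the intermediate selection passages (only the endpoint pair
is modeled), biological expression variability, and real annotation
databases (annotations are planted to exercise every filter branch).

## Problem sizes used in the test and acceptance runs

Chosen to make each property statistically meaningful at interactive
runtimes: null size on 10⁵ sites; selection recovery on 750 planted
subclone variants among 2,250 others; ploidy recovery on 9 configurations
× 100 replicates of 60 sites at mean depth 150; Fisher/enumeration
equivalence over all 628,055 tables with total ≤ 60; read geometry over
all 101 fragment lengths in [101, 202). The full suite runs in well under
a minute.
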