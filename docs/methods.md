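# Methods

This note documents the models, conventions, parameter choices and known
limitations of `sdrscan`, stage by stage.

## Coordinates and formats

All intervals are stored 0-based half-open (BED convention) and rendered
1-based inclusive in report tables, so a table row printed `25,381–29,199`
has length 29,199 − 25,381 + 1 = 3,819 bp and the two renderings are an
exact bijection. VCF input is restricted to biallelic SNPs; multi-allelic
and non-SNP records are skipped and tallied, never split, because the
association test and the genotype-configuration classes are defined on
biallelic diploid genotypes only. A record missing an INFO metric referenced
by the hard filter fails that rule (reason `metric_absent:<name>`): treating
absence as a pass would let unannotated records bypass quality control.

## Sex association

* **Hard filter**: a SNP fails iff any of `AF < 0.01`, `AF > 0.99`,
  `QD < 10`, `ExcessHet > 20`, `FS > 10`, `MQ < 58` holds, all strict — a
  value exactly at a threshold passes. These are the standard GATK
  hard-filter expressions for short variants; all five are exposed on
  `FilterRuleSet`.
* **MAF floor**: markers are kept when the pooled-cohort minor allele
  frequency *exceeds* 0.05 (strict, matching "above 0.05").
* **Test**: the allele-count convention of plink `--assoc --fisher` — each
  non-missing diploid genotype contributes two allele observations; missing
  genotypes contribute nothing (no imputation). The two-sided p-value sums
  hypergeometric probabilities of all tables at fixed margins whose
  probability does not exceed the observed table's (minimum-likelihood
  rule); `scipy.stats.fisher_exact` implements exactly this rule and is
  validated in the test suite against a from-scratch exact-rational
  enumeration over every table with total ≤ 30 (agreement ≤ 10⁻¹²).
  A site where one sex has no called genotype is untestable and is tallied
  rather than tested.
* **Multiplicity**: Bonferroni, α divided by the number of tests actually
  performed (after filtering, MAF floor and testability), reported at full
  precision. At the published panel sizes this reproduces 0.05/4,586,112 =
  1.0902×10⁻⁸ and 0.05/3,017,607 = 1.6569×10⁻⁸ (1.09/1.66 ×10⁻⁸ at 3 s.f.;
  note 1.66 vs the sometimes-quoted 1.65 is purely a rounding difference).
* **Clustering**: significant SNPs on one contig merge while consecutive
  gaps ≤ `max_gap_bp` (default 50,000). The default separates a ~115-kb SDR
  cluster from satellite signals ≳ 50 kb away while tolerating the
  marker-free gap across a hemizygous core, where Fisher testing loses power
  because females have almost no called genotypes.

## Depth-ratio hemizygosity scan

Per-sex pooled per-position depth (samtools-depth dialect, values capped at
80,000) is tiled into non-overlapping 1-kb windows from position 1; the
terminal partial window is kept and flagged. Window medians use the
even-count convention (mean of the two central order statistics). Windows
with `median_F + median_M < 400` are `low_depth` and never ratio-classified
(the floor is applied to the *sum* of the per-sex medians — the two tracks
are computed independently, and the guard exists to stabilise the ratio).
Otherwise r = log₂((F+1)/(M+1)); r < −1 is male-biased, r > +1
female-biased, the boundaries themselves unbiased (strict, as in the
source expressions). The r notation is the only reading under which
"smaller than −1" selects regions covered in males only. Runs of ≥ 3
consecutive same-class biased windows (parameter `min_consecutive`) become
sex-specific regions; region calling is deliberately simple run-length
merging, since windows, not regions, are the primary unit. With unequal
cohorts the depths should be rescaled before classification; the pipeline
assumes the balanced design and warns rather than silently rescaling.

## Genotype configurations and heterogamety

For each marker, within-sex genotype tallies decide a class, null classes
first: `female_null` iff the missing fraction among females ≥ 0.5 and among
males < 0.5 (mirror for `male_null`) — hemizygous markers must be caught
before the linked patterns, or their few spurious calls would be
misclassified. Then `xy_linked` iff ≥ 90% of called females are homozygous
for one allele **and** ≥ 90% of called males heterozygous (mirror for
`zw_linked`); otherwise `unlinked`. The 0.9/0.5 thresholds are free
parameters chosen to tolerate the ~2% genotyping error expected at ~11×
coverage while keeping Hardy–Weinberg markers (max ~50% heterozygotes at
MAF 0.5) far from the linked classes. System inference is a majority vote:
XY iff `xy_linked + female_null` strictly outnumber `zw_linked + male_null`
(mirror for ZW; ties are `ambiguous`), and the SDR span estimate is the
minimal interval covering all non-unlinked markers on the contig carrying
most of them. Relabelling every sample's sex provably mirrors every class
and the system call.

## LTR insertion dating

Terminal repeats are aligned globally (match +1, mismatch −1, gap open −5,
gap extend −1; Biopython's `PairwiseAligner`, whose deterministic first
optimum breaks ties). The substitution proportion d excludes gapped columns
from numerator and denominator and is deliberately *uncorrected* for
multiple hits, matching the per-kb reporting convention of LTR dating
tables; a Jukes–Cantor-corrected mode (with delta-method SE scaling) is
available but off by default. The SE of d is a 1000-replicate bootstrap
over aligned columns, which converges to the binomial closed form
√(d(1−d)/n) (verified within 10% at n ≥ 500).

Age conversion defaults to **t = d/μ** with μ = 2.5×10⁻⁹ substitutions
site⁻¹ yr⁻¹ — the convention under which 33.95 subs/kb gives 13.6 Myr, kept
as the default for comparability with that worked example. The
population-genetic convention t = d/(2μ), appropriate when both repeats
mutate independently after insertion, is selectable (`convention=
"standard"`) and halves the ages. The synthetic LTR generator honours
whichever convention is in force, so recovery tests are convention-
consistent. Published per-element tables are internally inconsistent about
the oldest element's rate (0.078 vs 0.034 for the same element); the
pipeline follows the worked example and treats the 162-site/0.078 regime
only as a bootstrap-SE test fixture.

## Telomere and inverted-repeat detection

Telomeric regions are maximal chains of exact TTTAGGG (or CCCTAAA) copies
with inter-copy interruptions ≤ 7 bp (one motif length — a free parameter,
since the upstream tandem-repeat discovery that would define interruptions
is out of scope); a chain is designated telomeric iff it contains ≥ 1000 bp
of motif-matched sequence.

The self-dotplot indexes all k-mers (k = 15) and reports maximal collinear
runs of ≥ 3 consecutive shared k-mers, forward (off-diagonal) and
reverse-complement, the trivial self-diagonal suppressed. At k = 15 a random
120-kb contig has ≪ 1 expected shared k-mer pair, so the defaults give an
essentially noise-free plot; k-mers occurring > 50 times are masked
(standard seed masking) so short-period satellite arrays do not contribute
quadratically many seeds. Reverse-complement seeds of one inverted-repeat
pair lie on a common anti-diagonal (query start + subject end ≈ constant up
to indel drift), so candidate arm pairs are built by banding seeds on that
coordinate (tolerance 300 bp) and splitting bands at query gaps > 300 bp.
Each candidate envelope is extended by ungapped X-drop extension (+1/−2,
drop 10) to recover the arm edges beyond the outermost exact seed, then
re-aligned globally; **percent identity = identical columns / all alignment
columns × 100** (gap columns count in the denominator — this definition is
pinned because the recovery target of ~93.3% is only reproducible under a
fixed denominator convention). Arms are kept at length ≥ 500 bp and
identity ≥ 85%; overlapping and partial arm calls are permitted, since real
IR clusters contain nested partial homologies.

## dS/dN and phylogenetics

dS/dN uses the Nei–Gojobori counting method rather than an ML codon model:
it is fully specified, exactly testable by hand, and adequate for flagging
divergence classes. Per codon, the synonymous site count is the fraction of
the nine single-nucleotide changes preserving the amino acid (averaged
across the two sequences; changes to stop codons count as nonsynonymous
sites, keeping S + N = 3 × codons); multi-site codon differences average
all minimal substitution paths with equal weight, excluding paths through
stop codons (if every path passes a stop, all are used). Proportions are
Jukes–Cantor corrected, dX = −¾·ln(1 − 4pX/3), raising a saturation error
at pX ≥ ¾. Pairs with dS > 0.5 (strict) are dropped as putative tandem
paralogs of uncertain orthology. Codons with gaps or ambiguity codes are
excluded pairwise; only the standard genetic code is supported.

K2P distances use transition/transversion proportions P and Q over
pairwise-comparable columns: d = −½·ln((1−2P−Q)·√(1−2Q)), or with
Γ-distributed rate variation of shape a,
d = (a/2)·[(1−2P−Q)^(−1/a) + ½·(1−2Q)^(−1/a) − 3/2], which converges to the
plain form as a → ∞. At P = 0.1, Q = 0.05 these evaluate to 0.17018 and (at
a = 1) 0.19444; the Γ form always exceeds the uncorrected distance.

Neighbor-joining follows Saitou–Nei: the Q-criterion is minimised with ties
broken by the lowest (row, column) index pair; branch lengths come from the
standard two-point formulas with negative estimates clamped to zero and
tallied; the final three nodes join at a central trifurcating vertex, so the
tree is unrooted. On additive matrices the algorithm returns the generating
topology and branch lengths exactly (property-tested against an independent
path-distance oracle, and cross-checked against scikit-bio's NJ). Bootstrap
supports resample alignment columns, rebuild K2P(+Γ)+NJ, and report the
percentage of successful replicates containing each internal bipartition;
replicates whose resample saturates a distance are skipped and excluded
from the denominator.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed) — identical seeds give
byte-identical files. It emulates the *design* of a two-cohort plant
resequencing study: 100 females + 100 males at 11× mean per-sample depth
(pooled cohort depth negative-binomial with size 10, overdispersed as real
coverage is; Poisson is the size → ∞ limit); a 115-kb SDR on a 200-kb contig
with a 45-kb male-specific core; fully sex-linked markers (X-hom/Y-alt, so
males are uniformly heterozygous) on a 400-bp grid outside the core and
female-null markers inside it; Hardy–Weinberg autosomal SNPs with MAF ~
0.5·Beta(1,3); a 2% symmetric genotype-miscall rate (uniform over the other
three codes); female coverage over the core at 2% of the male mean (the
residual mis-mapping level is a free parameter — published depth ratios
around 9:1 are reachable by configuration); LTR pairs whose expected
*observed* divergence matches the dating convention in force; a
(TTTAGGG)₁₁₁₄ array (≈ 7.8 kb); and a five-arm IR cluster with the
published arm/spacer geometry (1624/3819/3836/2761/1428 bp arms, 2.2/2.7-kb
spacers) at per-pair divergence 0.067 (identity 93.3%), arms planted as
template copies at per-site rate ε solving 2ε − (4/3)ε² = 0.067.

It does **not** simulate reads, mapping artifacts, linkage disequilibrium,
recombination or coalescent genealogy, indels, GC/mappability bias, or
population structure. Passing recovery tests therefore demonstrate the
*inference machinery* under the stated noise model, not robustness to
mapping artifacts or demographic confounding; published marker counts from
real cohorts (e.g. 119 associated SNPs, 107 male-biased windows, "about
146/138" configuration counts) depend on the original reads and are
emulated qualitatively, not reproduced numerically.

## Problem sizes and determinism

The default simulation uses 5,000 autosomal SNPs (plus 20 planted
hard-filter failures) rather than millions: the package's per-marker
operations are scale-free, and this size exercises every code path while
keeping a full pipeline run under a minute. Every stochastic step (genotype
errors, depth draws, LTR mutation, bootstraps) flows from the single run
seed via fixed offsets, so reruns are byte-identical and the run manifest
(config snapshot + seed + per-stage outputs and wall times) reproduces any
result. Recovery panels reported by `scripts/acceptance.py` use 50 LTR
pairs of 10 kb, 200 random additive trees of 4–12 taxa, and the exhaustive
Fisher sweep over all 44,515 tables with total ≤ 30.

## Known limitations

* Association is a marginal per-SNP test: no LD pruning, kinship or
  structure correction; cryptic relatedness would inflate significance.
* The depth scan has no GC/mappability correction and assumes balanced
  cohorts.
* NG86 underestimates dN/dS under strong transition/transversion bias
  compared to ML codon models; values here are for filtering and class
  comparisons, not for formal selection inference.
* The IR caller reports pairwise arms, not a full multi-arm decomposition;
  heavily nested clusters yield several partial pairs per physical arm.
* Telomere scanning requires exact motif copies; degenerate telomeric
  variants are not matched.
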