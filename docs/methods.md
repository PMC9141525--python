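# Methods

This note records the statistical procedures implemented in `radiadiv`, the
modelling assumptions behind the synthetic data generator, and the design
choices made where several defensible options existed.

## Variant and methylome input model

Variants are read from VCF with SnpEff-style `ANN` annotations
(`allele|consequence|impact|gene`). QC follows a per-sample reading of the
depth rule: a genotype with DP ≤ 3 is set missing, and a record is dropped
when the missing-call fraction reaches 1% or site MQ ≤ 20. Multiallelic
records are split into biallelic rows; a genotype carrying a different alt
allele counts as reference for the row under consideration. Only biallelic
SNPs enter π/F<sub>ST</sub>/PCA/NJ; INDELs participate in clade-specific
variant calling and CG-loss classification.

Cytosine reports (Bismark CX dialect, CG context only) are merged across
strands by default: the minus-strand call of a symmetric CpG is added to the
plus-strand C at position − 1. A site–sample cell with total coverage < 3 is
*missing*, never β = 0. The PCA coverage mask keeps sites covered in ≥ 80% of
samples; the published locus count implies some coverage QC but not its rule,
so the 80% mask is this package's choice and is configurable.

## Windowed scans

π uses the unbiased per-site heterozygosity Σ [n/(n−1)]·2p(1−p) divided by
the *full* window length (monomorphic positions count), the convention of
windowed VCF scans. F<sub>ST</sub> is the two-population Weir–Cockerham
variance-component estimator with the ratio-of-sums windowed form
θ̂ = Σa / Σ(a+b+c); sites with a group entirely missing, or monomorphic
overall with no heterozygotes, contribute nothing. Quantile tails (5% by
default) use closed thresholds, so ties at the cutoff are all included and a
tail can exceed its nominal size.

LD pruning is greedy and deterministic: sliding windows of 50 SNPs, step 5,
dropping the right-hand SNP of any pair with dosage r² > 0.2 (missing
entries pairwise-deleted). Only the pruned count is published for the
original analysis; the window/step/threshold triple is the community
convention.

NJ trees are Saitou–Nei with ties broken by the smallest (i, j) index pair
and negative branch lengths clamped to zero. The distance is the
allele-sharing distance 1 − shared/(2·compared) computed on homozygous
genotypes (heterozygous and missing calls excluded) — the published trees
were built from homozygous SNPs, and the metric itself was unstated, so
allele sharing is this package's documented choice.

## dN/dS and selection classes

Pairwise dN/dS uses Nei–Gojobori (1986): synonymous site counts averaged
over both sequences, pathway-averaged difference counts for multi-hit codons
(pathways through stop codons excluded; mutations *to* stops counted as
nonsynonymous for site counting), and Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). This replaces the ML yn00 estimator used
originally: the downstream 5%-tail classification depends only on the
ranking of per-gene means, which NG86 preserves, and it keeps the package
free of an external PAML dependency. Conventions at the boundaries: an
identical pair is undefined; pN = 0 with any synonymous divergence gives a
ratio of exactly 0 even when the JC correction for pS saturates (p ≥ 3/4);
a saturated class with positive divergence is undefined and the pair is
skipped. Per-sample coding sequences substitute homozygous-alt SNPs into the
reference CDS (first mRNA); heterozygous calls and INDELs are left at the
reference base, because the biological consequence of a heterozygous variant
is not affirmable at the consensus level. Gene classes come from the mean of
defined cross-clade pairwise ratios: top 5% positive, bottom 5% purifying,
closed thresholds.

## Differential methylation

Each 100-bp window is tested with a Cochran–Mantel–Haenszel test whose
strata are the window's CG sites; the per-stratum 2×2 table holds the read
counts (methylated/unmethylated) pooled over the covered samples of each
group. Stratifying by site is the natural way to keep windows with very
unequal read depths comparable — the statistic conditions on each site's
margins — and is configurable should a different stratification be wanted.
χ² = (Σ(a−E))²/ΣV with hypergeometric E and V, no continuity correction,
1 df. Windows with fewer than 3 informative strata (all four margins
positive) are *untested* and excluded from the BH family; BH runs over all
tested windows of one comparison genome-wide. A DMR requires BH-adjusted
p < 0.05 *and* pooled-β divergence > 0.25; a DMG requires DMR windows to
cover > 20% (strict) of the gene body.

The CMH test conditions on margins and does not model biological-replicate
overdispersion. Consequently the generator's *null mode* draws binomial
counts from a site-level β shared by every sample — the exact sampling null
under which the type-I-error behaviour of the scan is meaningful. With
replicate-level noise present (the default), raw p-values are
anticonservative, and it is the divergence gate that keeps false DMR calls
near zero; this mirrors how the divergence threshold functions in the
original design.

MDI (chromosomal methylation discrepancy index) is implemented as
100 × mean over 100-kb windows of |pooled-β(sample) − pooled-β(reference)|
over windows where both samples have coverage. The source the original
analysis cites for MDI was not available; this definition is an explicit,
documented stand-in with the right qualitative behaviour (zero on identity,
symmetric, bounded by 100).

CG islands follow the Gardiner-Garden–Frommer/cpgplot criteria: 100-bp
windows at step 1 flagged when GC > 50% and observed/expected CpG > 0.6
(expected = C·G/length, Ns excluded from composition, windows > 50% N
skipped); the union of flagged windows is merged and runs > 200 bp are
islands. Metaprofiles pool read counts per bin (read-weighted β): gene
profiles use 5-kb flanks at 100-bp bins with the body rescaled to 100 bins,
strand-aware; island profiles use 2-kb shores (community-standard width;
unstated originally) and a 40-bin body.

## Genetic–epigenetic integration

A CG locus "carries" a CG-loss variant when a SNP hits the C or the G, or an
INDEL's reference span overlaps either base (insertions anchored at the C
break the dinucleotide). The per-locus effect is an OLS regression of β on
alt-dosage. Variability categories rank loci by cross-sample β SD; the
published rank cutoffs (10,000 / 50,000 / 150,000 of 588,659 loci) are used
verbatim when ≥ 150,000 loci are present and otherwise scaled as the same
fractions of the panel's locus count.

The cis-driver scan residualizes the DMR phenotype (per-sample pooled β over
the window) and each candidate dosage (±500 bp) on the top genome-wide
genotype PCs, then uses χ² = (n − k − 1)·r² with 1 df. The number of PCs
defaults to 10, the Eigenstrat convention: with ten species the axis that
separates the two focal sister species is not contained in the first two or
three genome-wide PCs, and the scan is only meaningful once species-level
structure is regressed out. A DMR is "associated" at a threshold when any
candidate passes — no per-DMR multiplicity correction, matching the
at-least-one-driver question. The threshold grid is
{5×10⁻⁵, 5×10⁻⁶, 5×10⁻⁷, 5×10⁻⁸}. The DMG × selection χ² uses no continuity
correction and reports unadjusted p values (the gene sets overlap across
comparisons, so familywise adjustment is not attempted).

## Synthetic data generator

The generator emulates the study design rather than a full evolutionary
model:

* **Panel** — 3 lineages / 10 species / 36 accessions: 7+7 accessions of the
  two focal sister species plus 4 of their hybrids, 2+2 for the other two
  Asian species, 6 European and 8 North American accessions across five
  further species. Two 1-Mb chromosomes.
* **Reference** — iid background at 36% GC with most background CpGs
  deaminated (C→T, retention 0.35), so background CpG density is depleted as
  in real genomes and GC-rich patches alone do not satisfy the island
  criteria; planted islands (250–1500 bp, GC-rich, obs/exp ≈ 1) and
  stop-free genes (150–300 codons, codon usage matched to genomic base
  composition, 30% with two exons, 150-bp UTR pads) are written over the
  background.
* **Variants** — a tree-drop model: each background variant is assigned to a
  lineage, species, or terminal branch (probabilities 0.15/0.45/0.40) and
  all descendants carry it (terminal-branch variants are het or hom with
  equal probability). Hybrids carry one allele from each parent species'
  fixation state. This creates the clade-fixed/private structure the
  analyses consume without a coalescent. Background variants avoid CpG
  dinucleotides (so CG-loss truth is exactly the planted set) and never
  create premature stop codons. VCF depth is NegBin(mean 30, dispersion 8)
  per genotype so the <1% missingness rule bites only occasionally; planted
  variants are floored at DP 10.
* **Planted truth** — CCVs (hom-alt in every carrier-clade sample, hom-ref
  in the reference clade, one sample outside the pair set heterozygous so
  each variant is attributable to exactly one ordered pair); per-gene
  selection classes (positive: 15 nonsynonymous + 1 synonymous species-fixed
  substitutions; purifying: 4 synonymous only; these genes are shielded from
  background CDS variants, and 3+3 planted genes fit inside the 5% tails of
  the defined-gene universe at the default 100 genes); CG-loss variants at
  38% of CpG loci (the fraction observed in the original panel), branch-
  assigned, with hom carriers drawing β ≈ 0 and hets halved; planted DMR
  windows with Δβ = 0.4 between the compared groups (≈40% placed inside
  gene bodies in runs long enough to trigger the 20% DMG rule); and cis
  drivers for half of the focal-pair DMR windows — a clade-correlated
  variant (allele frequency 0.9/0.1 in the compared clades, 0.5 elsewhere)
  whose dosage sets the window's β across a 0.8 span, making those windows
  both group-differential and mechanistically dosage-keyed, as a strong
  *cis*-driving mutation would.
* **Methylomes** — site-level baseline β from the bimodal mixture
  0.6·Beta(8,2) + 0.4·Beta(2,8) (plant gene-body-like), per-species effects
  (SD 0.05) and per-sample noise (SD 0.03); depth NegBin(mean 12,
  dispersion 5); read counts beta-binomial (concentration 30) split
  read-by-read across strands for the two report rows of each CpG.

What the generator does *not* emulate: linkage disequilibrium decay and
recombination, sequencing error, bisulfite non-conversion, CHG/CHH contexts,
locus-specific mutation rates, and realistic gene structure (UTR/intron
content is minimal). Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted signals under the
designed conditions — not performance on real resequencing data, where
replicate overdispersion, LD between drivers and passengers, and annotation
errors will all matter.

## Numerical and procedural choices

* All randomness flows through one `numpy.random.default_rng(seed)`; output
  bytes are a pure function of the configuration, and re-runs are compared
  byte-for-byte in the tests.
* PCA: per-feature mean imputation of missing entries, centering (and
  variance standardization for genotype dosages), SVD, component signs fixed
  by the largest-magnitude loading. Zero-variance features are dropped.
* NJ Q-matrix search is restricted to the upper triangle (the matrix is
  symmetric only up to floating-point rounding); at four remaining nodes the
  Q criterion is exactly degenerate between complementary pairs, which is
  topology-neutral.
* Quantile thresholds use linear-interpolation quantiles with closed
  comparisons; tied values are all included.
* BH adjustment delegates to statsmodels (`fdr_bh`), which enforces step-up
  monotonicity and preserves input order; NaN p-values are an error, and
  untested windows never enter the family.
* Degenerate CMH strata (any zero margin) are skipped; a window with no
  informative stratum or zero total variance is untested, not significant.
* Problem sizes in the test-suite and reproduction script follow the bundled
  design (2 × 1 Mb, 36 accessions, 20,000–25,000 windows for the null and
  recovery panels), which keeps every planted-signal analysis comfortably
  powered while the full suite runs in minutes.
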