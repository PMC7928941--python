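# Methods

This note records the statistical models behind each pleioscan stage, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the numerical and design choices made where the underlying procedures
were open.

## Bivariate association statistics

Two GWAS over partly shared samples yield, per SNP, signed z-scores
(z_a, z_b) on a common effect allele. Under the null these are bivariate
normal with unit variances and a correlation ρ induced by the sample
overlap; under a pleiotropic alternative both means shift. Three statistics
are computed:

- **S_Hom** = (wᵀz)²/(wᵀRw), referenced to χ²₁, with weights w ∝ √N per
  trait. It is the most powerful linear combination when effects are
  homogeneous across traits. With a single trait it reduces exactly to z²
  (checked to 1e-12 in the tests).
- **S_Het** truncates before combining: for each threshold t in a grid
  (default {0, 0.5, …, 3}), only traits with |z| ≥ t enter an S_Hom-type
  form with R and w subset accordingly, and the maximum over the grid is
  taken. The maximum of dependent truncated statistics has no closed-form
  null, so the genome-wide empirical distribution is summarized by a
  maximum-likelihood gamma fit (zeros replaced by half the smallest
  positive value, since the gamma support excludes 0) from which upper-tail
  p-values are read. *Known limitation:* the gamma family is an
  approximation. On 5×10⁴ null SNPs the fitted gamma deviates from the
  statistic's true distribution by KS distance ≈ 0.07, which a KS test at
  that sample size detects decisively; the fit is adequate for ranking and
  tail screening, not for distribution-level calibration.
- **dLC** = zᵀR⁻¹z referenced to χ²₂, the parametric linear-combination
  test; near-singular R (condition number > 10⁶) is rejected.

**Null-correlation estimation.** ρ is estimated from SNPs with |z| < 1.96
in both traits. Restricting to that box attenuates Pearson correlation
(a true 0.3 appears as ≈ 0.237), so the estimator inverts the
bivariate-normal box-truncation map (2-D Gauss–Legendre quadrature inside
a Brent root-finder). This keeps S_Hom's type-I error at nominal level:
measured 0.048–0.050 at α = 0.05 over 5×10⁴ null SNPs for ρ ∈ {0, 0.3,
0.5}. The uncorrected Pearson estimate remains available
(`truncation_correction=False`).

**Pleiotropy filter.** A SNP is called pleiotropic when (1) bivariate
P ≤ 5×10⁻⁶, (2) bivariate p / univariate p < 0.05, and (3) both univariate
P ≤ 0.05. Criterion 2 is evaluated against the weaker univariate p by
default: the strict both-traits reading would reject known pleiotropic
loci whose signal is imbalanced between traits (e.g. a bivariate 1.83×10⁻⁷
against univariate 2.96×10⁻³ and 2.26×10⁻⁶ gives ratios 6×10⁻⁵ and 0.081 —
a pass only under the weaker-p reading), and it also makes recovery of
planted loci with equal true effects unreliable, since finite-sample noise
routinely pulls one trait's univariate p below the bivariate p / 0.05.
`ratio_any=False` restores the strict reading. Passing SNPs are clumped
greedily: the smallest-p unassigned SNP leads a locus that absorbs passing
SNPs within ±1 Mb on the same chromosome; p-ties break by (chromosome,
position). The scan's default bivariate p for the filter is S_Hom's — its
χ²₁ reference has the sharp tail the ratio criterion presumes, whereas
gamma-fitted S_Het p-values decay too slowly to ever beat a strong
univariate test by 20-fold.

**Harmonization.** Records are matched by SNP id; swapped alleles (with or
without strand complement) flip the second study's z sign;
strand-ambiguous A/T and C/G SNPs are dropped (allele frequencies are not
guaranteed in both inputs, so frequency-based resolution is not
attempted); irreconcilable allele sets are dropped with a count.

## Conserved motif-module scoring

PWMs (probability columns, ACGT) are scanned over windows on both strands
with log₂-odds scores against a uniform background (pseudocount 10⁻³).
Per-PWM score cutoffs correspond to a background tail probability
(default 10⁻⁴ per position), computed exactly by dynamic-programming
convolution of the per-position score distributions, discretized at 10⁻³;
the scan quantizes its scores on the same lattice so cutoff and scan agree
exactly. N bases give −∞ and poison any overlapping placement. Hits
deduplicate to the best score per (family, start, strand).

A **module** is a set of ≥3 non-overlapping motif-family hits in the
reference window whose family order and pairwise gaps recur, within
±10 bp, in at least one other species (motif identity is matched at family
level across species). The search seeds with all conserved size-3
combinations of reference hits and extends each greedily while
conservation holds, keeping maximal modules; reference hits are capped at
the 24 best-scoring when a window is unusually hit-dense. The window
**score** counts distinct non-overlapping reference hits inside any
conserved module (greedy left-to-right selection), and its enrichment
p-value is the add-one permutation estimator
(1 + #{background ≥ observed})/(n + 1) over background ortholog sets —
never zero, uniform under an exchangeable null. Cross-species sequence
alignment is not re-run; ortholog windows are consumed pre-extracted and
conservation is judged by order/spacing, not alignment columns.

## Allelic imbalance

For k₁ reads on haplotype 1 and k₂ on haplotype 2, the test is the exact
binomial test of k₁ successes in k₁+k₂ trials against 0.5, two-sided by
the minimum-likelihood rule (sum of probabilities of all outcomes no more
likely than the observed one); a double-one-sided variant is available.
The fold is k₁/k₂, flagged infinite at k₂ = 0. Reads pool by summation
over variants, timepoints, and donors before a single test ("pooled",
the default), or per-donor evidence combines by Stouffer's method with
√reads weights and direction signs ("stouffer"). No reference-mapping-bias
correction is applied — the counts are accepted post-filtering — and no
beta-binomial overdispersion is modeled. Because the test is discrete, its
achievable size at moderate depth is below the nominal α; the calibration
test compares the simulated rejection rate against the enumerated
achievable size, not against α itself.

## Accessibility model and variant scoring

The classifier maps a one-hot (4 × width) sequence through valid
convolutions (ReLU, optional non-overlapping max-pooling), flattens the
final feature map into fully connected layers, and ends in one sigmoid per
task. Optimization is plain SGD with momentum 0.97 and learning rate 0.01,
batch 64, binary cross-entropy; the epoch with the best validation
accuracy supplies the final weights. Weight normalization
(W = g·V/‖V‖ per row) is implemented and on in the full-scale preset
(512/128 filters, sizes 9/5, 128-unit FC, 0.1/0.5 dropout); the desk-scale
default (32/16 filters, 32-unit FC) disables it because at small width the
reparameterization interacts badly with momentum 0.97 and can collapse
training to chance for some initializations. The flatten readout was
chosen over global max-pooling deliberately: with a global max, each
filter's gradient reaches one position only, and trained models can become
*exactly* invariant to parts of the planted motif, which breaks variant
scoring (observed as SAD ≡ 0 on genuinely disruptive substitutions).

**SAD** is the per-task difference in predicted peak probability between
the two allele-carrying windows (alt − ref; positive = more accessible
alternative allele), with the max-magnitude task as summary. When the
scorer exposes logits, the difference is computed in a saturation-stable
form (σ(a) − σ(b) rewritten via exp(−|·|)), since float64 rounds
near-certain probabilities to exactly 1.0 and would hide small allele
effects. SAD is antisymmetric and exactly zero at identity.
**Saturated mutagenesis** evaluates every substitution at every window
position; per position, loss = min(0, min Δ) and gain = max(0, max Δ);
reference-base cells are identically zero. Both scorers are
model-agnostic: anything with `predict_proba` (optionally
`predict_logits`) works, and the exact-contract tests run against a
PWM-logistic oracle rather than a trained network. Background SAD
distributions give empirical percentiles and add-one empirical p-values.

## Repressor clusters and clade enrichment

Repressed-state intervals (0-based half-open; state label configurable,
default "24") merge transitively when the gap next.start − prev.end is
≤ 200 bp, so touching intervals (gap 0) and the 200 bp boundary join while
201 bp splits. Cluster length is reported as the span (hull) length, with
the member-sum available; merging is idempotent and equals a union-find
over the pairwise gap relation. Locus signal is the base-pair-weighted
mean of a step track over the interval. On an epigenome linkage tree,
every internal node except the root defines a clade scored by
mean(in-clade leaf signals)/mean(out-of-clade); ratios are scale-invariant,
unweighted by branch lengths, and an all-zero outside mean is flagged
infinite rather than erroring.

## Intragenomic-replicate affinity

Anchors are exact occurrences of an allele-defining 8-mer on either strand
(reverse-complement matches reported at the forward match-start
coordinate; palindromes counted once), optionally excluding the source
locus. Per anchor, the mean signal in a centered window (default 1 kb,
configurable; `anchor_offset=k//2` centers on the k-mer midpoint rather
than its start) measures affinity; the allele fold is the ratio of the two
anchor-set means and significance comes from a Welch two-tailed t-test on
per-anchor means (the variance-handling choice where only "two-tailed
t test" is specified). A count-based mode (anchor-frequency ratio) covers
the alternative reading of the method; the count ratio is always reported
alongside.

## Synthetic fixtures

All generators are pure functions of a `SimulationConfig`; one global seed
expands into fixed per-generator substreams, so adding a generator never
perturbs another's output, and reruns are byte-identical.

- **Summary statistics**: null (z_a, z_b) ~ bivariate normal with
  correlation `overlap_correlation` (default 0.3); planted loci shift the
  mean by their effect pair. SE follows the standard GWAS approximation
  1/√(2·N·MAF·(1−MAF)) with MAF ~ U(0.05, 0.5); sample sizes default to
  32,961 and 46,186 (bone-density- and fasting-glucose-scale scans).
  Allele pairs are drawn non-ambiguous so harmonization is lossless unless
  ambiguity is planted deliberately. No LD structure is simulated: each
  SNP is independent, so clumping trivially isolates planted loci and
  power estimates do not transfer to LD-correlated panels.
- **Ortholog sets**: 120-bp windows; the case set carries three consensus
  motifs (gaps 10 and 12 bp, optional jitter) at identical offsets in the
  reference and one other species; backgrounds are i.i.d. uniform DNA.
  Real orthologs share homologous background sequence — conservation here
  is planted signal on independent noise, which makes background scores
  conservative (almost always 0).
- **Allele counts**: hap-1 count ~ Binomial(depth, f/(1+f)) with
  f = 1.9 over 20 variants at depth 50 by default, matching the scale of
  the replicated imbalance experiment.
- **Peak sequences**: positives carry a planted 12-bp consensus at a
  random offset with 5% per-base mutation noise; negatives are uniform
  DNA. The motif is 12 bp so it fits the default conv stack's 13-bp
  receptive field (9 + 5 − 1) with margin — a longer motif would make
  edge-base disruptions invisible to the model by construction — and the
  noise makes every motif position individually informative, so trained
  models respond to every disrupting substitution. Disrupting variants
  alter a planted consensus position; neutral variants sit ≥ 10 bp outside
  the motif. Real peaks differ in GC composition, motif multiplicity, and
  shoulder structure; passing these tests shows the scoring machinery
  recovers planted causal bases, not that the model generalizes to
  genomic accessibility.
- **Epigenome fixture**: a segmentation whose repressed runs have gaps
  bracketing the 200-bp rule (expected clusters known by construction); a
  balanced 8-leaf tree with one clade's leaf signals multiplied by
  `clade_fold`; a 50-kb genome with 50 planted occurrences of each allele
  k-mer (chance occurrences of either k-mer are scrambled away so anchor
  counts equal the planted truth) and a baseline-1 track multiplied by
  `kmer_fold` within ±25 bp of each reference-k-mer occurrence. With the
  profiling window inside the elevated span, the noiseless IGR fold equals
  the planted fold exactly.

## Problem sizes

Defaults are desk-scale by design: 5×10⁴ SNPs for null calibration, 10³
background ortholog sets for permutation p-values, 2,000 sequences ×
100 bp × 25 epochs for the accessibility model, 50 + 50 truth-labeled
variants, and 30 windows of saturated mutagenesis. The full test suite
runs in well under a minute of compute plus ~25 s of model training; the
acceptance script completes in ~30 s on one CPU.
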