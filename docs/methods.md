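# Methods

## Counting

The unit of data is a genotype code in {0, 1, 2} (0/0, 0/1, 1/1) for a
bi-allelic SNV; multi-allelic records must be split upstream (e.g.
`bcftools norm -m-`) and are rejected by the VCF reader. Each cohort is
encoded separately: per SNV, one byte per sample holding the 2-bit
genotype, plus three pre-shifted copies (2, 4, 6 bits). An m-SNV tuple
assigns its j-th member the shift 2(j−1) and ORs the m byte vectors
into one combined byte per sample; since 2-bit fields fill an 8-bit
byte, the order is capped at 4. The contingency table is the histogram
of combined byte values mapped onto rows

    r = Σⱼ gⱼ · 3^(j−1)   (little-endian base 3 in tuple slot order),

so the per-test cost is one pass over the cohort regardless of m. Valid
bytes are exactly the 3^m patterns whose 2-bit fields avoid `11` and
whose fields above slot m are zero; a count in any other bin raises an
internal-consistency error rather than being silently dropped.

Two independent paths verify the engine: the classical
three-indicator-vector method (per SNV and genotype, a one-bit-per-
sample mask packed with `numpy.packbits`; per genotype combination, m
ANDs and a popcount — 3^m passes per test) and a naive per-sample
grouping. The contract is the byte histogram itself: any internal
word-packing must leave all counts bit-identical, and the tests fuzz
cohort sizes that are not multiples of 8 or 64 to pin that down.
Padding is never used; cohort arrays keep their exact length.

## Statistics

β (combined association power) is the count-weighted mean Gini purity
of the table rows; β_∅ is the purity of the whole cohort. For the
implementation the row purity is rewritten as

    (x² + y²)/t² = 1/2 + ((x − y)/t)²/2,  t = x + y,

so β = 1/2 + Σ (tᵢ/n)·dᵢ²/2 is a sum of non-negative terms and the
mathematical bounds 0.5 ≤ β ≤ 1 hold exactly in double precision (the
direct formula can round one ulp below 0.5). Empty rows carry zero
weight and contribute nothing; purity(0, 0) is defined as 0.

β is invariant under permuting the tuple, but the float summation order
is not, so the β of a tuple is always computed on the sorted tuple —
this makes cached and freshly computed values bit-identical regardless
of how a caller orders the SNVs.

α at order m subtracts the maximum β over the m immediate
(m−1)-subsets; monotonicity of β makes smaller subsets redundant.
Differences in [−10⁻¹², 0) are clamped to zero as floating-point noise;
anything more negative raises, because a genuine monotonicity violation
can only come from inconsistent counts. Consequently β ∈ [0.5, 1] and
α ∈ [0, 0.5].

The lower-order β cache is a dense k-dimensional array indexed by the
sorted tuple. Cells off the sorted simplex are allocated but unused —
a deliberate memory/speed trade: subset βs are read m times per tuple
in an exhaustive scan, and a dense array keeps that read O(1). At the
default scan sizes (≤ a few thousand SNVs, order ≤ 4, cache order ≤ 3)
this stays well under typical memory budgets.

## Search

Tuples are enumerated by rank through the combinatorial number system
in colex order (rank of c₁ < … < c_m is Σ C(cᵢ, i)); the unranking
needs no knowledge of n, and balanced rank ranges give each worker an
equal share (sizes differ by ≤ 1). Workers run as threads and chunks
are concatenated in partition order before the final sort, so output is
identical for any worker count. Ranking is canonical everywhere: metric
descending, ties broken by the lexicographic tuple of SNV ids — chosen
so that repeated runs and regression tests are byte-stable; the tie
rule is this package's convention. `top_k`/`threshold` trim after
ranking. Best mode keeps, per SNV and order, the maximum-α tuple
containing that SNV under the same tie rule.

## Significance

The null for a tuple's α or β is built by permuting phenotype labels
(cohort sizes fixed) with a seeded generator. Genotypes never change
under permutation, so the per-sample contingency row indices are
computed once and each permutation only re-bins them by the new labels;
for α the m immediate subsets are re-binned the same way.

The empirical p-value is the plain one-sided ratio
#{permuted ≥ observed}/n_perm (one-sided because only larger α/β are
extreme). Its resolution is 1/n_perm, so a parametric tail is also
reported: a Gamma distribution with location fixed just below the null
minimum and shape/scale fitted by maximum likelihood, p = 1 − CDF(obs).
Gamma was chosen because the permutation nulls are non-negative and
right-skewed; if the fit fails a Normal fit is used, and a
zero-variance null falls back to the empirical ratio with a warning.
Fitted p-values are floored at the smallest positive double so that
−log₁₀ transforms stay finite; for very strong signals the reported
value is that floor and should be read as "far below resolution".
Bonferroni correction multiplies by the per-order test count C(n, m)
and caps at 1; no FDR option is provided.

The default n_perm is 1000; published runs should fix `--seed`.

## Simulation

The simulator draws truth-SNV genotypes under Hardy–Weinberg
equilibrium from the model MAFs, assigns disease by the penetrance
table, and rejection-samples to exact cohort sizes (default 1000 cases
/ 1000 controls among 100 SNVs, the standard detection-power protocol;
capped at 100× oversampling, after which an unattainable request —
e.g. all-zero penetrance with cases requested — raises). Noise SNVs
are independent of the phenotype with MAFs uniform in (0.05, 0.5), and
truth columns are scattered at seeded random positions. Detection power
for a model is the fraction of replicate datasets in which the planted
tuple is ranked first at its order; anything ranked above it is a false
positive.

The model library is defined here: XOR pair and 3-SNV parity
(strict-and-pure: at MAF 0.5 every proper-subset marginal is flat),
threshold (marginal effects), single-SNV additive, and flat (null).
External models load from a small JSON (label, MAF list, penetrance
table). The multi-truth dataset generator combines a marginal single
SNV, a pure XOR pair and a pure parity triplet through an additive,
clipped probability so each truth variable dominates exactly its own
order.

What the simulations do not emulate: linkage disequilibrium between
SNVs, population structure, genotyping error, missingness, and
quantitative phenotypes. Passing detection-power tests therefore shows
the statistics separate planted signal from independent noise — not
robustness to confounding in real cohorts.

A deterministic two-SNV fixture with a fully documented 9 × 2 table
(34 cases / 46 controls doubly heterozygous; every other cell 10/10)
exercises the counting paths exactly.

## Problem sizes in the test suite

The suite keeps whole-scan checks at panel sizes a desk run handles
comfortably while preserving the protocol shape: detection power uses
20 replicates of 100 SNVs × 2000 samples; counting equivalence fuzzes
500 random instances with cohort sizes up to 999; null calibration uses
200 replicate datasets at 200 permutations each; the multi-truth search
runs 50 SNVs at orders 1–3. Sizes are stated in the tests themselves.

## Graph export

Pair mode projects an m-tuple onto its C(m, 2) clique (recorded as
`clique_expanded` in graph metadata); a duplicated SNV pair keeps the
maximum statistic. Bipartite mode adds one interaction node per tuple,
connected to exactly its m SNVs. Node size is a linear map of the
chosen statistic onto a configurable range (default 10–50); the scaling
function is this package's choice. SIF output cannot carry attributes,
so they go to a sidecar TSV. Interactive filtering belongs to the
downstream viewer; pre-export filtering is done by trimming the result
list.

## Known limitations

* Order is capped at 4 by the byte encoding; a 16-bit extension would
  double the scan cost and is deliberately not offered.
* The exhaustive scan is O(C(n, m)): panels beyond a few thousand SNVs
  at order ≥ 3 need upstream filtering.
* Missing genotypes are rejected (or whole samples dropped on request);
  no imputation.
* The Gamma null family is a modelling choice, not a derived result;
  for observations inside the null bulk the fitted and empirical
  p-values agree to ≤ 0.05, but extreme-tail values depend on the
  family.
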