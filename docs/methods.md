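# Methods

## The additive model and variance accounting

Everything rests on the additive score ŷ = Σ_{i∈S} x_i β_i over a sparse
active set S, with x_i ∈ {0,1,2} the minor-allele count of SNP i. Under
Hardy–Weinberg equilibrium x_i ~ Binomial(2, f_i), so var(x_i) = 2(1−f_i)f_i
and SNP i contributes v_i = 2 β_i² (1−f_i) f_i to var(ŷ). The package sums
these contributions with **no covariance terms**: the approximation
var(ŷ) ≈ Σ v_i holds when active SNPs are largely uncorrelated, which L1
penalization encourages (keeping one of two highly correlated SNPs lowers
the penalty at no fit cost). `pairwise_snp_correlation` exists to check the
assumption empirically on genotype data; the analysis modules never estimate
covariances. On synthetic cohorts with independent SNPs the approximation is
exact in expectation, and a 5,000-individual Monte-Carlo run reproduces the
analytic total within a few percent (sampling noise of a variance estimate
at n = 5000 is ~2%).

Subset fractions (Σ_{i∈𝒮} v_i) / (Σ_{j∈S} v_j) inherit exact additivity
over disjoint subsets — the invariant the tests lean on hardest. MAF is
restricted to (0, 0.5]; inputs coding the major allele are rejected rather
than folded, because v_i is symmetric in f ↔ 1−f and silent folding would
hide upstream errors. For rare variants the common shortcut 2β²f overstates
v_i by a relative f/(1−f) (`small_maf_error`), ~1% at f = 0.01.

## Genic classification and the boundary sweep

A SNP is genic at expansion k (kilo base pairs) if its position lies in
[start − 1000k, end + 1000k] of any protein-coding gene body, inclusive at
both ends, clipped at position 1, symmetric regardless of strand. Where
genes "end" is genuinely uncertain, so the genic SNP-count fraction and
genic variance fraction are reported as functions of k. Defaults: k from 0
to 30 in 0.5 kbp steps — fine enough to localize single-SNP jumps at
half-integer k, coarse enough to stay cheap. Both series are non-decreasing
in k by construction; the implementation computes each SNP's distance to
the nearest gene body once and thresholds it per k, while point queries go
through an interval tree. The two routes are cross-checked against each
other and against brute-force scans in the tests.

Per-gene ranking at fixed k (default 30) assigns each gene the variance
fraction of the SNPs inside its expanded body. Two deliberate conventions:
a SNP inside several overlapping expanded genes contributes its full v_i to
*each* (per-gene fractions may double-count and need not sum to the overall
genic fraction), and genes carrying *exactly* the same SNP set are reported
as one group — with 30 kbp expansions neighboring genes frequently collapse
onto identical SNP sets, and reporting them separately would inflate the
list. `top_n` therefore counts distinct variance values, not genes.
`flag_genes` screens a ranking against an externally curated list of
problem genes (e.g. genes known to have unreliable exome variant calls) and
reports how many appear and how much variance they carry.

`random_baseline` gives the null: replicates of equally sized SNP sets drawn
uniformly without replacement from an array manifest, swept over k the same
way, summarized as mean ± sd per k.

## Exome accessibility

Exome capture targets sit inside gene bodies, so array-trained predictor
SNPs are callable from exome data only if they happen to fall in targets.
Matching is by exact chromosome+position — predictors and exome call sets
come from different platforms with no shared allele coding, so allele-aware
matching would be spurious precision. Genic status (at k, default 30) ×
exome-callable status yields four fractions in SNP counts and four in
variance, each quadruple summing to 1 (to 1e-12; they are four separate
float divisions). Nested targets force the non-genic∧exonic cell to zero at
the k used for nesting — a structural check, not an empirical finding.
Exonic status is nonetheless kept independent of genic status in the data
model so the four-way table stays honest for arbitrary inputs.

## Pairwise predictor overlap

SNPs from two predictors less than 4,000 bp apart (strict inequality) are
identified — a proximity proxy for "tagging the same signal through LD",
chosen because high-LD pairs at larger separations are rare. Two
statistics per ordered pair (matrices are intentionally asymmetric):

* count overlap: percent of row SNPs with ≥ 1 column match;
* sign-weighted variance overlap r̃: each matched column SNP gets weight of
  magnitude 1, signed by sgn(β_row β_col); weights multiply the *row* SNP's
  v_i and the sum is normalized by the row predictor's total variance.

The uniform weight magnitude is fixed at 1: with unique matches this makes
r̃ the signed variance fraction of the matched row SNPs, on [−100%, 100%].
Multiple matches are summed literally (no deduplication or clamping), so
|r̃| can exceed 100%; the CLI warns and lists the offending row SNPs. Only
the *signs* of column betas enter, making r̃ invariant under positive
rescaling of the column predictor. Anti-correlated neighboring SNPs within
one predictor push its own diagonal below 100% — a property, not a bug.
When both sides carry a `counted_allele` and they differ, the column sign
is flipped before comparison; without allele information, consistent
orientation is assumed. `restrict_top` trims very large predictors to their
n highest-variance SNPs (ties by position) before overlap analysis.

## L1 training

`SparseLinearModel` minimizes O_λ(β) = ½‖Y − Xβ‖² + nλ‖β‖₁ by cyclic
coordinate descent with exact soft-threshold updates on centered,
unit-variance columns (betas are reported back on the per-allele scale;
constant columns are left at zero). A sweep ends the fit only when both the
largest weight change is below `tol` (default 1e-6, standardized scale) and
the KKT stationarity residual is within 10·tol — the weight-change
criterion alone can stop with a materially violated gradient condition.
The objective is recorded per sweep and is non-increasing; both properties
are asserted in tests against closed-form solutions (single variable,
orthogonal designs).

The λ path is geometric from λ_max = max_j |x_jᵀY|/n (provably empty model)
down to ratio·λ_max (default 1e-3), warm-started; the top of the grid is
nudged up by 1e-10 relative so λ_max is empty despite ulp-level differences
between reductions. λ selection (`fit_cv`) holds out a seeded 20% split,
scores each path fit by held-out Pearson correlation, and picks the
*sparsest* λ within 1% relative of the best score — the usual parsimony
rule; plain argmax tends to drag in false positives. The selected λ is then
refit on all data. Case-control labels are fitted with the same squared
error (linear probability model), not logistic loss; score-to-risk
calibration is out of scope.

## Synthetic data: what it emulates and what it does not

The generators exist so every analysis has an exact planted truth:

* **Genomes** — non-overlapping protein-coding gene bodies laid left to
  right per chromosome; gene lengths log-normal (median 25 kbp, σ = 0.8),
  intergenic gaps exponential (mean 75 kbp) — order-of-magnitude realism
  for a human-like annotation, all overridable.
* **Predictors** — the planted genic SNP-count fraction is enforced
  *exactly* by stratified placement (genic SNPs uniform over genes then
  within bodies; intergenic SNPs uniform over the complement), so recovery
  tests are exact rather than statistical. Defaults: β ~ Laplace(0, 0.05),
  MAF ~ uniform(0.01, 0.5) — explicit choices, not estimates.
* **Exomes** — each genic manifest SNP is captured independently with
  probability `capture_fraction`; targets are 1-bp BED intervals at captured
  positions (whole gene bodies at capture 1), so the variant set is exactly
  manifest ∩ targets, targets nest in gene bodies, and the captured count is
  exactly Binomial.
* **Cohorts** — x ~ Binomial(2, f) i.i.d. per SNP, Gaussian noise scaled so
  the genetic variance share equals the requested heritability in
  expectation (exactly zero noise at h² = 1); binary labels threshold the
  continuous liability at its empirical 1 − prevalence quantile.
* **Pairs** — shared SNPs are planted within `jitter_bp` of base SNPs
  chosen to be *isolated* (no other base SNP within 4000 + jitter bp), so
  each partner proximity-matches exactly its base SNP and the ledger's
  predicted overlap statistics are exact; remaining SNPs are placed ≥ 4000
  bp from every base SNP. Sign concordance is enforced by count. Dense base
  predictors without enough isolated SNPs raise a generation error.

Deliberately absent: linkage disequilibrium between SNPs (the variance
arithmetic assumes it away, so planting it would test a different model),
realistic chromosome lengths and gene density gradients, allele-frequency
spectra tied to effect sizes, genotyping error, and population structure.
Passing tests therefore demonstrate internal correctness of the pipeline
and exact recovery under the stated model — not that real predictors have
any particular genic fraction.

## Benchmark and problem sizes

The support-recovery benchmark trains on n = 1000 individuals × p = 2000
SNPs with 20 causal SNPs at h² = 0.8, effect magnitudes uniform(0.05, 0.15)
with random signs; recovery is ill-posed for effects at zero, so a
detectability floor is part of the benchmark design, as is standard for
sparse-recovery evaluations. Gates: recall ≥ 0.9, false-discovery
proportion ≤ 0.2 at the cv-selected λ. Monte-Carlo checks use 5,000
individuals; oracle-equivalence tests run ~100 random instances up to
2,000 SNPs × 500 genes. `scripts/acceptance.py` reruns all of this from one
seed (child seeds via `SeedSequence`) in well under a minute.

## Numerical conventions

Coordinates are 1-based inclusive internally (GFF3); BED is converted at
the io boundary only (1-based p is in [s, e) iff s < p ≤ e). Chromosome
labels are opaque strings ("chr1" ≠ "1"; readers can strip the prefix).
Boundary membership is inclusive at expanded endpoints — it has to be one
way, and both sides of every boundary are tested. Gene-ranking ties break
by lexicographic gene id; `restrict_top` ties break by (chromosome,
position). Predictor TSVs are written with `%.17g` and read with
round-trip float parsing so file round-trips are lossless. Degenerate
inputs (empty annotation, zero capture, k = 0, empty subsets) are defined
results, not errors; empty predictors and empty active sets are errors.
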