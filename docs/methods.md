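# Methods

## Problem and model

A guide RNA in a pooled knockout screen depletes for two reasons: loss of
the targeted gene's function, and toxicity from cleavage at additional
genomic sites. We model the measured depletion (guide-level mean log2 fold
change) as the sum `D_i = G_i + O_i` and estimate the off-target component
`O` as a function of five covariates computed exactly from the genome:
H0–H3, the counts of PAM-adjacent sites at Hamming distance 0–3 from the
guide's protospacer, and the aggregate specificity `s = 1 / Σ CFD` over
that complete neighborhood. Hamming (substitution-only) neighborhoods are
used deliberately: bulged (insertion/deletion) alignments rarely retain
Cas9 activity and are excluded. The PAM is a match requirement, not a
mismatch position.

The `s = 1/ΣCFD` aggregation is adopted as the unique simple rule matching
the score's stated endpoints — exactly 1 for a guide whose only site is its
single perfect target, monotonically toward 0 as off-target CFD mass
accumulates. Guides with no perfect genomic target have no defined score;
they are flagged (`no_perfect_target`) and propagated as missing, never as
0, because a fake "maximally unspecific" value would inject signal.

## Off-target enumeration

All ACGT-only k-mers (k = 19 or 20) immediately 5' of a PAM (default NGG,
configurable IUPAC patterns) on both strands are collected; minus-strand
sites store the reverse complement so every stored protospacer reads 5'→3'
on the cutting strand, with `start` always the leftmost + strand coordinate
(0-based, half-open — round-trips to BED). Windows containing any ambiguous
base are skipped entirely, matching exact-index semantics. Alternative
contigs can be excluded by a configurable name regex (default `_alt`).

The index is a sorted array of 2-bit-packed protospacer keys with
occurrence lists grouped per unique key. Sorted keys are an implicit prefix
tree: the keys sharing a prefix form a contiguous slice and the four
single-base extensions partition it, so Hamming-bounded retrieval is a
depth-first traversal that spends its mismatch budget while descending and
collapses to a single binary search once the budget is exhausted. The
traversal is JIT-compiled (numba); queries on a 2 Mb genome take ~0.1 ms.
Correctness is not argued but measured: an independent brute-force window
scan (sliding windows, explicit PAM set, direct mismatch counting — a
separate numpy code path sharing no traversal logic) must agree
site-for-site, and does so across 20 genomes from 100 kb to 2 Mb × 1,000
guides in the acceptance suite. The scan refuses genomes above 50 Mb
without an explicit override.

## Screen preprocessing

Guides with fewer than 30 plasmid reads are removed (strict `<`), then all
samples — plasmid and replicates jointly — are median-ratio normalized:
size factor = median over all-nonzero guides of count / per-guide geometric
mean, centered so the factors' geometric mean is 1 (centering cancels in
every fold-change and makes normalization idempotent). Per-replicate
log2((post + 1)/(plasmid + 1)) values are averaged into the final `D_i`;
the pseudocount of 1 read-equivalent is applied after normalization.
Z-scores of logFC are provided as a display-layer diagnostic only — the
model always regresses raw mean logFC.

One caveat worth knowing: sequencing is compositional, so when a large
fraction of the library is strongly depleted the median guide is not
neutral and all fold changes share a small positive offset. This offset
cancels in the correction (which is anchored), in Bayes-factor ranking, and
in distortion; it only matters if absolute logFC values are read directly.

## MARS engine

Written from scratch. The forward pass starts from the intercept and at
each step adds the mirrored hinge pair — parent basis × max(0, ±(x_v − t))
— minimizing the residual sum of squares, with coefficients refit by OLS
after every addition (incremental orthogonalization makes each candidate an
O(n) update). Candidate knots are the unique observed values of the
variable on the parent's support, thinned to at most `max_knots` (default
64) evenly spaced order statistics; a knot at the variable's minimum yields
a pure linear term, so linear effects are representable. Degenerate or
collinear candidate columns are dropped and the search continues. The pass
stops at `max_terms` (default 21) or when the best relative RSS improvement
falls below `tol` (default 1e-4).

The backward pass deletes, stepwise, the term whose removal least increases
RSS (intercept never removed), records GCV for every visited sub-model with
effective parameters C(m) = m + d(m−1)/2, and returns the minimum-GCV
sub-model; d defaults to 3 with interactions (max_degree 2 default), 2 for
additive fits. Fitting uses a seeded 90/10 train/holdout split; holdout
RMSE is the model-quality statistic reported and used by the gate.
GCV is known to under-penalize forward-pass selection: on pure-noise
screens the pruned model occasionally keeps 1–5 spurious terms whose
offsets are large only on rare covariate corners (mean |offset| stays below
1% of the noise SD). The null-screen distortion checks in the acceptance
suite quantify this.

Ties in knot selection resolve to the first (lowest) candidate and deletion
ties to the earliest term, so fits are bit-reproducible given the seed.

## Correction

The per-screen model is fit on guides with H0 ≥ 1 and a defined score
(others pass through unchanged, flagged). Corrected depletion is
`D − Ô(x) + Ô(x_ref)` with `x_ref = (s=1, H0=1, H1=H2=H3=0)`: how corrected
values are re-leveled is a genuinely open design point, and anchoring at
the fully specific covariate vector is the minimal-intervention choice —
specific guides are provably untouched, and guides sharing covariates keep
their relative ordering. An optional RMSE gate disables correction (never
annotation) when holdout RMSE exceeds a user threshold. Externally
corrected fold changes (e.g. copy-number-corrected) can be supplied
directly as the depletion vector. An H0 = 1 filter pipeline is provided
purely as the benchmark comparator.

## Essentiality benchmark

Bayes factors follow the BAGEL idea in simplified form: Gaussian KDEs
(Silverman bandwidth, density floor 1e-12) of guide logFC for gold
essential and non-essential genes are the reference likelihoods, and
BF(gene) = Σ guides log2(p_ess/p_noness). Gold genes are scored under
10-fold cross-validation so a gene's own guides never shape the densities
that score it; non-gold genes are scored against the full references.
Exact numeric parity with the external BAGEL tool is explicitly not a goal.
Precision–recall curves walk the BF ranking (ties broken by gene name);
recall at 5% FDR takes the maximal recall among thresholds with
precision ≥ 0.95 (most-inclusive threshold on recall ties); AUC is
trapezoidal with the curve anchored at recall 0. Matched-hit false-positive
comparison varies each pipeline's threshold to a fixed hit count.
Distortion is per-guide |corrected − observed| (mean and median — the
per-guide absolute-difference reading of the metric) plus the change in
essential/non-essential mean separation. When a guide filter removes every
guide of a gene, the gene is kept in the evaluation universe with BF = −inf
so it counts as never-called instead of silently leaving the denominator.

### Binned specificity–depletion correlation

The confounding signature is summarized as the Pearson correlation between
specificity and mean logFC across specificity bins. Bins are equal-count
quantile bins (default 200) with the s = 1 atom as its own bin. The
granularity matters: with equal-count bins the unweighted bin-level
covariance telescopes to the guide-level covariance between residuals and
s, which the OLS fit orthogonalizes away after correction, so the statistic
measures remaining structure rather than bin-sampling noise. Coarse bins
(~20) would leave |r| ~ 1/√B noise from gene effects regardless of fit
quality — visible only at desk scale, since pooling hundreds of screens
averages it out.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions;
defaults: 2 Mb i.i.d. ACGT genome; 60 planted repeat families (copy numbers
2–20, units 150–250 bp, per-copy mutation rates 0–3%) giving guides with
controllable H0–H3 and scores on both sides of the 0.16 promiscuity
threshold; 1,000 genes × 4 guides; 20% essential genes with knockout effect
G ~ N(−2, 0.3); 25% of genes resident in repeat regions (their guides are
the promiscuous ones); plasmid depth 500 reads/guide; negative-binomial
dispersion 0.1; 2 replicates with depth factors U(0.7, 1.4). Planted
off-target toxicity uses the same covariates the corrector sees
(fair-recovery design): O = −β(ΣCFD − 1) with β = 0.5, clipped at −6; a
deliberately mis-specified variant (O ∝ H2) exists for robustness checks,
and guides with no perfect target cut nothing (expected logFC 0). Gold
lists are subsets (≤200 essential, ≤300 non-essential genes), as in real
screens where curated sets cover a fraction of the library. Everything is
driven by one mandatory seed; recomputing covariates from the emitted
genome reproduces the stored truth exactly.

What the generator does not emulate — and hence what green tests do not
show about real data: realistic genome composition and repeat taxonomy,
guide-efficiency variation, copy-number amplification, batch effects, and
the empirical CFD constants (the packaged table is a synthetic stand-in
with the right qualitative structure; conclusions about real genomes
require the published table, which users can inject).

## Problem sizes and numerical choices

The validation suite runs 5 libraries (500 kb genomes, 2,000 genes × 5
guides = 10,000 guides) × 4 screen seeds = 20 screens for the
correlation-removal, effect-recovery and benchmark-direction checks, plus
20 genomes (100 kb–2 Mb) × 1,000 guides for enumeration-oracle equality —
sizes chosen to give stable statistics at interactive runtimes. Floors and
tolerances: KDE density floor 1e-12; candidate-column norm threshold 1e-10
for degeneracy; GCV errors out when C(m) ≥ n; all RNG flows through
`numpy.random.default_rng` seeds. Known limitations: no bulged off-targets
(by design), no on-target efficiency modeling, single-threaded fits, and
the 19-mer score anchors to PAM-proximal table positions 2–20 — a
best-effort convention, since the CFD table is defined for 20-mers and the
score is weakly informative for 19-mer designs (the model is free to lean
on H0/H1 instead, and does).
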