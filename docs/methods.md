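# Methods

## The covariance-association model

Let Y be the N×K matrix of relative abundances at one taxonomic rank and X
a scaled host predictor with covariates C. After standardization, the
sample covariance of taxa i and j is the mean of the per-sample products
P_ij = Y_i·Y_j, so each sample contributes an individual-level observation
of every pairwise covariance. Testing whether X moves the covariance
matrix reduces to the multivariate regression Q ~ X + C, where Q holds p
principal components of the (inverse-normal transformed) product matrix.
The test statistic is Wilks' Λ for the single predictor, computed through
the rank-one identity Λ = 1 − R²(x̃ ~ Q̃) on residualized inputs (assert-
equal to the determinant form in the tests), with the exact transform
(1−Λ)/Λ·(N−p−c−1)/p ~ F(p, N−p−c−1), c the covariate count. Because Q
columns are rank-normalized, errors are near-Gaussian and the F reference
is accurate; measured null type-I over 1000 full-chain replicates is
0.039 at nominal 0.05 with p-values indistinguishable from uniform.

The component count p is a tuning dimension, not a parameter with a true
value. The scan fits one PCA at the largest requested p and re-tests with
nested leading components over a grid (default 2–100, capped by default at
min(100, N/10); the cap is configurable and the power analyses use the
full 2–100 grid). The reported optimum is the argmin of the p-value;
because the minimum over a grid is selection-biased, screening decisions
use Bonferroni thresholds that charge for the grid size: stringent
0.05/(n_predictors × n_models), suggestive 0.05/n_predictors.

### Rank-normalizing taxa before products

Each taxon column is inverse-normal transformed (Blom offsets,
(rank−3/8)/(N+1/4), average ranks for ties) before standardization. This
is the package's resolution of a genuinely open design point, and it is
load-bearing: the advertised independence of the test from pure mean
effects relies on mean responses being *linear* in the predictor, so that
product means pick up only x² terms (uncorrelated with x for symmetric
predictors). Relative abundances are approximately log-normal, so a mean
shift on the raw scale is multiplicative — a convex response whose
pairwise products correlate *linearly* with the predictor. Measured on the
generator: a log-scale shift explaining 10% of variance of 5 of 20 taxa
drives the raw-product chain to a 70–100% rejection rate at the nominal 5%
level, while the rank-normalized chain stays in the binomial band. The
transform is switchable (`pre_int=False`) for data already on a suitable
scale. Ties — the zero block of a sparse taxon — map to a single atom, so
absent taxa contribute no spurious ordering.

The per-pair direction of effect deliberately uses the *raw* centered
products (residualized on covariates): a sign is only interpretable on the
covariance scale, whereas φ weights live in the transformed PCA space.

## Synthetic data generator

The generator emulates a prevalence-filtered relative-abundance table with
host metadata:

* **Covariance signal.** Two endpoint correlation matrices: Σ_A = I and
  Σ_B = I plus ±δ on `n_modulated_pairs` random pairs (eigenvalue-clipped
  and re-normalized to unit diagonal if needed; the construction errors if
  the repair erodes a modulated entry below δ/2). Each individual samples
  a latent Gaussian with covariance (1−w)Σ_A + wΣ_B, w the logistic of a
  standard-normal predictor or the 0/1 group of a binary one; convexity
  guarantees a valid covariance for every individual.
* **Abundance scale.** Taxon j gets exp(μ_j + σ z_j) with μ_j uniform over
  three decades (log 10⁻³ to 1) and σ = 1 — heavy-tailed abundances whose
  dynamic range mimics genus-level profiles.
* **Mean effects.** `mean_effect`·x is added to μ_j for a designated taxa
  subset; designation mode "rarest" picks the lowest-abundance taxa so the
  shift stays a pure mean effect (see limitations).
* **Sparsity and closure.** Entries are zeroed independently with
  probability `sparsity` (default 0.2; the per-sample maximum is protected
  so no row empties), then rows are re-closed to sum 1. One covariate is
  generated with correlation 0.3 to the predictor.

Defaults (N=600, K=30, 10 families, δ=0.6 on 20 pairs) describe a moderate
cohort screen. Seeding is bit-reproducible.

### What the generator does not emulate

No phylogenetic correlation between related taxa, no baseline (x-free)
co-abundance structure beyond what closure induces, no longitudinal
sampling, no read-level noise. Passing tests therefore demonstrate the
statistical machinery under controlled signal, not performance on any
particular real cohort.

### Attenuation: what the stated signal means

Two properties of realistic compositional data *dilute* a latent
correlation shift before the test sees it, and both are worth knowing when
reading the test suite:

* **Closure** subtracts a common log-total component from every taxon; at
  K=30 this shrinks a 0.6 latent shift to ≈0.49 on the analyzed scale (the
  effect fades as K grows, which is why large-cohort screens at hundreds
  of taxa are less affected).
* **Zero-inflation** at rate s removes the pairwise signal from
  ≈1−(1−s)² of entries; at s=0.2 the realized shift drops to ≈0.21.

The statistical fixtures that state a signal size ("a 0.6 correlation
shift") therefore generate it undiluted by zero-inflation — with a binary
predictor (both endpoint matrices realized exactly) and sparsity 0 — while
the calibration fixtures keep the sparse defaults. Under the sparse
defaults the same scan retains ≈70% power at the stated shift.

Mean shifts interact with closure the same way: shifting *dominant* taxa
moves every sample's total, which re-closure converts into a genuine
covariance change that the test rightly detects. A "pure mean effect" is
only realizable on taxa with negligible compositional feedback, hence the
"rarest" designation in the mean-independence fixture; the effect size is
calibrated at run time (bisection on a large pilot) so the predictor
explains 10% of per-taxon variance on the analyzed scale.

## Contribution attribution and its resolution limit

φ(P_ij) = Σ_r β̂_r²(λ_ij⁽ʳ⁾)² attributes the global statistic along PCA
directions; the identity Σφ = Σβ̂² holds to machine precision (unit-norm
loadings). Attribution fidelity, however, is limited by whether the
x-driven component of the product matrix rises above the sampling noise of
the PCA itself. The modulated pairs share the predictor as a common
factor, forming a spike of size ≈ 1 + n_pairs·(Δ/2)² in the product
covariance (Δ the realized product-mean shift); by the BBP phase
transition, sample eigenvectors only begin to align with the spike above
1 + √(M/N). At M=435, N=600 the threshold is 1.85 while the realized
spike is ≈2.2 — barely above it — so loadings recover the truth direction
only partially and the top-5% φ set typically captures 3–4 of 20 truth
pairs (enrichment p ~10⁻²), even though the *global* test has essentially
full power. The per-pair signed coefficients β_ij, which regress each
product on the predictor directly, recover the same truth pairs almost
perfectly and are the recommended per-pair ranking at small K; φ remains
the exact decomposition of the test statistic itself. An optional
permutation null for φ (`phi_permutation_null`) supports outlier
assessment against chance loadings.

## Prediction

The covariance predictor freezes every train-fitted transform — taxa
quantile maps, product quantile maps (replayed by linear interpolation,
clipped at train extremes), centering offsets, loadings — and scores new
samples as S = Σ β̂_i PC_i^(test); PCA is never refit on test data, which
both avoids component-matching problems and makes the train=test case
reproduce in-sample fitted values exactly. The abundance baseline is OLS
on the leading L abundance PCs (raw OLS on K columns would be ill-posed as
K approaches N), giving a like-for-like comparison at the same L.
"30-fold cross-validation with 90/10 splits" is internally inconsistent
with standard k-fold; it is implemented as 30 repeated random 90/10
splits, matching the split description. Single-class test splits for
binary outcomes are redrawn and logged. Metrics: squared Pearson
correlation, and the Mann–Whitney AUC with ties counted ½. Covariates are
not used in prediction.

## Baselines

* **MANOVA**: proportions → arcsin√ → column scaling → residualization →
  the same Wilks routine as the covariance test (shared code, asserted
  identical). Requires N > K + c + 1.
* **Alpha diversity**: Shannon −Σp·log p (the conventional non-negative
  sign; the sign convention is irrelevant to the Wald test) and the
  finite-sample Simpson 1 − Σx(x−1)/(T(T−1)), which needs integer counts —
  reconstructed from relative abundances with a configurable library size
  (default 10,000).
* **Univariate regressions**: per-taxon OLS on the rank-normalized
  abundance (raw scale switchable), Wald p on X, Bonferroni 0.05/K.
* **Permutation network** (binary predictors): per-group pair covariances
  against an empirical null from shuffling one member taxon within the
  group; two-sided detection at a quantile threshold; pairs detected in
  exactly one group are reported. Its null detection rate matches
  1 − quantile only for exchangeable data — on compositional tables the
  closure-induced correlations are real detections (measured ≈0.17 at
  K=20 versus 0.05 nominal), which is precisely the specificity problem
  that motivates the model-based test.

## Numerical choices

* Standardization uses the population (divisor-N) convention so product
  means equal correlations exactly.
* Blom INT constant 3/8 with average ranks; all-constant vectors are
  errors, exact-constant columns are dropped from scans with a warning
  (the floating-point std of a constant column need not be zero).
* PCA via SVD of the centered matrix; loadings kept at unit norm; grid
  ties in the argmin break to the smallest component count.
* Greedy largest-marginal-gain set cover for the "families covering ≥50%
  of top pairs" summary (ties alphabetical); exhaustive search on small
  instances bounds it within one family of optimal in the tests.
* Top-k pair selection breaks φ ties lexicographically for determinism.
* Overlap significance between detected pair sets is a one-sided
  hypergeometric tail with universe K(K−1)/2 (undirected pairs).
* One global seed; per-stage substreams derived by hashing the stage name
  (simulate / permute / cv), so single stages can be reproduced.

## Problem sizes used in the checks

Calibration runs use N=300, K=20, p=10 with 500 replicates; power and
recovery use N=600, K=30, δ=0.6 on 20 of 435 pairs with 100 replicate
scans over the 2–100 grid; prediction uses the same cohort size with L=20
over 30 splits; the permutation-network null uses K=20 with 1000
permutations. These sizes keep a full suite run within a few minutes on
one CPU while leaving the binomial tolerance bands meaningful.

## Known limitations

* Compositionality is not modelled explicitly (no log-ratio transform);
  its closure effects are an offset at large K but materially attenuate
  and distort signals at small K, as quantified above.
* The PCA-loading attribution has limited per-pair resolution near the
  spike-detection threshold; use the signed per-pair coefficients for
  fine-grained rankings at small K.
* The exact-F Wilks test needs N comfortably above p + c; screens of small
  cohorts must cap the component grid accordingly.
* Binary predictors with mean effects leak quadratically into products
  (x² = x); the mean-independence property is specific to symmetric
  continuous predictors.
* Regularized, mixed-model and nonlinear variants are out of scope.
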