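# Methods

## The model

`mmlgp` predicts the subcellular location set of a protein from several
feature views simultaneously. For `Q` locations and `m` views it posits
one zero-mean latent Gaussian-process function per (location, view)
pair. Because the likelihood depends on the per-view latents only
through their sum, inference runs on the collapsed latents

    g_ik = sum_j f_k^j(x_i),
    cov(g_ik, g_i'k') = C_kk' * K_ii',     K = sum_j a_j K_j,

a Kronecker-structured prior `C ⊗ K` in which

* `C` is a `Q × Q` unit-diagonal PSD **label-correlation matrix** — it
  couples the latent functions of different locations, so evidence for
  one location (say cytoplasm) informs a correlated one (nucleus);
* `K_j` is the Gaussian (RBF) Gram matrix of view `j` with bandwidth
  `θ_j`, and `a_j ≥ 0` are the **view-combination weights** — learning
  `a` is multiple-kernel learning, i.e. the optimal linear combination
  of feature extraction technologies;
* the collapsed representation is exactly equivalent to the explicit
  per-view latent stack (block prior `⊕_j a_j (C ⊗ K_j)` marginalized
  onto the sum); `collapse_equivalence_check` verifies this identity on
  small instances and the equivalence is covered by tests.

Labels are conditionally independent Bernoulli given the latents,
`P(y_ik = +1 | g_ik) = σ(g_ik)` with the logistic σ, and each sample's
log-likelihood is multiplied by a positive weight `w_i` (below), which
is equivalent to exponentiating its likelihood.

**Identifiability.** Scaling `C` by `c` and `a` by `1/c` leaves the
prior unchanged, so `C` is constrained to a correlation matrix (unit
diagonal) and all amplitude lives in `a`. `C` is parameterized through
a row-normalized Cholesky factor (unconstrained reals map smoothly onto
valid correlation matrices; the zero vector maps to the identity), and
`a` through its logarithm.

## Inference

The posterior over the collapsed latents is non-Gaussian; we use the
Laplace approximation. Newton iterations maximize

    ψ(g) = Σ_ik w_i log σ(y_ik g_ik) − ½ gᵀ (C ⊗ K)⁻¹ g,

solving each step through `B = I + W^{1/2} (C⊗K) W^{1/2}` (eigenvalues
≥ 1, so the factorization is stable) with iterates kept in the form
`g = (C⊗K) α` so the prior inverse is never formed. A backtracking line
search in `α`-space guarantees monotone ascent; convergence is declared
at max-abs gradient < 1e-6 (configurable) or an objective change below
1e-10, with a 100-iteration cap. The approximate log marginal
likelihood is the standard Laplace expression
`log p(Y|ĝ) − ½ αᵀĝ − ½ log|B|`.

`C` and `a` are learned by maximizing this evidence with quasi-Newton
(L-BFGS) ascent and finite-difference gradients; the Newton mode is
warm-started between evaluations. Accepted steps never decrease the
evidence (descent method on the negated objective), which the test
suite asserts. Bandwidths `θ_j` are *pre-set* — by default the median
of the nonzero pairwise distances of each view's training inputs — and
never optimized jointly with `C` and `a`; this keeps the evidence
search identifiable.

**Per-sample weights.** To counter class imbalance, `w_i` is the mean
over sample `i`'s positive labels `k` of `1/n_k` (`n_k` = number of
positive samples of label `k`), normalized so `mean(w) = 1`. Samples
carrying only rare locations get proportionally larger weights; on a
balanced single-label dataset all weights are 1. The rule is invariant
to duplicating the dataset.

**Prediction.** For a test point, the collapsed test latents are
Gaussian with mean `C (A k*)` (with `A` the reshaped `α̂`) and
covariance `kss·C − VᵀV` obtained from the stored `B`-factor
(`kss = Σ_j a_j`, the prior variance of the combined unit-diagonal
kernels; a test point far from all training data reverts exactly to
the prior `N(0, kss·C)`). The label probability
`p_k = E[σ(g*_k)]` is computed by Monte-Carlo averaging (default
S = 5000, seed required in the CLI) or, optionally, by deterministic
Gauss–Hermite quadrature on the marginals — `p_k` depends only on the
marginal of `g*_k`, so the 1-D quadrature is exact up to quadrature
error and is what paired ablation experiments use to avoid Monte-Carlo
noise in the gaps.

**Decisions.** The predicted location set is `{k : p_k > 0.5}`, with a
top-1 fallback (every protein has at least one site) and lowest-index
tie-breaking. Note this per-label thresholding maximizes Hamming-type
accuracy, *not* subset accuracy; see "Known limitations".

**Degenerate labels.** A location with zero training positives is
dropped with a warning and always predicted absent.

**Numerics.** `log σ` is evaluated through `logaddexp` (no overflow for
|g| > 35); combined kernels get escalating diagonal jitter starting at
1e-8 × mean diagonal before factorization; predictive covariances are
symmetrized and eigenvalue-checked (tolerance −1e-8) before sampling.
Cost is O((nQ)³) per Newton step from the dense `B` factorization;
the implementation targets the n ≲ 3000 regime of curated multi-site
benchmarks.

## Feature views

Five views mirror common practice for human multi-site prediction:
three binary GO-term indicator views (biological process, molecular
function, cellular component; vocabulary frozen from the training
annotations per namespace), amino-acid composition (AAC, 20 residue
fractions in fixed alphabetical order), and pseudo amino-acid
composition (PseAAC): AAC augmented with λ sequence-order correlation
factors computed from hydrophobicity, hydrophilicity and side-chain
mass, each standardized to zero mean / unit variance over the 20
residues (making the features invariant to affine rescaling of the
property tables). Defaults λ = 15 and weight 0.05 are conventional and
configurable. Sequences are sanitized (U→C; ambiguity codes B/Z/J/X
and gaps rejected, or records dropped with `--drop-invalid`) because
silently coercing ambiguity codes corrupts composition features.

## The synthetic-data generator

The generator draws datasets from the model's own generative
assumptions so every component is testable without downloads:

* view inputs are Gaussian cluster draws (4 clusters, spread 2 by
  default); per-view bandwidths are the median heuristic times
  `bandwidth_scale`;
* collapsed latents `G = L_K Z L_Cᵀ` with iid normal `Z`, giving
  exactly `cov = C ⊗ ΣaK`;
* labels are Bernoulli through `σ(g_ik + b_k + δ)` with per-label
  offsets `b_k` controlling imbalance (the *model* stays zero-mean; the
  offsets exist only in the generator) and a common shift `δ` found by
  bisection on the exact Poisson-binomial multi-label probability so
  the expected multi-label fraction among retained samples hits the
  target (0.17 by default, matching the ~17% multi-site share of
  curated human benchmarks);
* rows with no positive label are resampled (every benchmark protein
  has ≥ 1 site). This conditioning induces mild *negative* label
  dependence through explaining-away — a real property of the
  generator, detectable in the evidence — so experiments that need
  exact label independence switch it off (`require_positive=False`).

The `humlike` preset emulates the benchmark's shape: Q = 14 locations,
5 views, n = 400, ~17% multi-label, heavy imbalance including one
location under 1% positives, and moderate (0.6) coupling on two label
pairs. What the generator does **not** emulate: real amino-acid
statistics, GO DAG structure or annotation sparsity patterns, and
between-view redundancy of real feature extraction pipelines. Passing
tests therefore demonstrate correctness and the claimed qualitative
effects *under the model's own assumptions*, not benchmark-level
accuracy on real proteins.

## Study conditions of the validation experiments

All sizes were chosen once as the smallest instances at which the
effects of interest are identifiable.

**Correlation recovery** (`run_recovery`): Q = 3 labels, m = 2 2-D
views, n = 150, zero offsets, no forced-positive constraint, generator
bandwidths at 0.25 × median so the Gram has enough effective degrees
of freedom to identify `C` (at the plain median bandwidth the Gram of
a Gaussian point cloud has effective rank ≈ 2–3 and `C` is essentially
unidentifiable from a single latent draw — a fact worth knowing when
applying the model). The fit conditions on the generator's bandwidths
and uniform weights (the data are balanced by construction). With
coupling 0.9 on one pair the learned `C_12` lands near the truth; with
independent labels the learned off-diagonals stay small.

**Correlation-benefit harness** (`table1_harness`, `coupled` preset):
Q = 4 with two label pairs coupled at 0.9, each pair a common location
(offset −1.0) and a rarer partner (−2.5) — the regime where partner
evidence genuinely helps; n = 240, 5 random half-splits per seed,
8 seeds. Both arms condition on the generator's `θ` and `a` and differ
only in `C` (learned vs fixed identity): learning `a` jointly at
n_train ≈ 120 inflated the amplitude several-fold and destroyed the
identifiability of `C`, contaminating the ablation. The influence of
the multi-site percentage is studied by thinning single-label samples
from the *test* half only (training fixed), which isolates the
composition effect from training-set shrinkage.

**Imbalance ablation** (`minority_recall`): Q = 3 with two ~50%
locations and one at offset −5.4 (≈ 20:1 skew against latent sd 2),
n = 400, C = I in both arms; the arms differ only in the likelihood
weights. Recall of the rare label is pooled over 3 half-splits and
compared between weighted and uniform arms, paired per seed.

## Known limitations and open choices

* **Subset accuracy vs thresholding.** Under strong label
  correlations, per-label 0.5-thresholding over-predicts partner
  labels on single-site samples: the exact-match (absolute-true) rate
  on the *whole* test set can tie or trail the identity-`C` ablation
  even when the model uses the true `C`, while ranking metrics and
  multi-site exact-match clearly improve. Maximizing subset accuracy
  would require decoding the joint label-set mode instead of
  thresholding marginals; we keep marginal thresholding as the
  documented default and report the effect honestly in the harness.
* The evidence is a Laplace approximation; its maximizer inherits the
  approximation's biases (e.g. a tendency to inflate amplitude on
  imbalanced data, which is why the ablations pre-set `a`).
* Finite-difference evidence gradients are an approximation to exact
  Laplace-evidence derivatives; exact gradients would speed up and
  sharpen hyperparameter learning.
* The PseAAC variant (classic vs amphiphilic) and λ are configuration,
  not fidelity claims; the bandwidth rule is the median heuristic.
* Monte-Carlo probabilities carry O(S^{-1/2}) noise (the suite checks
  the rate); the quadrature path is deterministic but ignores nothing —
  marginals suffice for `p_k`.
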