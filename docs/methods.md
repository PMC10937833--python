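# Methods

## The decomposition

`sigplier` factors a log-scale bulk expression matrix Y (N genes × M
samples) as Y ≈ ZB while pulling the loadings toward a binary
prior-knowledge matrix C of gene-signature memberships through Z ≈ CU.
The objective is

    ‖Y − ZB‖²_F + λ₁‖Z − CU‖²_F + λ₂‖B‖²_F + λ₃·Σ|U|,

with Z ≥ 0 and U ≥ 0 elementwise (non-negativity is a config switch,
`nonneg`; it makes "a held-out gene receives a larger loading" a
meaningful one-sided statement and keeps U interpretable as
signature-usage weights).

Genes are z-scored before fitting (`standardize=True`); the training
means and standard deviations are stored in the model and reused when
projecting new data, so a new cohort is standardized *with the training
statistics*, not its own. Standardization is exposed as a switch because
the decomposition itself does not require it; with it, the automatic
penalty calibration below has a natural variance scale.

### Optimizer

The loss is minimized by block coordinate descent, each block solved
exactly so the outer-iteration loss trace is non-increasing by
construction (the test suite enforces ≤ 1e−8 relative slack):

- **B**: closed-form ridge, B = (ZᵀZ + λ₂I)⁻¹ZᵀY.
- **Z**: the subproblem is a convex quadratic with a shared K×K coupling
  (BBᵀ + λ₁I) across gene rows; cyclic coordinate descent over the K
  columns with non-negative clipping, vectorized over genes (up to
  `inner_sweeps` = 10 sweeps per outer iteration).
- **U**: same structure with coupling λ₁CᵀC over signatures; the exact
  coordinate update is a soft-threshold by λ₃/(2·λ₁(CᵀC)ₛₛ) clipped at
  zero, which drives most entries of U exactly to zero.

Initialization is the truncated SVD of the standardized matrix: the top-k
left singular vectors scaled by their singular values, each column
sign-flipped if majority-negative, then clipped at zero (columns that die
under clipping fall back to their absolute values). The fit stops when
the relative loss change drops below `tol` = 1e−6 or after
`max_outer_iter` = 200 outer iterations; a final B-update follows so that
the stored scores are exactly the ridge solution for the final loadings,
which makes projection of the training data reproduce B to numerical
precision. The whole fit is deterministic given the seed.

### Choosing k and the penalty weights

The number of LVs is estimated by a permutation scree test: singular
values of the row-standardized matrix are compared component-by-component
against the 95th percentile of singular values from 20 within-row entry
permutations; k is the count of leading components exceeding their
thresholds. On the generator's default data this lands on the planted
rank.

Defaults for the penalty weights are calibrated from the data, as some
deterministic rule is needed:

- λ₁ = λ₂ = the residual variance of the standardized scree beyond rank
  k, Σ_{i≥k} sᵢ² / ((N−k)(M−k)) — an estimate of the per-entry noise
  variance (≈1 for pure noise after z-scoring, smaller when k captures
  real structure).
- λ₃ is set from `frac` ∈ (0, 1] (default 0.5): the unpenalized
  non-negative least-squares fit of U at initialization provides the
  candidate weight magnitudes, and λ₃ is chosen so the soft-threshold
  scale equals the (1−frac) quantile of the positive candidates times the
  median signature size. Smaller `frac` therefore yields a sparser U;
  0.5 keeps roughly the top half of candidate links. This is this
  package's convention for the sparsity-control fraction; its effect
  (monotone sparsification in λ₃) is property-tested.

### Projection (transfer)

A trained model projects any new preprocessed dataset via
B′ = (ZᵀZ + λ₂I)⁻¹ZᵀY′ with genes reordered to the training universe and
missing genes imputed at the training mean (zero after standardization).
Gene overlap below 80% logs a warning; below 50% it is an error, since at
that point most loadings act on imputed values.

## Association scoring

A positive U entry only says the optimizer used a signature; the
association scan measures whether the link is real. For each signature
with ≥5 genes in the universe, ⌈0.2·|genes|⌉ genes (rounding up so at
least one gene is always held out) are removed from its prior column, the
model is re-fit with the training hyperparameters and seed, and for every
(LV, signature) pair with positive re-fit weight the held-out genes'
loadings are compared with the loadings of all genes outside the
signature (held-in genes belong to neither group). The AUC is the
probability a held-out gene out-loads a non-member (ties ½); the p-value
is the one-sided Mann–Whitney test of that probability exceeding ½; FDRs
are Benjamini–Hochberg across all scored pairs in one family. Signatures
with fewer than five universe genes are skipped with a warning — a
hold-out split of such sets is too small to score.

The interpretability rule is strict on both sides: AUC > 0.7 and
FDR < 0.05. Cell-type labels for LVs come from the passing record with
the highest AUC (ties broken by lower FDR, then higher weight);
signatures without a cell-type annotation map to the residual category
"Rest".

A single seeded hold-out draw is the default; `replicates` repeats the
scan with fresh draws and aggregates per-pair (mean AUC, median p) for
users who want draw-stability. The `include_zero_weight` flag scores
*all* pairs regardless of U — a calibration diagnostic only: with a
correctly calibrated statistic, signatures unrelated to any factor score
near AUC 0.5, which is how the test suite checks decoy behaviour (the
sparse U correctly assigns decoys no weight at all, so they never appear
in the default scan output).

## Differential testing

LV scores are compared between two groups with the unpaired two-sided
Mann–Whitney test. P-values are exact (full enumeration, via the
permutation distribution of U) when the combined sample size is ≤ 20 and
there are no ties — a bound at which enumeration is instant — and use the
normal approximation with tie and continuity corrections otherwise. The
degenerate all-tied case returns U = n₁n₂/2 and p = 1 (the tie-corrected
variance vanishes there). BH correction is applied across exactly the
tested LV family — the interpretable set in the standard workflow — and
direction is reported from group medians.

## Cell-type models and attribution

For each cell type, up to four interpretable LVs ranked by best passing
AUC form the feature set. Classification performance is estimated by
stratified 10-fold cross-validation repeated 10 times: within each
repetition the out-of-fold prediction scores are pooled and give one
AUROC; the mean and the standard deviation are taken **across the ten
repetitions** (the across-repetition SD is the documented convention).
The default classifier is a random forest with library-default
hyperparameters — no tuning, as the intended datasets are small — and
logistic regression is available as a secondary check through
`model_spec`.

Shapley attributions are computed exactly: the value of a feature
coalition S for a sample is the mean model output over background rows
with the features in S replaced by the sample's values, and all 2^d
coalitions are enumerated (d ≤ 12 enforced; the cell-type models use
d ≤ 4). Exactness buys testable contracts — efficiency to 1e−8, the dummy
and symmetry axioms, and the closed form for additive models — that
kernel approximations only satisfy approximately. Features are ranked by
decreasing mean |value|.

## Synthetic data

The generator emulates the post-log statistical structure the model
assumes, not the sequencing process. Defaults: 2000 genes, 80 samples, 30
signatures of 50 random genes each, 5 active signatures each driving one
factor (loading 1 on the signature's genes, |N(0, 0.02)| off-support),
standard-normal sample scores, the first two factors shifted by
`group_effect` = 1.0 in the second half of the samples, additive
N(0, 0.5²) noise, and a scalar shift keeping the minimum at or above −1
(the log image of a zero TPM). Labels are balanced. These defaults give a
per-gene signal-to-noise ratio at which recovery is expected but not
trivial: the permutation scree finds the planted rank, and the hold-out
scan flags planted pairs at AUC ≈ 1 while decoys sit at 0.5.

What passing these tests shows — and does not show: the pipeline recovers
planted structure under its own modelling assumptions (log-scale additive
Gaussian noise, factors exactly supported on signatures). Real RNA-seq
adds count noise, library-size variation, batch structure, and signatures
that only approximately match any cell state; performance there is an
empirical question the fixture cannot answer.

## Numerical and design notes

- End-to-end recovery tests fit with k = 10 rather than the estimated
  k ≈ 5: the method is insensitive to the exact k (extra LVs simply fail
  the interpretability screen), and a generous fixed k decouples the
  recovery property from the scree estimator.
- Gene filtering (null variance, >95% zeros — strictly more than; exactly
  95% is kept — and membership in ≥1 signature) is defined on the TPM
  scale; on an already-logged matrix, zeros are detected as values equal
  to −1, the exact log image of TPM 0.
- Gene identifiers are opaque case-sensitive strings; no alias
  resolution is attempted.
- All TSV serialization uses %.17g and round-trip float parsing, so model
  and expression round-trips are value-exact and seeded CLI runs are
  byte-reproducible.
- Library usage: the Mann–Whitney machinery is scipy's (behind the
  exact/asymptotic switch above), BH is statsmodels', and cross-validation
  and classifiers are scikit-learn's; the decomposition, its optimizer,
  the hold-out association scan and the exact Shapley enumeration are
  implemented here. Test oracles for the statistics (pair counting, label
  enumeration, hand-coded step-up) are independent re-implementations.
- Known limitations: the optimizer finds a local minimum of a non-convex
  objective (the SVD initialization makes it deterministic, not global);
  λ calibration conventions differ from other implementations of this
  model family, so fitted weights are comparable within this package
  only; the association scan's single hold-out draw leaves AUCs with
  draw-to-draw variability that `replicates` can average away.

## Problem sizes

Default test and acceptance runs use the generator defaults (2000×80,
30 signatures) for end-to-end checks, 200×50 instances for optimizer
property checks, and 100 samples × 4 features for classifier calibration —
sizes at which every documented property is measurable in seconds while
matching the structure of the intended biopsy-cohort use case (tens to
hundreds of samples, a few thousand signature genes).
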