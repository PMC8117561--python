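# Methods

## Model

A window-level beta matrix D (W windows × n samples, entries in [0, 1]) is
modelled as a convex mixture of K latent methylation components (LMCs):

    D ≈ T · A,   T ∈ [0, 1]^(W×K),   A ≥ 0,   1ᵀA = 1ᵀ  (simplex columns)

fit by minimizing

    f(T, A) = ‖D − T·A‖²_F + λ · Σᵢⱼ Tᵢⱼ(1 − Tᵢⱼ).

The quadratic penalty is maximal at Tᵢⱼ = 0.5 and zero at 0/1: it encodes
the prior that a pure cell population's methylome is near-binary per
window. λ = 0 reduces to plain box/simplex-constrained least squares.

Assumptions: mixing is linear in beta space (valid when windows average
enough probes that probe-level chemistry effects wash out); components are
shared across samples; proportions are sample-specific and sum to one.

## Optimization

Alternating minimization with two exactly monotone blocks:

- **A-step** — for fixed T, each sample's proportion vector solves a
  simplex-constrained least-squares problem; we use projected gradient
  with the Lipschitz step 1/L, L = 2·λ_max(TᵀT), and Euclidean simplex
  projection. Each step provably decreases every column's objective.
- **T-step** — for fixed A, each entry's coordinate objective is the
  quadratic (c₂ − λ)t² − (2c₁ − λ)t + const; it is minimized in closed
  form on [0, 1] (interior stationary point when convex, otherwise the
  better endpoint, ties to 0). Entries are swept per component with an
  incrementally updated residual.
- **Monotone extrapolation** — after each pair of block updates a momentum
  step (clipped/projected back to the feasible set) is *tried* and
  accepted only if it lowers the objective; on rejection the momentum
  weight halves. This preserves the non-increasing objective trace by
  construction while removing the slow linear tail of plain alternation:
  on exact-fit instances the objective reaches numerical zero well within
  the default 300 iterations.

Defaults: `max_iter=300`, `n_init=10` seeded random restarts
(T ~ Uniform(0,1), A columns ~ Dirichlet(1), one substream per restart,
best final objective wins), `tol=1e-6` relative decrease, `lam=0.01`.
Grid defaults for model selection mirror the tumor-cohort use case
(K ∈ {9, 10, 11}, λ ∈ [1e-5, 1] log-spaced); K ∈ {5..20} suits
reference-cell deconvolution.

Cross-validation folds are over samples: T is fit on training columns,
held-out proportions are the simplex least-squares fit with T fixed, and
the fold error is the held-out mean squared reconstruction error. Sample
folds keep T estimable and mirror holdout of tumors. The stability score
is the mean best-matched component correlation of the restarts against the
winning restart; a (K, λ) choice should combine low CV error with high
stability, because CV error alone is nearly flat above the true K.

## Identifiability and the synthetic generator

The generator emulates the statistical structure the pipeline assumes:
background windows draw one bimodal beta (equal mixture of Beta(2,10) and
Beta(10,2)) shared by all components; per component, planted VMR windows
are separated from every other component by at least the configured
effect; proportions are Dirichlet; expression counts for signature genes
are `baseline · exp(slope · proportion)` with log-normal noise, rounded to
integers; alteration probabilities follow a logistic function of the
immune component's proportion; survival is exponential with log-hazard
decreasing in the immune proportion and administrative censoring.

One design point matters and is easy to miss: **a mixture whose components
differ only in interior-valued windows is not identifiable.** If every
discriminating window is strictly inside (0, 1) and the sampled
proportions do not reach the simplex vertices, a continuum of exact
factorizations (T·M⁻¹, M·A) exists, and no solver can pin down the true
proportions (we observed exact fits — objective ~1e-17 — with proportion
errors of 0.06 under such a design). The generator therefore plants half
of each component's VMR windows *saturated* — the target component at beta
exactly 0 (hypo) or 1 (hyper), as in component-specific fully
unmethylated/methylated regions — and gives the non-target components
small mutual jitter (< 0.15, below the 0.2 VMR threshold) instead of
identical values. Real methylomes have exactly this structure; with it,
the true factorization is the extreme point of the feasible set, and the
binarization penalty (any small λ > 0) selects it. At λ = 0 a residual
proportion ambiguity of the order of the smallest sampled proportions
remains, which is why recovery accuracy is quoted at the operating
λ = 0.01.

What the generator does **not** emulate: Infinium type I/II probe
chemistry, batch and FFPE artifacts, copy-number-induced beta shifts,
sex-chromosome dosage, fragment-length or GC biases in expression, and
clonal heterogeneity within a component. Passing recovery tests therefore
demonstrate correctness of the algorithms under the mixture model, not
robustness to array artifacts — on real data, preprocessing
(normalization, probe QC) is assumed done upstream.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 5000 bp | genomic bin width for beta averaging; bins are 0-based half-open, anchored at 0 |
| `k`, `lam` | 9, 0.01 | component count and binarization weight for tumor cohorts |
| VMR `threshold` | 0.2 | minimum beta separation from *all* other components (strict inequality) |
| `r_threshold` | 0.3 | absolute Pearson cutoff for signature genes |
| promoter | −1000/+100 bp | strand-adjusted interval around the TSS |
| TIL zero floor | 0.01 | numerator floor and median pseudocount in the log-ratio |
| UQ target | 1000 | 75th-percentile normalization constant (any positive value shifts per-sample log-ratios uniformly) |
| CNA thresholds | ±0.3 | segment log2-ratio cutoffs for gene-level amp/del calls (overridable; precomputed calls can be ingested) |
| fusion filter | — | split_reads1+split_reads2 > max(1, discordant_mates/10); genes in > 20 samples dropped |
| enrichment gate | 0.2 | per-type and combined p-value retention threshold (exploratory screen, no across-gene correction) |

Simulation defaults are the conditions the recovery properties are stated
under: W = 300, n = 60, K = 3, Dirichlet(1) proportions, beta noise sd
0.02, VMR effect 0.4, expression slope 1.0 with log-noise sd 0.3 (giving
|r| ≈ 0.6 methylation–expression coupling at the planted effect),
baseline count 1000, hazard log-ratio 2.1 (tertile hazard ratio ≈ 3 under
Dirichlet(1) immune proportions), censoring at t = 3 (≈ 20% censored),
deletion logit intercept 1.0 / slope 6.4 (penetrance ≈ 0.6 in the
lowest-immune third vs ≈ 0.05 in the highest). These sizes keep the full
test suite in the minutes range on one CPU while leaving all recovery
margins wide.

## Numerical and rule choices

- **VMR rule is strict**: a difference of exactly 0.2 does not qualify. A
  window can be hypo (hyper) for at most one component — the row argmin
  (argmax) — so per-component hypo/hyper sets are disjoint by
  construction.
- **Multi-gene probes** contribute to every annotated gene (array
  annotations are many-to-many).
- **Correlations** require ≥ 3 paired samples and nonzero variance on both
  sides; degenerate genes are skipped with a logged reason, never
  NaN-propagated.
- **Zero counts** are floored at 0.01 before any log-ratio; the TIL
  denominator uses the raw cohort median plus 0.01. Flooring leaves the
  median-based score unchanged whenever fewer than half a sample's
  signature genes are zero.
- **Tertiles** sort by score with ties broken by sample id; remainders go
  to low, then medium. The LMS residual tie (both proportions equal and
  above threshold) goes to group 2 and is logged.
- **Fisher's exact test** is computed by exact rational (Fraction)
  hypergeometric summation of all tables whose probability does not exceed
  the observed one — exact arithmetic makes the two-sided tie rule
  unambiguous where floating-point pmf comparisons can flip near-ties.
  Two-sided throughout; the enrichment direction is reported separately.
  Note the test is conditionally exact and therefore conservative at
  finite margins: under a simulated null at n = 150 (50 vs 50 tertiles)
  the attained per-type size at α = 0.05 is ≈ 0.027–0.031, not 0.05.
- **Fisher's method** is applied only to genes with tested events in ≥ 2
  alteration types; single-type genes keep their per-type p. The screen
  applies no across-gene correction and flags results `exploratory=true`.
- **Log-rank** uses the standard hypergeometric variance with tie
  multiplicities; subjects censored exactly at an event time count as at
  risk. Estimation and testing delegate to lifelines; an independent
  hand-rolled Mantel–Haenszel oracle in the test suite agrees to 1e-8.
- **BH adjustment** is the textbook step-up (statsmodels); it is monotone
  in the order statistics but not idempotent in general — only fixed
  points such as constant vectors re-adjust to themselves.
- **Oncoprint memo-sort** treats the gene × sample indicator as a binary
  number (most-altered gene most significant) and sorts columns
  descending within each tertile; gene ties break by name, sample ties by
  id, so output is deterministic.

## Limitations

- The factorization is biconvex; global optimality is approached by
  restarts, not guaranteed. The restart-stability score is the practical
  diagnostic.
- Model selection by CV error alone is weakly informative above the true
  K (error plateaus); stability must be consulted.
- Gene-level CNA calling from segment means ignores focality and ploidy;
  the thresholds are conventions, and precomputed calls are the better
  input when available.
- The enrichment screen is exploratory by design: retention at p < 0.2
  without across-gene correction will admit false positives in
  genome-wide use.
- No Cox modelling beyond a thin univariable wrapper; competing risks and
  multivariable adjustment are out of scope.
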