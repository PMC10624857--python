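# Methods

## Model and assumptions

The package works in the classical multi-trait selection-index framework.
Each genotype i carries an unobserved vector of genotypic values g_i for m
traits; the observed phenotype is x_i = μ + g_i + environmental deviation.
Selection aims to improve the aggregate genotype H = a'g, a linear
combination of genotypic values with relative economic weights a, but can
only act on a linear index of phenotypes I = b'x. Under multivariate
normality of (g, x) with genotypic covariance G and phenotypic covariance P:

* the index maximizing corr(I, H) has coefficients solving P b = G a
  (optimum / Smith–Hazel);
* b = a (base / Brim) needs no genetic parameters and is the natural choice
  when P and G estimates are unavailable or untrusted;
* b solving G b = d (Pešek–Baker) targets a stated vector of desired gains d
  instead of economic weights; by default d = √diag(G), one genetic standard
  deviation per trait, so "desired" means an equally ambitious gain on every
  trait in its own genetic scale.

All evaluation criteria are exact consequences of this model rather than
asymptotic approximations: accuracy R_HI = b'Gw / √(b'Pb · w'Gw) (w = a, or
d for Pešek–Baker), total gain ΔH = k·R_HI·√(w'Gw), per-trait gains
Δ = k·G b / √(b'Pb), relative efficiency RE = r_G(A)I / h_A with
r_G(A)I = b'g_A / √(G_AA · b'Pb), and CV_I = 100·σ_I/X̄ over realized
scores. R_HI is always computed from the general covariance form; the
optimum-only shortcut √(b'Ga / a'Ga) is wrong for the base and Pešek–Baker
indices (it would overstate their accuracy) and is used nowhere.

The truncation-selection differential is k = φ(z)/p for selected proportion
p with z the upper-p standard-normal quantile — the mean of the selected
tail in SD units. It is carried at full precision (k(0.10) = 1.75498…);
rounding (e.g. the customary 1.76) is left to the caller or report layer.

## Variance-component estimation

Input is a balanced randomized complete block design: every genotype exactly
once in every replicate block, no missing plots. Per trait, the two-way
ANOVA (genotype + replicate + residual) yields MS_g and MS_e, and equating
to expected mean squares under random genotype effects gives
σ²_g = (MS_g − MS_e)/r and σ²_e = MS_e. The identical quadratic forms
applied to trait pairs (mean cross-products) give the genotypic covariances,
so setting j = k reproduces the univariate path exactly — a tested
invariant, along with the sum-of-squares decomposition itself.

Two phenotypic-variance conventions exist in practice and the literature is
often silent about which was used: per-plot (σ²_p = σ²_g + σ²_e) and
per-genotype-mean (σ²_p = σ²_g + σ²_e/r). Both are implemented
(`basis="plot" | "mean"`); "plot" is the default. G is identical under both.

Negative σ²_g estimates (MS_g < MS_e) are legitimate method-of-moments
outcomes in low-heritability data; they are reported as estimated, with a
warning, because silently clamping breaks the SS identity and the symmetry
between the variance and covariance paths. An explicit `clamp_negative=True`
clamps the G diagonal to zero. Unbalanced or incomplete designs are rejected
with the offending genotype/replicate named — the expected-mean-square
solution assumes balance, and REML-style imputation is out of scope.

Correlation entries whose parent trait has nonpositive variance are NaN
("undefined"), never zero: a zero would silently feed downstream weights.

## Weighting schemes

* `unit`: a = 1 for every trait.
* `correlation`: a_j = Pearson correlation of trait j with the target trait
  across the rows of the trait panel ("total" correlation over genotype-level
  records); rows of a precomputed genetic or phenotypic correlation matrix
  can be substituted. The target's own weight is 1.
* `stepwise_beta`: standardized regression coefficients of the traits that
  enter a stepwise OLS regression of the target on the other traits;
  non-entered traits get 0, the target 1. Entry/stay significance levels
  default to 0.15/0.15, the long-standing convention of stepwise selection in
  agricultural statistics packages; both are exposed. Entry ties break to the
  lowest column index for cross-platform determinism. Note that at the 0.15
  default an unrelated trait has roughly a 15% chance of a spurious entry —
  that is a property of stepwise selection itself, not of this
  implementation; the test suite uses stricter thresholds where it asserts
  non-entry.

## Numerical choices

* Linear systems (P b = G a, G b = d) are solved (`scipy.linalg.solve`,
  symmetric path), never via explicit inversion; a condition number above
  1e12 raises with a suggestion to drop redundant traits. A pseudo-inverse
  fallback for singular G exists only behind an explicit `allow_pinv` flag,
  because a minimum-norm b silently changes the question being answered.
* Ranking is by descending score — larger I is always better; traits to be
  decreased must carry negative weights. Ties share first-appearance order
  (stable sort), so results are platform-independent.
* Selection keeps the top ⌈n·p⌉ genotypes.
* CV_I uses the sample mean and SD (ddof=1) of the realized scores rather
  than √(b'Pb): its definition is over per-individual index values, and the
  two differ when the panel's sample covariance is not exactly P. It is
  undefined (error) when the mean score is at machine-zero scale.
* Covariance CSVs asymmetric by ≤ 1e-6 (relative) are symmetrized with a
  warning; worse asymmetry is an error naming the worst cell. Reports round
  to 4 decimals; machine-readable outputs keep full precision.

## Synthetic trials

`simulate_rcbd_trial` draws genotype effects g_i ~ MVN(0, G_true), optional
per-trait replicate (block) effects ~ N(0, rep_sd²), and plot errors
e_ij ~ MVN(0, E_true), emitting y_ij = μ + g_i + r_j + e_ij. Draws happen in
that fixed order from one seeded generator, so trials are bit-reproducible.
Replicate effects default to zero — they cancel from genotype means and
never enter the evaluation criteria — but a nonzero value exercises the
block stratum of the ANOVA. The generator emulates a balanced normal-theory
trial only: no genotype×environment interaction, no spatial field trend, no
missing plots, no non-normal traits. Passing recovery tests therefore show
the estimator chain is correct under its own assumptions, not that it is
robust to their violation.

Default study conditions for recovery checks: 4 traits, 200 genotypes,
3 replicates, 50 seeded trial replicates, with heritabilities between 0.5
and 0.67 — sizes typical of a single-location preliminary yield trial, large
enough that 3 Monte-Carlo standard errors separate real bias from noise.
The acceptance script uses 30 trial replicates for the same design, which
keeps its runtime in seconds while leaving Monte-Carlo error well below the
effects being measured.

`worked_fixture` provides the hand-checkable two-trait example
(P = [[4,1],[1,2]], G = [[2,.5],[.5,1]], a = (1,1)) with a 6-genotype panel
constructed by exact whitening/recolouring so its sample covariance equals P
to machine precision; every downstream criterion for it has a closed-form
value documented in the tests.

## Design notes and limitations

* The model/results split (`SelectionIndex.fit()` →
  `SelectionIndexResults.summary()`) wraps the functional layer
  (`optimum_coefficients`, `evaluate_index`, …), which remains public for
  scripting and testing.
* Trait positions are 1-based in the CLI (field convention) and 0-based in
  the library (Python convention).
* Out of scope: restricted/constrained indices (Kempthorne–Nordskog),
  BLUP- or marker-based indices, REML variance components, designs other
  than balanced RCBD, multi-stage or multi-generation (realized) gain, and
  economic discounting.
* A reference reproduction test for a published 28-line maize analysis is
  included but requires the user to supply that dataset's CSVs
  (`data/maize-reference/`); the package does not redistribute them.
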