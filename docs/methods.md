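# Methods

## The model

For n species with trait vector y (here: EDP residuals from the
Charadriiform egg-mass allometry, in days) and design matrix X (intercept,
clutch size ∈ {1,2}, offshore foraging ∈ {0,1}, diurnality ∈ {0,1}, open
nest ∈ {0,1}), the regression is

    y = Xβ + ε,   ε ~ N(0, σ² V(λ)),

where V is the Brownian-motion tree covariance — V[i,j] is the branch-length
distance from the root to the most recent common ancestor of species i and j,
V[i,i] the root-to-tip distance — and V(λ) multiplies the off-diagonal
entries by λ while keeping the diagonal.  λ = 1 corresponds to pure Brownian
evolution of the residuals, λ = 0 to phylogenetic independence.  The model
assumes the tree (topology and branch lengths) is known without error, the
predictors act linearly and without interactions, and the residual process
is homoskedastic in the Brownian sense.

### Estimation

* β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y is computed by whitening: both y and X are
  premultiplied by L⁻¹ (L the lower Cholesky factor of V(λ)), then solved by
  QR least squares.  No explicit matrix inverse is formed anywhere.
* σ̂²(ML) = RSS_w/n (whitened residual sum of squares over n); the profile
  log-likelihood is −(n/2)·ln(2πσ̂²) − ½·ln|V(λ)| − n/2.
* λ̂ maximizes the profile log-likelihood over [0, 1] by bounded scalar
  (Brent-type) minimization on 5 equal sub-intervals plus both endpoints,
  convergence tolerance 1e-8 on λ.  [0, 1] is the standard interpretable
  range; `lambda_upper="max"` extends the search to the algebraic bound
  −1/μ_min(D^{-1/2}(V−D)D^{-1/2}) at which V(λ) loses positive
  definiteness.  Non-positive-definite covariances raise rather than being
  jittered: silent regularization would corrupt likelihood comparisons.
* Standard errors use the unbiased divisor: se² = diag(RSS_w/(n−k) ·
  (X_w'X_w)⁻¹), computed from the triangular QR factor.  t = β̂/se.
* Degrees of freedom for t tests default to **n taxa** — the stated
  convention of the analysis this package reproduces — with the textbook
  n − k selectable.  Both one- and two-sided p-values are always reported;
  the significance markers (`*` p<0.05, `**` p<0.01) follow the one-sided
  values by default because the study's predictions were directional (its
  printed marker on the open-nest term is consistent with a one-sided but
  not a two-sided test).  The reported coefficients are raw partial
  regression coefficients (the source's "standardized coefficient
  (sometimes called β)" is, by its printed magnitudes in days, not
  z-scored); fully z-scored coefficients are available separately.
* r² = 1 − RSS_w/TSS_w in the whitened space, with TSS_w around the GLS
  intercept-only fit of the same V(λ̂); this is one of several inequivalent
  r² definitions for GLS, so published r² values from other software are
  treated as approximate.
* On a star covariance (all off-diagonals zero) λ is unidentifiable; the
  fit equals OLS and λ̂ is reported as NaN with an `lambda_indeterminate`
  flag.

### Scale equivariance

Multiplying y by c multiplies β̂ and se by c and leaves t, p and r²
unchanged — exactly, in the fixed-λ algebra (tested at 1e-10).  The
*estimated* λ̂ is the output of an iterative optimizer with xatol 1e-8, so
two runs on y and c·y can differ in λ̂ at that order; the test suite asserts
1e-6 agreement there and 1e-8 downstream.

## Trees

* Newick parsing is delegated to dendropy (quoted labels, scientific
  notation, Nexus `trees` blocks with `translate` tables); absent branch
  lengths stay absent rather than becoming 0.  Numeric internal-node labels
  are read as supports ([0,1] directly, (1,100] divided by 100).
* Writing is canonical: children ordered by lexicographically smallest
  descendant label, supports printed to 3 significant digits, branch
  lengths in shortest round-tripping decimal form.  Structurally equal
  trees therefore serialize identically.
* Outgroup rooting places the root at the midpoint of the outgroup's
  branch; supports along the reversed path are dropped (their clades no
  longer exist).  Rooting is a no-op when the root already separates the
  outgroup.
* Pruning suppresses degree-2 nodes with branch lengths summed.  By
  default the stem above the kept leaves' MRCA is discarded (covariance
  defined relative to the ingroup root — the comparative-methods
  convention); `keep_stem=True` preserves the original root position, under
  which pruning commutes exactly with covariance submatrix selection.
* Majority-rule consensus is **strict** (> threshold, ties excluded, so
  incompatible splits can never co-occur for threshold ≥ 0.5) and **plain**
  (no greedy addition of compatible minority splits).  Support = clade
  sample frequency; consensus branch lengths are the mean over the trees
  containing the clade — the common convention, chosen because the source
  is silent and the mean is deterministic.
* Burn-in removal drops the first ⌈fraction·N⌉ trees.  The source
  describes its own burn-in inconsistently (25% of a 3M-generation chain
  vs. the first 2.5M of 10M generations); the fraction is therefore an
  explicit parameter, default 0.25, and the package takes no position.

## Allometry

Predicted EDP = a·m^b with a = 17.18 days, b = 0.119 (the published
Charadriiform relationship; the package never refits these).  Residuals are
carried at full floating precision; the printed 2-decimal residual column of
the source table is packaged only for a sensitivity flag
(`use_printed_residuals`) and for test comparison at ±0.01 days.

## Missing data

Two penguins (erect-crested, yellow-eyed) lack the foraging predictor.
Default policy: drop those taxa (n = 31) and prune them from the tree, with
the report stating every dropped taxon and its reason.  Alternatives, one
flag away: drop the foraging variable (n = 33), or impute the modal value.
The source does not say which set it used; the report always does.

## Synthetic data

The generator emulates the analysis' assumed world: a Yule (pure-birth)
ultrametric tree (waiting times Exp(k·birth_rate), uniform splitting
lineage; expected depth Σ_{k=2..n} 1/(k·birth_rate)); predictors drawn
i.i.d. per tip (clutch 1/2 with P(2) = 0.5, binaries Bernoulli(0.5)), or
phylogenetically autocorrelated via median-thresholded latent Brownian
traits; response = Xβ + MVN(0, σ²·V(λ)) noise via Cholesky (eigen-fallback
with eigenvalues clipped at −1e-10 for PSD-singular cases such as λ = 0
stars or duplicated tips).  One root seed fans out to tree / predictor /
noise substreams (`numpy` `SeedSequence.spawn`), so the tree draw is
invariant to the predictor model.  Default scales (100 tips, birth rate 1,
σ² = 25, β = (0, −8, 2, −3.5, −4)) echo the recovery study's stated design;
σ² = 25 puts the noise standard deviation (5 days) on the order of the real
residual spread.

What the generator does **not** emulate: tree estimation error, correlated
predictors with the phylogenetically clumped pattern of the real table
(unless `phylo_predictors` is set), measurement error in EDP or egg mass,
extinction.  A green recovery test therefore establishes correctness of the
estimator under its own assumptions, not robustness to their violation.

Type-I calibration is run under the generator's null defaults — all-zero
coefficients, pure Brownian noise (λ = 1), σ² = 1 — with two-sided tests at
df = n − k; estimating λ before plugging it in inflates rejection rates
mildly above nominal under misspecified interior λ, which is visible if the
null is instead simulated at λ = 0.8.

## The stand-in tree

`load_standin_tree()` returns a **synthetic** consensus-tree surrogate: the
accepted genus-level topology of the 33 study species (both families and
all genera monophyletic), with branch lengths from the node-depth rule
(every internal node one unit above its tallest child; ultrametric,
arbitrary units).  It exists because the study's own consensus tree and
branch lengths were never published and the package performs no sequence
retrieval or tree inference.  On this tree the *qualitative* published
pattern reproduces (clutch size negative, largest in magnitude, significant;
diurnality and open nests negative; offshore foraging positive,
non-significant; λ̂ near 1), but coefficient magnitudes, λ̂ = 0.999995 and
r² = 0.445 are tree-dependent and are not asserted anywhere.

## Known limitations

* No κ/δ branch-length transforms, no Ornstein–Uhlenbeck or REML variants,
  no independent contrasts, no AIC model comparison — out of scope by
  design.
* The λ profile can be nearly flat close to 1 on trees with little depth
  structure; the multi-start bounded search guards against local optima but
  the reported λ̂ near a boundary should be read with its likelihood curve
  in mind (profile endpoints are logged at INFO).
* Consensus branch lengths are summaries (means over containing trees), not
  joint estimates; depths of the consensus tree need not be ultrametric
  even when every sampled tree is.
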