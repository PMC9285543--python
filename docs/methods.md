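# Methods

## Model

The core model is a phylogenetic regression under Brownian motion. For N
taxa with predictor x (log10 skull width, mm) and response y (log10
A_Phys, mm²) observed at the tips of a rooted time-scaled tree,

    y ~ MVN(α·1 + β·x,  σ²·C_λ)

C is the phylogenetic variance–covariance matrix: C_ij is the path length
(Myr) from the root to the most recent common ancestor of tips i and j,
and C_ii the root-to-tip path length. Fossil tips terminate above the
present, so trees need not be ultrametric and the diagonal of C is not
constant. Pagel's λ rescales the off-diagonal of C; λ = 1 (pure Brownian
motion) is the default and λ can optionally be estimated on [0, 1]. The
matrix is built natively on polytomies; no dichotomization is forced.

Regression is performed in log10–log10 space. A log transform is required
for an area-on-length scaling model (expected slope 2 for geometric
similarity); log10 is used so slopes read directly as scaling exponents.

## Inference

Priors: improper flat on (α, β); uniform on log σ² over [1e−12, 1e12]
(i.e. p(σ²) ∝ 1/σ² on a wide range); uniform(0, 1) on λ when estimated.
These make the posterior mean of (α, β) coincide with the
generalized-least-squares estimator (X'C⁻¹X)⁻¹X'C⁻¹y, which the test
suite uses as an exact oracle.

The sampler is a Gibbs scheme with exact conditionals:

* (α, β) | σ², λ  ~  N(b_GLS, σ²(X'C_λ⁻¹X)⁻¹)
* σ² | (α, β), λ  ~  InvGamma(n/2, RSS_λ/2), clipped to the prior range
* λ (optional)    — random-walk Metropolis with reflection at 0 and 1,
  step SD 0.15.

At fixed λ the Cholesky factor of C is computed once per fit and each
iteration costs O(1) beyond it, so a 59-tip fit with the default settings
takes ~40 ms. Default chain settings are 2,000 iterations, 1,000 burn-in,
thinning 1, one chain — i.e. 1,000 retained draws, the posterior size used
for prediction throughout; longer, thinned, multi-chain runs in the style
of full BayesTraits analyses (tens of millions of iterations) are
available through `McmcConfig` but add nothing at this model size. Chains
are seeded from (seed, chain-index) streams and runs are exactly
reproducible.

If C is numerically singular (e.g. two tips separated by zero branch
length) a diagonal jitter of 1e−8·max(C_ii) is added once with a warning;
if the factorization still fails a `SingularCovarianceError` suggests
resolving zero-length branches.

## Prediction at unobserved tips

For a target tip with predictor x* and no response, each posterior draw
(α, β, σ², λ) contributes one draw from the conditional normal given the
observed tips:

    mean = α + β·x* + c*' C_λ⁻¹ (y − α·1 − β·x)
    var  = σ² (c** − c*' C_λ⁻¹ c*)

with c* the target–observed covariance vector and c** the target's
diagonal entry (off-diagonal terms λ-scaled). The sampling step is
included, so the predictive distribution carries parameter *and*
conditional-normal uncertainty; conditioning can only shrink the variance
below σ²·c**. Predictions therefore exploit phylogenetic position: a
target nested inside a clade with correlated residuals borrows their
information (the phylogenetic-BLUP behaviour), while a λ = 0 or
maximally distant target reduces to the regression line. Batch prediction
conditions every target on the observed tips only — never on other
targets — and is draw-for-draw identical to single-tip prediction (the
per-target random stream is derived from the posterior seed and a CRC of
the taxon name, so target order is irrelevant).

## Scoring

The posterior predictive p-value is two-tailed and rank-based:
p = 2·min(#{draws ≤ obs}, #{draws ≥ obs})/M, capped at 1, ties counted
inclusively on both sides (so p can never be 0 for a value inside the
draws). "Beyond 95% of the distribution" therefore means p < 0.05 against
a central interval; the tail convention is switchable (`tails=`) for
one-sided use. A LOOCV fold passes at p ≥ 0.05 exactly (failure is the
strict inequality). Per-fold seeds are derived from the master seed and a
CRC of the left-out taxon's name, so folds are order-independent and
parallelizable; a fold with a singular reduced covariance is recorded as
failed with its reason rather than aborting the run.

## Tree preparation

FAD/LAD time-scaling assumes the input tree is dated with fossil tips at
their first appearance dates and extant tips at the present (an explicit
root-age calibration can be supplied instead). Each fossil terminal
branch is then extended to the taxon's last appearance date, so the full
stratigraphic range is included in the terminal branch — the scaling that
maximizes the time available for trait evolution. Extant tips extend to
0 Ma.

Zero-length internal branches are resolved by equal time-sharing: for
each maximal run of consecutive zero-length branches, the nearest
ancestral branch with positive duration donates its time, divided equally
along every root-to-tip path through the run (a run of k zeros below a
donor of duration d yields k+1 branches of d/(k+1) along the chain). The
reallocation moves only node ages inside the run, so every root-to-tip
distance is preserved exactly — this is the property that matters for C —
and branching runs are handled without ambiguity. Zero-length *terminal*
branches (a tip whose LAD equals its divergence date) are legitimate and
left alone. A zero branch with no positive ancestor (at the root) is an
error.

## Muscle and lever mechanics

* A_Phys = M·cosθ/(ρL), with ρ = 1.056×10⁻³ g/mm³; angles are accepted in
  degrees and converted internally.
* Fossil reconstructions supply A_Gross (section perpendicular to the
  muscle body's long axis), corrected by division by sinθ with group
  defaults θ = 45° (temporal), 0° (quadrate), 30° (pterygoid). The
  correction is undefined at θ = 0, where the parallel-fibre reading of
  the architecture formula applies and the area is used unchanged. The
  sinθ direction is implemented exactly as specified for the workflow it
  supports, not silently replaced by cosθ, although the two corrections
  move in opposite directions — a deliberate fidelity choice.
* Left/right gross areas are averaged; a single measurable side is
  accepted (fossil damage and asymmetry are the norm).
* Muscle force F = σ_M·A_Phys with σ_M = 0.3 N/mm² applied identically to
  all groups; bite force F_Bite = 2·Σ(F_i·r_i)/d at the anterior- and
  posterior-most bite points. The model is 2-D and scalar (forces
  perpendicular to in-levers); the posterior bite force always dominates
  because its out-lever is shorter. When bite force is computed from
  predictive distributions, the predictive median is taken per muscle
  group on the log10 scale and back-transformed (equivalent to the median
  of back-transformed draws, since medians commute with monotone maps);
  full precision is kept internally and rounding is left to the reporting
  layer.

## Synthetic data generator

`simulate_tree` grows a pure-birth tree to the requested tip count
(extended past the final birth event so tips are distinct), rescales it
to a root age of 250 Myr — the depth of the archosaur problem the package
targets — and, in "fossil" style, truncates a 30% subset of terminal
branches by a uniform fraction, emulating last-appearance-terminated
tips. `simulate_dataset` draws the predictor as a Brownian trait on the
same tree (root state 1.8 log10 mm, variance 1e−3 per Myr, spanning
roughly skull widths of 16–900 mm), then the response from the model with
defaults α = −1.5, β = 2.0 and σ² = 1.6×10⁻⁴ per Myr, chosen so the
residual SD at the tips is ≈ 0.2 log10 units. An i.i.d.-predictor option
exists for ordinary-least-squares oracle tests.

What the generator does *not* emulate: measurement error in W_Sk or
A_Phys, reconstruction bias in fossil A_Gross, topology/branch-length
uncertainty, and non-Brownian evolution (OU, early burst). Passing
calibration tests therefore demonstrate the statistical machinery is
correct under its own assumptions, not that real muscle data meet them.

## Validation design

* Oracle layer: posterior means against closed-form GLS/OLS (within 3
  Monte-Carlo standard errors, batch-means estimate); log-likelihood
  against brute-force multivariate-normal density (1e−8).
* Recovery layer: 95% credible-interval coverage for (α, β) over 300
  seeded 59-tip simulations, required within 92–98%.
* Calibration layer: mean LOOCV accuracy over 20 replicate N = 40
  datasets at reduced chain length (1,000 iterations), required within
  0.95 ± 0.05; a planted 10-predictive-SD outlier must always fail its
  fold. Replicate counts and chain lengths were fixed once from the
  binomial error budget of each check.
* Mechanics layer: exact hand-computed PCSA, pennation and lever values.
* Reproduction layer: the published LOOCV/prediction accuracies are
  re-run verbatim when the original supplementary data files (trait table
  and supertree) are placed under `data/archosaur/`; those files are not
  redistributable with the package, so the check reports its requirement
  when they are absent.

## Known limitations

Single predictor and single response only (as is general for phylogenetic
regression); no OU or early-burst residual models; the λ sampler is a
simple random-walk Metropolis and mixes slowly near the boundaries for
very small trees; BayesTraits' exact priors and proposals are not
reproduced — the posterior is anchored to the GLS closed form instead,
which is what the accuracy statistics depend on.
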