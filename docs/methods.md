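# Methods

## The constrained maximum-entropy model

For one plot, the model predicts relative abundances `p` over S genera as
the distribution minimizing `D_KL(p‖q)` subject to matching the plot's
community-weighted means (CWMs) of J traits.  The optimum has the Gibbs
form `p_i ∝ q_i exp(Σ_j λ_j t_ij)` on the support of the prior `q`;
genera with zero prior mass receive exactly zero predicted abundance.
With a uniform prior this is ordinary maximum entropy; with the regional
(metacommunity) relative abundances as prior it asks what the traits add
*beyond* the regional pool.

The multipliers are found by minimizing the smooth convex dual
`log Z(λ) − λ·c`.  We use a damped Newton iteration: the Hessian is the
prior-tilted trait covariance (J×J, cheap, PSD), gradients are constraint
residuals, and all exponentials go through log-sum-exp.  The line search
accepts non-increasing steps within float noise so the final quadratic
Newton step is not rejected when objective differences underflow.
Numerical choices:

* traits are standardized with prior-weighted z-scores before solving;
  multipliers are back-transformed to raw-trait units (predictions are
  exactly invariant to affine trait rescaling, multipliers scale as 1/a);
* convergence: max constraint residual ≤ `tol` (default 1e-8, standardized
  units), iteration cap 200;
* degenerate traits (zero variance over the support) are dropped with a
  warning and reported with λ = 0 — their multiplier is not identifiable;
* targets strictly outside the trait hull over the support raise an
  explicit infeasibility error *before* iterating; targets within 1e-9
  (relative) of the hull boundary are flagged and the multiplier magnitude
  is capped at 1e3, with `converged=False` if residuals stay above
  tolerance (multipliers diverge at the boundary).

The selection-gradient identity `∂p_i/∂t_ij = λ_j p_i(1−p_i)` (at fixed
multipliers) is exposed directly and verified against finite differences.

## Goodness of fit and the information decomposition

`R²_KL = 1 − D_KL(o‖p)/D_KL(o‖u)` with the `0·ln(0/x) = 0` convention.
The reference `u` is the uniform distribution on the analysis support for
*all four* models, so the four R² values share one denominator and the
partition below is additive by construction.  A plot whose observed
distribution is exactly uniform has an undefined R² and is flagged (NaN);
single-genus plots are flagged degenerate with all R² = 1.

Per plot, the four-step sequence fits: (1) uniform prior + permuted
constraints, averaged over `n_perm` permutations (**bias**); (2) uniform
prior + observed constraints (**trait model**); (3) metacommunity prior +
permuted constraints (**metacommunity model**); (4) metacommunity prior +
observed constraints (**hybrid model**).  Each permutation shuffles whole
trait vectors among genera **and recomputes the CWM targets from the
shuffled assignment** — the genus–trait combinations are randomized while
the community stays fixed.  This makes the permuted and observed
constraint sets exchangeable under neutral assembly, so the bias arm
measures exactly the self-information that any CWM constraint set extracts
from the plot's own composition.  (Holding the targets fixed instead makes
the permuted model systematically *worse* than the uniform baseline and
leaves the trait model's self-information uncorrected, so a neutral
community would appear trait-filtered.)  Permutations whose shuffled hull
cannot contain the targets — only possible when the prior support is a
strict subset of the genera — are dropped with a log message.  The same
permutation draws are reused in the uniform-prior and metacommunity-prior
arms to reduce Monte-Carlo noise in their difference.

The partition (raw values, possibly negative; truncation is presentation
only):

    bias        = R²(1)
    pure trait  = R²(4) − R²(3)
    pure meta   = R²(4) − R²(2)
    joint       = R²(2) + R²(3) − R²(4) − bias
    unexplained = 1 − R²(4)

which sums to one as an algebraic identity.

The metacommunity prior is built from summed counts over a scope (all
plots, the focal plot's forest type, or a distance radius), with the focal
plot included by default (`exclude_focal` available).  Genera observed in
the focal plot but absent from the pool receive a pseudocount ε (default
1e-6 of prior mass) so divergences stay finite.  Genera that carry counts
but no trait data at all stay in priors and observed abundances and enter
constraint matrices at the column mean — a selection-neutral value that
leaves their prediction governed by the prior.

Rarefaction (default 28 plots per group, 25 bootstrap repetitions, sampling
without replacement) removes group-size artefacts from forest-type
comparisons.

## Reading selection off the multipliers

Multipliers are in inverse raw-trait units and are comparable only within
a trait, so each trait is analysed separately: a one-way ANOVA of λ across
forest types (implemented from the textbook sums of squares; infinite F
with zero within-group variance is flagged explicitly), with raw and
Holm-adjusted p-values across the J traits, plus Pearson/Spearman
associations between λ and CWM per trait.

Two multiplier sources answer two different questions.  The uniform-prior
trait model's λ carries the *absolute* direction of selection — it is the
default for sign summaries.  The hybrid model's λ measures selection
*relative to the regional average* already embedded in the metacommunity
prior: under region-wide directional selection the prior absorbs the
shared component and the hybrid multipliers hover near zero, which makes
them the natural statistic for local-departure tests but unstable for
absolute sign.  Both are exposed (`--lambda-source`).

## Spatial scaling of the metacommunity effect

Pools grow as cumulative discs of radius 50, 100, … km (annulus mode
behind a flag), with great-circle (haversine) distances on a sphere of
radius 6371.0088 km.  Permutation counts drop to 2 per radius — the sweep
multiplies the full decomposition by the number of radii — and permutation
seeds are held fixed per plot across radii so profiles reflect the
changing pool, not re-randomization.  Unchanged pools reuse the previous
fit.  The per-radius mean pure-metacommunity profile is smoothed by a
hand-rolled loess (locally weighted quadratic, tricube weights over
`ceil(span·n)` nearest neighbours; the window must hold at least
degree + 2 points) and summarized by nonlinear least squares on
`y(t) = y_f + (y_0 − y_f)·exp(−exp(log α)t)` with self-start values
(asymptote just beyond the data extreme on the far side, intercept at the
smallest radius, rate from a log-linear regression of the offset).
Constant profiles are returned flagged: the rate is not identifiable.

## The synthetic-data generator

The generator emulates the *structure* of a large tropical-forest
inventory — not any real data values: a skewed regional abundance
distribution (lognormal rank abundances, sdlog 1.5, a typical skew for
tropical tree communities; log-series optional), genus-level trait vectors
(equicorrelated normals plus Bernoulli binaries on the {1, 2} coding,
prevalence 0.3), and K plots placed uniformly on a square region with a
smooth environment field thresholded into forest types.

Default study conditions: S = 100 genera, K = 50 plots, J = 500 stems per
plot, 3 continuous + 2 binary traits, a 500 km window, environment
correlation length 150 km.  Local assembly draws J stems multinomially
with weights

    w_ik ∝ q_eff_ik · exp(Σ_j β_j z_ij e_jk)

where `z` are standardized traits and `e_jk = 1 + 0.5·GP(x_k)` is the
environment loading: the unit mean makes β a region-wide selection
direction, the 0.5 spatial amplitude modulates its local strength and sign.
The amplitude is deliberately below the mean so that a scenario declared
as directional selection realizes that direction in essentially every
simulated window (with unit amplitude the window-mean environment flips
sign in ~2% of realizations, silently contradicting the ground truth
label); local reversals still occur, which is what the forest-type ANOVA
detects.

Dispersal limitation has two components.  First, the effective local pool
mixes the global metacommunity with the neighbourhood,
`q_eff = m·q* + (1−m)·local`, where the neighbourhood is a Gaussian-kernel
(250 km) average of realized plot compositions, iterated over five mixing
sweeps in randomized order.  Second, `local` also blends (50/50) a
**landscape drift field**: `q_land(x) ∝ q*·exp(σ(1−m)·G(x))` with `G` a
per-genus spatial Gaussian process (σ = 1, correlation length 1000 km,
i.e. longer than the window).  The drift field represents the deep-time
divergence of the surrounding forest matrix from the global pool — a
finite set of sample plots resampling each other cannot generate it: with
K plots of J stems the plot-to-plot mixture's stationary drift is of order
1/(K·J) in divergence terms, essentially zero.  The long correlation
length makes the drift largely shared across the window (so the pooled
empirical prior captures it, which is what gives the prior its extra
explanatory power under limitation) while retaining enough locality for a
monotone radius decay.  `m = 1` with β = 0 reduces exactly to i.i.d.
multinomial sampling from q*.

All randomness flows from one root seed through named independent streams
(metacommunity, traits, layout, environment, assembly); datasets are
bit-reproducible.

What passing tests on these scenarios do and do not show: the generator
produces clean multinomial sampling, exchangeable trait assignments under
neutrality, and exactly the mixture/tilt forms above.  Real inventories
add taxonomic noise, unequal plot sizes and effort, trait measurement
error and phylogenetic structure, none of which are emulated; recovery
results here validate the *inference machinery*, not the field
applicability of any specific number.

## Trait preparation and imputation

Species-to-genus aggregation: continuous traits average over species with
observed values; a binary trait is positive only when strictly more than
half of the observed species are positive.  Order-of-magnitude traits
(e.g. seed mass) should be declared log-scale at table preparation; no
transform is hard-coded.

Missing genus-level values are filled by chained-equation predictive mean
matching: traits visited in ascending missingness, each regressed (OLS) on
all other traits' current values, each missing cell filled with the
observed value of one of the 5 donors (classic PMM choice) whose
predictions are closest, chosen uniformly at random; 50 sweeps by default.
Singular regressions fall back to mean prediction with a warning.  Binary
traits are imputed on their numeric coding and rounded to the nearer code
after the final sweep.  The delta adjustment subtracts a fixed offset from
imputed continuous cells *after* convergence (so a delta run differs from
the baseline by exactly −delta under the same seed), supporting
sensitivity analysis against not-missing-at-random mechanisms; the
sensitivity helper reruns the imputation across a delta grid and reports
observed-vs-imputed distribution summaries and the slope of imputed values
on their model predictions.  One completed table per seed feeds the
pipeline; replicate seeds quantify imputation noise.

## Known limitations

* **Small-sample bias of multiplier estimates for asymmetric binary
  traits.**  The fitted λ is a concave function of the sampled
  abundance-weighted trait share when prevalence is below one half
  (logit-like curvature), so its expectation under pure neutrality is
  slightly negative: ≈ −0.004 at J = 500 stems for the hybrid model, and
  of order −0.1 to −0.2 for the uniform-prior model under a strongly
  skewed regional pool (where the effective number of genera in the share
  is small).  Any single study's confidence interval is much wider than
  this, but pooled replicate-level intervals can resolve it; interpret
  near-zero mean multipliers of rare binary traits accordingly, or use a
  symmetric recoding when absolute sign matters.
* The bias arm equals trait-model self-information only in expectation;
  with few permutations its Monte-Carlo error enters the joint/bias terms
  (SD shrinks as 1/√n_perm).
* The decomposition's components are raw differences of R² values and can
  be slightly negative; this is informative (e.g. constraints that
  mislead relative to the prior), not an error.
* Haversine distances assume a sphere; adequate at the 50 km granularity
  of the radius sweep.
* The loess smoother refits at every observed radius (O(n·k) per curve);
  it is meant for profiles of tens of points, not thousands.
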