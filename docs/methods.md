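# Methods

## The model and the testing pipeline

The data are a nonnegative quantification matrix *X* (nT × m): *n*
individuals, *T* time points (incomplete designs allowed), *m*
metabolites, with each individual assigned to one condition.  Rows are
canonicalized time-major (all individuals at the first time point, then
the second, …).  Pathways are possibly-overlapping metabolite sets; only
pathways with at least two quantified metabolites are testable, and
pathways whose usable member count drops below two after zero-variance
column removal are skipped with a logged reason rather than reported as
NA rows.

For each pathway the member submatrix is centered and scaled to unit
variance per column (quantifications span orders of magnitude; an
unscaled PCA would be dominated by the most abundant metabolites), and a
score matrix with *m\** = *F* columns is extracted, *F* being the number
of fixed effects under test (capped by the usable member count and the
rank).  Two factorizations:

* **Global PCA.** Scores are SVD projections; the variance of score
  column *j* equals eigenvalue *j* (ddof = 1 convention), and each
  loading column is sign-fixed so its largest-magnitude entry is
  positive, for platform-independent reproducibility.
* **MFA partial PCA.** The submatrix is split into one block per time
  level; each block is standardized *within the block* (each partial PCA
  is a self-contained PCA) and analyzed separately; block scores are
  multiplied by the block weight and stacked in observation order.  The
  weight is 1/√λ₁ of the block — the standard MFA balancing in which
  each block's first axis is brought to unit scale; a 1/λ₁ option is
  exposed (`mfa_weight="inv_lambda1"`) since the balancing convention
  differs between MFA formulations.  Because per-block PCA signs are
  arbitrary, each partial component is sign-aligned to the corresponding
  global-PCA loading (flip when the dot product is negative); without
  this the stacked column would be meaningless.  Splitting by time
  removes between-time mean differences, so results for the
  block-defining effect are flagged `not_recommended` — this variant is
  for condition testing.

Each score column is fitted with a Gaussian linear mixed model: fixed
categorical effects for time and condition, a single random intercept
per individual, iid residuals.  Fits use **maximum likelihood**, not
REML, because the likelihood-ratio test compares models with different
fixed-effect structures and REML likelihoods are not comparable across
those.  The LRT statistic 2(ℓ_full − ℓ_restricted) is clipped at zero
and referred to χ² with df = (levels − 1) of the dropped factor.  No
Satterthwaite/Kenward–Roger correction is applied; with few individuals
the χ² reference for *between-individual* (condition) effects is known
to be somewhat anticonservative, which is visible in the simulation
results below.

The *m\** component p-values are combined per pathway with the Simes
rule min_j (m·p_(j)/j) — valid under independence/PRDS and robust to
moderate deviations; component p-values that are NA (unconverged fits)
are removed with *m* reduced, and a pathway is NA only if all components
fail.  Pathway p-values are then BH-adjusted separately per effect,
since significant-pathway counts are reported per effect.

### Mixed-model implementation

For a single random intercept the ML problem profiles down to one
dimension: with λ = σ²_u/σ²_ε, the marginal covariance is block diagonal
with blocks I + λJ, whose inverse and log-determinant are closed-form,
so GLS coefficients and the residual variance are exact functions of λ.
The scalar profile likelihood is maximized over a coarse log-λ grid
(25 points over e^±12, plus the λ = 0 boundary) refined by bounded Brent
search (xatol 1e-10; loglik comparisons at 1e-8).  The optimization is
deterministic, needs no starting values, and handles unbalanced designs
natively.  The test suite cross-checks the optimum against statsmodels
MixedLM (ML) and against the OLS closed form N·ln(RSS₀/RSS₁) at the
λ = 0 boundary.

### ORA comparator

Metabolites are tested individually with the same mixed model; those
with adjusted (BH) p below 0.05 form the significant set — raw p-values
are used instead under null-simulation runs, where no signal exists and
metabolite-level BH would empty the set.  Each pathway is then tested
for over-representation with the one-sided hypergeometric tail
P(X ≥ overlap), the standard over-representation alternative, against a
background that defaults to the quantified metabolites (configurable to
a larger identifiable-metabolite list).  Metabolites with NA p-values
are excluded from both the significant set and the background.

## Simulation framework

* **Condition null:** condition labels are permuted *between
  individuals* (each individual keeps one label; the label multiset is
  preserved).  Per-sample permutation would hand one individual two
  conditions, destroying the design and the within-individual
  correlation the null is meant to preserve.  Values are untouched.
* **Time null:** every later-time row is replaced by that individual's
  first-time row, then iid Gaussian noise is added to all rows with
  variance σ²_b = noise_factor × (max − min) of the pre-noise matrix
  (noise_factor 0.05).  The variance-equals-scaled-range convention is
  taken literally; noised values are floored at 0 to keep
  quantifications nonnegative.
* **Condition injection:** X̃_ij = X_ij·γ_d(i) for target metabolites
  (defaults γ = 1 for controls; scenario ladder 10, 3, 2 for the
  treated condition).
* **Time injection:** targets are rebuilt as S_ij·γ_t(i) + b with S the
  first-time block repeated and σ²_b = noise_factor × range(S·γ)
  (scenario ladders (1,5,10), (1,2,3), (1,1.5,2), (1,1.2,1.5)).
  Non-target metabolites are rebuilt as S + same-law noise so that *only*
  target pathways carry time signal, mirroring the time-null
  construction; a strict mode (`nontargets="keep"`) leaves them
  untouched instead.
* **Combined effects** compose time injection first, then condition.
* **H1 designs** select k = 3 pathways uniformly without replacement;
  **VSize designs** inject only p̃ members of the largest pathway plus
  k − 1 full pathways.  Replicate r of any experiment uses seed
  base_seed + r.

Ground truth is three-way: selected pathways are *differential*,
unselected pathways sharing a target metabolite are *overlapping* (no
clean label — counted separately as positive/negative calls), the rest
are *non-differential*.  PPV and sensitivity are computed on totals
summed over replicates, and PPV is NA (not 0) when nothing is called.
Type-I experiments threshold **raw** pathway p-values (BH under a global
null rejects nothing); power experiments threshold **adjusted** ones.

## Synthetic base generator

The generator emulates the structure of a small longitudinal NMR feces
study: 16 individuals in 2 conditions, 3 time points, 120 metabolites,
40 overlapping pathways with sizes 2–32 (one pinned at 32 for
variable-size experiments), mean size ≈ 6 and mean membership ≈ 4 over
the covered metabolites.  Those two targets force part of the metabolite
universe to lie outside all pathways (240 memberships over ~60 covered
metabolites), as in real KEGG annotation.  Log-quantifications are
μ_j + u_i + c_{i,home(j),t} + e_ijt with u_i ~ N(0, 0.1²) an individual
offset shared across metabolites, c a per-(individual, time) fluctuation
shared within a metabolite's *home* pathway (first containing pathway in
id order; metabolites outside pathways get a private term of equal
variance), and e ~ N(0, 0.25²).  The shared-fluctuation variance is set
so the within-home-pathway log-scale correlation equals `pathway_corr`
(default 0.3).  Exponentiation gives positive values, and multiplicative
injected effects become additive on the log scale — matching the
working assumptions of the tests.

What the generator does **not** emulate: quantification error from
spectral deconvolution (real NMR quantifications are much noisier),
heavy-tailed abundance distributions, metabolite-specific variances, or
batch effects.  Consequently injected effects are easier to detect than
in real data: at the default settings the sensitivity of the pathway
tests saturates near 1.0 across the whole scenario ladder, so the power
experiments here verify *orderings and calibration*, not absolute power
levels.  Null-transform results are the informative ones: with 16
individuals and a strong shared individual effect, the condition test's
raw positive rate runs a few points above the nominal 5% (the
between-individual χ² asymptotics), with large replicate-to-replicate
variance because one unlucky permutation shifts many correlated pathway
scores at once — hence type-I conclusions are stated with Monte-Carlo
standard errors over replicates, not binomial ones.

## Problem sizes and numerical conventions

Replicated experiments in the test suite and the acceptance script use
20 replicates for null and power runs and 10 for variable-size runs —
enough for stable orderings at the chosen effect sizes while keeping a
full run in minutes on one CPU.  Ties in sorts are broken by stable
(mergesort) ordering; pathway ids break size ties for "largest pathway";
time levels order numerically when parseable, lexically otherwise.
Degenerate inputs (constant responses, single-level factors,
rank-deficient blocks) are either dropped with a warning or produce
flagged/NA results rather than exceptions, except where the input
violates a structural invariant, which raises a validation error naming
the offending cells.

## Known limitations

* One random intercept only: no random slopes, AR(1) within-individual
  correlation, or heteroscedastic residuals.
* χ²-based LRT p-values are asymptotic; with very few individuals the
  condition test is mildly anticonservative (see above).
* The Simes step assumes PRDS-type dependence among component p-values,
  which cannot be verified for principal-component scores; it is used
  for its robustness, as is standard for this aggregation.
* Pathway membership must be supplied by the user (GMT or long TSV); no
  online pathway-database queries.
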