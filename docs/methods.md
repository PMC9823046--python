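# Methods

## Model

Two phenotypes, Ph1 and Ph2, are measured on both members of monozygotic
(MZ) and dizygotic (DZ) twin pairs, together with one polygenic score for
each phenotype (PS1, PS2).  Per twin,

    Ph1 = a1*A1 + c1*C1 + e1*E1 + g2*Ph2 + b1*PS1 (+ b4*PS2)
    Ph2 = a2*A2 + c2*C2 + e2*E2 + g1*Ph1 + b3*PS2 (+ b2*PS1)

A, C and E are unit-variance additive-genetic, shared-environment and
unique-environment factors; cross-trait factor correlations ra, rc, re and
the instrument correlation rf (linkage disequilibrium / genetic overlap
between scores) carry the confounding.  g1 and g2 are the reciprocal causal
paths; b2 and b4 are the direct horizontal-pleiotropy paths, fixed at zero
in the canonical identified model.  The full parameter vector is
θ = (ra, rc, re, rf, a1, c1, e1, a2, c2, e2, g1, g2, b1, b3, b2, b4, σx, σy),
where σx, σy are the instrument standard deviations (1 throughout the power
studies; the designs never vary them).

With B = [[0, g2], [g1, 0]] the reciprocal loop has the reduced form
(I − B)^(−1) = [[1, g2], [g1, 1]] / (1 − g1·g2), defined whenever
g1·g2 ≠ 1; the library enforces |g1·g2| < 1.

**Pair-level covariance.**  The observed 8-vector is ordered
(Ph1_t1, Ph2_t1, PS1_t1, PS2_t1, Ph1_t2, Ph2_t2, PS1_t2, PS2_t2); means are
structurally zero.  Cross-twin covariance follows the biometrical rules:
A-factors (and polygenic scores, which are additive aggregates of genotype)
covary across co-twins with coefficient 1 (MZ) or 0.5 (DZ); C-factors with
1; E-factors with 0.  Cross-twin cross-trait terms carry the same
coefficient times the relevant correlation (for the scores: rf·σx·σy for
MZ, 0.5·rf·σx·σy for DZ — the additive-genetic expectation).  Polygenic
scores and latent A factors are uncorrelated: ra and rf are distinct
parameters, linkable through the optional constraint ra = m·rf.

Direction conventions adopted (the model is symmetric, so any consistent
convention works): b2 is PS1 → Ph2 and b4 is PS2 → Ph1.

A consequence worth stating explicitly: MZ co-twins have *identical*
polygenic scores, so the 8×8 MZ implied covariance is structurally singular
(rank 6).  The likelihood for the MZ group is therefore formed on its six
distinct variables — the four phenotypes plus one pair-level copy of each
score, taken as the average of the two (numerically identical) columns.
The exact-simulation noncentrality parameters computed this way reproduce
the published exemplary values to their printed precision, which supports
this reading of how the original multi-group model was set up.

## Maximum-likelihood fitting

Fitting consumes per-zygosity sample covariances only (complete-data
multivariate-normal likelihood with known zero means depends on the data
only through them) and minimises the multigroup discrepancy

    F(θ) = Σ_g n_g [ ln|Σ_g(θ)| + tr(S_g Σ_g(θ)^(−1)) − ln|S_g| − p_g ],

the excess of −2 ln L over the saturated model (p_g = 6 for MZ, 8 for DZ).

Numerics:

* Optimizer: L-BFGS-B with native box bounds — correlations in
  [−0.995, 0.995], loadings a, c, e in [0, 5] (nonnegativity removes the
  sign indeterminacy of variance-component loadings at no cost in fit),
  causal paths in [−0.99, 0.99] (so |g1·g2| < 1 automatically), σ in
  [10⁻⁶, 10].  Objective tolerance 10⁻¹³ by default (gradient tolerance
  100× that, floored at 10⁻¹¹); the factorial power engine relaxes this to
  10⁻⁹, far below the ~10⁻³ at which noncentrality parameters are read.
* Gradient: the exact trace identity
  dF = Σ_g n_g tr[(Σ⁻¹ − Σ⁻¹ S Σ⁻¹) dΣ], with dΣ by central differences
  (step 10⁻⁶) on the covariance builder.
* Infeasible trial points (non-positive-definite Σ) return a large finite
  penalty (10¹²) rather than infinity, which the line search handles
  gracefully.
* Multi-start: after the first run, jittered restarts (N(0, 0.05+0.05·k)
  on the free vector, clipped to bounds) continue until the best
  discrepancy is reproduced twice within 10⁻⁶ or the restart budget (6) is
  exhausted; a non-reproduced optimum is flagged `converged=False`, never
  silent.
* Degrees of freedom of a nested comparison are counted as the difference
  in free-parameter counts; power is the upper-tail mass of the noncentral
  χ²(df, NCP) beyond the central χ² critical value (power = α exactly at
  NCP = 0).

## Exact data simulation

The model-implied population moments are handed to the fitter as the sample
moments ("exact data simulation").  The full-model fit then returns the
generating parameters exactly and a constrained fit's discrepancy equals
the exact likelihood-ratio noncentrality at the chosen group sizes — the
power calculation needs no raw data and no replication.  This is
mathematically identical to simulating data whose sample moments equal the
population ones, but cheaper.  The stochastic mode exists for bias studies
and end-user realism: pairs are drawn from the zygosity-specific
multivariate normal via an eigendecomposition square root (the MZ
covariance is singular, so a Cholesky factor does not exist), which makes
MZ co-twin scores literally identical and runs reproducibly under a single
seed.

## Local identification

A free/fixed pattern is locally identified at a point when the Jacobian of
the stacked unique implied-covariance elements (36 MZ + 36 DZ) with respect
to the free parameters has full column rank.  The Jacobian uses central
differences (step 10⁻⁶); rank is read from singular values with relative
tolerance 10⁻⁸ of the largest.  Verdicts are evaluated at 5 generic random
points (correlations from (−0.6, 0.6), paths from (0.1, 0.7), σ from
(0.8, 1.25), fixed recorded seed); a pattern whose rank varies across
points is flagged unstable rather than guessed at.  Means carry no
information (structurally zero) and are excluded.  The documented verdicts:
b2 = b4 = 0 identified (rank 16/16); all 18 parameters free not identified;
re = 0 frees exactly one of b2/b4; ra = m·rf frees one but not both.

## Power engine

Three factorial designs enumerate parameter grids (levels specified on the
variance scale enter as signed square roots, the θ scale):

* Design 1 (ACE): 12 two-level factors, 2¹² = 4096 cells.
* Design 2 (AE, rc = c1 = c2 = 0): seven 3-level and two 2-level factors,
  3⁷·2² = 8748 cells.
* Design 3 (AE, signed paths): four 4-level factors (b1, b3, g1, g2
  including negative levels), 4⁴ = 256 cells.

Per cell: exact moments at 1000 + 1000 pairs → constrained fits (g1 = 0;
g2 = 0; both) → NCP and power (1-df, 1-df, 2-df tests at α = 0.05).  The
full-model discrepancy is identically zero on exact data, so a 1-df NCP
needs only the constrained fit.  Runs are deterministic given the design;
per-cell fit failures are recorded in the cell, not raised.

**NCP regression.**  The standardized NCP is regressed on the standardized
path-scale levels of the varying parameters (ordinary least squares);
squared standardized coefficients are the per-factor variance shares, which
on an orthogonal factorial equal the ANOVA sum-of-squares shares (tested
against that independent decomposition at 10⁻¹⁰).  The derived e1, e2 are
excluded as regressors — they are functions of a and c by construction.
Order 2 adds squared terms and reports the R² gain.  The full 4096- and
8748-cell regressions are a nightly-scale job; the test suite and the
acceptance script run a deterministic 128-cell subsample whose
decomposition shows the same structure: the instrument and causal paths
dominate, the instrument correlation rf is a distant third, and background
correlations and variance components are negligible.

**Required-N curves.**  For a target instrument strength R²(Ph1 ~ PS1), b1
is solved by root-finding on the implied R²; one exact NCP evaluation at a
reference size then gives the required total pair count in closed form
(NCP is exactly proportional to sample size), followed by an integer
adjustment so that power(N) ≥ target > power(N − 2) under an even MZ/DZ
split.  A grid point with zero per-pair NCP is flagged instead of looped
on.

## Assumption-violation studies

**Direct pleiotropy.**  Data generated with b2, b4 > 0 (default grid:
b2², b4² ∈ {0.005, 0.01, 0.02}, our choice) but fitted with b2 = b4 = 0.
Exact moments isolate the systematic distortion: the causal estimates g1,
g2 absorb the unmodelled instrument–outcome covariance (upward bias), and
ra, rc, re compensate downward.  With g1 = g2 = 0 truth the same mechanism
inflates the false-positive rate of the causal tests above α.

**Unmodelled measurement error.**  Reliability is defined as the share of
observed-phenotype variance that is true score.  The injector adds
independent normal noise calibrated to the observed column's variance,
x → x + sqrt(Var(x)·(1 − rel)/rel)·ε, leaving the true score on its
original scale.  Defined this way, the error is absorbed *exactly* by the
unique-environment block (e1, e2, re) at the population level — the E
factors are the only source of phenotype-specific, cross-twin-uncorrelated
variance, and the 2×2 symmetric E covariance has exactly the three degrees
of freedom needed — so a, c, g and b estimates are untouched while power
falls.  (An injector that also rescales the true score by sqrt(rel) would
attenuate b1, b3 by that factor and conflate scale change with
unreliability; we deliberately avoid it.)  The stochastic study
(default 100 replicates at 1000 + 1000 pairs, reliability 0.8) adds
Monte-Carlo confirmation and empirical power; the population-level version
(`attenuated_exact_moments`) gives the same conclusions without noise.

## What the synthetic data does and does not emulate

The generator draws exactly multivariate-normal phenotypes and scores with
zero means and the model's covariance — the idealised regime in which the
NCP calculus is exact.  Real data bring non-normality, ascertainment,
missingness, mean and covariate structure, unequal group sizes and
imperfectly measured polygenic scores; none of these are emulated, so
passing tests certify the statistical machinery under the model, not
robustness to those complications.  Scores are simulated at the pair level
(shared for MZ), not built from SNP genotypes.

## Known limitations

* Covariance-structure-only ML: no missing-data (FIML) likelihood, no
  means/covariates, no ordinal phenotypes.
* No dominance (D) components, sex-limitation/five-group designs, or
  assortative mating.
* Identification checks are local (Jacobian rank), not global proofs.
* Standard errors are not reported; inference is via likelihood-ratio
  comparisons.
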