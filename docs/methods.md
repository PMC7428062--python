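# Methods

## Model and assumptions

Every analysis is a Gaussian linear mixed model over long-format
phenotype records (individual x trait x session). Random terms attach a
latent vector to each individual: a *genetic* term with covariance
`A (x) Sigma_G` across individuals, where `A` is the pedigree additive
relationship matrix, and a *permanent-environment / among-individual*
term with covariance `I (x) Sigma_U`. Random regression uses the basis
`phi(s) = (1, s)` with the session covariate rescaled so the final
session sits at zero; intercept-indexed variances therefore describe
end-of-testing performance, and a slope variance lets genetic or
individual merit change across sessions. Residuals are independent with
one free variance per trait.

Assumptions worth keeping in mind:

* Gaussian errors are assumed even for bounded counts (number correct
  of 10, error counts of at most 18, peck counts after a square-root
  transform). Residual diagnostics, not the fitting machinery, must
  justify this for a given dataset.
* Founders and unknown parents are draws from an unrelated, non-inbred
  base population; an unknown parent contributes nothing to the
  relatedness recursion.
* Traits are never co-observed at the same observation in this design,
  so no cross-trait residual covariance exists in the structure; for
  traits measured once per individual the residual is fixed to zero
  whenever an individual-level intercept would otherwise be confounded
  with it.

## REML engine

The restricted log-likelihood
`l = -1/2 [log|V| + log|X'V^-1X| + y'Py]` (additive constant dropped,
fixed across compared models) is evaluated through one of three routes,
chosen automatically:

1. **No genetic term** — individuals are independent, V is block
   diagonal; each distinct per-individual record template is processed
   with one Cholesky factor and one triangular solve against the stacked
   design. Handles arbitrarily unbalanced data.
2. **Genetic term, balanced template** — when every phenotyped
   individual carries the same trait/session layout,
   `V_i = C0 + d_i Cg` after rotating records by the eigenvectors of the
   relationship matrix restricted to phenotyped individuals. A single
   generalized eigendecomposition `Cg v = lambda C0 v` per likelihood
   evaluation then diagonalises every individual's covariance at once.
3. **Genetic term, unbalanced** — the dense marginal covariance is
   assembled and factorised directly; intended for modest record counts
   (missing-session analyses at a few hundred individuals).

Covariance matrices are parameterised by Cholesky factors (blockwise for
structures with cross-trait covariances fixed at zero), so positive
semi-definiteness holds by construction; residual variances use a
square-root parameterisation. Optimisation is L-BFGS-B with
finite-difference gradients, followed by a Nelder–Mead polish when the
quasi-Newton run ends without meeting its criteria; non-convergence is
reported on the fit object, never silently discarded, since boundary
solutions routinely stop gradient-based criteria from triggering.

Starting values split each trait's residual phenotypic variance (after
an OLS fixed-effect fit) equally among the free variance terms, with
slope variances at 10% of the intercept share and covariances at zero.

Standard errors come from the observed information — a central
finite-difference Hessian in the *natural* covariance parameters — and
delta-method propagation for ratios (h2, R) and correlations. A
parameter at a constraint (variance within `1e-6 x` the trait's
phenotypic variance of zero, |correlation| at or above 0.9999) is
flagged as a boundary solution and reported without a standard error.

## Model ladder and tests

For repeated traits, Models 0–4 add, in order: individual intercept,
individual slope (2x2 unstructured), genetic intercept, genetic slope
(2x2 unstructured), all with identical fixed effects. Permanent-
environment intercept and slope are retained in Models 3–4. A
single-measure trait supports only Model 0 and the plain animal model
(genetic intercept, free residual, no permanent-environment term).

Null conventions: a single variance tested at its zero boundary uses the
50:50 `chi2_0 : chi2_1` mixture (p = 1 at a zero statistic, by the >=
convention); a block of k parameters (variance + covariances) uses plain
`chi2_k`. AIC counts variance parameters only — fixed effects are
identical across the fits being compared, as REML requires. Negative
likelihood-ratio statistics beyond numerical tolerance trigger a warning
and are clipped at zero.

## Multivariate structure

The among-individual (ID) model places an intercept on all four traits
and a slope on the two traits with many sessions (visual discrimination,
spatial ability), with a *full* unstructured 6x6 among-individual
covariance. Spatial discrimination enters as the per-individual mean of
its (up to three) sessions. The global structure test compares this
against a per-trait-block null; the degrees of freedom equal the number
of freed cross-trait covariances — 13 for the full model (15 off-
diagonal pairs minus the 2 within-trait intercept–slope pairs), which is
also why the all-covariances alternative, rather than an
intercepts-only-across-traits variant, is the supported specification.

G is estimated piecewise — a trivariate animal model for inhibitory
control, visual discrimination and spatial ability (8 freed genetic
covariances under the global test, by the same counting) plus three
bivariate models pairing spatial discrimination with each other trait —
and the six pairwise genetic correlations are patched into a 4x4 matrix.
The patchwork need not be positive semi-definite; its PSD status is
reported, and an eigenvalue-clipping repair (`nearest_psd`) exists but
only runs when explicitly invoked. Estimates at |r| >= 0.9999 are kept
at their clamped value with a boundary flag and no standard error.

PCA sign convention: each eigenvector is flipped so the count of
positive loadings is maximal, ties broken by making the first trait's
loading positive.

Score orientation: all responses are arranged so positive values mean
good performance before correlation analyses. Error counts are reversed
about the task maximum (18 per spatial-ability session); peck counts are
square-root transformed and reversed about the observed maximum on the
transformed scale, since the task itself has no natural upper bound —
this reversal constant is a dataset property, and shifts of origin never
change variances or correlations (they do change CV_A, which is why the
mean used for CV_A is recorded together with its scale).

## Synthetic data

The generator emulates the study design the estimators assume: annual
cohorts (~200 individuals each, four cohorts), 20% survival of a cohort
to breeding, harems of one male with two to four females, offspring
assigned a harem and a dam within it, and parent identities masked
independently (dams kept with probability 0.5, sires 0.61). Breeding
values flow down the *masked* pedigree — an unknown parent is a phantom
base-population founder — so the relationship matrix the estimator
conditions on is exactly the generative covariance, and recovery tests
probe estimation error rather than pedigree error. Mendelian sampling
deviations carry covariance `1/2 (1 - (F_s + F_d)/2) Sigma` with
parental inbreeding from the same pedigree.

Default trait parameters (analysis scale) give heritabilities of roughly
0.1–0.25 and repeatabilities of roughly 0.17–0.33 with session counts
and count ranges matching the four tasks (1 session for inhibitory
control; 5 x 10 trials; 3 x 10; 8 sessions with at most 18 errors).
Cross-trait structure is specified at the intercept level only: a
genetic intercept correlation of 0.6 between every trait pair (a
moderate shared factor — the hypothesis the G-level PCA probes) and an
among-individual correlation of 0.1; slope effects are independent
across traits. Test order is a persistent standard-normal individual
covariate; sex and rearing-group effects and a common session slope make
up the fixed part.

What the generator does *not* emulate: discretisation is off by default
(the estimator is Gaussian, and recovery tests evaluate it under its own
assumptions; switching `discretize` on rounds and clips to each task's
legal range for robustness runs), survival is random rather than
selective on the traits, and parentage error beyond masking (wrong
assignments) is absent. Passing recovery tests therefore demonstrates
correctness of the estimation machinery, not robustness to
non-Gaussian measurement or pedigree mis-assignment in real data.

Missingness follows the completion classes seen in practice (complete /
70–99% / 50–70% of sessions, dropped from the end, never below half the
sessions).

## Numerical choices

* Convergence: L-BFGS-B default tolerances with `gtol = 1e-6`; fits
  report `converged=False` rather than raising when criteria are unmet.
* Relationship matrices are built dense (study scale <= ~1,500
  individuals); no A-inverse is ever formed because all likelihood
  routes work with the marginal covariance.
* Eigenvalues of A are clipped at zero (masked pedigrees make A
  numerically PSD but occasionally with -1e-15 noise).
* The LRT statistic is clipped at zero; a deficit beyond 1e-6 warns.
* Boundary detection thresholds: variance `< 1e-6 x` trait phenotypic
  variance; |correlation| `>= 0.9999`.
* Problem sizes in the shipped validation runs are scaled to desk
  hardware: recovery and power use 500 phenotyped individuals per
  replicate (two cohorts of 250) with 12–20 replicates; the end-to-end
  synthetic study uses two cohorts of 150. These sizes were chosen so
  the whole validation suite runs in minutes while keeping Monte-Carlo
  error inside the stated tolerances.

## Known limitations

* No Bayesian/MCMC alternative, no non-Gaussian links, no maternal or
  dominance effects.
* The Hessian-based standard errors are asymptotic and degrade near
  boundaries (where they are suppressed entirely).
* A simultaneous four-trait genetic model is deliberately unsupported;
  the partial plan is the only G path, mirroring what the data structure
  can identify at this scale.
* The generalized-eigen fast path requires a balanced record template;
  heavily unbalanced animal-model fits fall back to dense linear algebra
  and should be kept to a few thousand records.
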