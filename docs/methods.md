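# Methods

This document records the modelling, estimation and design choices behind
`bifax` in enough detail to re-derive every number the package produces.

## 1. Latent structure and item models

Abilities are a triple `theta = (theta_g, theta_mc, theta_cr)` of mutually
orthogonal standard normal variables: a general factor measured by every
item and one specific factor per item format. All simulees are drawn
i.i.d. `N(0, I_3)`.

**Bi-factor MC items** follow the multidimensional 3-parameter normal-ogive
model (M3PNOM):

    P(y = 1 | theta) = g + (1 - g) * Phi(a_g*theta_g + a_mc*theta_mc - d)

with `Phi` the standard normal CDF, `g in [0, 1)` the lower asymptote, `d`
an intercept-style difficulty.

**Bi-factor CR items** follow the multidimensional graded normal-ogive
model (MGRM). With `z = a_g*theta_g + a_cr*theta_cr` and strictly
increasing boundaries `t_c = d + o_c` (`o_1 = 0` by convention, so an item
with C categories stores offsets `o_2 < ... < o_{C-1}`):

    P(y >= c) = Phi(z - t_c),   c = 1..C-1
    P(y = c)  = P(y >= c) - P(y >= c+1)

Category probabilities telescope, so they sum to 1 to machine precision
(the test suite asserts 1e-12 over random items and abilities).

**Unidimensional models** are the logistic 3PL for MC,
`P = g + (1-g)/(1 + exp(-a(theta - b)))`, and the logistic graded response
model for CR with absolute thresholds `b_1 < ... < b_{C-1}`. No `D = 1.7`
scaling constant is applied anywhere in the package: the bi-factor family
is genuinely normal-ogive and the unidimensional family genuinely logistic,
and each is calibrated and scored in its own metric.

Deep normal tails are evaluated with `scipy.special.ndtr`/`log1p` and
probability floors, so extreme abilities (|z| well beyond 38) stay finite.

## 2. Synthetic item pools with a controlled disattenuated correlation

A study condition is defined by the target disattenuated correlation
between the MC and CR subtest true scores. Base item parameters are drawn
once per condition:

* `a_g, a_spec ~ U(0.8, 2.0)` (general and specific loadings)
* MC `d ~ N(0, 1)`; CR `d ~ N(-1.25, 0.6)` (CR items easier at low
  categories, matching typical operational CR difficulty)
* `g ~ U(0.05, 0.35)`; CR boundary gaps `~ U(0.6, 1.05)`

A single non-negative scale `lambda` multiplies **every** specific loading.
The model-implied disattenuated correlation

    rho(lambda) = corr( tau_MC(theta), tau_CR(theta) ),  theta ~ N(0, I_3)

is estimated by Monte Carlo on a fixed ability sample (80,000 triples, so
`rho(lambda)` is smooth) and is monotonically decreasing in `lambda`:
`lambda = 0` collapses both formats onto `theta_g` alone (`rho = 1`), and
larger specific loadings pull the subtests apart. Bisection (with bracket
doubling up to `lambda = 8`) solves `rho(lambda) = target` to within 0.004,
comfortably inside the pool contract of +/- 0.01. Unreachable targets
raise with diagnostics rather than returning a mismatched pool.

Why this construction: it leaves the marginal difficulty/discrimination
profile of the pool untouched across conditions (the same base draws are
reused for every target given the same seed), so conditions differ *only*
in dimensional distinctness.

The implied correlation is the population quantity that the classical
disattenuation formula estimates from data; the package also computes the
observed version `r(X_MC, X_CR) / sqrt(alpha_MC * alpha_CR)` with Cronbach
alpha, and the test suite checks the two agree on large simulated samples.

**Category recoding.** Operational CR items are often rated on more
categories than the analysis scale. `recode_categories` collapses a raw
scale onto `C` categories by equal-count (quantile) collapsing of the
observed marginal: each raw category lands in the bin containing the
midpoint of its cumulative-count interval, followed by repair passes that
make the map non-decreasing, adjacent-step between occupied categories, and
surjective. The map is deterministic with ties to the lower bin.

## 3. Calibration

### Unidimensional: marginal maximum likelihood via EM

The ability distribution is fixed at `N(0, 1)`, discretised on 41 equally
spaced quadrature nodes over [-5, 5] with normalised normal weights. The
E-step computes posterior node weights per person; the M-step maximises
each item's expected complete-data log-likelihood with L-BFGS-B
(parameters bounded: `a in [0.05, 5]`, `b in [-6, 6]`, `g in [0.001, 0.5]`;
GRM thresholds parameterised as `b_1` plus log-gaps so order is maintained
by construction). An item's update is kept only when it improves its
objective, so the marginal log-likelihood trace is monotone — asserted in
the tests. Convergence is a relative log-likelihood change below 1e-5.
Constant response columns are excluded with a warning; `guessing_fixed`
pins the lower asymptote (e.g. 0 for a 2PL). Reported standard errors are
per-item BHHH (outer product of numerical score vectors).

### Bi-factor: Metropolis-within-Gibbs MCMC

Block random-walk Metropolis updates cycle over (i) all person ability
triples, (ii) each MC item's `(a_g, a_mc, d, logit g)`, (iii) each CR
item's `(a_g, a_cr, d, log-gaps)`, vectorised within each block. Priors:
loadings `N(0, 2)`, intercepts `N(0, 4)`, `g ~ Beta(5, 15)` (proposed on
the logit scale with the Jacobian included), log boundary gaps
`N(-0.3, 1)`. The Beta prior keeps the normal-ogive guessing parameter
away from its well-known instability; the log-gap parameterisation keeps
boundaries ordered by construction.

Proposal scales adapt during burn-in only (every 100 cycles, targeting
~0.3 acceptance), so the retained chain is a fixed-kernel Markov chain.
Sign indeterminacy is resolved by flipping any loading block (and the
matching ability column) whose mean loading is negative. Point estimates
are posterior means of the retained draws; reported uncertainty is the
posterior standard deviation. Retained draws = `floor((cycles - burnin) /
thin)`; the fidelity protocol 60,000 / 10,000 / 50 retains exactly 1,000.

Desk-scale default is 6,000 cycles / 1,000 burn-in / thin 5 — enough for
the recovery checks in the test suite (general-loading correlation ~0.89
at n = 1,500) while keeping a calibration in the tens of seconds.

## 4. MAP scoring

Ability estimates are posterior modes under the standard normal prior.

* **Per pattern:** L-BFGS-B with analytic gradients of the log posterior,
  box [-6, 6] per coordinate, plus a fixed set of restart points; failure
  to meet the gradient tolerance raises a `ScoringError` carrying the best
  point found.
* **Batch:** expected-information Fisher scoring over all persons at once
  (Newton steps with step-halving), falling back to the per-pattern
  optimiser for any person whose gradient sup-norm exceeds tolerance. The
  two paths agree to ~1e-6 and the batch path is what the study loop uses.

The bi-factor posterior is only three-dimensional, so the mode can be
verified against an exhaustive grid search. The posterior separates as
`A(theta_g, theta_mc) + B(theta_g, theta_cr) + prior(theta_g)`, making the
exact grid argmax computable from two 2-D grids. One subtlety: with grid
step `h`, the lattice argmax is the lattice point nearest the mode in the
Hessian metric, which along a strongly correlated ridge can deviate from
the continuous mode by up to `(h/2) * sqrt((1+r)/(1-r))` per coordinate
(`r` the local posterior correlation) — more than `h/2`. The test oracle
therefore uses step 0.01 to verify agreement within 0.02 per coordinate.

The unidimensional scorer is the scalar analogue (MAP, not EAP): both
scoring approaches use the same estimator class so the comparison isolates
the latent structure, not the estimator.

## 5. True scores and classification

True scores are model-expected observed scores at an ability point:

    tau_MC(theta) = sum_j P_j(correct | theta)
    tau_CR(theta) = sum_j sum_c c * P_jc(theta)
    tau           = w_mc * tau_MC + w_cr * tau_CR,  (w_mc, w_cr) = (1.125, 2.75)

The weights are the operational composite weights of the mixed-format
examination program studied; they are configuration, not constants.

Simulees are classified into five ordered grades with fixed fractions
(0.216, 0.258, 0.228, 0.188, 0.11) from lowest to highest — so the top
grade holds 11% — by empirical quantiles computed **separately for each
score vector** (truth, bi-factor estimate, unidimensional estimate) and
**within each replication**. Non-integer quota are resolved by
largest-remainder rounding with ties to the lower category, making the
counts deterministic: n = 10,000 yields exactly (2160, 2580, 2280, 1880,
1100). Accuracy is `100 * trace(T) / n` of the 5 x 5 cross-classification
table T (truth in rows, estimate in columns).

## 6. Study design

Each condition runs an eight-step replication loop:

1. sample `n_simulees` ability triples;
2. compute truth composite true scores;
3. simulate responses;
4. MAP-score under the bi-factor parameters;
5. convert to bi-factor composite true-score estimates;
6. MAP-score under the unidimensional parameters;
7. convert to unidimensional true-score estimates;
8. classify all three vectors and cross-tabulate against truth.

Calibration happens **once per condition** on a separate calibration
sample and is shared by all replications. By default the replications use
the *estimated* bi-factor parameters as the generating truth (the accuracy
comparison is then made under a model actually fitted to data, as in an
operational re-analysis); `truth="generator"` substitutes the known
generating pool for clean recovery experiments — including the degenerate
check that with all specific loadings zero the two scoring approaches are
equivalent up to Monte Carlo noise.

Every random stream derives from a single master seed via
`numpy.random.SeedSequence` (all derived seeds < 2^31), so a study is
reproducible bit for bit. Reported summaries are per-condition means with
standard errors `sd / sqrt(R)`; a condition whose calibration fails to
converge is flagged but still run.

**Profiles.** The package defaults form a desk-scale profile (calibration
n = 2,000; 5,000 simulees; 20 replications; 6,000-cycle MCMC) that runs in
minutes. An operational-fidelity profile (calibration n = 20,000; 10,000
simulees; 60,000-cycle MCMC) is available purely through configuration —
nothing in the code is specific to either scale.

## 7. Known limitations

* Complete response matrices only; no missing-data handling.
* The EM standard errors ignore cross-item information (per-item BHHH).
* MCMC convergence monitoring is acceptance-rate and finiteness based; no
  multi-chain R-hat is computed.
* The generator's item-parameter ranges are stylised (uniform loadings,
  normal intercepts); they produce realistic score distributions but are
  not fitted to any particular operational program.
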