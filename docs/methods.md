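# Methods

## Estimands

All estimands are built on nested counterfactuals
Y(a₀, M₁(a₁), M₂(a₂, M₁(a₃))) with (a₀,a₁,a₂,a₃) ∈ {0,1}⁴, for a binary
exposure, two causally ordered continuous mediators (M₁ may affect M₂) and a
continuous outcome. A natural path-specific effect switches one argument
0 → 1; the fixed pattern of the other three is the effect's *type*, its
*level* the number of 1s among them. Four paths × eight types give 32
estimands. Type labels list the fixed arguments in slot order
(a₀,a₁,a₂,a₃) with the varying slot removed; decomposition listings use the
code scheme 1=000, 2=100, 3=010, 4=001, 5=110, 6=101, 7=011, 8=111.

Decompositions are generated, not stored: each of the 4! orderings in which
the four arguments can be switched 0 → 1 produces four contrasts whose
formal sum telescopes from Y(0,0,0,0) to Y(1,1,1,1), i.e. the TCE. An
independent brute-force oracle enumerates all 8⁴ = 4096 ways of choosing one
type per path, represents each candidate as an integer-weighted sum of the
16 counterfactual indices, and confirms that exactly the 24 generated
orderings cancel to the TCE. The same oracle, run on smaller index systems,
verifies the single-mediator case (2 valid sums of 4: pure direct + total
indirect and total direct + pure indirect), the unordered-mediator system
with no M₁ → M₂ path (12 effects, 6 decompositions on {0,1}³), and the two
merged mediator-specific families.

Mediator-specific (MS) families merge the through-both path into one
mediator's effect. MS¹ ("all of the effect through M₂") uses counterfactuals
Y(a₀, M₁(a₁), M₂(a, M₁(a))), so a₂ = a₃ always; MS² ("all of the effect
through M₁") uses Y(a₀, M₁(a), M₂(a₂, M₁(a))), so a₁ = a₃ always. MS labels
list the two fixed bits in slot order with the merged argument removed. Each
family has 12 effects and 6 exact three-way decompositions, and its
contrasts embed into the full 16-cell system, so MS estimates come from the
same simulated table as everything else.

Summary effects average the 8 types of a path with weights proportional to
their appearances among the 24 decompositions — 6/24 for types 000 and 111,
2/24 for the rest — counted from the generated decompositions at run time.
The four summaries decompose the TCE exactly. The accompanying variability
measure is the weighted variance of the 8 type estimates about the summary,
with the same weights; it is zero exactly when interactions are absent, and
we document this weighted-variance form as our reading of the intended
"weighted to sit closer to the 000/111 types" behaviour.

## Identification and the sensitivity parameter

Estimands whose two halves both satisfy a₁ = a₃ never involve the joint law
of (M₁(0), M₁(1)) and are identified under standard no-unmeasured-confounding
and consistency conditions; the package derives this set by the a₁ = a₃
predicate (it comprises NDE-000/010/101/111, NIE₂-000/100/011/111,
MS¹-NDE-00/11, and all twelve MS² effects). All other effects require the
cross-world joint law, on which the data carry no information. We
parameterize it by ρ ∈ [0,1], the proportion of M₁'s residual variance
shared across worlds, via the shared-component construction

    ε(x) = √ρ·U + √(1−ρ)·V_x,   U, V₀, V₁ ~ iid N(0, σ₁²),

which leaves each marginal N(0, σ₁²) for every ρ and makes the cross-world
residual correlation equal ρ, so the shared-variance and correlation
parameterizations coincide by construction. M₂ needs no analogous parameter:
within any single nested counterfactual only one M₂ world appears, so
independent M₂ residual draws across worlds leave all mean contrasts
unchanged.

## Estimation

Parametric g-computation by Monte-Carlo simulation:

1. Fit M₁ | X,C; M₂ | X,M₁,C; Y | X,M₁,M₂,C by OLS **on the original
   sample**. The default outcome model includes all two- and three-way
   exposure–mediator interactions (X·M₁, X·M₂, M₁·M₂, X·M₁·M₂) and the M₂
   model includes X·M₁, so effect types can differ as much as the data
   dictate; residual variances use the n−p denominator.
2. Copy each subject's confounders K times (default K = 200; K = 1000
   further reduces Monte-Carlo error at proportional cost).
3. Per pseudo-subject, draw (M₁(0), M₁(1)) jointly at the current ρ.
4. Per (a₂, a₁-world) pair, draw M₂(a₂, M₁(a₁)) with fresh Gaussian noise.
5. Fill all 16 cells Y(a₀, M₁(a₁), M₂(a₂, M₁(a₃))) with the outcome model's
   conditional mean — by default without a Y residual draw, which is
   identical in expectation for mean contrasts and strictly lower-variance;
   a `y_draw` flag restores the literal draw.
6. Each effect is the mean over pseudo-subjects of its cell contrast.

All 16 cells of a pseudo-subject share one set of mediator draws, so every
decomposition sum, the summary-effect sum, and both MS ordering sums equal
the TCE estimate to floating-point cancellation — an exact identity, not a
statistical one, and the package tests it at ~10⁻¹⁰ relative tolerance.

The standard-normal streams (U, V₀, V₁, the four M₂ streams, the optional Y
stream) are drawn once per run and reused across the ρ grid (common random
numbers): sensitivity curves are smooth in ρ and the ρ-free effects are
invariant up to the (small) Monte-Carlo noise of the residual draws
themselves. Seeds derive from a single master seed via `SeedSequence`
spawning (point estimate, then one child per bootstrap replicate), so runs
are bit-reproducible.

Inference is by nonparametric bootstrap: subjects resampled with
replacement, all three models refitted, the full simulation re-run with
fresh draws per replicate. SE is the SD across replicates; CIs are normal
approximation (estimate ± 1.96·SE) by default, matching SE-centred
reporting, with percentile CIs optional (requiring B ≥ 40). Design matrices
are built once on the full sample and bootstrap refits slice their rows,
which both speeds the loop and keeps the categorical treatment coding
(alphabetical reference level) stable when a resample drops a rare level.

An interaction-free LSEM comparator returns the classical
product-of-coefficients path effects (direct = outcome-model X coefficient;
via-M₁ = (M₁-model X)·(Y-model M₁); via-M₂ = (M₂-model X)·(Y-model M₂);
via-both = the triple product). It refuses specifications containing
interactions, since coefficient products are not valid there; without
interactions it coincides with the natural effects, which the tests check.

## Synthetic data and what it does (not) show

The generator samples from a linear SEM with interactions: one standardized
continuous confounder and one three-level categorical confounder, a
Bernoulli exposure, Gaussian errors on the (log-scale) mediators and the
outcome, and cross-world M₁ residuals coupled at a known `rho_true` by the
same shared-component construction. The default parameter set is an
"izhevsk-like" fixture: exposure prevalence 0.25, log-BMI-like M₁
(level ≈ 3.2, σ₁ = 0.15), log-GGT-like M₂ (σ₂ = 0.5), SBP-like outcome in
mmHg (σ_Y = 16) with weak interactions, chosen so the exposure explains only
a small share of outcome variance — illustrative of a blood-pressure
mediation study's structure, not a reproduction of any dataset. A second
fixture (`product_of_coefficients`) has no interactions and known
closed-form effects (direct 1.0, via-M₁ 0.30, via-M₂ 0.21, via-both 0.14).

`generate_potential_outcomes` produces the full 16-column potential-outcome
table (the outcome error is shared across all 16 indices of a row; it
cancels in every contrast, so the choice is inconsequential and is tested as
such), with the factual rows equal to the potential rows at the factual
indices by construction. `true_effects_oracle` evaluates every estimand as a
mean over that table at large n — the truth standard for all parameter-
recovery tests.

Because the generator's structural equations match the estimator's model
family, passing recovery tests demonstrates correctness of the estimator
under correct specification; they say nothing about robustness to model
misspecification, missing data, exposure misclassification, or intermediate
(exposure-induced) confounding, none of which the package addresses.

## Numerical choices and problem sizes

- OLS via statsmodels on design matrices from an in-package term evaluator
  (numeric columns, categorical indicators with alphabetical reference,
  `a:b` products, `a^k` powers); rank-deficient designs raise an error
  naming the collinear columns (pivoted QR), as do n ≤ p, non-binary or
  constant exposures, and zero-variance mediators. Complete-case analysis:
  rows with missing analysis values are dropped with a logged count.
- Test-suite problem sizes are chosen for desk-scale runs: exact identities
  at n = 500, K = 50; ρ-machinery at 10⁵ residual draws and n = 800, K = 50
  tables; recovery at n = 2000, K = 200 with B = 60 bootstrap replicates
  against an oracle at n = 10⁶; CI coverage over 200 replicates at n = 500,
  K = 10, B = 100 (TCE-only cells via the table's cell-subset option).
  Tolerances are 3 Monte-Carlo/bootstrap SEs for stochastic checks and
  ~10⁻¹⁰ relative for the exact identities.
- The number of pseudo-subjects K trades Monte-Carlo error against time;
  estimates are unbiased for any K, and the default 200 keeps per-run
  Monte-Carlo error well below sampling error at n in the low thousands.

## Limitations

No intermediate (exposure-induced) confounders; no more than two mediators;
continuous mediators and outcome only (no GLM links); no missing-data
modelling beyond complete-case; no semiparametric or multiply robust
estimators; the sensitivity analysis addresses only the cross-world mediator
law, not unmeasured confounding.
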