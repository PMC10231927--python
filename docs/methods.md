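# Methods

This note documents the models implemented in `wormchoice`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Price, consumption, and the budget identity

The package treats a pharyngeal pump as the unit of expenditure. With
bacterial density `d` in OD units and pump volume fixed at one lumen volume
(not configurable), the price of a food is `P = 1/d` pumps per cell-scale
unit: doubling density halves the energetic cost of eating a unit of food.
Consumption is expressed proportionally, `q_X = (n_X/N)·d_X`, so that each
worm's choice satisfies `P_H q_H + P_M q_M = 1` identically and the pump
share `f_H = n_H/N` equals the expenditure share on H. The identity is
enforced at relative tolerance 1e-9 — it is pure arithmetic, and a tight
tolerance catches unit or mapping bugs rather than numerical noise.
Densities are kept in OD units throughout; no CFU conversion is applied.
Optional fields (dwell times, pump frequencies) are never imputed; an
operation that needs an absent field raises a missing-field error.

## GARP engine

Given K budgets with prices `p_i` and chosen bundles `x_i`:

* `R0[i,j]` (weak direct preference) iff `p_i·x_j ≤ p_i·x_i (1 + tol)`;
* `P0[i,j]` (strict direct preference) iff `p_i·x_j < p_i·x_i (1 − tol)`;
* `R` is the reflexive–transitive closure of `R0`, computed by boolean
  matrix squaring (K is at most a few dozen; exactness beats sparse-graph
  machinery at this size);
* a violation is an ordered pair with `R[i,j]` and `P0[j,i]`, classified
  direct when `R0[i,j]` holds, else indirect. Ordered pairs are also
  aggregated to unordered cycles for human-readable output; the ordered
  count is the reported one.

The default expenditure tolerance is relative 1e-8. Mean choices are ratios
of pump counts, so exact ties can occur and must classify as weak, not
strict; the tolerance absorbs float noise in the cost matrix without
swallowing genuine strict relations. All-zero bundles are accepted; they
are affordable everywhere and never strictly preferred to anything.

CCEI (Afriat's critical cost efficiency index) is the largest `e ∈ [0,1]`
for which relations built from deflated expenditures `e·p_i·x_i ≥ p_i·x_j`
are violation-free. It is found by bisection to 1e-6 (conventional CCEI
reporting precision); inside the bisection the comparisons are exact
(tolerance zero), per the index's definition. A violation-free dataset has
CCEI 1 by construction.

Two theorem-backed properties are used as randomized oracles: for two goods,
indirect violations cannot occur without direct ones (Rose's theorem), and
deterministic choices generated by any non-decreasing price-ratio curve
satisfy GARP on any ensemble. `monotone_curve_implies_garp` checks curve
monotonicity on a grid spanning the ensemble's ratios; a non-monotone curve
does not abort the check but flags the report, since the theorem's guarantee
no longer applies.

## Curve fits

**Demand.** `q = A·p^ε` is fit by OLS of `log10 q` on `log10 p` — the model
is exactly linear in logs, so nonlinear fitting in linear space would only
add iteration error and implicit reweighting. The elasticity's standard
error and CI come from the OLS slope.

**Price-ratio sigmoid.** `f_H(r) = 1/(1 + 10^{−(r−r0)/k})` is fit by
bounded nonlinear least squares over `(r0, k)`. Initialization is
data-driven: `r0` starts at the observed `r` whose share is nearest 0.5,
`k` at half the `r` range; `k` is constrained to (1e-3, 100). When
per-budget sample sizes are supplied they enter as weights `n`
(inverse-variance surrogate for means of equally noisy worms); the fit is
unweighted otherwise, and both options are exposed because the appropriate
weighting of summary points is a judgment call.

The exchange weight near indifference is exposed in two readings:
`w = 1/r0` (the form used in downstream value computations) and
`w_linear = 10^{−r0}` (the linear density ratio at the indifference point).
`1/r0` is dimensionally odd for a log ratio and undefined at `r0 = 0`, so
neither reading is declared "correct"; both accessors are provided and the
caller chooses.

**Piecewise-linear curves** interpolate between ordered `(r, f_H)` knots
and clamp to the end values outside the knot range, keeping `f_H ∈ [0,1]`
when a prediction ensemble spans wider ratios than the fitted points.

## CES utility and the two-limit tobit

`U(q_H, q_M) = (β q_H^ρ + (1−β) q_M^ρ)^{1/ρ}` with weight `β ∈ (0,1)` and
curvature `ρ ≤ 1, ρ ≠ 0`. `ρ = 1` is the perfect-substitute (linear) case;
`ρ → 0` is the Cobb–Douglas limit, provided as an explicit separate
function and excluded from the optimizer's range; for `ρ < 0` a zero
quantity gives utility 0 (the mathematical limit). Maximizing U on the
normalized budget gives the interior optimum as an expenditure share,

    s = expit( log(p_H/p_M) + log( β p_M / ((1−β) p_H) ) / (1−ρ) ),

computed in log-odds space so it stays finite as `ρ → 1`. At `ρ ≥ 1` the
optimum is a corner decided by comparing `β·d_H` with `(1−β)·d_M` (a
warning is emitted, since a corner rather than tangency is returned).

Estimation follows the share-equation form of the censored regression: the
latent share is `s(β, ρ; p_i) + ε`, `ε ~ N(0, σ²)` i.i.d., observed shares
censored at 0 and 1. Interior observations contribute normal density terms;
boundary observations contribute the corresponding normal tail
probabilities. The likelihood can be multi-modal in ρ, so the optimizer is
bounded L-BFGS-B from six starts on a (β, ρ) grid, with
`β ∈ [0.01, 0.99]`, `ρ ∈ [−5, 0.999]`, `σ ∈ [1e-4, 1]`. Standard errors
come from the numerical Hessian of the log-likelihood at the optimum; a NaN
standard error signals a parameter at its bound (e.g. data from a
perfect-substitute chooser push `ρ̂` to its upper bound, which the test
suite exercises deliberately).

Alternative maximization targets (H-food intake, total intake, growth
potential with characteristic growth rates 0.50 and 0.43 per day on H and M
food) are implemented as per-budget share predictions. All three predict
corner solutions away from their equality loci — the contrast with observed
interior choices is what rules them out. At equal densities the
growth-potential target prefers H whenever its growth rate is larger; the
total-intake target is indifferent (share 0.5).

## Monte-Carlo procedures

All simulations draw shares per budget, map them to bundles by proportional
consumption (own expenditure exactly 1), and run a vectorized version of
the GARP check (batched boolean closure over replicates; equivalence with
the reference engine is itself a test). The three procedures:

1. **Random-chooser false positive** (Bronars-style power): shares i.i.d.
   Uniform(0,1) per budget; the estimate is the pass fraction. It is 1.0 on
   mutually non-crossing ensembles and shrinks as intersecting budgets are
   added — the measure of an ensemble's stringency.
2. **Gaussian resampling**: shares from Normal(mean, SEM) per budget; the
   estimate is the probability of at least one violation, i.e. how fragile
   an observed "zero violations" is to sampling error.
3. **Model-predicted maximization**: shares from a fitted curve plus
   Normal(0, sd) noise on a prediction ensemble; with zero noise and a
   monotone curve the probability is exactly 1 (the theorem), and as
   `sd → ∞` it converges to the random-chooser rate.

Out-of-range normal draws are clipped to [0,1] by default (censoring, mass
at the bounds); a `resample` switch draws from the truncated normal proper
instead, and the fraction clipped is logged when it exceeds 1%. Draws are
independent across budgets and replicates. Every procedure takes an
explicit seed and reports it, with exact binomial (Clopper–Pearson) 95%
intervals; identical seeds reproduce counts bit-for-bit.

The library default is 10^6 replicates per procedure. The test suite and
the pipeline default run at 10^3–2×10^5 replicates — the same estimands at
desk scale — and the convergence of estimates across replicate counts is
itself tested.

## Synthetic data generator

The generator emulates the *statistical* structure of single-worm assay
recordings: per budget line, each worm's mean preference follows the
exponential sigmoid of the price-ratio curve; the observed share adds
bounded noise (truncated normal by default, sd 0.1; a mean-parameterized
beta alternative for boundary-heavy data); total pumps per worm come from a
negative binomial with mean 1000 (an arbitrary fixture constant — assay
totals are variable and no distribution is reported — chosen large enough
that integer rounding barely moves the share); `n_H = round(f·N)` with
round-half-to-even. When dwell times are requested they are allocated so
that pumping frequency is equal on both sides and preference is expressed
purely through time per side — the dwell-time mechanism — making the
dwell-time index equal the pump share exactly. A CES variant draws latent
shares from the CES optimum plus normal noise *censored* to [0,1], which is
exactly the two-limit tobit's data-generating process.

Ensembles are parameterized by log price ratios with geometric-mean
anchoring (`d_H·d_M = anchor²`), the default being seven ratios spanning
−1.48 to 0.52 with the equal-density budget at r = 0; explicit density
pairs are also accepted verbatim. The package additionally ships
`data/worm7_synthetic.json`, an intercept-sharing seven-budget example
whose triplet structure (two triplets holding the M price fixed, one
holding the H price fixed) mirrors assay-style designs; it is synthetic and
labeled as such.

What the generator does **not** emulate: satiety drift within a recording,
locomotor mechanics (head angles, klinotaxis dynamics), pump-frequency
differences between foods, correlations between a worm's total pumps and
its preference, or accumulation-assay spatial dynamics. Passing recovery
tests on generated data therefore shows the estimators are correct for the
assumed noise structure, not that real recordings satisfy that structure.

A property worth knowing when interpreting recovery studies: bounded noise
truncates asymmetrically near 0 and 1, pulling extreme per-budget means
toward the interior. The sigmoid's indifference point `r0` is recovered
essentially unbiased, but the range parameter `k` is biased upward under
heavy truncation (with sd 0.1 and the default ensemble, `k̂ ≈ 0.62` for a
true 0.5). This is a feature of the bounded data, not an estimator defect —
with zero noise both parameters are recovered to 1e-6.

## Problem sizes

Property suites run at: 1,000 random datasets (K ≤ 6) for engine-vs-oracle
equivalence; 10⁴ random (monotone curve, ensemble) pairs with K ≤ 12 for
the monotonicity theorem; 10⁴ random two-good datasets for the Rose
property; 500 seeded replicates for sigmoid recovery (15 worms × 7 budgets,
sd 0.1) and 200 for CES-tobit recovery (20 worms × 7 budgets, σ = 0.1);
10⁴ observations for the expenditure-share identity. These sizes make the
full suite a desk-scale run while keeping binomial uncertainty on every
asserted rate far below the asserted margin.

## Known limitations

* The CCEI is reported as a single deflation index; no Afriat utility
  reconstruction or per-budget efficiency vector is attempted.
* No WARP/SARP variants beyond what GARP subsumes; two goods are assumed in
  the Rose check and the simulations (the relation engine itself is n-good).
* Sigmoid parameters carry no bootstrap or profile intervals, only RSS; the
  demand and substitutes fits report OLS intervals.
* The tobit assumes homoscedastic share noise across budgets; real
  recordings may have budget-dependent dispersion.
* The 11-budget human-style benchmark ensemble is externally published and
  ships only as a null-valued template (`data/harbaugh11_template.yaml`)
  that the user must populate; loading it unpopulated is an error by design.
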