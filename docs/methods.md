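# Methods

## Stage 1: demographic dose-response models

### Growth

Observed growth `G` (kg C tree⁻¹ yr⁻¹, the difference in aboveground carbon
between censuses divided by the interval; may be negative) is modelled as

    G ~ Normal( a · m^z · e^{a2·BAL + a3·ln BA} · g_T(T) · g_P(P) · [g_N(N)] · [s(S)],  σ² )

with `g_c(x) = exp(−½ (ln(x/c₁)/c₂)²)`, a unimodal multiplier in (0, 1]
peaking at `c₁` with ln-scale width `c₂`. Units: size `m` in kg C,
temperature in K, precipitation in dm, deposition in kg ha⁻¹ yr⁻¹,
basal areas in m² ha⁻¹.

The Gaussian error with constant σ is a modelling choice: the likelihood
family is otherwise unconstrained by the estimand, a constant-σ normal
supports negative observed growth, and σ is estimated by maximum likelihood
and counted as a free parameter in `k`. Within the annealing objective, `a`
and `σ` are concentrated out analytically (for fixed shape parameters the
Gaussian ML solutions are `â = Σ G·g / Σ g²` and `σ̂² = mean squared
residual`, clipped to their boxes). This is exact profile likelihood — the
annealer searches only the nonlinear shape parameters — not a separate
refinement stage; no gradient methods are used anywhere.

The S term has two forms. The sigmoid `s(S) = s₃ + (1−s₃)/(1+(S/s₁)^{s₂})`
declines from 1 with its half-decline at `s₁`, steepness `s₂`, and plateau
`s₃`. The lognormal form reuses `g` but is constrained to its decreasing
limb by bounding `s₁` at the unit's minimum observed S, so only a
monotonically negative response can be expressed (kept for comparability
with older monotone-negative fits). N at zero is floored at 0.01 kg ha⁻¹
yr⁻¹ before the log; S = 0 is legal for the sigmoid and floored likewise
for the lognormal form.

The growth family has exactly 7 members: intercept-only; base (size,
competition, climate); base+N; base+S(sigmoid); base+S(lognormal);
base+N+S(sigmoid); base+N+S(lognormal).

### Survival

The annual survival multiplier is raised to the census interval `dt` in
years: `P(survive interval) = bracket^{dt}`. The exponent's time unit is a
genuine ambiguity in this model family's notation; it is isolated in one
function (`survival_prob`) and a 10-year reporting helper
(`survival_prob_10yr = bracket¹⁰`) is provided. Two competition forms:

  * form A: `a · (1 − zc₁ e^{−zc₂·m}) · e^{−zc₃·m^{zc₄}} · e^{−br₁·BAratio^{br₂}·BA^{br₃}}`
    with `BAratio = BAL/BA ∈ [0,1]`, the only dimensionless crowding ratio
    constructible from the declared inputs;
  * form B: `a · g(m) · g(BA) · g(BAL+1)` (the +1 offset keeps the log
    defined at BAL = 0).

Both are multiplied by the shared climate/N/S modifiers. Under the default
bounds (all factor parameters non-negative, `a ∈ (0,1]`) the bracket cannot
exceed 1; the likelihood still rejects any parameter vector giving an
interval probability outside (0, 1) with a −∞ objective rather than an
exception. The survival family is the six non-trivial structures × two
competition forms + one intercept-only model = 13.

### Annealing

Maximisation uses a Metropolis annealer: single-coordinate Gaussian
proposals scaled per-coordinate to the box width, Corana-style width
adaptation toward a 40% acceptance rate every 60 proposals per coordinate,
geometric cooling from an initial temperature set by the dispersion of a
21-point random probe (clipped to [0.01, 10⁴]) down to 10⁻⁸ of that over
the budget, and best-point tracking. The default budget is 100,000
objective evaluations split across 3 restarts; the first restart starts
from a data-informed point (modifier locations at covariate medians, widths
at 1, exponents at field-typical values), later restarts start uniformly at
random in the box. All randomness flows from the fit seed; two runs with
the same seed are bit-identical, and the returned objective is never below
the initial point's.

Default boxes: location parameters in [0.5 × min, 2 × max] of their
observed covariate; ln-widths in [0.05, 10]; growth `a` in (0, 10 × max |G|];
survival `a` in (0, 1]; `s₃ ∈ [0, 0.99]`; `z ∈ [0, 2]`; competition
coefficients in small non-negative (or symmetric) boxes. Rationale: the
data cannot inform a modifier peaking far outside the observed covariate
range, and the boxes keep the profile surface identifiable.

### Selection and exclusion

Per unit, AIC = 2k − 2·logLik for every converged fit; the candidate set is
all fits within ΔAIC ≤ 4 of the best. If any candidate carries both an N
and an S term, the lowest-AIC such candidate is selected (separate
deposition effects are preferred at a small AIC cost). Otherwise the
lowest-AIC candidate is selected, unless the unit's Pearson corr(N, S) ≥ 0.7
and some candidate carries exactly one deposition term — then N and S
effects cannot be attributed to either pollutant and the unit is excluded
(`excluded_ns_collinearity`). A candidate set containing only
deposition-free models is never excluded (nothing to confound). Ties break
on fewer parameters, then enumeration order. An undefined correlation (zero
variance) never triggers exclusion. The 500-tree inclusion cutoff applies
per species × Division × endpoint.

### Shapes and critical loads

The vulnerability scale is increase (0) < flat (1) < unimodal/sigmoid (2) <
decrease (3). The N-shape rule uses the fitted peak against the unit's
observed N range [N_min, N_max]: no N term → flat; n₁ ≥ N_max → increase
(only the rising limb is realized); n₁ ≤ N_min → decrease; interior peak →
unimodal. Boundary equality is assigned to the monotone class (the realized
curve is monotone on the closed window). The S shape follows the selected
form: none → flat, lognormal → decrease, sigmoid → the sigmoid category. A
sigmoid whose decline sits entirely above the observed S range is still
reported as sigmoid; the critical-load table carries the observed
deposition range per unit precisely so such out-of-range cases are
flaggable downstream.

Critical loads: CL(N) = n₁; lognormal CL(S) = s₁; sigmoid CL(S) solves
`s(S) = 1 − f`, giving `CL = s₁ (f/(1−f−s₃))^{1/s₂}`, with f = 0.05 for
growth and 0.01 for survival by default (per-endpoint config scalars). An
f ≥ 1 − s₃ is reported as undefined — the curve never declines that far —
never clipped.

## Stage 2: vulnerability regressions

One row per species × Division × endpoint × pollutant: the ordered shape
plus Division-scale species means of MAT (°C), MAP (mm), soil pH, N and S
deposition (long-term normals, a coarser time basis than the stage-1
between-census means), and two species-level traits (mycorrhizal
association AM/EcM, leaf habit deciduous/evergreen). Excluded units and
species without trait assignments are dropped with logged counts. The
growth and survival tables are built separately (their unit sets differ
because growth needs trees alive at both censuses).

The proportional-odds model is `P(Y ≤ j) = logistic(α_j − x'β)` with common
slopes: a positive β shifts odds toward more vulnerable shapes and
`exp(β)` is the per-unit odds ratio of a more vulnerable response.
Continuous predictors enter in raw units by default (odds ratios per unit;
a standardization flag exists). Fits use statsmodels' ordinal model
(BFGS, gtol 10⁻⁸) with a score-norm convergence check; Wald
(observed-information) 95% CIs; the null (thresholds-only) log-likelihood
is closed-form from the category proportions; Nagelkerke R² =
[1 − e^{2(L₀−L₁)/n}]/[1 − e^{2L₀/n}].

Stepwise selection starts from the full hypothesis model — 7 main effects
plus the six hypothesis-driven interactions MAT×MAP, MAT×Ndep, pH×Sdep,
Ndep×Sdep, Ndep×myco, pH×myco — and applies the best single add/drop move
until AIC stops improving, honouring marginality (an interaction is only
present with both its main effects; this follows the stepwise convention
even where not strictly required). Failed candidate fits are skipped with a
log entry; the accepted-step trace is attached to the result. The
collinearity screen flags |r| strictly above 0.7 but removes nothing.

Fisher exact tests of shape × Division tables: 2×2 by exact hypergeometric
two-sided probability ordering; R×C by Monte-Carlo over margin-preserving
permutations, `p = (1 + #{P(sim) ≤ P(obs)})/(B+1)` with B = 10,000 by
default. ANOVA is the standard one-way F with Tukey HSD post-hoc.

Blomberg's K* uses the Brownian covariance V (shared root-to-MRCA path
lengths), the phylogenetic GLS mean â, and
`K = (MSE₀/MSE) / [(tr V − n/(1'V⁻¹1))/(n−1)]`; the permutation p-value is
the fraction of tip-shuffled trait vectors whose phylogenetically corrected
MSE is at most the observed one (with the +1 convention). On a star
phylogeny V ∝ I and K = 1 identically. In the pipeline the per-species
trait is the mean shape rank across Divisions; a test cross-checks the
statistic against an independent R implementation on a fixed small tree.

## Synthetic study conditions

The generator draws every input from the model equations above with known
parameters. Defaults emulate a national inventory's structure: 11 Division
codes with covariate gradients (higher N and S deposition in the eastern
Divisions, higher soil pH and lower precipitation in the central ones —
parameters, not data); tree sizes lognormal(ln 150, 0.8) kg C; plot basal
area lognormal(ln 25, 0.4) m² ha⁻¹ with BAL = u·BA, u ~ Beta(2,2); census
intervals normal(8.2, 2.9) yr truncated to [5, 10]; per-tree N and S
deposition lognormal around the Division mean with a configurable log-scale
correlation (default 0.4; the knob sweeps 0–0.95 to exercise the exclusion
rule); ≥ 500 trees per unit (600 in the bundled small scenario, 2,000 in
recovery experiments — sizes chosen to keep a full run in minutes on one
CPU). Growth = model mean + N(0, σ); survival ~ Bernoulli(bracket^{dt}).
Strong-effect defaults put n₁ = 12 inside the sampled N range and s₁ near
the Division S mean so deposition effects are identifiable. An optional
flag injects harvested / dead-at-both-censuses rows so the ingest filter is
testable. Every dataset ships with a truth manifest (generative spec,
parameters, expected shapes over the realized covariate ranges, expected
critical loads, stage-2 β).

What the synthetic conditions do **not** emulate: spatially explicit plot
coordinates and spatial autocorrelation, the inventory's panel/rotating
remeasurement design, measurement error in carbon allometry, temporal
deposition trends within an interval, and real species' trait phylogenies.
Passing recovery tests therefore demonstrates that the estimation machinery
is correct and well calibrated under the model's own assumptions — not that
the model is adequate for any particular real forest dataset.

## Numerical choices and degenerate inputs

* Modifier underflow: `g(x)` can underflow to exactly 0 for extreme
  arguments; the likelihood treats non-finite or non-positive survival
  probabilities as −∞ rejections.
* Pipeline seeds: one run seed feeds `SeedSequence.spawn` — child 0
  simulation, child 1 fitting (one grandchild per unit), child 2 stage-2
  tests, child 3 phylogenetics. Outputs are byte-identical across runs with
  the same seed (timestamps are deliberately kept out of artifacts).
* Ordinal fits require ≥ 2 realized categories and a full-rank centred
  design; the pipeline requires ≥ 20 units per ordinal model and records a
  structured error otherwise (the bundled 12-unit scenario exercises this
  path deliberately).
* AICc (reported alongside AIC for stage 2) is undefined for n ≤ k+1 and
  raised/reported as such.
* Row validation at ingest rejects BAL > BA, non-positive sizes/intervals
  and non-numeric covariates per row, and hard-fails above 1% invalid rows.

## Known limitations

* Simulated annealing gives no standard errors for stage-1 parameters, and
  none are reported (no bootstrap; matching the method's scope).
* The sigmoid `s₂` and lognormal widths are weakly identified when the
  observed deposition range misses the curve's bend; critical loads from
  such fits inherit that uncertainty silently (the reported observed ranges
  are the guard).
* The exclusion rule keys on the unit-level Pearson correlation only;
  nonlinear N-S dependence is not screened.
* Stage-2 inference treats stage-1 shapes as known, ignoring their
  estimation uncertainty.
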