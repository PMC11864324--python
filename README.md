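# treecl

Regional tree growth and survival responses to nitrogen and sulfur
deposition: nonlinear dose-response fitting, critical-load estimation, and
ordinal vulnerability analysis.

## The problem

Atmospheric N and S deposition alter tree demography, but a single
continental response curve per species can hide opposing regional
responses. `treecl` implements a two-stage analysis for forest-inventory
style data (remeasured trees with growth rates or survival outcomes, plus
climate and deposition covariates), with species × ecoregion Division as the
analytical unit:

**Stage 1 — dose-response fits.** Growth of a tree is modelled as a
potential rate modified by bounded multiplicative terms,

```
G = a · m^z · exp(a2·BAL + a3·ln BA) · g(T) · g(P) · g(N) · s(S)
```

where `g(x) = exp(−½(ln(x/c₁)/c₂)²)` is a two-parameter lognormal modifier
(peak location c₁, ln-scale width c₂) and the S term is either a declining
sigmoid `s(S) = s₃ + (1−s₃)/(1+(S/s₁)^s₂)` or a lognormal constrained to its
decreasing limb. Annual survival is modelled analogously and raised to the
census interval in years, with two competition representations. Each species
× Division unit (≥ 500 trees) is fitted against a family of 7 growth / 13
survival candidate models by maximum likelihood via simulated annealing
(100,000 iterations by default; the growth `a` and residual SD `σ` are
profiled in closed form). Selection is by AIC with a ΔAIC ≤ 4 candidate
window that prefers models carrying **separate** N and S terms; units where
corr(N, S) ≥ 0.7 and the candidates cannot separate the two pollutants are
excluded. The fitted curve's realized shape over the unit's observed
deposition range is classified on an ordered vulnerability scale

```
increase (0) < flat (1) < unimodal/sigmoid (2) < decrease (3)
```

and critical loads follow from the parameters: CL(N) = n₁ (the peak of the
N modifier), CL(S) = s₁ for the lognormal form, and for the sigmoid form the
inversion at a fractional reduction f (defaults 0.05 for growth, 0.01 for
survival):

```
CL(S) = s₁ · ( f / (1 − f − s₃) )^{1/s₂}
```

**Stage 2 — what drives vulnerability.** The ordered shapes are regressed on
Division-scale species means (MAT, MAP, soil pH, N and S deposition) and
species traits (mycorrhizal association AM/EcM, leaf habit) with
proportional-odds ordinal logistic models — four models: {growth, survival}
× {N, S} — including six hypothesis-driven interactions, selected by
bidirectional stepwise AIC. Supporting statistics: Pearson collinearity
screen (|r| > 0.7 flagged, nothing removed), Fisher exact tests of shape ×
Division tables (Monte-Carlo for R×C), one-way ANOVA with Tukey HSD across
Divisions, and Blomberg's K* with a tip-permutation test for phylogenetic
signal in the residual vulnerability.

Because no inventory extract ships with the package, a first-class
synthetic-data module generates every input **from the model equations
themselves** with known parameters and writes a truth manifest, so recovery
can be scored exactly.

## Worked example

Fit the whole growth candidate family to one strong-effect synthetic unit
and apply the selection rule (`examples/02_fit_and_select.py`):

```
$ python examples/02_fit_and_select.py
generated unit SP01 x Division 22 from growth:base+N+S-sigmoid with n1 = 12.0, s1 = 9.0

model                                k     logLik        AIC
growth:base+N+S-sigmoid             14    -1065.6     2159.2
growth:base+N+S-lognormal           13    -1172.3     2370.6
growth:base+N                       11    -3421.0     6864.1
growth:base+S-sigmoid               12    -4809.0     9642.1
growth:base+S-lognormal             11    -4842.6     9707.2
growth:base                          9    -4916.6     9851.2
growth:intercept                     2    -5198.0    10400.0

N-S correlation: 0.34 -> selected
selected: growth:base+N+S-sigmoid
recovered n1 = 11.99 (truth 12.0), s1 = 10.59 (truth 9.0)
```

The true generative model wins by > 200 AIC points, the N-S correlation is
below the 0.7 exclusion threshold so the unit is kept, and the N critical
load (n₁) is recovered to 0.1%. Other examples cover the response-curve
algebra (`01`), critical loads (`03`), the stage-2 ordinal regression with
stepwise selection (`04`), phylogenetic signal (`05`) and the full pipeline
(`06`). The CLI mirrors the pipeline:

```bash
treecl all --seed 5 --iterations 2000 --min-trees 400 --out scratch/run
```

writing `trees.csv`, `fits.csv`, `selection.csv`, `shapes.csv`, `cl.csv`,
`ordinal_results.json`, `tests.csv` and `report.json` into the run
directory.

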