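"""Stage-2 statistics: what drives vulnerable deposition responses.

Each species x Division unit contributes one ordered response shape
(increase < flat < unimodal/sigmoid < decrease) per endpoint and pollutant.
This module builds the unit-level covariate table (Division-scale species
means of climate, soil pH and deposition plus two species traits), screens
it for collinearity, fits proportional-odds ordinal regressions with
hypothesis-driven interactions and stepwise AIC selection, and runs the
supporting tests: Fisher exact tests on shape-by-Division contingency
tables, one-way ANOVA with Tukey HSD on covariates across Divisions, and
Blomberg's K* for phylogenetic signal (see :mod:`treecl.phylo`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .phylo import blomberg_k  # noqa: F401  (module surface)

__all__ = [
    "MAIN_EFFECTS",
    "INTERACTIONS",
    "OrdinalFit",
    "FitDiagnosticError",
    "build_covariate_table",
    "collinearity_screen",
    "encode_predictors",
    "fit_proportional_odds",
    "stepwise_aic",
    "nagelkerke_r2",
    "fisher_exact_shapes",
    "anova_tukey",
    "blomberg_k",
]

#: Main-effect scope of the vulnerability regressions.
MAIN_EFFECTS = ["MAT", "MAP", "soil_pH", "Ndep", "Sdep", "myco", "leaf_habit"]

#: The six hypothesis-driven first-order interactions.
INTERACTIONS = [
    "MAT:MAP",
    "MAT:Ndep",
    "soil_pH:Sdep",
    "Ndep:Sdep",
    "Ndep:myco",
    "soil_pH:myco",
]

_CATEGORICAL = {"myco": ("AM", "EcM"), "leaf_habit": ("deciduous", "evergreen")}


class FitDiagnosticError(RuntimeError):
    """Ordinal fit failed to converge (separation or flat likelihood)."""


# ---------------------------------------------------------------------------
# covariate table
# ---------------------------------------------------------------------------


def build_covariate_table(shapes: pd.DataFrame, plot_covariates: pd.DataFrame,
                          traits: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """One row per species x Division x endpoint x pollutant with unit means.

    ``shapes`` needs columns species, division, endpoint, pollutant, shape
    (category code, or the label 'not_applicable' / NaN for excluded units).
    ``plot_covariates`` needs species, division, mat_C, map_mm, soil_ph,
    ndep, sdep (one row per plot occurrence).  ``traits`` needs species,
    mycorrhiza, leaf_habit.  Units with not_applicable shapes or species
    missing from the trait table are dropped; the counts are returned in the
    log dict.
    """
    log = {"input_rows": int(len(shapes)), "dropped_not_applicable": 0,
           "dropped_missing_trait": 0, "dropped_missing_covariates": 0}
    shp = shapes.copy()
    na_mask = shp["shape"].isna() | (shp["shape"].astype(str) == "not_applicable")
    log["dropped_not_applicable"] = int(na_mask.sum())
    shp = shp[~na_mask]

    means = (plot_covariates
             .groupby(["species", "division"], as_index=False)
             [["mat_C", "map_mm", "soil_ph", "ndep", "sdep"]]
             .mean())
    means = means.rename(columns={"mat_C": "MAT", "map_mm": "MAP",
                                  "soil_ph": "soil_pH", "ndep": "Ndep",
                                  "sdep": "Sdep"})
    tr = traits.rename(columns={"mycorrhiza": "myco"})[
        ["species", "myco", "leaf_habit"]]

    merged = shp.merge(means, on=["species", "division"], how="left")
    miss_cov = merged["MAT"].isna()
    log["dropped_missing_covariates"] = int(miss_cov.sum())
    merged = merged[~miss_cov]
    merged = merged.merge(tr, on="species", how="left")
    bad_trait = (merged["myco"].isna() | merged["leaf_habit"].isna()
                 | ~merged["myco"].isin(_CATEGORICAL["myco"])
                 | ~merged["leaf_habit"].isin(_CATEGORICAL["leaf_habit"]))
    log["dropped_missing_trait"] = int(bad_trait.sum())
    merged = merged[~bad_trait].reset_index(drop=True)
    merged["shape"] = merged["shape"].astype(int)
    log["output_rows"] = int(len(merged))
    return merged, log


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7,
                        columns: Optional[Sequence[str]] = None):
    """Pairwise Pearson matrix over continuous predictors plus flagged pairs.

    Pairs with ``|r|`` strictly above the threshold are flagged; nothing is
    removed.  Constant columns yield an undefined (NaN) correlation and are
    flagged as such.
    """
    if columns is None:
        columns = [c for c in ("MAT", "MAP", "soil_pH", "Ndep", "Sdep")
                   if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    sub = table[list(columns)].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = sub.corr(method="pearson")
    flagged = []
    for a, b in itertools.combinations(columns, 2):
        r = corr.loc[a, b]
        if math.isnan(r):
            flagged.append((a, b, float("nan"), "undefined (constant column)"))
        elif abs(r) > threshold:
            flagged.append((a, b, float(r), f"|r| > {threshold}"))
    return corr, flagged


# ---------------------------------------------------------------------------
# proportional-odds regression
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model on the vulnerability scale."""

    terms: list
    beta: dict
    se: dict
    thresholds: np.ndarray
    logLik: float
    logLik_null: float
    AIC: float
    AICc: float
    nagelkerke_r2: float
    odds_ratios: dict  # term -> (OR, lo95, hi95)
    n: int
    n_categories: int
    converged: bool = True
    step_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.beta) + (self.n_categories - 1)

    def predict_probs(self, X: np.ndarray) -> np.ndarray:
        """Category probabilities for an encoded design matrix (columns = terms)."""
        eta = X @ np.array([self.beta[t] for t in self.terms]) if self.terms \
            else np.zeros(X.shape[0] if X is not None else 1)
        cut = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        cum = 1.0 / (1.0 + np.exp(-(cut[None, :] - eta[:, None])))
        return np.diff(cum, axis=1)


def encode_predictors(table: pd.DataFrame, terms: Sequence[str],
                      standardize: bool = False) -> np.ndarray:
    """Numeric design matrix for a term list (no intercept).

    Categorical predictors are indicator-coded against their first level
    (myco: EcM vs AM; leaf_habit: evergreen vs deciduous); interactions
    ``A:B`` are elementwise products of the encoded columns.  Continuous
    predictors enter in raw units unless ``standardize``.
    """

    def col(name: str) -> np.ndarray:
        if name in _CATEGORICAL:
            ref, alt = _CATEGORICAL[name]
            vals = table[name].astype(str)
            bad = ~vals.isin((ref, alt))
            if bad.any():
                raise ValueError(f"unknown {name} levels: {sorted(vals[bad].unique())}")
            return (vals == alt).to_numpy(dtype=float)
        x = table[name].to_numpy(dtype=float)
        if standardize:
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        return x

    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(col(a) * col(b))
        else:
            cols.append(col(t))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _null_loglik(y: np.ndarray, J: int) -> tuple[float, np.ndarray]:
    """Closed-form intercept-only fit: MLE category probabilities are the
    sample proportions; thresholds are the cumulative logits."""
    n = y.size
    counts = np.bincount(y, minlength=J).astype(float)
    p = counts / n
    ll = float(np.sum(counts[counts > 0] * np.log(p[counts > 0])))
    cum = np.clip(np.cumsum(p)[:-1], 1e-12, 1 - 1e-12)
    thresholds = np.log(cum / (1 - cum))
    return ll, thresholds


def fit_proportional_odds(table: pd.DataFrame, terms: Sequence[str],
                          shape_col: str = "shape",
                          standardize: bool = False) -> OrdinalFit:
    """Fit a cumulative-logit proportional-odds model.

    ``P(Y <= j) = logistic(alpha_j - x'beta)`` with common slopes across
    thresholds: a positive coefficient shifts odds toward the more
    vulnerable categories, so ``exp(beta)`` is the per-unit odds ratio of a
    more vulnerable response.  Wald (observed-information) 95% CIs.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y_raw = table[shape_col].to_numpy()
    levels = np.unique(y_raw)
    if levels.size < 2:
        raise ValueError("need at least 2 realized categories")
    y = np.searchsorted(levels, y_raw)
    J = levels.size
    n = y.size
    ll0, thr0 = _null_loglik(y, J)

    terms = list(terms)
    if not terms:
        k = J - 1
        return OrdinalFit(terms=[], beta={}, se={}, thresholds=thr0,
                          logLik=ll0, logLik_null=ll0, AIC=aic_(ll0, k),
                          AICc=aicc_(ll0, k, n), nagelkerke_r2=0.0,
                          odds_ratios={}, n=n, n_categories=J)

    X = encode_predictors(table, terms, standardize=standardize)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("model matrix is rank deficient for terms " + str(terms))
    model = OrderedModel(y, X, distr="logit")
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    with np.errstate(over="ignore"), _warnings.catch_warnings():
        # convergence is re-checked below via the score norm
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(method="bfgs", maxiter=1000, gtol=1e-8, disp=False)
    score = model.score(res.params)
    if not res.mle_retvals.get("converged", False) and \
       float(np.linalg.norm(score)) > 1e-2 * n:
        raise FitDiagnosticError(
            f"ordinal fit did not converge for terms {terms}; "
            f"score norm {float(np.linalg.norm(score)):.3g}")
    p = np.asarray(res.params, dtype=float)
    beta = dict(zip(terms, p[: len(terms)]))
    bse = np.asarray(res.bse, dtype=float)
    se = dict(zip(terms, bse[: len(terms)]))
    thresholds = np.asarray(
        model.transform_threshold_params(p)[1:-1], dtype=float)
    ll = float(res.llf)
    k = len(terms) + (J - 1)
    zc = stats.norm.ppf(0.975)
    ors = {t: (math.exp(beta[t]),
               math.exp(beta[t] - zc * se[t]),
               math.exp(beta[t] + zc * se[t])) for t in terms}
    return OrdinalFit(terms=terms, beta=beta, se=se, thresholds=thresholds,
                      logLik=ll, logLik_null=ll0, AIC=aic_(ll, k),
                      AICc=aicc_(ll, k, n),
                      nagelkerke_r2=nagelkerke_r2(ll, ll0, n),
                      odds_ratios=ors, n=n, n_categories=J)


def aic_(ll: float, k: int) -> float:
    return 2.0 * k - 2.0 * ll


def aicc_(ll: float, k: int, n: int) -> float:
    if n <= k + 1:
        return float("inf")
    return aic_(ll, k) + 2.0 * k * (k + 1) / (n - k - 1)


def nagelkerke_r2(logLik_fit: float, logLik_null: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo-R^2 in [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cox_snell = 1.0 - math.exp(2.0 * (logLik_null - logLik_fit) / n)
    max_r2 = 1.0 - math.exp(2.0 * logLik_null / n)
    if max_r2 <= 0:
        return 0.0
    return min(max(cox_snell / max_r2, 0.0), 1.0)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


def _mains_of(term: str) -> list[str]:
    return term.split(":") if ":" in term else [term]


def _droppable(term: str, current: Sequence[str]) -> bool:
    # marginality: a main effect stays while any retained interaction uses it
    if ":" in term:
        return True
    return not any(":" in t and term in _mains_of(t) for t in current)


def _addable(term: str, current: Sequence[str]) -> bool:
    if ":" not in term:
        return True
    return all(m in current for m in _mains_of(term))


def stepwise_aic(table: pd.DataFrame,
                 scope_main: Sequence[str] = tuple(MAIN_EFFECTS),
                 scope_interactions: Sequence[str] = tuple(INTERACTIONS),
                 shape_col: str = "shape",
                 standardize: bool = False,
                 log: Optional[list] = None) -> OrdinalFit:
    """Bidirectional stepwise AIC minimisation over the hypothesis scope.

    Starts from the full model (all mains plus the hypothesis-driven
    interactions), then repeatedly applies the single add or drop move that
    most lowers AIC, respecting marginality (an interaction is only present
    with both its main effects).  The step trace (term list, AIC per
    accepted model) is attached to the returned fit; candidate fits that
    fail are skipped with a log entry.
    """
    scope = list(scope_main) + list(scope_interactions)
    current = list(scope)
    cache: dict = {}
    notes = log if log is not None else []

    def fitted(terms: tuple) -> Optional[OrdinalFit]:
        if terms not in cache:
            try:
                cache[terms] = fit_proportional_odds(
                    table, list(terms), shape_col=shape_col,
                    standardize=standardize)
            except (FitDiagnosticError, ValueError, np.linalg.LinAlgError) as e:
                notes.append(f"skipped candidate {list(terms)}: {e}")
                cache[terms] = None
        return cache[terms]

    cur_fit = fitted(tuple(current))
    # if even the full model fails, back off to mains, then to the null
    if cur_fit is None:
        current = list(scope_main)
        cur_fit = fitted(tuple(current))
    if cur_fit is None:
        current = []
        cur_fit = fit_proportional_odds(table, [], shape_col=shape_col)
    trace = [(list(current), cur_fit.AIC)]

    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list]] = []
        for t in current:
            if _droppable(t, [x for x in current if x != t]):
                cand = [x for x in current if x != t]
                f = fitted(tuple(cand))
                if f is not None:
                    moves.append((f.AIC, cand))
        for t in scope:
            if t not in current and _addable(t, current):
                cand = current + [t]
                f = fitted(tuple(cand))
                if f is not None:
                    moves.append((f.AIC, cand))
        if moves:
            best_aic, best_terms = min(moves, key=lambda m: (m[0], len(m[1])))
            if best_aic < cur_fit.AIC - 1e-9:
                current = best_terms
                cur_fit = fitted(tuple(current))
                trace.append((list(current), cur_fit.AIC))
                improved = True
    cur_fit.step_trace = trace
    return cur_fit


# ---------------------------------------------------------------------------
# supporting tests
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact_shapes(contingency, B: int = 10_000,
                        seed: int = 0) -> float:
    """Two-sided Fisher exact test of a shapes x Divisions count table.

    2x2 tables use the exact hypergeometric test (two-sided by probability
    ordering).  Larger tables use a Monte-Carlo estimate over
    margin-preserving permutations: ``p = (1 + #{P(sim) <= P(obs)})/(B+1)``.
    """
    tab = np.asarray(contingency, dtype=float)
    if tab.size == 0 or tab.sum() == 0:
        raise ValueError("empty contingency table")
    if np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValueError("contingency table must hold non-negative integers")
    tab = tab.astype(np.int64)
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    if tab.shape == (2, 2):
        return float(stats.fisher_exact(tab, alternative="two-sided")[1])
    if B < 1000:
        raise ValueError("need B >= 1000 Monte-Carlo draws for an RxC table")
    rng = np.random.default_rng(seed)
    lp_obs = _log_table_prob(tab)
    rows = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1))
    cols = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0))
    R, C = tab.shape
    hits = 0
    for _ in range(B):
        perm = rng.permutation(cols)
        sim = np.bincount(rows * C + perm, minlength=R * C).reshape(R, C)
        if _log_table_prob(sim) <= lp_obs + 1e-9:
            hits += 1
    return (1 + hits) / (B + 1)


def anova_tukey(values_by_group: dict) -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Returns ``{"F", "p", "df", "tukey": DataFrame}`` where df is
    (k-1, n-k).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("each group needs at least 2 values")
    arrays = list(groups.values())
    F, p = stats.f_oneway(*arrays)
    n = sum(a.size for a in arrays)
    k = len(arrays)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    data = np.concatenate(arrays)
    labels = np.concatenate([np.repeat(str(g), a.size)
                             for g, a in groups.items()])
    tk = pairwise_tukeyhsd(data, labels)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return {"F": float(F), "p": float(p), "df": (k - 1, n - k), "tukey": tukey}
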