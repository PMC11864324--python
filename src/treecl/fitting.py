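"""Maximum-likelihood fitting by simulated annealing, AIC, and model selection.

Each species x Division x endpoint unit is fitted independently: every
candidate model in the family is maximised by a Metropolis annealer inside
box constraints, AIC is computed for each converged fit, and a selection rule
picks one model per unit — preferring, within a small AIC window, models that
carry separate N and S terms, and excluding units where N and S deposition
are too collinear to separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    FitResult,
    ModelSpec,
    TreeArrays,
    param_names,
    params_from_vector,
)

__all__ = [
    "FitConfig",
    "SelectionOutcome",
    "aic",
    "aicc",
    "ns_correlation",
    "default_bounds",
    "fit_model",
    "select_model",
]


@dataclass
class FitConfig:
    """Knobs of the annealing fit and the per-unit selection rule.

    ``iterations`` is the total objective-evaluation budget for one model fit,
    split evenly across ``restarts``.  ``bounds`` maps parameter names to
    (lo, hi) boxes and overrides the data-derived defaults.  ``delta_aic`` is
    the candidate window; ``ns_corr_threshold`` the N-S collinearity cutoff.
    """

    iterations: int = 100_000
    seed: int = 0
    bounds: Optional[dict] = None
    restarts: int = 3
    min_trees: int = 500
    delta_aic: float = 4.0
    ns_corr_threshold: float = 0.7
    cooling: dict = field(default_factory=lambda: {
        "t_ratio": 1e-8,   # final/initial temperature of the geometric schedule
        "adapt_every": 60,  # proposal-width adaptation cadence (per coordinate)
        "target_accept": 0.4,
    })

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.delta_aic < 0:
            raise ValueError("delta_aic must be >= 0")
        if not (0 < self.ns_corr_threshold <= 1):
            raise ValueError("ns_corr_threshold must lie in (0, 1]")


@dataclass
class SelectionOutcome:
    species: str
    division: str
    endpoint: str
    status: str  # "selected" | "excluded_ns_collinearity" | "insufficient_data"
    selected_fit: Optional[FitResult] = None
    candidate_set: list = field(default_factory=list)
    ns_correlation: Optional[float] = None


def aic(logLik: float, k: int) -> float:
    """Akaike's information criterion, 2k - 2*logLik."""
    return 2.0 * k - 2.0 * logLik


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    base = aic(logLik, k)
    return base + 2.0 * k * (k + 1) / (n - k - 1)


def ns_correlation(recs: TreeArrays) -> float:
    """Pearson correlation between per-tree N and S deposition.

    Returns ``nan`` when either column has (numerically) zero variance; the
    selection rule treats an undefined correlation as not exceeding the
    threshold.
    """
    N = np.asarray(recs.N, dtype=float)
    S = np.asarray(recs.S, dtype=float)
    if N.size < 3:
        raise ValueError("need at least 3 records for a correlation")
    if np.std(N) < 1e-12 * max(1.0, abs(float(np.mean(N)))) or \
       np.std(S) < 1e-12 * max(1.0, abs(float(np.mean(S)))):
        return float("nan")
    return float(np.corrcoef(N, S)[0, 1])


# ---------------------------------------------------------------------------
# bounds
# ---------------------------------------------------------------------------

_WIDTH_BOUNDS = (0.05, 10.0)


def default_bounds(recs: TreeArrays, endpoint: str) -> dict:
    """Data-derived parameter boxes keeping the search identifiable.

    Location parameters are boxed to [0.5*min, 2*max] of the matching observed
    covariate, widths to [0.05, 10]; the growth potential to 10x the largest
    absolute observed growth; survival baseline to (0, 1].
    """

    def loc(x):
        x = np.asarray(x, dtype=float)
        lo = 0.5 * float(np.min(x[x > 0])) if np.any(x > 0) else 1e-3
        hi = 2.0 * float(np.max(x))
        return (max(lo, 1e-6), max(hi, 2e-6))

    b: dict = {
        "t1": loc(recs.T), "t2": _WIDTH_BOUNDS,
        "p1": loc(recs.P), "p2": _WIDTH_BOUNDS,
        "n1": loc(recs.N), "n2": _WIDTH_BOUNDS,
        "s1": loc(np.maximum(recs.S, 0.01)), "s2": _WIDTH_BOUNDS,
        "s3": (0.0, 0.99),
    }
    if endpoint == "growth":
        g = np.asarray(recs.growth_G, dtype=float)
        gmax = max(float(np.max(np.abs(g))), 1e-3)
        b.update({
            "a": (1e-6, 10.0 * gmax),
            "z": (0.0, 2.0),
            "a2": (-0.5, 0.5),
            "a3": (-2.0, 2.0),
            "sigma": (1e-4, 10.0 * max(float(np.std(g)), 1e-3)),
        })
    else:
        b.update({
            "a": (1e-6, 1.0),
            # form A
            "zc1": (0.0, 1.0), "zc2": (0.0, 5.0),
            "zc3": (0.0, 1.0), "zc4": (0.0, 3.0),
            "br1": (0.0, 5.0), "br2": (0.0, 5.0), "br3": (0.0, 3.0),
            # form B
            "z1": loc(recs.size_m), "z2": _WIDTH_BOUNDS,
            "ba1": loc(recs.BA), "ba2": _WIDTH_BOUNDS,
            "bl1": loc(recs.BAL + 1.0), "bl2": _WIDTH_BOUNDS,
        })
    return b


def _bounds_for(spec: ModelSpec, recs: TreeArrays, config: FitConfig):
    names = param_names(spec)
    table = default_bounds(recs, spec.endpoint)
    if config.bounds:
        table = {**table, **config.bounds}
    missing = [nm for nm in names if nm not in table]
    if missing:
        raise ValueError(f"no bounds for parameters {missing} of {spec.name}")
    lo = np.array([table[nm][0] for nm in names])
    hi = np.array([table[nm][1] for nm in names])
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy lo < hi")
    return lo, hi


# ---------------------------------------------------------------------------
# annealer
# ---------------------------------------------------------------------------

_INIT_HINTS = {  # data-independent starting values (clipped into bounds)
    "z": 0.3, "a2": 0.0, "a3": 0.0,
    "t2": 1.0, "p2": 1.0, "n2": 1.0, "s2": 1.0, "s3": 0.3,
    "a": 0.97, "zc1": 0.5, "zc2": 0.1, "zc3": 1e-3, "zc4": 1.0,
    "br1": 0.1, "br2": 1.0, "br3": 0.5,
    "z2": 2.0, "ba2": 2.0, "bl2": 2.0,
}


def _initial_point(names, lo, hi, recs: TreeArrays) -> np.ndarray:
    """Data-informed start: modifier locations at covariate medians."""
    med = {
        "t1": float(np.median(recs.T)), "p1": float(np.median(recs.P)),
        "n1": float(np.median(recs.N)),
        "s1": float(np.median(np.maximum(recs.S, 0.01))),
        "z1": float(np.median(recs.size_m)),
        "ba1": float(np.median(recs.BA)),
        "bl1": float(np.median(recs.BAL + 1.0)),
    }
    x = np.empty(len(names))
    for i, nm in enumerate(names):
        if nm in med:
            v = med[nm]
        elif nm in _INIT_HINTS:
            v = _INIT_HINTS[nm]
        else:
            v = 0.5 * (lo[i] + hi[i])
        x[i] = min(max(v, lo[i]), hi[i])
    return x


def _anneal(objective, lo, hi, n_iter, rng, cooling, x0=None):
    """One annealing run: returns (best_x, best_f, f_initial)."""
    d = lo.size
    span = hi - lo
    # feasible start
    x = f = None
    if x0 is not None:
        f0 = objective(x0)
        if math.isfinite(f0):
            x, f = np.asarray(x0, dtype=float).copy(), f0
    if x is None:
        for _ in range(200):
            cand = lo + span * rng.random(d)
            fc = objective(cand)
            if math.isfinite(fc):
                x, f = cand, fc
                break
    if x is None:
        return None, -math.inf, -math.inf
    f0 = f
    best_x, best_f = x.copy(), f
    # initial temperature from the dispersion of a short random probe
    probe = [f]
    for _ in range(20):
        fc = objective(lo + span * rng.random(d))
        if math.isfinite(fc):
            probe.append(fc)
    t0 = min(max(float(np.std(probe)), 1e-2), 1e4)
    alpha = cooling.get("t_ratio", 1e-8) ** (1.0 / max(n_iter, 2))
    adapt_every = cooling.get("adapt_every", 60)
    target = cooling.get("target_accept", 0.4)

    width = np.full(d, 0.25)
    accepted = np.zeros(d)
    proposed = np.zeros(d)
    temp = t0
    for it in range(n_iter):
        j = it % d
        step = width[j] * span[j] * rng.standard_normal()
        xc = x.copy()
        xc[j] = min(max(xc[j] + step, lo[j]), hi[j])
        fc = objective(xc)
        proposed[j] += 1
        if math.isfinite(fc) and (fc >= f or rng.random() < math.exp((fc - f) / temp)):
            x, f = xc, fc
            accepted[j] += 1
            if f > best_f:
                best_x, best_f = x.copy(), f
        temp *= alpha
        if proposed[j] >= adapt_every:
            rate = accepted[j] / proposed[j]
            if rate > target:
                width[j] = min(width[j] * 1.5, 2.0)
            elif rate < target / 2:
                width[j] = max(width[j] / 1.5, 1e-5)
            accepted[j] = proposed[j] = 0.0
    return best_x, best_f, f0


_LOG_2PI = math.log(2.0 * math.pi)


def _growth_shape_eval(recs: TreeArrays, spec: ModelSpec, names):
    """Fast evaluator of the growth mean with a=1 over a free-parameter vector.

    Precomputes the log-covariates once; algebraically identical to
    :func:`treecl.core.growth_mean` (asserted by tests to 1e-12).
    """
    from .core import DEPOSITION_FLOOR

    ln_m = np.log(recs.size_m)
    BAL = np.asarray(recs.BAL, dtype=float)
    ln_BA = np.log(recs.BA)
    ln_T = np.log(recs.T)
    ln_P = np.log(recs.P)
    ln_N = np.log(np.maximum(recs.N, DEPOSITION_FLOOR))
    S = np.asarray(recs.S, dtype=float)
    ln_S = np.log(np.maximum(S, DEPOSITION_FLOOR))
    ix = {nm: i for i, nm in enumerate(names)}

    def evaluate(x):
        lm = (x[ix["z"]] * ln_m + x[ix["a2"]] * BAL + x[ix["a3"]] * ln_BA
              - 0.5 * ((ln_T - math.log(x[ix["t1"]])) / x[ix["t2"]]) ** 2
              - 0.5 * ((ln_P - math.log(x[ix["p1"]])) / x[ix["p2"]]) ** 2)
        if spec.has_N:
            lm = lm - 0.5 * ((ln_N - math.log(x[ix["n1"]])) / x[ix["n2"]]) ** 2
        if spec.s_form == "lognormal":
            lm = lm - 0.5 * ((ln_S - math.log(x[ix["s1"]])) / x[ix["s2"]]) ** 2
        g = np.exp(lm)
        if spec.s_form == "sigmoid":
            s3 = x[ix["s3"]]
            g = g * (s3 + (1.0 - s3) / (1.0 + (S / x[ix["s1"]]) ** x[ix["s2"]]))
        return g

    return evaluate


def _survival_ll_eval(recs: TreeArrays, spec: ModelSpec, names):
    """Fast Bernoulli log-likelihood over a full survival parameter vector.

    Mirrors :func:`treecl.core.annual_survival` raised to dt (asserted by
    tests); returns -inf when the annual multiplier leaves (0, 1] or any
    interval probability leaves (0, 1).
    """
    from .core import DEPOSITION_FLOOR

    size = np.asarray(recs.size_m, dtype=float)
    ln_size = np.log(size)
    BA = np.asarray(recs.BA, dtype=float)
    ln_BA = np.log(BA)
    ln_BAL1 = np.log(recs.BAL + 1.0)
    ba_ratio = np.asarray(recs.BAL / recs.BA, dtype=float)
    ln_T = np.log(recs.T)
    ln_P = np.log(recs.P)
    ln_N = np.log(np.maximum(recs.N, DEPOSITION_FLOOR))
    S = np.asarray(recs.S, dtype=float)
    ln_S = np.log(np.maximum(S, DEPOSITION_FLOOR))
    dt = np.asarray(recs.dt, dtype=float)
    y = np.asarray(recs.survived_y, dtype=float)
    ix = {nm: i for i, nm in enumerate(names)}

    def evaluate(x):
        if spec.is_intercept_only:
            bracket = np.full(size.shape, x[ix["a"]])
            if np.any(bracket > 1.0 + 1e-12) or np.any(bracket <= 0.0):
                return -math.inf
            p = np.exp(dt * np.log(bracket))
            if np.any(p >= 1.0) or np.any(p <= 0.0):
                return -math.inf
            return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
        lm = (- 0.5 * ((ln_T - math.log(x[ix["t1"]])) / x[ix["t2"]]) ** 2
              - 0.5 * ((ln_P - math.log(x[ix["p1"]])) / x[ix["p2"]]) ** 2)
        if spec.has_N:
            lm = lm - 0.5 * ((ln_N - math.log(x[ix["n1"]])) / x[ix["n2"]]) ** 2
        if spec.s_form == "lognormal":
            lm = lm - 0.5 * ((ln_S - math.log(x[ix["s1"]])) / x[ix["s2"]]) ** 2
        if spec.competition_form == "A":
            bracket = (x[ix["a"]]
                       * (1.0 - x[ix["zc1"]] * np.exp(-x[ix["zc2"]] * size))
                       * np.exp(-x[ix["zc3"]] * size ** x[ix["zc4"]]
                                - x[ix["br1"]] * ba_ratio ** x[ix["br2"]]
                                * BA ** x[ix["br3"]] + lm))
        else:
            lm = (lm
                  - 0.5 * ((ln_size - math.log(x[ix["z1"]])) / x[ix["z2"]]) ** 2
                  - 0.5 * ((ln_BA - math.log(x[ix["ba1"]])) / x[ix["ba2"]]) ** 2
                  - 0.5 * ((ln_BAL1 - math.log(x[ix["bl1"]])) / x[ix["bl2"]]) ** 2)
            bracket = x[ix["a"]] * np.exp(lm)
        if spec.s_form == "sigmoid":
            s3 = x[ix["s3"]]
            bracket = bracket * (s3 + (1.0 - s3)
                                 / (1.0 + (S / x[ix["s1"]]) ** x[ix["s2"]]))
        if np.any(bracket > 1.0 + 1e-12) or np.any(bracket <= 0.0):
            return -math.inf
        p = np.exp(dt * np.log(bracket))
        if np.any(p >= 1.0) or np.any(p <= 0.0):
            return -math.inf
        return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))

    return evaluate


def _gaussian_ll(resid: np.ndarray, sigma: float) -> float:
    n = resid.size
    return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma))
                 - 0.5 * float(resid @ resid) / (sigma * sigma))


def fit_model(recs: TreeArrays, spec: ModelSpec, config: FitConfig) -> FitResult:
    """Fit one candidate model to one unit's records by simulated annealing.

    For growth models the potential rate ``a`` and residual SD ``sigma``
    enter the Gaussian likelihood linearly/analytically, so their exact ML
    values given the remaining parameters are computed in closed form inside
    the objective (profile likelihood); the annealer searches only the
    nonlinear shape parameters.  Survival models are annealed over the full
    parameter vector.

    Deterministic given ``config.seed``; the returned parameters never leave
    the bounds, and the returned objective is at least that of the initial
    feasible point.  An all-infeasible search yields ``converged=False`` with
    ``logLik=-inf`` (such fits are dropped from candidate sets).
    """
    n = len(recs)
    if n < config.min_trees:
        raise ValueError(
            f"unit has {n} trees, below the min_trees cutoff of {config.min_trees}")
    names = param_names(spec)
    lo, hi = _bounds_for(spec, recs, config)

    if spec.endpoint == "growth":
        return _fit_growth(recs, spec, config, names, lo, hi)
    return _fit_anneal_full(recs, spec, config, names, lo, hi)


def _fit_growth(recs, spec, config, names, lo, hi) -> FitResult:
    n = len(recs)
    G = np.asarray(recs.growth_G, dtype=float)
    ia, isig = names.index("a"), names.index("sigma")
    a_lo, a_hi = lo[ia], hi[ia]
    s_lo, s_hi = lo[isig], hi[isig]
    free = [i for i in range(len(names)) if i not in (ia, isig)]

    free_names = [names[i] for i in free]
    shape_eval = _growth_shape_eval(recs, spec, free_names)

    def profiled(x_free):
        """(logLik, a_hat, sigma_hat) with a and sigma at their ML values."""
        g = shape_eval(x_free)
        if not np.all(np.isfinite(g)):
            return -math.inf, None, None
        denom = float(g @ g)
        if denom <= 0:
            return -math.inf, None, None
        a_hat = min(max(float(G @ g) / denom, a_lo), a_hi)
        resid = G - a_hat * g
        sigma_hat = min(max(math.sqrt(float(resid @ resid) / n), s_lo), s_hi)
        return _gaussian_ll(resid, sigma_hat), a_hat, sigma_hat

    if not free:  # intercept-only: closed-form Gaussian location-scale ML
        a_hat = min(max(float(np.mean(G)), a_lo), a_hi)
        resid = G - a_hat
        sigma_hat = min(max(math.sqrt(float(resid @ resid) / n), s_lo), s_hi)
        ll = _gaussian_ll(resid, sigma_hat)
        params = params_from_vector(spec, [a_hat, sigma_hat])
        return FitResult(spec, params, ll, aic(ll, spec.k), n, True, config.seed)

    def objective(x):
        return profiled(x)[0]

    best_x, best_f = _run_restarts(objective, lo[free], hi[free], names, free,
                                   recs, config)
    if best_x is None:
        return FitResult(spec, None, -math.inf, math.inf, n, False, config.seed)
    ll, a_hat, sigma_hat = profiled(best_x)
    full = np.empty(len(names))
    full[free] = best_x
    full[ia], full[isig] = a_hat, sigma_hat
    return FitResult(spec, params_from_vector(spec, full), ll,
                     aic(ll, spec.k), n, True, config.seed)


def _fit_anneal_full(recs, spec, config, names, lo, hi) -> FitResult:
    n = len(recs)
    objective = _survival_ll_eval(recs, spec, names)
    best_x, best_f = _run_restarts(objective, lo, hi, names, None, recs, config)
    converged = best_x is not None and math.isfinite(best_f)
    params = params_from_vector(spec, best_x) if converged else None
    ll = best_f if converged else -math.inf
    return FitResult(spec, params, ll,
                     aic(ll, spec.k) if converged else math.inf,
                     n, converged, config.seed)


def _run_restarts(objective, lo, hi, names, free_idx, recs, config):
    """Best-of-restarts annealing; restart 0 starts from the data-informed point."""
    sub_names = [names[i] for i in free_idx] if free_idx is not None else names
    restarts = max(config.restarts, 1)
    per = max(config.iterations // restarts, 1)
    x_init = _initial_point(sub_names, lo, hi, recs)
    best_x, best_f = None, -math.inf
    for r in range(restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed % (2**31), r]))
        x0 = x_init if r == 0 else None
        x, fval, _ = _anneal(objective, lo, hi, per, rng, config.cooling, x0=x0)
        if fval > best_f:
            best_x, best_f = x, fval
    return best_x, best_f


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _n_dep_terms(spec: ModelSpec) -> int:
    return int(spec.has_N) + int(spec.has_S)


def select_model(fits: Sequence[FitResult], ns_r: float, config: FitConfig,
                 species: str = "", division: str = "",
                 endpoint: str = "") -> SelectionOutcome:
    """Apply the candidate-window selection rule to one unit's fits.

    Candidates are the converged fits within ``delta_aic`` of the best AIC.
    If any candidate carries both an N and an S term, the lowest-AIC such
    candidate wins (separate deposition effects are preferred even at a small
    AIC cost).  Otherwise the lowest-AIC candidate wins — unless the unit's
    N-S correlation reaches the threshold and some candidate carries exactly
    one deposition term, in which case N and S effects cannot be attributed
    and the unit is excluded.  Ties break on fewer parameters, then on family
    enumeration order.
    """
    fits = [f for f in fits if f.converged and math.isfinite(f.logLik)]
    if not fits:
        return SelectionOutcome(species, division, endpoint,
                                status="insufficient_data",
                                ns_correlation=ns_r)
    order = {id(f): i for i, f in enumerate(fits)}
    best_aic = min(f.AIC for f in fits)
    cands = [f for f in fits if f.AIC - best_aic <= config.delta_aic]
    cands.sort(key=lambda f: (f.AIC, f.spec.k, order[id(f)]))
    joint = [f for f in cands if f.spec.has_N and f.spec.has_S]
    if joint:
        chosen = joint[0]
    else:
        deposition_in_play = any(_n_dep_terms(f.spec) == 1 for f in cands)
        collinear = ns_r is not None and not math.isnan(ns_r) \
            and ns_r >= config.ns_corr_threshold
        if collinear and deposition_in_play:
            return SelectionOutcome(species, division, endpoint,
                                    status="excluded_ns_collinearity",
                                    candidate_set=cands,
                                    ns_correlation=ns_r)
        chosen = cands[0]
    return SelectionOutcome(species, division, endpoint, status="selected",
                            selected_fit=chosen, candidate_set=cands,
                            ns_correlation=ns_r)
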