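"""Response-curve mathematics for tree growth and survival under N and S deposition.

Growth of an individual tree is modelled as a potential rate ``a`` multiplied
by bounded modifier terms for tree size, competition, temperature,
precipitation, nitrogen deposition and sulfur deposition.  Annual survival is
modelled analogously as a baseline multiplier reduced by the same kinds of
modifiers, raised to the census interval in years.  Climate and N terms are
two-parameter lognormal curves peaking at a location ``c1`` with ln-scale
width ``c2``; the S term is either a declining sigmoid (no effect at low
deposition, decline around ``s1``, plateau at ``s3``) or a lognormal
constrained to its decreasing limb.

All mean functions accept either a single :class:`TreeRecord` or any object
exposing the same field names as numpy arrays (see :class:`TreeArrays`), so
the identical code path serves scalar examples and vectorised likelihood
evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DEPOSITION_FLOOR",
    "TreeRecord",
    "TreeArrays",
    "ModelSpec",
    "GrowthParams",
    "SurvivalParams",
    "FitResult",
    "DomainError",
    "SpecificationError",
    "InfeasibleParameters",
    "lognormal_modifier",
    "sulfur_sigmoid",
    "growth_mean",
    "survival_prob",
    "log_likelihood",
    "enumerate_models",
    "param_names",
    "params_from_vector",
    "params_to_vector",
]

#: Floor applied to N (and to S under the lognormal form) before taking logs,
#: in kg ha^-1 yr^-1.  Zero deposition is legal input; the lognormal modifier
#: is not defined at zero.
DEPOSITION_FLOOR = 0.01


class DomainError(ValueError):
    """An input lies outside the mathematical domain of a modifier."""


class SpecificationError(ValueError):
    """A parameter required by the model specification is missing."""


class InfeasibleParameters(ValueError):
    """Parameters imply an annual survival multiplier above one."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TreeRecord:
    """One tree's covariates plus its growth rate or survival outcome.

    Units: ``size_m`` kg C; ``growth_G`` kg C tree^-1 yr^-1 (may be negative);
    ``dt`` years; ``BA``/``BAL`` m^2 ha^-1; ``T`` K; ``P`` dm;
    ``N``/``S`` kg ha^-1 yr^-1.
    """

    tree_id: str
    species: str
    division: str
    plot_id: str
    size_m: float
    dt: float
    BA: float
    BAL: float
    T: float
    P: float
    N: float
    S: float
    growth_G: Optional[float] = None
    survived_y: Optional[int] = None

    def __post_init__(self) -> None:
        if self.size_m <= 0:
            raise DomainError("size_m must be positive")
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.BA <= 0:
            raise DomainError("BA must be positive")
        if not (0 <= self.BAL <= self.BA):
            raise DomainError("BAL must lie in [0, BA]")
        if self.T <= 0 or self.P <= 0:
            raise DomainError("T and P must be positive")
        if self.N <= 0:
            raise DomainError("N must be positive")
        if self.S < 0:
            raise DomainError("S must be non-negative")
        if self.survived_y is not None and self.survived_y not in (0, 1):
            raise DomainError("survived_y must be 0 or 1")


@dataclass
class TreeArrays:
    """Struct-of-arrays view of a set of tree records (vectorised evaluation)."""

    size_m: np.ndarray
    dt: np.ndarray
    BA: np.ndarray
    BAL: np.ndarray
    T: np.ndarray
    P: np.ndarray
    N: np.ndarray
    S: np.ndarray
    growth_G: Optional[np.ndarray] = None
    survived_y: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return int(np.asarray(self.size_m).shape[0])


#: CSV column name -> TreeArrays field name
CSV_COLUMNS = {
    "size_kgC": "size_m",
    "dt_yr": "dt",
    "ba_m2ha": "BA",
    "bal_m2ha": "BAL",
    "temp_K": "T",
    "precip_dm": "P",
    "ndep_kgN_ha_yr": "N",
    "sdep_kgS_ha_yr": "S",
    "growth_kgC_yr": "growth_G",
    "survived": "survived_y",
}


def to_arrays(df) -> TreeArrays:
    """Build a :class:`TreeArrays` from a DataFrame with the canonical columns."""
    kw = {}
    for col, name in CSV_COLUMNS.items():
        if col in df.columns:
            kw[name] = np.asarray(df[col], dtype=float)
    return TreeArrays(**kw)


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    ``k`` counts every fitted parameter, including the growth residual SD.
    ``competition_form`` distinguishes the two survival competition
    representations and is ``None`` for growth and for the survival
    intercept-only model.
    """

    endpoint: str  # "growth" | "survival"
    has_N: bool
    s_form: str  # "none" | "sigmoid" | "lognormal"
    competition_form: Optional[str] = None  # "A" | "B" | None
    is_intercept_only: bool = False

    @property
    def k(self) -> int:
        return len(param_names(self))

    @property
    def has_S(self) -> bool:
        return self.s_form != "none"

    @property
    def name(self) -> str:
        if self.is_intercept_only:
            return f"{self.endpoint}:intercept"
        parts = ["base"]
        if self.has_N:
            parts.append("N")
        if self.s_form != "none":
            parts.append(f"S-{self.s_form}")
        tag = "+".join(parts)
        if self.competition_form:
            tag += f":{self.competition_form}"
        return f"{self.endpoint}:{tag}"


_GROWTH_BASE = ["a", "z", "a2", "a3", "t1", "t2", "p1", "p2"]
_SURV_BASE_A = ["a", "zc1", "zc2", "zc3", "zc4", "br1", "br2", "br3",
                "t1", "t2", "p1", "p2"]
_SURV_BASE_B = ["a", "z1", "z2", "ba1", "ba2", "bl1", "bl2",
                "t1", "t2", "p1", "p2"]


def param_names(spec: ModelSpec) -> list[str]:
    """Ordered free-parameter names for a spec (growth includes ``sigma``)."""
    if spec.endpoint == "growth":
        if spec.is_intercept_only:
            return ["a", "sigma"]
        names = list(_GROWTH_BASE)
    elif spec.endpoint == "survival":
        if spec.is_intercept_only:
            return ["a"]
        if spec.competition_form == "A":
            names = list(_SURV_BASE_A)
        elif spec.competition_form == "B":
            names = list(_SURV_BASE_B)
        else:
            raise SpecificationError("survival spec requires competition_form")
    else:
        raise SpecificationError(f"unknown endpoint {spec.endpoint!r}")
    if spec.has_N:
        names += ["n1", "n2"]
    if spec.s_form == "sigmoid":
        names += ["s1", "s2", "s3"]
    elif spec.s_form == "lognormal":
        names += ["s1", "s2"]
    if spec.endpoint == "growth":
        names.append("sigma")
    return names


@dataclass
class GrowthParams:
    """Parameters of the growth mean function plus the residual SD ``sigma``."""

    a: float
    z: Optional[float] = None
    a2: Optional[float] = None
    a3: Optional[float] = None
    t1: Optional[float] = None
    t2: Optional[float] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    n1: Optional[float] = None
    n2: Optional[float] = None
    s1: Optional[float] = None
    s2: Optional[float] = None
    s3: Optional[float] = None
    sigma: Optional[float] = None


@dataclass
class SurvivalParams:
    """Parameters of the annual survival multiplier (forms A and B)."""

    a: float
    # form A size / competition
    zc1: Optional[float] = None
    zc2: Optional[float] = None
    zc3: Optional[float] = None
    zc4: Optional[float] = None
    br1: Optional[float] = None
    br2: Optional[float] = None
    br3: Optional[float] = None
    # form B size / competition
    z1: Optional[float] = None
    z2: Optional[float] = None
    ba1: Optional[float] = None
    ba2: Optional[float] = None
    bl1: Optional[float] = None
    bl2: Optional[float] = None
    # shared climate / deposition
    t1: Optional[float] = None
    t2: Optional[float] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    n1: Optional[float] = None
    n2: Optional[float] = None
    s1: Optional[float] = None
    s2: Optional[float] = None
    s3: Optional[float] = None


def params_from_vector(spec: ModelSpec, x: Sequence[float]):
    """Materialise a params object from a flat vector in ``param_names`` order."""
    names = param_names(spec)
    if len(x) != len(names):
        raise SpecificationError(
            f"expected {len(names)} parameters for {spec.name}, got {len(x)}")
    kw = dict(zip(names, (float(v) for v in x)))
    cls = GrowthParams if spec.endpoint == "growth" else SurvivalParams
    return cls(**kw)


def params_to_vector(spec: ModelSpec, params) -> np.ndarray:
    names = param_names(spec)
    out = []
    for nm in names:
        v = getattr(params, nm, None)
        if v is None:
            raise SpecificationError(f"{spec.name} requires parameter {nm!r}")
        out.append(float(v))
    return np.asarray(out)


@dataclass
class FitResult:
    spec: ModelSpec
    params: object
    logLik: float
    AIC: float
    n_obs: int
    converged: bool
    seed: int
    best_objective_trace: Optional[list] = None

    def __post_init__(self) -> None:
        if self.converged and math.isfinite(self.logLik):
            assert abs(self.AIC - (2 * self.spec.k - 2 * self.logLik)) < 1e-9


# ---------------------------------------------------------------------------
# modifier terms
# ---------------------------------------------------------------------------


def lognormal_modifier(x, c1: float, c2: float, symbol: str = "x"):
    """Two-parameter lognormal modifier ``exp(-0.5*(ln(x/c1)/c2)**2)``.

    Peaks at 1 when ``x == c1``; ``c2`` is the ln-scale width.  Bounded in
    (0, 1].
    """
    x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
    if np.any(np.asarray(x) <= 0):
        raise DomainError(f"{symbol} must be positive for the lognormal modifier")
    if c1 <= 0 or c2 <= 0:
        raise DomainError(f"location/width for {symbol} must be positive")
    return np.exp(-0.5 * (np.log(x / c1) / c2) ** 2)


def sulfur_sigmoid(S, s1: float, s2: float, s3: float):
    """Declining sigmoid S term ``s3 + (1-s3)/(1 + (S/s1)**s2)``.

    Equals 1 at S=0, passes the halfway point ``s3 + (1-s3)/2`` at ``S == s1``
    and plateaus at ``s3`` as S grows.  Strictly decreasing in S.
    """
    if s1 <= 0 or s2 <= 0:
        raise DomainError("s1 and s2 must be positive")
    if not (0 <= s3 < 1):
        raise DomainError("s3 must lie in [0, 1)")
    S = np.asarray(S, dtype=float) if np.ndim(S) else float(S)
    if np.any(np.asarray(S) < 0):
        raise DomainError("S must be non-negative")
    return s3 + (1.0 - s3) / (1.0 + (S / s1) ** s2)


def _need(params, names: Iterable[str], spec: ModelSpec) -> None:
    for nm in names:
        if getattr(params, nm, None) is None:
            raise SpecificationError(f"{spec.name} requires parameter {nm!r}")


def _s_term(spec: ModelSpec, params, S, floor: float):
    if spec.s_form == "sigmoid":
        _need(params, ("s1", "s2", "s3"), spec)
        return sulfur_sigmoid(S, params.s1, params.s2, params.s3)
    if spec.s_form == "lognormal":
        _need(params, ("s1", "s2"), spec)
        return lognormal_modifier(np.maximum(S, floor), params.s1, params.s2, "S")
    return 1.0


def _n_term(spec: ModelSpec, params, N, floor: float):
    if spec.has_N:
        _need(params, ("n1", "n2"), spec)
        return lognormal_modifier(np.maximum(N, floor), params.n1, params.n2, "N")
    return 1.0


# ---------------------------------------------------------------------------
# mean functions and likelihood
# ---------------------------------------------------------------------------


def growth_mean(rec, spec: ModelSpec, params: GrowthParams,
                floor: float = DEPOSITION_FLOOR):
    """Expected growth rate (kg C tree^-1 yr^-1) under a growth spec.

    Terms excluded from the spec are inert: the corresponding covariates do
    not enter the product at all.
    """
    if spec.endpoint != "growth":
        raise SpecificationError("growth_mean requires a growth spec")
    if spec.is_intercept_only:
        shape = np.shape(np.asarray(rec.size_m))
        return params.a if not shape else np.full(shape, params.a)
    _need(params, _GROWTH_BASE[:-4] + ["t1", "t2", "p1", "p2"], spec)
    m, BAL, BA = rec.size_m, rec.BAL, rec.BA
    mu = (params.a
          * np.power(m, params.z)
          * np.exp(params.a2 * BAL + params.a3 * np.log(BA))
          * lognormal_modifier(rec.T, params.t1, params.t2, "T")
          * lognormal_modifier(rec.P, params.p1, params.p2, "P"))
    mu = mu * _n_term(spec, params, rec.N, floor)
    mu = mu * _s_term(spec, params, rec.S, floor)
    return mu


def annual_survival(rec, spec: ModelSpec, params: SurvivalParams,
                    floor: float = DEPOSITION_FLOOR):
    """Annual survival multiplier (the bracketed term, before the time exponent)."""
    if spec.endpoint != "survival":
        raise SpecificationError("annual_survival requires a survival spec")
    if spec.is_intercept_only:
        shape = np.shape(np.asarray(rec.size_m))
        return params.a if not shape else np.full(shape, params.a)
    if spec.competition_form == "A":
        _need(params, ("zc1", "zc2", "zc3", "zc4", "br1", "br2", "br3"), spec)
        size = rec.size_m
        ba_ratio = rec.BAL / rec.BA  # dimensionless crowding index in [0, 1]
        s = (params.a
             * (1.0 - params.zc1 * np.exp(-params.zc2 * size))
             * np.exp(-params.zc3 * np.power(size, params.zc4))
             * np.exp(-params.br1 * np.power(ba_ratio, params.br2)
                      * np.power(rec.BA, params.br3)))
    elif spec.competition_form == "B":
        _need(params, ("z1", "z2", "ba1", "ba2", "bl1", "bl2"), spec)
        s = (params.a
             * lognormal_modifier(rec.size_m, params.z1, params.z2, "size")
             * lognormal_modifier(rec.BA, params.ba1, params.ba2, "BA")
             * lognormal_modifier(rec.BAL + 1.0, params.bl1, params.bl2, "BAL+1"))
    else:
        raise SpecificationError("survival spec requires competition_form A or B")
    _need(params, ("t1", "t2", "p1", "p2"), spec)
    s = s * lognormal_modifier(rec.T, params.t1, params.t2, "T")
    s = s * lognormal_modifier(rec.P, params.p1, params.p2, "P")
    s = s * _n_term(spec, params, rec.N, floor)
    s = s * _s_term(spec, params, rec.S, floor)
    return s


def survival_prob(rec, spec: ModelSpec, params: SurvivalParams,
                  floor: float = DEPOSITION_FLOOR):
    """Probability of surviving the record's census interval.

    The annual multiplier is raised to ``dt`` in years; the 10-year reporting
    scale is :func:`survival_prob_10yr`.  Raises
    :class:`InfeasibleParameters` if the multiplier exceeds 1 anywhere (the
    fitter treats that as a rejection).
    """
    s = annual_survival(rec, spec, params, floor)
    if np.any(np.asarray(s) > 1.0 + 1e-12):
        raise InfeasibleParameters("annual survival multiplier exceeds 1")
    return np.power(np.clip(s, 0.0, 1.0), rec.dt)


def survival_prob_10yr(rec, spec: ModelSpec, params: SurvivalParams,
                       floor: float = DEPOSITION_FLOOR):
    """Survival probability on the 10-year reporting scale (multiplier^10)."""
    s = annual_survival(rec, spec, params, floor)
    if np.any(np.asarray(s) > 1.0 + 1e-12):
        raise InfeasibleParameters("annual survival multiplier exceeds 1")
    return np.power(np.clip(s, 0.0, 1.0), 10.0)


_LOG_2PI = math.log(2.0 * math.pi)


def log_likelihood(recs, spec: ModelSpec, params,
                   floor: float = DEPOSITION_FLOOR) -> float:
    """Log-likelihood of a record collection under a spec and parameter set.

    Growth observations are Gaussian around the mean with SD ``sigma``;
    survival outcomes are Bernoulli with the interval survival probability.
    Any record with an out-of-range probability yields ``-inf`` (a rejection
    signal for the optimiser), never an exception.
    """
    if spec.endpoint == "growth":
        sigma = params.sigma
        if sigma is None or sigma <= 0:
            raise SpecificationError("growth likelihood requires sigma > 0")
        G = np.asarray(recs.growth_G, dtype=float)
        mu = np.asarray(growth_mean(recs, spec, params, floor), dtype=float)
        if not np.all(np.isfinite(mu)):
            return -np.inf
        resid = G - mu
        n = resid.size
        return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma))
                     - 0.5 * float(resid @ resid) / (sigma * sigma))
    try:
        p = np.asarray(survival_prob(recs, spec, params, floor), dtype=float)
    except InfeasibleParameters:
        return -np.inf
    y = np.asarray(recs.survived_y, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        return -np.inf
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# candidate model families
# ---------------------------------------------------------------------------

_STRUCTURES = [  # (has_N, s_form), in increasing complexity
    (False, "none"),       # base
    (True, "none"),        # base + N
    (False, "sigmoid"),    # base + S sigmoid
    (False, "lognormal"),  # base + S lognormal
    (True, "sigmoid"),     # base + N + S sigmoid
    (True, "lognormal"),   # base + N + S lognormal
]


def enumerate_models(endpoint: str) -> list[ModelSpec]:
    """The candidate family: 7 growth models, or 13 survival models.

    Growth: intercept-only, base, base+N, base+S (sigmoid or lognormal), and
    base+N+S (sigmoid or lognormal).  Survival: the same six structures
    crossed with the two competition representations, plus one intercept-only
    model (competition does not enter it).
    """
    if endpoint == "growth":
        specs = [ModelSpec("growth", False, "none", None, True)]
        specs += [ModelSpec("growth", n, s) for n, s in _STRUCTURES]
        return specs
    if endpoint == "survival":
        specs = [ModelSpec("survival", False, "none", None, True)]
        for has_n, s_form in _STRUCTURES:
            for form in ("A", "B"):
                specs.append(ModelSpec("survival", has_n, s_form, form))
        return specs
    raise SpecificationError(f"unknown endpoint {endpoint!r}")
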