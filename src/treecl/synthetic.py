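"""Synthetic forest-inventory data drawn from the package's own model equations.

The generator emulates the structure of a national remeasurement inventory:
species x Division units with at least several hundred trees each, plot
basal-area competition, Division-level climate/deposition gradients (higher
N and S deposition in the eastern Divisions, higher soil pH in the central
ones), census intervals of 8.2 +/- 2.9 years truncated to [5, 10], growth
generated as the model mean plus Gaussian noise, and survival outcomes drawn
from the annual survival multiplier raised to the interval length.  Every
dataset ships with a truth manifest recording the generative parameters, the
expected response shapes and the expected critical loads, so recovery can be
scored without reference data.

Also provided: ordinal shape datasets drawn from a known proportional-odds
model (for the stage-2 regressions) and Yule phylogenies with Brownian or
tip-shuffled traits (for the phylogenetic-signal test).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import GrowthParams, ModelSpec, SurvivalParams, TreeArrays
from .shapes import Shape, critical_load_sigmoid

__all__ = [
    "DIVISIONS",
    "DIVISION_GRADIENTS",
    "ScenarioConfig",
    "TruthManifest",
    "default_growth_truth",
    "default_survival_truth",
    "generate_trees",
    "generate_shape_dataset",
    "generate_phylogeny",
]

#: The 11 conterminous-U.S. Divisions used as regional fitting units.
DIVISIONS = ["21", "22", "23", "24", "25", "26", "31", "32", "33", "34", "41"]

#: Per-Division covariate gradients: mean T (K), P (dm), N and S deposition
#: (kg ha^-1 yr^-1) and soil pH.  Deposition rises toward the eastern
#: Divisions and pH toward the central ones; these are parameters of the
#: generator, not data.
DIVISION_GRADIENTS = {
    #        T      P     N     S    pH
    "21": (279.0, 10.0,  9.0, 7.0, 5.0),
    "22": (285.0, 11.0, 12.0, 9.0, 5.3),
    "23": (290.0, 13.0, 11.0, 8.0, 5.3),
    "24": (283.0, 16.0,  4.0, 2.0, 5.6),
    "25": (285.0,  8.0, 10.0, 6.0, 6.2),
    "26": (287.0,  6.0,  6.0, 3.0, 6.5),
    "31": (289.0,  5.0,  5.0, 2.5, 7.6),
    "32": (293.0,  4.0,  4.0, 2.0, 7.7),
    "33": (282.0,  5.0,  6.0, 3.0, 7.0),
    "34": (284.0,  4.0,  5.0, 2.5, 7.2),
    "41": (296.0, 13.0,  8.0, 5.0, 5.5),
}


def default_growth_truth(division: str, structure: str = "base+N+S-sigmoid"
                         ) -> tuple[ModelSpec, GrowthParams]:
    """Strong-effect generative growth model for one Division.

    The N peak (n1) sits inside the Division's plausible deposition range and
    the S half-decline (s1) near its mean S, so deposition effects are well
    expressed over the sampled covariates.
    """
    T, P, N, S, _ = DIVISION_GRADIENTS[division]
    has_n = "N" in structure.split("+")
    s_form = ("sigmoid" if "S-sigmoid" in structure
              else "lognormal" if "S-lognormal" in structure else "none")
    spec = ModelSpec("growth", has_n, s_form)
    kw = dict(a=3.0, z=0.33, a2=-0.01, a3=-0.05,
              t1=T, t2=0.05, p1=P, p2=0.9, sigma=0.4)
    if has_n:
        kw.update(n1=12.0, n2=0.5)
    if s_form == "sigmoid":
        kw.update(s1=max(S, 1.0), s2=2.0, s3=0.3)
    elif s_form == "lognormal":
        kw.update(s1=0.4, s2=2.5)  # below observed S: decreasing limb only
    return spec, GrowthParams(**kw)


def default_survival_truth(division: str, structure: str = "base+N+S-sigmoid",
                           form: str = "B") -> tuple[ModelSpec, SurvivalParams]:
    """Generative survival model (annual multiplier near 0.98) for one Division."""
    T, P, N, S, _ = DIVISION_GRADIENTS[division]
    has_n = "N" in structure.split("+")
    s_form = ("sigmoid" if "S-sigmoid" in structure
              else "lognormal" if "S-lognormal" in structure else "none")
    spec = ModelSpec("survival", has_n, s_form, competition_form=form)
    kw = dict(a=0.998, t1=T, t2=6.0, p1=P, p2=6.0)
    if form == "B":
        kw.update(z1=150.0, z2=8.0, ba1=25.0, ba2=8.0, bl1=10.0, bl2=8.0)
    else:
        kw.update(zc1=0.2, zc2=0.05, zc3=1e-5, zc4=1.0,
                  br1=0.005, br2=1.0, br3=0.5)
    if has_n:
        kw.update(n1=max(N, 2.0), n2=4.0)
    if s_form == "sigmoid":
        kw.update(s1=max(S, 1.0), s2=2.0, s3=0.95)
    elif s_form == "lognormal":
        kw.update(s1=0.4, s2=8.0)
    return spec, SurvivalParams(**kw)


@dataclass
class ScenarioConfig:
    """Study conditions for a generated dataset.

    ``structures`` assigns, per species (cycled), the generative model
    structure used in every Division the species occupies.  ``ns_corr`` sets
    the per-Division log-scale correlation between tree-level N and S
    deposition (the knob that exercises the collinearity exclusion rule).
    """

    divisions: Sequence[str] = field(default_factory=lambda: list(DIVISIONS))
    n_species: int = 8
    occupancy: Optional[dict] = None  # species -> list of divisions
    structures: Sequence[str] = ("base+N+S-sigmoid", "base+N", "base",
                                 "base+S-lognormal")
    survival_form: str = "B"
    n_trees_per_unit: int = 600
    trees_per_plot: int = 5
    dt_mean: float = 8.2
    dt_sd: float = 2.9
    dt_range: tuple = (5.0, 10.0)
    ns_corr: float = 0.4
    cov_sd_frac: float = 0.45   # log-scale SD of N and S draws
    trait_probs: tuple = (0.4, 0.6)  # P(AM), P(deciduous)
    inject_exclusions: float = 0.0   # fraction of harvested / dead-at-both rows
    true_params: Optional[dict] = None  # (species, division, endpoint) -> (spec, params)
    growth_for_all: bool = False  # record growth for dead trees too
    seed: int = 0

    def species_names(self) -> list[str]:
        return [f"SP{i:02d}" for i in range(1, self.n_species + 1)]

    def units(self) -> list[tuple[str, str]]:
        if self.occupancy:
            return [(sp, d) for sp, divs in self.occupancy.items() for d in divs]
        return [(sp, d) for sp in self.species_names() for d in self.divisions]

    @classmethod
    def small(cls, seed: int = 0) -> "ScenarioConfig":
        """The bundled small scenario: 4 species x 3 Divisions, 600 trees/unit."""
        return cls(divisions=["21", "25", "31"], n_species=4,
                   n_trees_per_unit=600, seed=seed)

    @classmethod
    def recovery(cls, seed: int = 0, n_trees: int = 2000) -> "ScenarioConfig":
        """One strong-effect unit for parameter-recovery experiments."""
        return cls(divisions=["22"], n_species=1,
                   structures=("base+N+S-sigmoid",),
                   n_trees_per_unit=n_trees, cov_sd_frac=0.55,
                   growth_for_all=True, seed=seed)


@dataclass
class TruthManifest:
    """Everything needed to score recovery on a generated dataset."""

    units: dict = field(default_factory=dict)
    stage2: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, Shape):
                return int(o)
            raise TypeError(f"not serializable: {o!r}")
        return json.dumps({"units": self.units, "stage2": self.stage2},
                          indent=1, default=default, sort_keys=True)


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _expected_shapes(spec, params, N, S):
    """Realized-range shape of the generative model (the recovery target)."""
    if spec.has_N:
        n1 = params.n1
        if n1 >= float(np.max(N)):
            n_shape = Shape.INCREASE
        elif n1 <= float(np.min(N)):
            n_shape = Shape.DECREASE
        else:
            n_shape = Shape.UNIMODAL_SIGMOID
    else:
        n_shape = Shape.FLAT
    if spec.s_form == "sigmoid":
        s_shape = Shape.UNIMODAL_SIGMOID
    elif spec.s_form == "lognormal":
        s_shape = Shape.DECREASE
    else:
        s_shape = Shape.FLAT
    return n_shape, s_shape


def generate_trees(config: ScenarioConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Generate tree records, a trait table and plot covariates, with truth.

    Returns ``(trees, traits, plot_covariates, manifest)``.  Tree sizes and
    plot basal areas are lognormal; BAL = u*BA with u ~ Beta(2, 2); growth is
    the model mean plus N(0, sigma) noise; survival outcomes are Bernoulli
    with p = (annual multiplier)^dt.  Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed % (2**31))
    units = config.units()
    unit_seeds = root.spawn(len(units) + 1)
    trait_rng = np.random.default_rng(unit_seeds[-1])

    p_am, p_dec = config.trait_probs
    traits = pd.DataFrame({
        "species": config.species_names(),
        "mycorrhiza": np.where(
            trait_rng.random(config.n_species) < p_am, "AM", "EcM"),
        "leaf_habit": np.where(
            trait_rng.random(config.n_species) < p_dec,
            "deciduous", "evergreen"),
    })

    structures = list(config.structures)
    species_structure = {sp: structures[i % len(structures)]
                         for i, sp in enumerate(config.species_names())}

    rows, plot_rows = [], []
    manifest = TruthManifest()
    tree_counter = 0
    for (sp, div), ss in zip(units, unit_seeds):
        rng = np.random.default_rng(ss)
        n = config.n_trees_per_unit
        Tm, Pm, Nm, Sm, pHm = DIVISION_GRADIENTS[div]
        structure = species_structure[sp]
        key_g = (sp, div, "growth")
        key_s = (sp, div, "survival")
        if config.true_params and key_g in config.true_params:
            gspec, gpar = config.true_params[key_g]
        else:
            gspec, gpar = default_growth_truth(div, structure)
        if config.true_params and key_s in config.true_params:
            sspec, spar = config.true_params[key_s]
        else:
            sspec, spar = default_survival_truth(div, structure,
                                                 config.survival_form)

        n_plots = max(1, math.ceil(n / config.trees_per_plot))
        plot_ids = [f"{sp}-{div}-P{i:04d}" for i in range(n_plots)]
        plot_BA = rng.lognormal(math.log(25.0), 0.4, n_plots)
        plot_T = _truncnorm(rng, Tm, 3.0, Tm - 12, Tm + 12, n_plots)
        plot_P = _truncnorm(rng, Pm, 0.15 * Pm, 0.4 * Pm, 2.5 * Pm, n_plots)
        plot_pH = np.clip(rng.normal(pHm, 0.3, n_plots), 3.8, 8.5)

        assign = np.arange(n) % n_plots
        sizes = rng.lognormal(math.log(150.0), 0.8, n)
        u = rng.beta(2.0, 2.0, n)
        BA = plot_BA[assign]
        BAL = u * BA
        T = plot_T[assign]
        P = plot_P[assign]
        # correlated lognormal N and S deposition
        sd = config.cov_sd_frac
        rho = config.ns_corr
        zz = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
        N = np.exp(math.log(Nm) - 0.5 * sd * sd + sd * zz[:, 0])
        S = np.exp(math.log(Sm) - 0.5 * sd * sd + sd * zz[:, 1])
        dt = _truncnorm(rng, config.dt_mean, config.dt_sd,
                        config.dt_range[0], config.dt_range[1], n)

        arrays = TreeArrays(size_m=sizes, dt=dt, BA=BA, BAL=BAL,
                            T=T, P=P, N=N, S=S)
        mu = np.asarray(core.growth_mean(arrays, gspec, gpar), dtype=float)
        G = mu + rng.normal(0.0, gpar.sigma, n) if gpar.sigma > 0 else mu.copy()
        bracket = np.asarray(core.annual_survival(arrays, sspec, spar),
                             dtype=float)
        if np.any(bracket > 1.0 + 1e-9):
            raise ValueError(
                f"unit {sp} x {div}: survival parameters imply an annual "
                "multiplier above 1 for sampled covariates")
        p_surv = np.clip(bracket, 0.0, 1.0) ** dt
        y = (rng.random(n) < p_surv).astype(int)

        harvested = np.zeros(n, dtype=int)
        dead_both = np.zeros(n, dtype=int)
        if config.inject_exclusions > 0:
            k = int(round(config.inject_exclusions * n))
            pick = rng.choice(n, size=min(2 * k, n), replace=False)
            harvested[pick[:k]] = 1
            dead_both[pick[k:2 * k]] = 1

        unit_df = pd.DataFrame({
            "tree_id": [f"T{tree_counter + i:07d}" for i in range(n)],
            "species": sp,
            "division": div,
            "plot_id": [plot_ids[a] for a in assign],
            "size_kgC": sizes,
            "growth_kgC_yr": (G if config.growth_for_all
                              else np.where(y == 1, G, np.nan)),
            "survived": y,
            "dt_yr": dt,
            "ba_m2ha": BA,
            "bal_m2ha": BAL,
            "temp_K": T,
            "precip_dm": P,
            "ndep_kgN_ha_yr": N,
            "sdep_kgS_ha_yr": S,
            "harvested": harvested,
            "dead_at_both": dead_both,
        })
        tree_counter += n
        rows.append(unit_df)

        # plot covariates on the stage-2 (long-term normals) scale
        plot_N = pd.DataFrame({"plot": assign, "N": N, "S": S}) \
            .groupby("plot")[["N", "S"]].mean()
        plot_rows.append(pd.DataFrame({
            "plot_id": plot_ids,
            "species": sp,
            "division": div,
            "mat_C": plot_T - 273.15,
            "map_mm": plot_P * 100.0,
            "soil_ph": plot_pH,
            "ndep": plot_N["N"].to_numpy(),
            "sdep": plot_N["S"].to_numpy(),
        }))

        n_shape, s_shape = _expected_shapes(gspec, gpar, N, S)
        sn_shape, ssv_shape = _expected_shapes(sspec, spar, N, S)
        entry = {
            "structure": structure,
            "growth": {"spec": gspec.name,
                       "params": dataclasses.asdict(gpar),
                       "expected_N_shape": int(n_shape),
                       "expected_S_shape": int(s_shape)},
            "survival": {"spec": sspec.name,
                         "params": dataclasses.asdict(spar),
                         "expected_N_shape": int(sn_shape),
                         "expected_S_shape": int(ssv_shape)},
            "N_range": [float(np.min(N)), float(np.max(N))],
            "S_range": [float(np.min(S)), float(np.max(S))],
        }
        for ep, pr in (("growth", gpar), ("survival", spar)):
            cls = {}
            spec_ep = gspec if ep == "growth" else sspec
            if spec_ep.has_N:
                cls["N"] = pr.n1
            if spec_ep.s_form == "lognormal":
                cls["S"] = pr.s1
            elif spec_ep.s_form == "sigmoid":
                f = 0.05 if ep == "growth" else 0.01
                cl = critical_load_sigmoid(pr.s1, pr.s2, pr.s3, f)
                cls["S"] = cl.value
            entry[ep]["expected_CL"] = cls
        manifest.units[f"{sp}|{div}"] = entry

    trees = pd.concat(rows, ignore_index=True)
    plots = pd.concat(plot_rows, ignore_index=True)
    return trees, traits, plots, manifest


# ---------------------------------------------------------------------------
# stage-2 shape dataset
# ---------------------------------------------------------------------------

DEFAULT_STAGE2_BETA = {"Ndep": 0.10, "leaf_habit": math.log(2.3)}
DEFAULT_STAGE2_THRESHOLDS = (-0.6, 1.2, 3.0)


def generate_shape_dataset(n_units: int = 268,
                           beta: Optional[dict] = None,
                           thresholds: Sequence[float] = DEFAULT_STAGE2_THRESHOLDS,
                           seed: int = 0) -> tuple[pd.DataFrame, TruthManifest]:
    """Draw species x Division shape rows from a known proportional-odds model.

    ``beta`` maps predictor terms (MAIN_EFFECTS / INTERACTIONS names) to true
    log-odds coefficients; a positive coefficient shifts units toward the
    more vulnerable categories.  Categories are drawn from
    ``P(Y <= j) = logistic(alpha_j - x'beta)``.
    """
    from .vulnerability import encode_predictors

    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if beta is None:
        beta = dict(DEFAULT_STAGE2_BETA)
    rng = np.random.default_rng(seed % (2**31))

    divs = [DIVISIONS[i % len(DIVISIONS)] for i in range(n_units)]
    base = np.array([DIVISION_GRADIENTS[d] for d in divs])
    tab = pd.DataFrame({
        "species": [f"SP{i:03d}" for i in range(n_units)],
        "division": divs,
        "MAT": base[:, 0] - 273.15 + rng.normal(0, 2.0, n_units),
        "MAP": np.maximum(base[:, 1] * 100 + rng.normal(0, 150.0, n_units), 100.0),
        "soil_pH": np.clip(base[:, 4] + rng.normal(0, 0.4, n_units), 3.8, 8.5),
        "myco": np.where(rng.random(n_units) < 0.4, "AM", "EcM"),
        "leaf_habit": np.where(rng.random(n_units) < 0.6,
                               "deciduous", "evergreen"),
    })
    rho = 0.5
    zz = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_units)
    tab["Ndep"] = base[:, 2] * np.exp(0.35 * zz[:, 0] - 0.5 * 0.35**2)
    tab["Sdep"] = base[:, 3] * np.exp(0.35 * zz[:, 1] - 0.5 * 0.35**2)

    terms = list(beta)
    X = encode_predictors(tab, terms)
    eta = X @ np.array([beta[t] for t in terms])
    cut = np.concatenate([[-np.inf], thresholds, [np.inf]])
    cum = 1.0 / (1.0 + np.exp(-(cut[None, :] - eta[:, None])))
    probs = np.diff(cum, axis=1)
    u = rng.random(n_units)
    y = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
    tab["shape"] = y.astype(int)
    manifest = TruthManifest(stage2={
        "beta": {k: float(v) for k, v in beta.items()},
        "thresholds": [float(t) for t in thresholds],
        "n_units": int(n_units),
    })
    return tab, manifest


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("t_birth", "t_end", "children", "name")

    def __init__(self, t_birth: float):
        self.t_birth = t_birth
        self.t_end: Optional[float] = None
        self.children: list["_Lineage"] = []
        self.name: Optional[str] = None


def _newick(node: _Lineage) -> str:
    length = node.t_end - node.t_birth
    if node.children:
        inner = ",".join(_newick(c) for c in node.children)
        return f"({inner}):{length:.10g}"
    return f"{node.name}:{length:.10g}"


def generate_phylogeny(n_tips: int, trait_model: str = "brownian",
                       birth_rate: float = 1.0, sigma2: float = 1.0,
                       seed: int = 0) -> tuple[str, dict]:
    """A Yule (pure-birth) clock tree plus tip traits.

    Lineages split after exponential waiting times; all tips end at the
    present, so the tree is ultrametric.  Traits evolve by Brownian motion
    along branches (variance ``sigma2`` per unit branch length); with
    ``trait_model='shuffled'`` the Brownian values are randomly reassigned
    across tips, destroying the signal while keeping the trait distribution.
    Returns ``(newick, {tip: value})``.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed % (2**31))
    root = _Lineage(0.0)
    root.t_end = 0.0
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.t_end = t
        kids = [_Lineage(t), _Lineage(t)]
        node.children = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for j, tip in enumerate(active):
        tip.t_end = t
        tip.name = f"t{j + 1}"
    newick = "(" + ",".join(_newick(c) for c in root.children) + ");"

    traits: dict = {}

    def walk(node: _Lineage, value: float) -> None:
        length = node.t_end - node.t_birth
        value = value + math.sqrt(max(length, 0.0) * sigma2) * rng.standard_normal()
        if node.children:
            for c in node.children:
                walk(c, value)
        else:
            traits[node.name] = value

    for c in root.children:
        walk(c, 0.0)
    if trait_model == "shuffled":
        names = list(traits)
        vals = rng.permutation([traits[nm] for nm in names])
        traits = dict(zip(names, (float(v) for v in vals)))
    elif trait_model != "brownian":
        raise ValueError(f"unknown trait model {trait_model!r}")
    return newick, {k: float(v) for k, v in traits.items()}
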