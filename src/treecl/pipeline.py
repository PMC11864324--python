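"""Orchestration of the simulate -> fit -> classify -> regress -> report flow.

Each stage reads and writes plain CSV/JSON artifacts inside one output
directory, so a run is resumable stage by stage and every intermediate is
inspectable.  All randomness descends from the single run seed through
``numpy.random.SeedSequence(seed).spawn(...)``: child 0 drives simulation,
child 1 the fits (one grandchild per unit x endpoint), child 2 the stage-2
tests, child 3 the phylogenetic analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import core
from .core import ModelSpec, enumerate_models, param_names, to_arrays
from .fitting import FitConfig, SelectionOutcome, fit_model, ns_correlation, select_model
from .shapes import (classify_n_shape, classify_s_shape, critical_load_direct,
                     critical_load_sigmoid)
from .synthetic import ScenarioConfig, generate_trees
from . import vulnerability as vuln

__all__ = ["RunConfig", "RunReport", "ingest_trees", "run_pipeline",
           "COLUMN_MANIFEST"]

REQUIRED_COLUMNS = ["tree_id", "species", "division", "plot_id", "size_kgC",
                    "growth_kgC_yr", "survived", "dt_yr", "ba_m2ha",
                    "bal_m2ha", "temp_K", "precip_dm", "ndep_kgN_ha_yr",
                    "sdep_kgS_ha_yr"]

#: Machine-readable description of the tree-table schema and units.
COLUMN_MANIFEST = {
    "tree_id": {"type": "str", "unit": None},
    "species": {"type": "str", "unit": None},
    "division": {"type": "str", "unit": "ecoregion Division code"},
    "plot_id": {"type": "str", "unit": None},
    "size_kgC": {"type": "float", "unit": "kg C", "constraint": "> 0"},
    "growth_kgC_yr": {"type": "float", "unit": "kg C tree-1 yr-1",
                      "constraint": "may be negative; blank for dead trees"},
    "survived": {"type": "int", "unit": None, "constraint": "0 or 1"},
    "dt_yr": {"type": "float", "unit": "yr", "constraint": "> 0"},
    "ba_m2ha": {"type": "float", "unit": "m2 ha-1", "constraint": "> 0"},
    "bal_m2ha": {"type": "float", "unit": "m2 ha-1", "constraint": "0 <= BAL <= BA"},
    "temp_K": {"type": "float", "unit": "K", "constraint": "> 0"},
    "precip_dm": {"type": "float", "unit": "dm", "constraint": "> 0"},
    "ndep_kgN_ha_yr": {"type": "float", "unit": "kg N ha-1 yr-1", "constraint": "> 0"},
    "sdep_kgS_ha_yr": {"type": "float", "unit": "kg S ha-1 yr-1", "constraint": ">= 0"},
    "harvested": {"type": "int", "unit": None,
                  "constraint": "optional flag; harvested trees leave the survival set"},
    "dead_at_both": {"type": "int", "unit": None,
                     "constraint": "optional flag; dead at both censuses leaves the survival set"},
}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: Path
    seed: int = 0
    scenario: Optional[ScenarioConfig] = None
    trees_csv: Optional[Path] = None
    traits_csv: Optional[Path] = None
    plot_cov_csv: Optional[Path] = None
    tree_newick: Optional[Path] = None
    fit: FitConfig = field(default_factory=FitConfig)
    f_growth: float = 0.05
    f_survival: float = 0.01
    endpoints: tuple = ("growth", "survival")
    stepwise: bool = True
    scope_main: tuple = tuple(vuln.MAIN_EFFECTS)
    scope_interactions: tuple = tuple(vuln.INTERACTIONS)

    def __post_init__(self) -> None:
        if not (0 < self.f_growth < 1) or not (0 < self.f_survival < 1):
            raise ValueError("f values must lie in (0, 1)")
        self.out_dir = Path(self.out_dir)


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=str)


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------


def ingest_trees(path, min_trees: int = 500):
    """Validate a tree table and split it into growth and survival sets.

    Growth records require a surviving tree with a recorded growth rate;
    harvested and dead-at-both-censuses trees are dropped from the survival
    set.  Rows violating the schema (non-numeric covariates, BAL > BA,
    non-positive sizes/intervals) are rejected with reasons; more than 1%
    invalid rows is a hard failure.  Units below ``min_trees`` are flagged.
    """
    df = pd.read_csv(path, dtype={"species": str, "division": str,
                                  "tree_id": str, "plot_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for c in ("harvested", "dead_at_both"):
        if c not in df.columns:
            df[c] = 0

    num_cols = [c for c in REQUIRED_COLUMNS[4:]]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    reasons = pd.Series("", index=df.index)
    checks = [
        (df["size_kgC"].isna() | (df["size_kgC"] <= 0), "size_kgC must be > 0"),
        (df["dt_yr"].isna() | (df["dt_yr"] <= 0), "dt_yr must be > 0"),
        (df["ba_m2ha"].isna() | (df["ba_m2ha"] <= 0), "ba_m2ha must be > 0"),
        (df["bal_m2ha"].isna() | (df["bal_m2ha"] < 0)
         | (df["bal_m2ha"] > df["ba_m2ha"]), "BAL must lie in [0, BA]"),
        (df["temp_K"].isna() | (df["temp_K"] <= 0), "temp_K must be > 0"),
        (df["precip_dm"].isna() | (df["precip_dm"] <= 0), "precip_dm must be > 0"),
        (df["ndep_kgN_ha_yr"].isna() | (df["ndep_kgN_ha_yr"] <= 0),
         "ndep must be > 0"),
        (df["sdep_kgS_ha_yr"].isna() | (df["sdep_kgS_ha_yr"] < 0),
         "sdep must be >= 0"),
        (~df["survived"].isin([0, 1]), "survived must be 0 or 1"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, why in checks:
        newly = mask & ~bad
        reasons[newly] = why
        bad |= mask
    invalid = df[bad].assign(reason=reasons[bad])
    if len(df) and len(invalid) / len(df) > 0.01:
        raise ValueError(
            f"{len(invalid)} of {len(df)} rows invalid (> 1%); first reasons: "
            + "; ".join(invalid['reason'].head(5).tolist()))
    valid = df[~bad].copy()

    survival = valid[(valid["harvested"] != 1) & (valid["dead_at_both"] != 1)]
    growth = valid[(valid["survived"] == 1) & valid["growth_kgC_yr"].notna()]

    def unit_counts(d):
        return d.groupby(["species", "division"]).size()

    report = {
        "n_rows": int(len(df)),
        "n_invalid": int(len(invalid)),
        "invalid_reasons": invalid["reason"].value_counts().to_dict(),
        "n_dropped_harvested": int((valid["harvested"] == 1).sum()),
        "n_dropped_dead_at_both": int(
            ((valid["dead_at_both"] == 1) & (valid["harvested"] != 1)).sum()),
        "n_growth": int(len(growth)),
        "n_survival": int(len(survival)),
        "units_below_min_trees": {
            "growth": [f"{s}|{d}" for (s, d), c in unit_counts(growth).items()
                       if c < min_trees],
            "survival": [f"{s}|{d}" for (s, d), c in unit_counts(survival).items()
                         if c < min_trees],
        },
    }
    return growth, survival, report


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _params_json(spec: ModelSpec, params) -> str:
    return json.dumps({nm: getattr(params, nm) for nm in param_names(spec)},
                      sort_keys=True)


def _fit_units(df: pd.DataFrame, endpoint: str, config: RunConfig,
               seed_root: np.random.SeedSequence):
    """Fit the full candidate family per unit and apply the selection rule."""
    fits_rows, sel_rows, outcomes = [], [], {}
    units = sorted(df.groupby(["species", "division"]).groups)
    specs = enumerate_models(endpoint)
    seeds = seed_root.spawn(len(units))
    for (sp, div), ss in zip(units, seeds):
        sub = df[(df["species"] == sp) & (df["division"] == div)]
        recs = to_arrays(sub)
        unit_seed = int(ss.generate_state(1)[0] % (2**31))
        if len(sub) < config.fit.min_trees:
            outcomes[(sp, div)] = SelectionOutcome(
                sp, div, endpoint, status="insufficient_data")
            sel_rows.append({"species": sp, "division": div,
                             "endpoint": endpoint,
                             "status": "insufficient_data",
                             "ns_correlation": np.nan, "selected_spec": "",
                             "selected_params": "", "n_obs": len(sub),
                             "seed": unit_seed})
            continue
        ns_r = ns_correlation(recs)
        fits = []
        ucfg = dataclasses.replace(config.fit, seed=unit_seed)
        for spec in specs:
            fr = fit_model(recs, spec, ucfg)
            fits.append(fr)
            fits_rows.append({
                "species": sp, "division": div, "endpoint": endpoint,
                "spec": spec.name, "k": spec.k, "logLik": fr.logLik,
                "AIC": fr.AIC, "converged": fr.converged, "seed": unit_seed,
                "n_obs": fr.n_obs,
                "params": _params_json(spec, fr.params) if fr.converged else "",
            })
        outcome = select_model(fits, ns_r, config.fit, sp, div, endpoint)
        outcomes[(sp, div)] = outcome
        sel_rows.append({
            "species": sp, "division": div, "endpoint": endpoint,
            "status": outcome.status,
            "ns_correlation": ns_r,
            "selected_spec": (outcome.selected_fit.spec.name
                              if outcome.selected_fit else ""),
            "selected_params": (_params_json(outcome.selected_fit.spec,
                                             outcome.selected_fit.params)
                                if outcome.selected_fit else ""),
            "n_obs": len(sub), "seed": unit_seed,
        })
    return pd.DataFrame(fits_rows), pd.DataFrame(sel_rows), outcomes


def _classify_units(selection: pd.DataFrame, trees: pd.DataFrame,
                    config: RunConfig):
    """Shapes and critical loads for every selected unit."""
    from .core import GrowthParams, SurvivalParams

    shape_rows, cl_rows = [], []
    for _, row in selection.iterrows():
        sp, div, ep = row["species"], row["division"], row["endpoint"]
        sub = trees[(trees["species"] == sp) & (trees["division"] == div)]
        nmin, nmax = (float(sub["ndep_kgN_ha_yr"].min()),
                      float(sub["ndep_kgN_ha_yr"].max())) if len(sub) else (0, 0)
        smin, smax = (float(sub["sdep_kgS_ha_yr"].min()),
                      float(sub["sdep_kgS_ha_yr"].max())) if len(sub) else (0, 0)
        if row["status"] != "selected":
            outcome = SelectionOutcome(sp, div, ep, status=row["status"])
            spec = None
        else:
            spec = _spec_from_name(row["selected_spec"])
            cls = GrowthParams if ep == "growth" else SurvivalParams
            params = cls(**json.loads(row["selected_params"]))
            fr = core.FitResult(spec, params, 0.0, 2 * spec.k, int(row["n_obs"]),
                                True, int(row["seed"]))
            outcome = SelectionOutcome(sp, div, ep, status="selected",
                                       selected_fit=fr)
        n_shape = classify_n_shape(outcome, (nmin, nmax)) if nmax > nmin \
            else classify_n_shape(outcome, (0.0, 1.0))
        s_shape = classify_s_shape(outcome)
        for rshape in (n_shape, s_shape):
            shape_rows.append({
                "species": sp, "division": div, "endpoint": ep,
                "pollutant": rshape.pollutant,
                "shape": (int(rshape.shape) if rshape.shape is not None
                          else np.nan),
                "shape_label": rshape.label,
                "basis": row["selected_spec"] or row["status"],
            })
        if outcome.status == "selected":
            params = outcome.selected_fit.params
            f = config.f_growth if ep == "growth" else config.f_survival
            cl_n = critical_load_direct(params, "N", spec.s_form, ep)
            if spec.s_form == "sigmoid":
                cl_s = critical_load_sigmoid(params.s1, params.s2, params.s3,
                                             f, ep)
            else:
                cl_s = critical_load_direct(params, "S", spec.s_form, ep)
            for cl, (omin, omax) in ((cl_n, (nmin, nmax)), (cl_s, (smin, smax))):
                cl_rows.append({
                    "species": sp, "division": div, "endpoint": ep,
                    "pollutant": cl.pollutant, "basis": cl.basis,
                    "f": cl.f if cl.f is not None else np.nan,
                    "CL_kg_ha_yr": cl.value if cl.value is not None else np.nan,
                    "obs_min_dep": omin, "obs_max_dep": omax,
                    "note": cl.note,
                })
    return pd.DataFrame(shape_rows), pd.DataFrame(cl_rows)


def _spec_from_name(name: str) -> ModelSpec:
    for ep in ("growth", "survival"):
        for spec in enumerate_models(ep):
            if spec.name == name:
                return spec
    raise ValueError(f"unknown spec name {name!r}")


def _regress(shapes: pd.DataFrame, plot_cov: pd.DataFrame,
             traits: pd.DataFrame, config: RunConfig, seed: int):
    """The four ordinal vulnerability models plus supporting tests."""
    results, tests_rows = {}, []
    for ep in config.endpoints:
        for pol in ("N", "S"):
            key = f"{ep}_{pol}"
            sub = shapes[(shapes["endpoint"] == ep)
                         & (shapes["pollutant"] == pol)]
            table, log = vuln.build_covariate_table(sub, plot_cov, traits)
            entry = {"n_units": int(len(table)), "build_log": log}
            # Fisher test of shape distribution across Divisions
            if len(table):
                ct = pd.crosstab(table["shape"], table["division"])
                try:
                    p = vuln.fisher_exact_shapes(ct.to_numpy(), seed=seed)
                    tests_rows.append({"test": "fisher_shapes_by_division",
                                       "endpoint": ep, "pollutant": pol,
                                       "statistic": np.nan, "p": p})
                except ValueError:
                    pass
            try:
                if len(table) < 20:
                    raise ValueError(f"only {len(table)} units; too few for "
                                     "a stable ordinal fit")
                corr, flagged = vuln.collinearity_screen(table)
                entry["collinearity_flags"] = [
                    {"pair": [a, b], "r": None if math.isnan(r) else r,
                     "note": why} for a, b, r, why in flagged]
                notes: list = []
                if config.stepwise:
                    fit = vuln.stepwise_aic(
                        table, config.scope_main, config.scope_interactions,
                        log=notes)
                else:
                    fit = vuln.fit_proportional_odds(
                        table, list(config.scope_main))
                entry.update({
                    "terms": fit.terms,
                    "coefficients": fit.beta,
                    "se": fit.se,
                    "thresholds": list(map(float, fit.thresholds)),
                    "odds_ratios": {t: list(v)
                                    for t, v in fit.odds_ratios.items()},
                    "logLik": fit.logLik, "AIC": fit.AIC, "AICc": fit.AICc,
                    "nagelkerke_r2": fit.nagelkerke_r2,
                    "step_trace": [[t, a] for t, a in fit.step_trace],
                    "notes": notes,
                })
            except (ValueError, vuln.FitDiagnosticError) as e:
                entry["error"] = str(e)
            results[key] = entry
    # ANOVA/Tukey of each continuous covariate across Divisions
    cov_all = (plot_cov.groupby(["species", "division"], as_index=False)
               [["mat_C", "map_mm", "soil_ph", "ndep", "sdep"]].mean())
    for covariate in ("mat_C", "map_mm", "soil_ph", "ndep", "sdep"):
        groups = {d: g[covariate].to_numpy()
                  for d, g in cov_all.groupby("division") if len(g) >= 2}
        if len(groups) >= 2:
            res = vuln.anova_tukey(groups)
            tests_rows.append({"test": f"anova_{covariate}_by_division",
                               "endpoint": "", "pollutant": "",
                               "statistic": res["F"], "p": res["p"]})
    return results, pd.DataFrame(tests_rows)


def _phylo_signal(results: dict, shapes: pd.DataFrame, newick_path,
                  seed: int) -> dict:
    """Blomberg's K* on per-species mean shape ranks, given a phylogeny."""
    from .phylo import blomberg_k, tree_from_newick

    tree = tree_from_newick(Path(newick_path).read_text())
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out = {}
    for key in results:
        ep, pol = key.split("_")
        sub = shapes[(shapes["endpoint"] == ep) & (shapes["pollutant"] == pol)
                     & shapes["shape"].notna()]
        trait = sub.groupby("species")["shape"].mean()
        trait = trait[trait.index.isin(tips)]
        if len(trait) < 3 or trait.std() == 0:
            out[key] = {"error": "too few matched tips with variable shapes"}
            continue
        pruned = tree.clone(depth=1)
        pruned.retain_taxa_with_labels(list(trait.index))
        try:
            K, p = blomberg_k(pruned, trait.to_dict(), seed=seed)
            out[key] = {"K": K, "p": p, "n_tips": int(len(trait))}
        except ValueError as e:
            out[key] = {"error": str(e)}
    return out


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages, writing artifacts under ``config.out_dir``.

    Fully reproducible given the seed; on a stage failure the partial
    outputs are retained and the report marks the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    root = np.random.SeedSequence(config.seed % (2**31))
    s_sim, s_fit, s_tests, s_phylo = root.spawn(4)
    (out / "column_manifest.json").write_text(
        json.dumps(COLUMN_MANIFEST, indent=1, sort_keys=True))

    stage = "simulate"
    try:
        if config.trees_csv is None:
            scenario = config.scenario or ScenarioConfig.small(seed=config.seed)
            scenario = dataclasses.replace(
                scenario, seed=int(s_sim.generate_state(1)[0] % (2**31)))
            trees, traits, plots, manifest = generate_trees(scenario)
            trees.to_csv(out / "trees.csv", index=False)
            traits.to_csv(out / "traits.csv", index=False)
            plots.to_csv(out / "plot_covariates.csv", index=False)
            (out / "truth_manifest.json").write_text(manifest.to_json())
            trees_path = out / "trees.csv"
            traits_path = out / "traits.csv"
            plots_path = out / "plot_covariates.csv"
        else:
            trees_path, traits_path, plots_path = (
                config.trees_csv, config.traits_csv, config.plot_cov_csv)
        report.stages["simulate"] = "ok" if config.trees_csv is None else "skipped (input provided)"

        stage = "ingest"
        growth_df, survival_df, ingest_rep = ingest_trees(
            trees_path, config.fit.min_trees)
        report.stages["ingest"] = ingest_rep

        stage = "fit"
        all_fits, all_sel = [], []
        ep_dfs = {"growth": growth_df, "survival": survival_df}
        fit_seeds = s_fit.spawn(2)
        for ep, ss in zip(("growth", "survival"), fit_seeds):
            if ep not in config.endpoints:
                continue
            fits, sel, _ = _fit_units(ep_dfs[ep], ep, config, ss)
            all_fits.append(fits)
            all_sel.append(sel)
        fits_df = pd.concat(all_fits, ignore_index=True) if all_fits else pd.DataFrame()
        sel_df = pd.concat(all_sel, ignore_index=True) if all_sel else pd.DataFrame()
        fits_df.to_csv(out / "fits.csv", index=False)
        sel_df.to_csv(out / "selection.csv", index=False)
        report.stages["fit"] = {
            "units": int(len(sel_df)),
            "selected": int((sel_df["status"] == "selected").sum()),
            "excluded_ns_collinearity": int(
                (sel_df["status"] == "excluded_ns_collinearity").sum()),
            "insufficient_data": int(
                (sel_df["status"] == "insufficient_data").sum()),
        } if len(sel_df) else {"units": 0}

        stage = "classify"
        trees_all = pd.read_csv(trees_path,
                                dtype={"species": str, "division": str})
        shapes_df, cl_df = _classify_units(sel_df, trees_all, config)
        shapes_df.to_csv(out / "shapes.csv", index=False)
        cl_df.to_csv(out / "cl.csv", index=False)
        report.stages["classify"] = {
            "shape_rows": int(len(shapes_df)), "cl_rows": int(len(cl_df))}

        stage = "regress"
        plots_cov = pd.read_csv(plots_path,
                                dtype={"species": str, "division": str})
        traits_tab = pd.read_csv(traits_path, dtype={"species": str})
        tests_seed = int(s_tests.generate_state(1)[0] % (2**31))
        ordinal, tests_df = _regress(shapes_df, plots_cov, traits_tab,
                                     config, tests_seed)
        (out / "ordinal_results.json").write_text(
            json.dumps(ordinal, indent=1, sort_keys=True, default=float))
        tests_df.to_csv(out / "tests.csv", index=False)
        report.stages["regress"] = {
            "models": len(ordinal),
            "fitted": sum(1 for v in ordinal.values() if "error" not in v)}

        if config.tree_newick is not None:
            stage = "phylo"
            phylo_seed = int(s_phylo.generate_state(1)[0] % (2**31))
            signal = _phylo_signal(ordinal, shapes_df, config.tree_newick,
                                   phylo_seed)
            (out / "phylo_signal.json").write_text(
                json.dumps(signal, indent=1, sort_keys=True, default=float))
            report.stages["phylo"] = "ok"

        stage = "report"
        counts = {
            "units_attempted": int(len(sel_df)),
            "units_selected": int((sel_df["status"] == "selected").sum()),
            "units_excluded": int(
                (sel_df["status"] != "selected").sum()),
            "shape_distribution": {
                f"{ep}|{pol}|{lab}": int(n)
                for (ep, pol, lab), n in shapes_df.groupby(
                    ["endpoint", "pollutant", "shape_label"]).size().items()},
            "cl_quantiles": {
                pol: {q: float(v) for q, v in
                      cl_df[cl_df["pollutant"] == pol]["CL_kg_ha_yr"]
                      .quantile([0.25, 0.5, 0.75]).items()}
                for pol in ("N", "S")
                if len(cl_df) and cl_df[cl_df["pollutant"] == pol]
                ["CL_kg_ha_yr"].notna().any()},
        }
        report.counts = counts
        # stage-count reconciliation
        assert counts["units_attempted"] == \
            counts["units_selected"] + counts["units_excluded"]
    except Exception as e:  # partial outputs stay on disk
        report.failed_stage = stage
        report.stages[stage] = f"failed: {e}"
        (out / "report.json").write_text(report.to_json())
        raise
    (out / "report.json").write_text(report.to_json())
    return report
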