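"""Config-driven orchestration: simulate/load -> score -> select -> decompose.

A single root seed feeds named substreams (generator, fold assignment,
bootstrap) so stages are individually re-runnable and the whole run is
deterministic: two runs with the same config and seed produce
byte-identical ``results.json``.  Timestamps and other non-reproducible
metadata live only in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .inequality import (DEFAULT_NEED_FACTORS, bootstrap_inequality,
                         concentration_index, horizontal_inequity,
                         subgroup_inequality, wagstaff_decomposition)
from .lasso import DesignMatrix, ols_fit, post_double_selection
from .scores import health_education_score, pca_composite
from .synthetic import GeneratorConfig, generate_survey

logger = logging.getLogger(__name__)

CONSUMPTION_ITEMS = [f"consumption_item_{d}" for d in range(1, 6)]
HE_ITEMS = [f"he_item_{k}" for k in range(1, 5)]
CONTROL_COLUMNS = ["age_sq", "gender", "married", "education_years",
                   "residence_rural", "insurance", "health_status",
                   "monthly_income_group", "annual_income_group"]
REQUIRED_COLUMNS = (HE_ITEMS + ["he_total"] + CONSUMPTION_ITEMS
                    + ["age", "gender", "married", "education_years",
                       "residence_rural", "insurance", "health_status",
                       "monthly_income_group", "annual_income_group",
                       "city_id", "community_id"])


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``outcome`` is the regression outcome (``log_total`` matches a
    semi-elasticity reading of the exposure coefficient); ``ci_outcome``
    is the variable whose concentration is measured (the raw 0-32 score
    by default); ``ranking`` picks the socioeconomic ranking variable.
    """

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    outcome: str = "log_total"  # regression outcome: log_total | total
    ci_outcome: str = "total"  # concentration outcome: total | log_total
    ranking: str = "consumption"  # consumption | annual_income_group
    need_factors: tuple = DEFAULT_NEED_FACTORS
    use_age_squared: bool = True
    lasso_folds: int = 10
    lasso_grid_size: int = 50
    lasso_rule: str = "min"
    bootstrap: int = 0  # draws; 0 disables
    subgroup_floor: int = 30
    ci_correction: str | None = None  # None | erreygers | wagstaff
    outdir: str = "results"
    make_figures: bool = True
    verbosity: str = "info"

    def validate(self) -> None:
        if self.outcome not in ("log_total", "total"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.ci_outcome not in ("log_total", "total"):
            raise ConfigurationError(f"unknown ci_outcome {self.ci_outcome!r}")
        if self.ranking not in ("consumption", "annual_income_group"):
            raise ConfigurationError(f"unknown ranking {self.ranking!r}")
        if self.input_csv is None and self.generator is None:
            raise ConfigurationError("either input_csv or generator config required")
        if self.bootstrap < 0:
            raise ConfigurationError("bootstrap draws must be >= 0")
        if self.generator is not None:
            self.generator.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["need_factors"] = list(self.need_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        if isinstance(gen, dict):
            d["generator"] = GeneratorConfig.from_dict(gen)
        if "need_factors" in d and d["need_factors"] is not None:
            d["need_factors"] = tuple(d["need_factors"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# input validation


def validate_input(csv_path, schema=REQUIRED_COLUMNS) -> tuple[pd.DataFrame, dict]:
    """Load a survey CSV, enforce row invariants, drop violators.

    Returns (table, drop report).  More than 50% dropped rows aborts with
    a data error (probable schema mismatch).
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise DataError(f"input schema mismatch; missing columns: {missing}")
    n_read = len(df)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if "age_sq" not in df.columns:
        df["age_sq"] = df["age"] ** 2

    reasons: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)

    def flag(mask, reason):
        nonlocal bad
        mask = mask & ~bad
        if mask.any():
            reasons[reason] = int(mask.sum())
        bad |= mask

    items = df[HE_ITEMS]
    flag(((items < 0) | (items > 8) | (items != items.round())).any(axis=1),
         "item out of range")
    flag(items.sum(axis=1) != df["he_total"], "total != sum of items")
    flag(~((df["weight"] > 0) & np.isfinite(df["weight"])), "non-positive weight")
    flag((df["age"] < 18) | (df["age"] > 80), "age out of range")
    for c in ("gender", "married", "residence_rural", "insurance"):
        flag(~df[c].isin([0, 1]), f"{c} not binary")
    flag(~df["health_status"].isin([1, 2, 3, 4, 5]), "health_status out of range")
    cons = df[CONSUMPTION_ITEMS]
    flag(((cons < 0) | (cons > 1)).any(axis=1), "consumption item outside [0,1]")

    clean = df[~bad].reset_index(drop=True)
    report = {"rows_read": n_read, "rows_dropped": int(bad.sum()),
              "rows_analyzed": len(clean), "reasons": reasons}
    if n_read and bad.sum() / n_read > 0.5:
        raise DataError(f">50% of rows dropped ({report}); "
                        "probable schema mismatch")
    return clean, report


# ---------------------------------------------------------------------------
# stages


def stage_scores(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Attach outcome transforms and the PCA consumption composite."""
    df = df.copy()
    if np.issubdtype(df["he_total"].dtype, np.integer):
        he = health_education_score(df[HE_ITEMS].to_numpy())
        df["log_total"] = he.log_total
    else:  # continuous-outcome tables (generator's discretize=False mode)
        df["log_total"] = np.log1p(df["he_total"])
    df["total"] = df["he_total"].astype(float)
    comp = pca_composite(df[CONSUMPTION_ITEMS].to_numpy())
    df["consumption"] = comp.standardized_scores
    report = {
        "cronbach_alpha": comp.cronbach_alpha,
        "pca_loadings": comp.loadings.tolist(),
        "explained_variance_ratio": comp.explained_variance_ratio,
    }
    return df, report


def build_fixed_effects(df: pd.DataFrame) -> pd.DataFrame:
    """Nested city/community dummies at full rank.

    Communities nest within cities, so the blocks are city dummies (first
    city as base) plus within-city community dummies (first community of
    each city as base).
    """
    city = df["city_id"].astype(int)
    comm = df["community_id"].astype(int)
    city_d = pd.get_dummies(city, prefix="city", drop_first=True, dtype=float)
    base_comm = comm.groupby(city).transform("min")
    comm_lab = comm.where(comm != base_comm, -1)
    comm_d = pd.get_dummies(comm_lab, prefix="comm", dtype=float)
    comm_d = comm_d.drop(columns=["comm_-1"], errors="ignore")
    return pd.concat([city_d, comm_d], axis=1)


def build_design(df: pd.DataFrame, config: PipelineConfig) -> DesignMatrix:
    controls = list(CONTROL_COLUMNS)
    if not config.use_age_squared:
        controls[controls.index("age_sq")] = "age"
    fe = build_fixed_effects(df)
    X = pd.concat([df[["consumption"] + controls].astype(float), fe], axis=1)
    return DesignMatrix(outcome=df[config.outcome].to_numpy(), X=X,
                        exposure="consumption",
                        penalty_free=tuple(fe.columns))


def stage_fit(df: pd.DataFrame, config: PipelineConfig, fold_seed: int) -> dict:
    """OLS and post-double-Lasso columns of the regression report."""
    design = build_design(df, config)
    ols = ols_fit(design.outcome, design.X)
    pd_res = post_double_selection(design, n_folds=config.lasso_folds,
                                   grid_size=config.lasso_grid_size,
                                   fold_seed=fold_seed, rule=config.lasso_rule)
    return {"design": design, "ols": ols, "post_double": pd_res}


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def table2_frame(fit: dict, config: PipelineConfig) -> pd.DataFrame:
    """OLS vs post-double-Lasso comparison, star convention 0.05/0.01/0.001."""
    from scipy import stats as st

    ols, pdr = fit["ols"], fit["post_double"]
    rows = []
    show = ["consumption"] + [c for c in fit["design"].controls
                              if not c.startswith(("city_", "comm_"))]
    for c in show:
        z = ols.params[c] / ols.se[c]
        p = 2 * st.norm.sf(abs(z))
        entry = {"variable": c,
                 "ols_coef": float(ols.params[c]), "ols_se": float(ols.se[c]),
                 "ols_stars": _stars(p)}
        if c in pdr.ols_coefficients.index:
            zz = pdr.ols_coefficients[c] / pdr.ols_se[c]
            pp = 2 * st.norm.sf(abs(zz))
            entry.update(pd_coef=float(pdr.ols_coefficients[c]),
                         pd_se=float(pdr.ols_se[c]), pd_stars=_stars(pp))
        else:
            entry.update(pd_coef=np.nan, pd_se=np.nan, pd_stars="")
        rows.append(entry)
    return pd.DataFrame(rows)


def stage_inequality(df: pd.DataFrame, config: PipelineConfig,
                     fit: dict | None, boot_seed: int) -> dict:
    """CI, curve, subgroup table, decomposition and HI."""
    w = df["weight"].to_numpy()
    y = df[config.ci_outcome].to_numpy(dtype=float)
    rank_var = df[config.ranking].to_numpy(dtype=float)
    conc = concentration_index(y, rank_var, w, ranking_name=config.ranking,
                               correction=config.ci_correction)

    # decomposition covariate set = exposure + Lasso-selected controls + FE
    if fit is not None:
        pdr = fit["post_double"]
        factor_cols = list(pdr.ols_coefficients.index.drop("const"))
        fe_all = pd.concat([df, fit["design"].X[
            [c for c in fit["design"].X.columns
             if c.startswith(("city_", "comm_"))]]], axis=1)
        usable = [c for c in factor_cols if fe_all[c].nunique() > 1]
        factors = fe_all[usable]
    else:
        usable = ["consumption"] + [c for c in CONTROL_COLUMNS
                                    if df[c].nunique() > 1]
        factors = df[usable]
    decomp = wagstaff_decomposition(y, rank_var, factors, w)
    need = [f for f in config.need_factors if f in usable]
    hi = horizontal_inequity(decomp, need)

    groups = {c: ("cities" if c.startswith("city_") else "community")
              for c in usable if c.startswith(("city_", "comm_"))}
    grouped = decomp.grouped(groups)

    try:
        strata = subgroup_inequality(
            df, "annual_income_group", config.ci_outcome, config.ranking,
            usable_subgroup_factors(df, usable), need_factors=need,
            weight_col="weight", min_rows=config.subgroup_floor)
    except DataError as exc:
        logger.warning("subgroup analysis skipped: %s", exc)
        strata = []

    out = {"concentration": conc, "decomposition": decomp, "hi": hi,
           "grouped": grouped, "strata": strata}
    if config.bootstrap > 0:
        # fixed-effect dummies are excluded from the bootstrap refits:
        # resampling empties small community cells and the per-draw OLS
        # would dominate the runtime
        boot_factors = [c for c in usable
                        if not c.startswith(("city_", "comm_"))]
        boot_need = [f for f in need if f in boot_factors]
        out["bootstrap"] = bootstrap_inequality(
            df, config.ci_outcome, config.ranking, boot_factors, boot_need,
            weight_col="weight", n_boot=config.bootstrap, seed=boot_seed)
    return out


def usable_subgroup_factors(df: pd.DataFrame, factors: list[str]) -> list[str]:
    """Within-stratum decompositions exclude the fixed-effect dummies (too
    sparse per stratum) and the stratifying variable itself."""
    return [f for f in factors
            if not f.startswith(("city_", "comm_"))
            and f != "annual_income_group" and f in df.columns]


# ---------------------------------------------------------------------------
# serialization helpers


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Series):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, pd.DataFrame):
        return [{k: _jsonable(v) for k, v in rec.items()}
                for rec in x.to_dict(orient="records")]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def results_bundle(config: PipelineConfig, score_report: dict, fit: dict | None,
                   ineq: dict) -> dict:
    conc = ineq["concentration"]
    decomp = ineq["decomposition"]
    hi = ineq["hi"]
    curve = conc.curve
    if len(curve) > 513:  # decimate for the serialized bundle only
        keep = np.unique(np.linspace(0, len(curve) - 1, 513).round().astype(int))
        curve = curve[keep]
    bundle = {
        "version": __version__,
        "config": config.to_dict(),
        "reliability": score_report,
        "concentration": {
            "ci": conc.ci, "se": conc.se, "ci95": list(conc.ci95),
            "p_value": conc.p_value, "n": conc.n_used,
            "ranking": conc.ranking_name, "mean_outcome": conc.mean_outcome,
            "curve": curve,
        },
        "decomposition": {
            "table": decomp.table, "residual": decomp.residual,
            "residual_pct": decomp.residual_pct, "ci": decomp.ci,
            "grouped": ineq["grouped"],
        },
        "horizontal_inequity": {
            "hi": hi.hi, "need_factors": list(hi.need_factors),
            "need_contribution_total": hi.need_contribution_total,
        },
        "strata": [{
            "stratum": s.stratum, "n": s.n, "ci": s.concentration.ci,
            "ci_se": s.concentration.se,
            "hi": s.inequity.hi if s.inequity else None,
            "quartile_means": s.quartile_means,
        } for s in ineq["strata"]],
    }
    if fit is not None:
        pdr = fit["post_double"]
        sel = pdr.step1
        bundle["regression"] = {
            "ols": {"params": fit["ols"].params, "se": fit["ols"].se,
                    "adj_r2": fit["ols"].adj_r2},
            "post_double": {
                "exposure_coefficient": pdr.exposure_coefficient,
                "standard_error": pdr.standard_error,
                "selected_controls": list(pdr.selected_controls),
                "n_used": pdr.n_used,
            },
            "cv": {"n_folds": sel.n_folds if sel else None,
                   "selected_lambda_outcome": sel.selected_lambda if sel else None,
                   "selected_lambda_exposure":
                       pdr.step2.selected_lambda if pdr.step2 else None},
        }
    if "bootstrap" in ineq:
        bundle["bootstrap"] = ineq["bootstrap"]
    return _jsonable(bundle)


def json_bytes(obj: dict) -> bytes:
    return json.dumps(obj, sort_keys=True, indent=2).encode()


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the results bundle.

    Writes results.json, table2/3/4 CSVs, figures and manifest.json under
    ``config.outdir``.  The manifest is written even on failure, recording
    the failed stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "version": __version__,
                "seed": config.seed, "started": time.time(),
                "stages": {}, "status": "running"}
    stage = "init"
    try:
        stage = "load"
        if config.input_csv is not None:
            df, drop_report = validate_input(config.input_csv)
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            df, _truth = generate_survey(gen)
            drop_report = {"rows_read": len(df), "rows_dropped": 0,
                           "rows_analyzed": len(df), "reasons": {}}
        manifest["stages"]["load"] = drop_report

        stage = "scores"
        df, score_report = stage_scores(df)
        manifest["stages"]["scores"] = {"rows": len(df)}

        stage = "fit"
        fit = stage_fit(df, config, fold_seed=config.seed * 1000 + 17)
        t2 = table2_frame(fit, config)
        t2.to_csv(outdir / "table2_regression.csv", index=False)
        manifest["stages"]["fit"] = {
            "selected_controls": list(fit["post_double"].selected_controls)}

        stage = "inequality"
        ineq = stage_inequality(df, config, fit,
                                boot_seed=config.seed * 1000 + 29)
        strata_rows = []
        for s in ineq["strata"]:
            strata_rows.append({
                "stratum": s.stratum, "n": s.n, "ci": s.concentration.ci,
                "ci_se": s.concentration.se,
                "hi": s.inequity.hi if s.inequity else np.nan})
        pd.DataFrame(strata_rows).to_csv(outdir / "table3_subgroups.csv",
                                         index=False)
        decomp = ineq["decomposition"]
        tab4 = decomp.table.copy()
        tab4.to_csv(outdir / "table4_decomposition.csv", index=False)
        ineq["grouped"].to_csv(outdir / "table4_decomposition_grouped.csv",
                               index=False)
        manifest["stages"]["inequality"] = {"ci": ineq["concentration"].ci,
                                            "hi": ineq["hi"].hi}

        stage = "report"
        bundle = results_bundle(config, score_report, fit, ineq)
        (outdir / "results.json").write_bytes(json_bytes(bundle))

        if config.make_figures:
            stage = "figures"
            from . import plots
            plots.save_all(outdir, df, fit, ineq)

        manifest["status"] = "ok"
        return bundle
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        raise
    finally:
        manifest["finished"] = time.time()
        (outdir / "manifest.json").write_text(
            json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
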