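"""End-to-end runs: simulate -> vector metrics -> CUE -> stocks -> inference.

Every run writes a manifest echoing all effective parameters and the package
version, so a manifest plus seed fully determines all outputs.  Derived
tables are written at 6 significant digits; the cohort CSV keeps full float
precision so that read(write(x)) round-trips exactly.  No rows are ever
dropped silently; exclusions and method choices are itemized in run_log.txt.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbon_pools import stock_table
from .cue_model import CUE_MAX_DEFAULT, K_N_DEFAULT, cue_table
from .enzyme_stoichiometry import metrics_table
from .errors import ConfigError
from .stats_pipeline import (correlation_network, group_compare, path_model,
                             rf_importance, restoration_correlation)
from .synthetic_cohort import (DEPTHS, TREATMENTS, VARIABLES, GeneratorConfig,
                               generate_cohort, read_cohort, write_cohort)

FLOAT_FORMAT = "%.6g"

#: Default directed edges of the path stage: vector angle drives CUE down,
#: low CUE routes C into POC, POC feeds MAOC, MAOC builds the SOC stock.
DEFAULT_PATH_EDGES: tuple[tuple[str, str], ...] = (
    ("angle_deg", "cue_st"),
    ("cue_st", "poc"),
    ("poc", "maoc"),
    ("maoc", "soc_stock_kg_m2"),
)

SUMMARY_VARIABLES: tuple[str, ...] = (
    "soc_stock_kg_m2", "poc", "maoc", "cue_st", "angle_deg", "length",
)

RF_PREDICTORS: tuple[str, ...] = (
    "bd_kg_m3", "moisture", "ph", "poc", "maoc", "doc", "tdn", "mbc", "mbn",
    "angle_deg", "length", "cue_st",
)

CORR_VARIABLES: tuple[str, ...] = (
    "soc_stock_kg_m2", "poc", "maoc", "cue_st", "angle_deg", "length",
    "bd_kg_m3", "moisture", "ph", "doc", "tdn", "mbc", "mbn",
)


@dataclass
class RunConfig:
    """Effective parameters of one reproducible run."""

    input_csv: str | None = None          # read this cohort instead of simulating
    out_dir: str = "results"
    seed: int = 20220801
    depth: str = "both"                   # "0-15", "15-30", or "both"
    strict_length: bool = False
    cue_max: float = CUE_MAX_DEFAULT
    k_n: float = K_N_DEFAULT
    transform: str = "auto"               # ANOVA transform policy
    n_trees: int = 1000
    generator: GeneratorConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.depth not in (*DEPTHS, "both"):
            raise ConfigError(f"depth must be one of {DEPTHS + ('both',)}")


def augmented_cohort(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Cohort joined with per-sample stocks, vector metrics, and CUE."""
    metrics = metrics_table(cohort, strict_length=config.strict_length)
    cue = cue_table(cohort, cue_max=config.cue_max, k_n=config.k_n)
    stocks = stock_table(cohort)
    out = cohort.copy()
    for table, cols in ((metrics, ["eea_cn", "eea_np", "angle_deg", "length",
                                   "limitation_class"]),
                        (cue, ["s_cn", "cue_st"]),
                        (stocks, ["soc_stock_kg_m2"])):
        out = out.merge(table[["plot_id", "depth_cm"] + cols],
                        on=["plot_id", "depth_cm"], validate="one_to_one")
    return out


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_all(config: RunConfig) -> dict[str, object]:
    """Execute all stages in order; identical config + seed -> identical outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"stoichlim {__version__}", f"seed {config.seed}",
                      f"constants cue_max={config.cue_max} k_n={config.k_n}",
                      f"vector length mode: "
                      f"{'strict (ln bg / ln ap P term)' if config.strict_length else 'consistent pooled axes'}"]

    if config.input_csv is not None:
        cohort = read_cohort(config.input_csv)
        log.append(f"cohort read from {config.input_csv} ({len(cohort)} rows)")
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort = generate_cohort(gen)
        write_cohort(cohort, out_dir / "cohort.csv")
        log.append(f"cohort simulated (seed {gen.seed}, {len(cohort)} rows)")

    full = augmented_cohort(cohort, config)
    _write(full.loc[:, ["plot_id", "treatment", "depth_cm", "eea_cn", "eea_np",
                        "angle_deg", "length", "limitation_class"]],
           out_dir / "metrics.csv")
    _write(full.loc[:, ["plot_id", "treatment", "depth_cm", "s_cn", "cue_st"]]
           .assign(cue_max=config.cue_max, k_n=config.k_n), out_dir / "cue.csv")
    _write(full.loc[:, ["plot_id", "treatment", "depth_cm", "soc_stock_kg_m2"]],
           out_dir / "stocks.csv")

    depths = list(DEPTHS) if config.depth == "both" else [config.depth]
    depths = [d for d in depths if d in set(full["depth_cm"])]

    summaries = []
    for depth in depths:
        for variable in SUMMARY_VARIABLES:
            comp = group_compare(full, variable, depth=depth,
                                 transform=config.transform)
            summaries.append(comp.summary)
            log.append(
                f"ANOVA {variable} @ {depth}: F={comp.anova_f:.3g} p={comp.anova_p:.3g}"
                f" shapiro_p={comp.shapiro_p:.3g}"
                f"{' sqrt-transformed' if comp.sqrt_transformed else ''}")
    summary_table = pd.concat(summaries, ignore_index=True)
    _write(summary_table, out_dir / "summaries.csv")

    corr_frames = []
    for treatment in [t for t in ("passive", "active") if t in set(full["treatment"])]:
        edges, omitted = correlation_network(
            full, list(CORR_VARIABLES), treatment_subset=["degraded", treatment])
        edges.insert(0, "subset", f"degraded+{treatment}")
        corr_frames.append(edges)
        status = restoration_correlation(full, list(CORR_VARIABLES), treatment)
        status = status.rename(columns={"variable": "var1"})
        status["var2"] = "restoration_status"
        status.insert(0, "subset", f"degraded+{treatment}")
        corr_frames.append(status.loc[:, ["subset", "var1", "var2", "r", "p", "n"]])
        for line in omitted:
            log.append(f"correlation ({treatment}): {line}")
    _write(pd.concat(corr_frames, ignore_index=True), out_dir / "correlations.csv")

    importance = rf_importance(full, "soc_stock_kg_m2", list(RF_PREDICTORS),
                               n_trees=config.n_trees, seed=config.seed)
    _write(importance.table, out_dir / "importance.csv")
    log.append(f"random forest: {config.n_trees} trees, %IncMSE via {importance.method}")

    fit = path_model(full, list(DEFAULT_PATH_EDGES))
    path_rows = fit.edges.copy()
    path_rows["kind"] = "path"
    totals = fit.total_effects.copy()
    totals = totals.rename(columns={"total_effect": "coefficient"})
    totals["kind"] = "total_effect"
    path_out = pd.concat([path_rows, totals], ignore_index=True)
    path_out["chi_square"] = fit.chi_square
    path_out["chi_df"] = fit.df
    path_out["chi_p"] = fit.chi_p
    _write(path_out, out_dir / "path_fit.csv")
    log.append(f"path analysis: chi2={fit.chi_square:.3g} df={fit.df} "
               f"p={fit.chi_p:.3g} ({'consistent with data' if fit.consistent else 'rejected'})")

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()
                   if k not in ("generator", "out_dir")},
        "generator_defaults_used": config.input_csv is None and config.generator is None,
        "n_rows": int(len(full)),
        "outputs": ["metrics.csv", "cue.csv", "stocks.csv", "summaries.csv",
                    "correlations.csv", "importance.csv", "path_fit.csv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return {"cohort": cohort, "augmented": full, "summaries": summary_table,
            "importance": importance, "path_fit": fit, "manifest": manifest}


# --------------------------------------------------------------------------
# Schema validation report
# --------------------------------------------------------------------------

def validate(path) -> list[str]:
    """Schema report for a cohort CSV; an empty list means a clean file."""
    issues: list[str] = []
    try:
        raw = pd.read_csv(path)
    except Exception as err:  # unreadable file
        return [f"unreadable file: {err}"]
    missing = sorted(set(("plot_id", "treatment", "depth_cm") + VARIABLES)
                     - set(raw.columns))
    if missing:
        issues.append(f"missing columns: {missing}")
        return issues
    bad_treat = raw.loc[~raw["treatment"].isin(TREATMENTS)]
    for i, label in bad_treat["treatment"].items():
        issues.append(f"row {i}: unknown treatment label {label!r}")
    for col in VARIABLES:
        values = pd.to_numeric(raw[col], errors="coerce")
        for i in values.index[values.isna()]:
            issues.append(f"row {i}: non-numeric value in {col!r}")
        for i in values.index[values <= 0]:
            issues.append(f"row {i}: non-positive value in {col!r}")
    soc = pd.to_numeric(raw["soc_pct"], errors="coerce")
    for i in soc.index[soc > 100]:
        issues.append(f"row {i}: soc_pct > 100 percent")
    for col in ("bg", "cbh", "nag", "lap", "ue", "ap"):
        values = pd.to_numeric(raw[col], errors="coerce")
        for i in values.index[(values > 0) & (values <= 1)]:
            issues.append(
                f"row {i}: {col!r} <= 1 working unit (log-domain violation "
                "for vector metrics)")
    dup = raw.duplicated(subset=["plot_id", "depth_cm"], keep=False)
    for i in raw.index[dup]:
        issues.append(f"row {i}: duplicate plot_id x depth "
                      f"({raw.loc[i, 'plot_id']!r}, {raw.loc[i, 'depth_cm']!r})")
    return issues


# --------------------------------------------------------------------------
# Qualitative direction pattern (the study's headline contrast)
# --------------------------------------------------------------------------

def qualitative_pattern(config: RunConfig | None = None,
                        cohort: pd.DataFrame | None = None) -> dict[str, bool]:
    """Check the restoration direction pattern on one cohort, per depth.

    active vs degraded: higher vector angle, lower CUE_ST, and higher SOC
    stock, POC and MAOC with Tukey letter groups disjoint from degraded;
    passive vs degraded: higher vector angle but a shared SOC-stock letter.
    """
    config = config or RunConfig()
    if cohort is None:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort = generate_cohort(gen)
    full = augmented_cohort(cohort, config)
    checks: dict[str, bool] = {}
    for depth in DEPTHS:
        sub = full.loc[full["depth_cm"] == depth]
        means = sub.groupby("treatment").mean(numeric_only=True)
        checks[f"active_angle_up@{depth}"] = (
            means.loc["active", "angle_deg"] > means.loc["degraded", "angle_deg"])
        checks[f"passive_angle_up@{depth}"] = (
            means.loc["passive", "angle_deg"] > means.loc["degraded", "angle_deg"])
        checks[f"active_cue_down@{depth}"] = (
            means.loc["active", "cue_st"] < means.loc["degraded", "cue_st"])
        for variable in ("soc_stock_kg_m2", "poc", "maoc"):
            comp = group_compare(full, variable, depth=depth,
                                 transform=config.transform)
            letters = dict(zip(comp.summary["treatment"], comp.summary["letter_group"]))
            higher = means.loc["active", variable] > means.loc["degraded", variable]
            disjoint = not (set(letters["active"]) & set(letters["degraded"]))
            checks[f"active_{variable}_up_distinct@{depth}"] = bool(higher and disjoint)
            if variable == "soc_stock_kg_m2":
                checks[f"passive_soc_letter_shared@{depth}"] = bool(
                    set(letters["passive"]) & set(letters["degraded"]))
    return checks
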