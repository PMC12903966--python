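"""Inference stages over a cohort: group comparisons, correlations, random-forest
importance, and recursive path analysis.

Group comparisons follow the classical field-ecology recipe: residual
normality screened by Shapiro-Wilk, a square-root transform applied to flagged
variables, one-way ANOVA across treatments, Tukey HSD mean separation, and a
compact letter display (groups sharing a letter do not differ at alpha).
Means and standard errors are always reported on the original scale.

The path stage fits a fully recursive system on z-scored variables (each
endogenous variable regressed on its parents by OLS, which is the maximum
likelihood estimator for recursive models with uncorrelated errors), computes
the model-implied covariance, and reports the ML chi-square discrepancy
against the observed covariance; a non-significant chi-square (p > 0.05) is
declared consistent with the data.  Outputs are labelled "path analysis" --
no latent variables are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import AnalysisError
from .synthetic_cohort import TREATMENTS

ALPHA_DEFAULT = 0.05


# --------------------------------------------------------------------------
# Compact letter display
# --------------------------------------------------------------------------

def compact_letter_display(groups: list[str],
                           significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Groups sharing a letter are not significantly different; every
    significant pair ends up with disjoint letter sets, and the display is
    transitive-consistent by construction.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant_pairs):
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend((col - {a}, col - {b}))
            else:
                new_columns.append(col)
        # absorb columns that are subsets of another; deduplicate
        columns = []
        for col in new_columns:
            if any(col < other or (col == other and col in columns)
                   for other in new_columns if col is not other):
                continue
            if col not in columns:
                columns.append(col)
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    letters = {g: "" for g in groups}
    for letter_idx, col in enumerate(columns):
        letter = chr(ord("a") + letter_idx)
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


# --------------------------------------------------------------------------
# Group comparison (ANOVA + Tukey)
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Result bundle of one variable x depth comparison."""

    summary: pd.DataFrame          # treatment, mean, se, n, letter_group, pct_change
    anova_f: float
    anova_p: float
    shapiro_p: float
    sqrt_transformed: bool
    tukey_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)


def group_compare(cohort: pd.DataFrame, variable: str, depth: str | None = None,
                  alpha: float = ALPHA_DEFAULT, baseline: str = "degraded",
                  transform: str = "auto") -> GroupComparison:
    """One-way ANOVA + Tukey HSD across treatments for one variable.

    ``transform`` is ``"auto"`` (square-root when Shapiro-Wilk flags the
    ANOVA residuals at p < 0.05), ``"none"``, or ``"sqrt"``.
    """
    data = cohort if depth is None else cohort.loc[cohort["depth_cm"] == depth]
    if variable not in data.columns:
        raise AnalysisError(f"variable {variable!r} not in cohort")
    treatments = [t for t in TREATMENTS if t in set(data["treatment"])]
    treatments += sorted(set(data["treatment"]) - set(TREATMENTS))
    if len(treatments) < 2:
        raise AnalysisError("need at least two treatments to compare")
    groups = {t: data.loc[data["treatment"] == t, variable].to_numpy(dtype=float)
              for t in treatments}
    for t, g in groups.items():
        if len(g) < 2:
            raise AnalysisError(f"treatment {t!r} has fewer than 2 replicates")

    values = np.concatenate([groups[t] for t in treatments])
    labels = np.concatenate([[t] * len(groups[t]) for t in treatments])
    residuals = np.concatenate([groups[t] - groups[t].mean() for t in treatments])

    if np.ptp(residuals) == 0.0:
        shapiro_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    use_sqrt = transform == "sqrt" or (transform == "auto" and shapiro_p < 0.05)
    if use_sqrt and np.any(values < 0):
        raise AnalysisError(f"square-root transform needs non-negative {variable!r}")
    tvalues = np.sqrt(values) if use_sqrt else values
    tgroups = [tvalues[labels == t] for t in treatments]

    if all(np.ptp(g) == 0.0 for g in tgroups):
        # zero within-group variance everywhere: F undefined -> no difference
        anova_f, anova_p = np.nan, 1.0
        letters = {t: "a" for t in treatments}
        tukey_p: dict[tuple[str, str], float] = {}
    else:
        anova = stats.f_oneway(*tgroups)
        anova_f, anova_p = float(anova.statistic), float(anova.pvalue)
        tukey = pairwise_tukeyhsd(tvalues, labels, alpha=alpha)
        res = tukey.summary().data[1:]
        tukey_p = {}
        significant = set()
        for row in res:
            a, b, p_adj, reject = str(row[0]), str(row[1]), float(row[3]), bool(row[6])
            tukey_p[(a, b)] = p_adj
            if reject:
                significant.add(tuple(sorted((a, b))))
        letters = compact_letter_display(treatments, significant)

    rows = []
    for t in treatments:
        g = groups[t]
        pct = None
        if baseline in groups and groups[baseline].mean() > 0:
            from .carbon_pools import percent_change, round_percent
            pct = round_percent(percent_change(groups[baseline].mean(), g.mean()))
        rows.append({
            "variable": variable, "treatment": t,
            "depth_cm": depth if depth is not None else "pooled",
            "mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(len(g)), "n": len(g),
            "letter_group": letters[t], "pct_change_vs_degraded": pct,
        })
    return GroupComparison(pd.DataFrame(rows), anova_f, anova_p, shapiro_p,
                           use_sqrt, tukey_p)


# --------------------------------------------------------------------------
# Correlation network
# --------------------------------------------------------------------------

def correlation_network(data: pd.DataFrame, variables: list[str],
                        treatment_subset: list[str] | None = None
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson r and two-sided p; constant variables are omitted.

    Returns (edge table, log of omitted variables).
    """
    frame = data
    if treatment_subset is not None:
        frame = frame.loc[frame["treatment"].isin(treatment_subset)]
    omitted = []
    usable = []
    for v in variables:
        col = frame[v].to_numpy(dtype=float)
        if len(col) < 3:
            raise AnalysisError(f"variable {v!r} has fewer than 3 observations")
        if np.ptp(col) == 0.0:
            omitted.append(f"{v}: constant, correlation undefined, edge omitted")
        else:
            usable.append(v)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            r, p = stats.pearsonr(frame[a], frame[b])
            rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p),
                         "n": len(frame)})
    return pd.DataFrame(rows), omitted


def restoration_correlation(data: pd.DataFrame, variables: list[str],
                            restored_treatment: str,
                            baseline: str = "degraded") -> pd.DataFrame:
    """Point-biserial correlation of each variable with restoration status.

    Restoration status is the 0/1 indicator (baseline vs the named restored
    treatment) within that treatment pair.
    """
    frame = data.loc[data["treatment"].isin([baseline, restored_treatment])]
    indicator = (frame["treatment"] == restored_treatment).astype(float)
    rows = []
    for v in variables:
        r, p = stats.pearsonr(frame[v].astype(float), indicator)
        rows.append({"variable": v, "treatment": restored_treatment,
                     "r": float(r), "p": float(p), "n": len(frame)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Random-forest importance (%IncMSE analogue)
# --------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    """Permutation importance table plus fit metadata."""

    table: pd.DataFrame            # predictor, pct_inc_mse, p_value, significant
    baseline_mse: float
    method: str


def _holdout_pct_inc_mse(X_tr, X_te, y_tr, y_te, n_trees, n_repeats,
                         fit_state, perm_state) -> tuple[np.ndarray, float]:
    """%IncMSE per predictor: fit on train, permute each holdout column
    ``n_repeats`` times, and measure the relative MSE increase.

    All permuted copies are scored in one batched forest.predict call.
    """
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=fit_state)
    forest.fit(X_tr, y_tr)
    baseline_mse = float(np.mean((forest.predict(X_te) - y_te) ** 2))
    n_te, n_feat = X_te.shape
    if baseline_mse == 0.0:
        return np.zeros(n_feat), baseline_mse
    rng = np.random.default_rng(perm_state)
    blocks = []
    for j in range(n_feat):
        for _ in range(n_repeats):
            copy = X_te.copy()
            copy[:, j] = copy[rng.permutation(n_te), j]
            blocks.append(copy)
    pred = forest.predict(np.vstack(blocks)).reshape(n_feat, n_repeats, n_te)
    mse = np.mean((pred - y_te[None, None, :]) ** 2, axis=2)   # feat x repeat
    increase = mse.mean(axis=1) - baseline_mse
    return 100.0 * increase / baseline_mse, baseline_mse


def rf_importance(data: pd.DataFrame, response: str, predictors: list[str],
                  n_trees: int = 1000, seed: int = 0, holdout_frac: float = 0.3,
                  n_repeats: int = 10, n_null: int = 99,
                  alpha: float = ALPHA_DEFAULT) -> ImportanceResult:
    """Rank predictors of ``response`` by percent increase in holdout MSE.

    A random forest (``n_trees`` trees) is fit on a train split; each
    predictor column of the holdout is permuted ``n_repeats`` times and the
    relative MSE increase (%IncMSE) is the importance.  Significance is an
    exact response-permutation test: the response is permuted and the whole
    procedure refit ``n_null`` times, and p = (1 + #{null >= observed}) /
    (n_null + 1).  ``n_null = 0`` skips the significance stage (p = NaN).
    Fixed seed gives a reproducible ranking.
    """
    if len(data) < 6:
        raise AnalysisError("random forest stage needs at least 6 observations")
    X = data.loc[:, predictors].to_numpy(dtype=float)
    y = data.loc[:, response].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    split_state = int(rng.integers(2**31 - 1))
    fit_state = int(rng.integers(2**31 - 1))
    perm_state = int(rng.integers(2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_frac, random_state=split_state)
    observed, baseline_mse = _holdout_pct_inc_mse(
        X_tr, X_te, y_tr, y_te, n_trees, n_repeats, fit_state, perm_state)
    if n_null > 0:
        # response-permutation null: breaks every X-y association while
        # keeping the predictor structure, so a pure-noise predictor's
        # observed importance falls inside its own null
        null = np.empty((n_null, len(predictors)))
        for k in range(n_null):
            y_perm = rng.permutation(y)
            ytr_p, yte_p = y_perm[:len(y_tr)], y_perm[len(y_tr):]
            null[k], _ = _holdout_pct_inc_mse(
                X_tr, X_te, ytr_p, yte_p, n_trees, n_repeats,
                fit_state, perm_state)
        p_values = (1 + np.sum(null >= observed[None, :] - 1e-12, axis=0)) / (n_null + 1)
    else:
        p_values = np.full(len(predictors), np.nan)
    rows = [{"predictor": name, "pct_inc_mse": float(observed[j]),
             "p_value": float(p_values[j]),
             "significant": bool(p_values[j] < alpha)}
            for j, name in enumerate(predictors)]
    table = pd.DataFrame(rows).sort_values(
        "pct_inc_mse", ascending=False, ignore_index=True)
    return ImportanceResult(table, baseline_mse,
                            method=f"holdout permutation ({n_repeats} repeats, "
                                   f"{holdout_frac:.0%} holdout); significance by "
                                   f"{n_null}-fold response permutation")


# --------------------------------------------------------------------------
# Recursive path analysis
# --------------------------------------------------------------------------

@dataclass
class PathModelFit:
    """Standardized recursive path model fit."""

    edges: pd.DataFrame            # source, target, coefficient, se, p_value
    r2: dict[str, float]
    chi_square: float
    df: int
    chi_p: float
    consistent: bool               # chi-square p > 0.05
    total_effects: pd.DataFrame    # source, target, total_effect
    n: int


def _toposort(nodes: list[str], edges: list[tuple[str, str]]) -> list[str]:
    indeg = {v: 0 for v in nodes}
    for _, tgt in edges:
        indeg[tgt] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    order = []
    remaining = list(edges)
    while queue:
        v = queue.pop(0)
        order.append(v)
        for e in [e for e in remaining if e[0] == v]:
            remaining.remove(e)
            indeg[e[1]] -= 1
            if indeg[e[1]] == 0:
                queue.append(e[1])
    if len(order) != len(nodes):
        raise AnalysisError("path model specification contains a cycle")
    return order


def path_model(data: pd.DataFrame, edges: list[tuple[str, str]]) -> PathModelFit:
    """Fit a recursive path model on z-scored variables.

    ``edges`` are directed (source, target) pairs forming a DAG over columns
    of ``data``.  Standardized coefficients, R^2 per endogenous variable, the
    ML chi-square against the observed covariance, and standardized total
    effects (path-tracing sums of coefficient products) are returned.
    """
    nodes: list[str] = []
    for s, t in edges:
        for v in (s, t):
            if v not in nodes:
                nodes.append(v)
    missing = [v for v in nodes if v not in data.columns]
    if missing:
        raise AnalysisError(f"path model variables not in data: {missing}")
    _toposort(nodes, list(edges))

    n = len(data)
    k_edges = len(edges)
    endog = sorted({t for _, t in edges}, key=nodes.index)
    exog = [v for v in nodes if v not in endog]
    n_params = k_edges + len(endog) + len(exog) * (len(exog) + 1) // 2
    if n <= n_params:
        raise AnalysisError(f"n = {n} must exceed the {n_params} free parameters")

    Z = data.loc[:, nodes].to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [nodes[i] for i in np.flatnonzero(sd == 0)]
        raise AnalysisError(f"constant variables cannot enter the path model: {const}")
    Z = (Z - Z.mean(axis=0)) / sd
    S = np.cov(Z, rowvar=False, ddof=1)
    p = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    edge_rows = []
    r2 = {}
    for child in endog:
        parents = [s for s, t in edges if t == child]
        pi = [idx[v] for v in parents]
        ci = idx[child]
        S_pp = S[np.ix_(pi, pi)]
        cond = np.linalg.cond(S_pp)
        if cond > 1e10:
            raise AnalysisError(
                f"singular design for {child!r}: collinear parents {parents}")
        beta = np.linalg.solve(S_pp, S[pi, ci])
        err_var = float(S[ci, ci] - S[pi, ci] @ beta)
        B[ci, pi] = beta
        psi[ci, ci] = err_var
        r2[child] = 1.0 - err_var / float(S[ci, ci])
        # OLS standard errors / p-values for the standardized coefficients
        dof = n - len(parents) - 1
        sigma2 = err_var * (n - 1) / dof
        cov_beta = np.linalg.inv(S_pp) * sigma2 / (n - 1)
        for b_j, parent, var_b in zip(beta, parents, np.diag(cov_beta)):
            se = float(np.sqrt(var_b))
            tval = b_j / se if se > 0 else np.inf
            edge_rows.append({
                "source": parent, "target": child, "coefficient": float(b_j),
                "se": se, "p_value": float(2 * stats.t.sf(abs(tval), dof)),
            })
    for i, a in enumerate(exog):
        for b in exog[i:]:
            psi[idx[a], idx[b]] = psi[idx[b], idx[a]] = S[idx[a], idx[b]]

    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ psi @ A.T
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise AnalysisError("covariance matrix not positive definite")
    f_ml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    chi_square = max((n - 1) * f_ml, 0.0)
    df = p * (p + 1) // 2 - n_params
    chi_p = float(stats.chi2.sf(chi_square, df)) if df > 0 else 1.0

    total = A - np.eye(p)      # sum over directed paths of coefficient products
    total_rows = [{"source": src, "target": tgt,
                   "total_effect": float(total[idx[tgt], idx[src]])}
                  for src in nodes for tgt in endog
                  if src != tgt and total[idx[tgt], idx[src]] != 0.0]
    return PathModelFit(pd.DataFrame(edge_rows), r2, chi_square, df, chi_p,
                        chi_p > 0.05, pd.DataFrame(total_rows), n)
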