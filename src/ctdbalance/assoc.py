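"""Dependency analysis over the gene x mark matrix.

Given per-gene promoter levels of the CTD marks (plus the post-TES
elongation mark, mRNA, the mock control and CpG), this module quantifies
how the marks relate to productive elongation:

- a Spearman correlation matrix ordered by correlation with mRNA;
- partial correlations (precision-matrix identity) of a mark with the
  elongation mark given sets of intervening marks;
- exhaustive best-subset least-squares regression (adjusted R^2, Mallow's
  Cp against the full-predictor model, AIC, coefficient signs and t-test
  significance codes);
- cross-validated LASSO with the one-standard-error rule.

The statsmodels-style entry point is :class:`CTDMarkModel`, whose ``fit``
returns a :class:`CTDMarkResults` carrying all four analyses and a text
``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "standardize",
    "build_mark_table",
    "spearman_matrix",
    "partial_correlation",
    "best_subset",
    "lasso_1se",
    "SubsetModel",
    "LassoResult",
    "CTDMarkModel",
    "CTDMarkResults",
]

DEFAULT_SUBSET_PREDICTORS = ["K7me1", "K7me2", "8WG16", "S5p", "S7p", "K7ac", "CpG"]
DEFAULT_LASSO_PREDICTORS = ["8WG16", "S5p", "S7p", "K7me1", "K7me2", "K7ac", "mock", "CpG"]


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column (sample sd)."""
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s): {bad}")
    return (df - df.mean()) / sd


def build_mark_table(
    scaled_counts: pd.DataFrame,
    mrna: pd.Series | None = None,
    cpg: pd.Series | None = None,
    transform: str = "log",
    standardized: bool = True,
) -> pd.DataFrame:
    """Assemble the gene x variable matrix for the dependency analyses.

    ``scaled_counts`` holds depth-scaled window counts per mark. Counts are
    log-transformed by default (log(x + half the smallest positive value),
    keeping zeros finite) before centering and scaling; ``transform="none"``
    uses the raw scaled counts.
    """
    df = scaled_counts.copy()
    if transform == "log":
        for col in df.columns:
            x = df[col].astype(float)
            pos = x[x > 0]
            eps = (pos.min() / 2.0) if len(pos) else 1.0
            df[col] = np.log(x + eps)
    elif transform != "none":
        raise ValueError("transform must be 'log' or 'none'")
    if mrna is not None:
        df["mRNA"] = mrna.reindex(df.index)
    if cpg is not None:
        df["CpG"] = cpg.reindex(df.index)
    df = df.dropna()
    return standardize(df) if standardized else df


def _rank_transform(df: pd.DataFrame) -> pd.DataFrame:
    return df.rank(method="average")


def spearman_matrix(table: pd.DataFrame, order_by: str | None = "mRNA") -> pd.DataFrame:
    """Spearman correlation matrix, ordered by increasing correlation with mRNA.

    Average ranks per column, then Pearson on the ranks. Constant columns
    yield NaN rows/columns.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 genes")
    corr = _rank_transform(table).corr(method="pearson")
    for col in table.columns:  # constant columns: undefined correlation
        if table[col].nunique() <= 1:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
            corr.loc[col, col] = 1.0
    if order_by is not None and order_by in corr.columns:
        order = corr[order_by].sort_values(ascending=True, kind="stable").index
        corr = corr.loc[order, order]
    return corr


def partial_correlation(
    table: pd.DataFrame,
    x: str,
    y: str,
    given: list[str] | tuple = (),
    method: str = "spearman",
) -> tuple[float, float]:
    """Partial correlation of x and y given a conditioning set, with p-value.

    With ``method="spearman"`` (default) columns are rank-transformed first,
    so marginal and partial analyses share the Spearman convention;
    ``method="pearson"`` uses the raw columns. The coefficient comes from
    the precision matrix Omega of [x, y, given]:
    r = -Omega_xy / sqrt(Omega_xx * Omega_yy). The p-value uses
    t = r * sqrt((n - k - 2) / (1 - r^2)) on n - k - 2 df (k = |given|).
    """
    given = list(given)
    cols = [x, y] + given
    sub = table[cols].dropna()
    n = len(sub)
    if n <= len(given) + 2:
        raise ValueError("need n > |given| + 2 observations")
    data = _rank_transform(sub) if method == "spearman" else sub
    c = np.corrcoef(data.to_numpy(), rowvar=False)
    try:
        omega = np.linalg.inv(c)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular conditioning set among {cols}") from err
    if np.linalg.cond(c) > 1e10:
        raise ValueError(f"near-collinear variables among {cols}")
    r = float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))
    r = max(-1.0, min(1.0, r))
    df_resid = n - len(given) - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df_resid / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return r, float(p)


def _sig_code(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


@dataclass
class SubsetModel:
    """One least-squares model over a predictor subset (standardized data)."""

    predictors: tuple
    coefficients: dict
    pvalues: dict
    adj_r2: float
    cp: float
    aic: float

    @property
    def significance(self) -> dict:
        return {k: _sig_code(v) for k, v in self.pvalues.items()}

    @property
    def signs(self) -> dict:
        return {k: int(np.sign(v)) for k, v in self.coefficients.items()}


def best_subset(
    table: pd.DataFrame,
    response: str = "S2p",
    predictors: list[str] | None = None,
    max_size: int = 5,
    top_k: int = 5,
) -> dict[int, list[SubsetModel]]:
    """Exhaustive subset regression: for each size 1..max_size, the top_k
    models by adjusted R^2, with Mallow's Cp referenced to the full model."""
    predictors = list(predictors or [c for c in DEFAULT_SUBSET_PREDICTORS if c in table.columns])
    y = table[response].to_numpy()
    n = len(y)
    p_full = len(predictors)
    if n <= p_full + 1:
        raise ValueError("need n > number of predictors + 1")
    X_full = sm.add_constant(table[predictors].to_numpy())
    full_fit = sm.OLS(y, X_full).fit()
    sigma2_full = full_fit.ssr / (n - p_full - 1)

    out: dict[int, list[SubsetModel]] = {}
    for size in range(1, min(max_size, p_full) + 1):
        models = []
        for combo in itertools.combinations(predictors, size):
            X = sm.add_constant(table[list(combo)].to_numpy())
            fit = sm.OLS(y, X).fit()
            cp = fit.ssr / sigma2_full - n + 2 * (size + 1)
            models.append(
                SubsetModel(
                    predictors=combo,
                    coefficients={v: float(b) for v, b in zip(combo, fit.params[1:])},
                    pvalues={v: float(pv) for v, pv in zip(combo, fit.pvalues[1:])},
                    adj_r2=float(fit.rsquared_adj),
                    cp=float(cp),
                    aic=float(fit.aic),
                )
            )
        models.sort(key=lambda m: -m.adj_r2)
        out[size] = models[:top_k]
    return out


def subset_table(models: dict[int, list[SubsetModel]]) -> pd.DataFrame:
    """Flatten best-subset results into a report table."""
    rows = []
    for size, ms in models.items():
        for rank, m in enumerate(ms, 1):
            rows.append(
                {
                    "size": size,
                    "rank": rank,
                    "predictors": "+".join(m.predictors),
                    "adj_r2": m.adj_r2,
                    "cp": m.cp,
                    "aic": m.aic,
                    "coefficients": ";".join(
                        f"{k}={v:.4f}{m.significance[k]}" for k, v in m.coefficients.items()
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LassoResult:
    """LASSO path with 10-fold CV and the one-standard-error selection."""

    coefficients: pd.Series
    alpha_selected: float
    alpha_min: float
    alphas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    coef_path: pd.DataFrame = field(repr=False)

    @property
    def selected(self) -> list:
        return list(self.coefficients.index[self.coefficients != 0])


def lasso_1se(
    table: pd.DataFrame,
    response: str = "S2p",
    predictors: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
) -> LassoResult:
    """LASSO over the full regularization path with seeded K-fold CV.

    The selected penalty is the largest alpha whose mean CV error is within
    one standard error of the minimum (the most parsimonious model that is
    statistically indistinguishable from the best). The path's alpha -> 0
    endpoint equals the OLS solution.
    """
    predictors = list(predictors or [c for c in DEFAULT_LASSO_PREDICTORS if c in table.columns])
    X = table[predictors].to_numpy()
    y = table[response].to_numpy()
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many observations as folds")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Xc.T @ yc)) / n
    alphas = np.geomspace(alpha_max, alpha_max * 1e-4, n_alphas)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = np.zeros((folds, n_alphas))
    for k, (tr, te) in enumerate(kf.split(X)):
        if len(te) == 0:
            raise ValueError("degenerate (empty) CV fold")
        mx, my = X[tr].mean(axis=0), y[tr].mean()
        _, coefs, _ = lasso_path(X[tr] - mx, y[tr] - my, alphas=alphas)
        pred = (X[te] - mx) @ coefs + my  # lasso_path assumes centered data
        errs[k] = np.mean((y[te][:, None] - pred) ** 2, axis=0)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / math.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.flatnonzero(cv_mean <= threshold)
    i_sel = int(ok[0])  # alphas descend: first qualifying index = largest penalty
    alpha_sel = float(alphas[i_sel])

    fit = Lasso(alpha=alpha_sel, max_iter=50_000).fit(X, y)
    coefficients = pd.Series(fit.coef_, index=predictors, name="coefficient")
    _, path_coefs, _ = lasso_path(Xc, yc, alphas=alphas)
    coef_path = pd.DataFrame(path_coefs.T, index=alphas, columns=predictors)
    return LassoResult(
        coefficients=coefficients,
        alpha_selected=alpha_sel,
        alpha_min=float(alphas[i_min]),
        alphas=alphas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        coef_path=coef_path,
    )


def lasso_coef_at_zero(table: pd.DataFrame, response: str, predictors: list[str]) -> pd.Series:
    """The alpha -> 0 endpoint of the LASSO path: the OLS solution."""
    X = sm.add_constant(table[predictors].to_numpy())
    beta = np.linalg.lstsq(X, table[response].to_numpy(), rcond=None)[0]
    return pd.Series(beta[1:], index=predictors)


class CTDMarkModel:
    """Dependency model of CTD marks around a response (default: the
    elongation mark S2p measured after the TES).

    Parameters
    ----------
    table : DataFrame
        Gene x variable matrix; standardized columns are expected (see
        :func:`build_mark_table`).
    response : str
        Response variable for the regression analyses.

    Examples
    --------
    >>> model = CTDMarkModel(table, response="S2p")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, table: pd.DataFrame, response: str = "S2p"):
        if response not in table.columns:
            raise ValueError(f"response {response!r} not in table")
        self.table = table
        self.response = response

    @classmethod
    def from_dataframe(cls, scaled_counts, mrna=None, cpg=None, response="S2p", transform="log"):
        return cls(build_mark_table(scaled_counts, mrna, cpg, transform=transform), response)

    def fit(
        self,
        subset_predictors: list[str] | None = None,
        lasso_predictors: list[str] | None = None,
        partial_pairs: list[tuple] | None = None,
        max_size: int = 5,
        top_k: int = 5,
        folds: int = 10,
        seed: int = 0,
        partial_method: str = "spearman",
    ) -> "CTDMarkResults":
        t = self.table
        corr = spearman_matrix(t)
        if partial_pairs is None:
            partial_pairs = []
            if {"K7me2", self.response} <= set(t.columns):
                for given in (["S5p"], ["K7ac"], ["S7p"], ["S7p", "S5p", "K7ac"]):
                    if set(given) <= set(t.columns):
                        partial_pairs.append(("K7me2", self.response, tuple(given)))
            if {"S7p", "K7ac", self.response} <= set(t.columns):
                partial_pairs.append(("S7p", self.response, ("K7ac",)))
                partial_pairs.append(("K7ac", self.response, ("S7p",)))
        partials = []
        for x, y, given in partial_pairs:
            r, p = partial_correlation(t, x, y, list(given), method=partial_method)
            partials.append({"x": x, "y": y, "given": "+".join(given), "r": r, "p": p})
        partials = pd.DataFrame(partials)
        subsets = best_subset(t, self.response, subset_predictors, max_size, top_k)
        lasso = lasso_1se(t, self.response, lasso_predictors, folds=folds, seed=seed)
        return CTDMarkResults(self, corr, partials, subsets, lasso)


class CTDMarkResults:
    """Fitted results of :class:`CTDMarkModel`."""

    def __init__(self, model, spearman, partial_correlations, subset_models, lasso):
        self.model = model
        self.spearman = spearman
        self.partial_correlations = partial_correlations
        self.subset_models = subset_models
        self.lasso = lasso

    @property
    def subset_table(self) -> pd.DataFrame:
        return subset_table(self.subset_models)

    def summary(self) -> str:
        lines = [
            "CTD mark dependency analysis",
            "=" * 60,
            f"response: {self.model.response}   genes: {len(self.model.table)}",
            "",
            "Spearman correlation with mRNA (ascending):",
        ]
        if "mRNA" in self.spearman.columns:
            for v, r in self.spearman["mRNA"].items():
                if v != "mRNA":
                    lines.append(f"  {v:>8s}  {r:+.3f}")
        lines.append("")
        lines.append("Partial correlations:")
        for _, row in self.partial_correlations.iterrows():
            lines.append(
                f"  {row['x']} ~ {row['y']} | {row['given']:<16s} "
                f"r = {row['r']:+.3f}  ({_sig_code(row['p'])})"
            )
        lines.append("")
        lines.append("Best subsets (top model per size):")
        for size, models in self.subset_models.items():
            m = models[0]
            coefs = ", ".join(
                f"{k}:{v:+.2f}{m.significance[k]}" for k, v in m.coefficients.items()
            )
            lines.append(f"  size {size}: adjR2={m.adj_r2:.3f} Cp={m.cp:7.1f} [{coefs}]")
        lines.append("")
        sel = ", ".join(
            f"{k}:{v:+.3f}" for k, v in self.lasso.coefficients.items() if v != 0
        ) or "(all zero)"
        lines.append(f"LASSO (1-SE rule, alpha={self.lasso.alpha_selected:.4g}): {sel}")
        return "\n".join(lines)
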