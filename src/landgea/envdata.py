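"""Environmental tables and grids: standardization, collinearity control, PCA.

Tables are pandas DataFrames with a ``site_id``/coordinate block and named
variable columns (bio1..bio19, altitude, or synthetic var_*). Grids follow
the same layout with ``row``/``col`` pixel indices. Standardization always
uses an explicit reference (the training sites) so that current and future
grids share one scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_META_COLUMNS = {"site_id", "lat", "lon", "row", "col", "mask"}


def variable_columns(E: pd.DataFrame) -> list[str]:
    """Names of the environmental variable columns (everything non-meta)."""
    return [c for c in E.columns if c not in _META_COLUMNS]


def reference_stats(
    E: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-variable means and SDs (ddof=1) of the training sites."""
    variables = variables or variable_columns(E)
    sub = E[variables].astype(float)
    return sub.mean(), sub.std(ddof=1)


def standardize(
    E: pd.DataFrame,
    ref_means: pd.Series,
    ref_sds: pd.Series,
) -> pd.DataFrame:
    """Return a copy with each reference variable mapped to (x - mean)/sd.

    The same reference (training-site statistics) must be applied to both
    current and future grids so projected shifts reflect climate change
    rather than re-standardization.
    """
    zero = ref_sds[ref_sds <= 0]
    if len(zero):
        raise ValueError(f"zero-SD reference variable(s): {', '.join(zero.index)}")
    out = E.copy()
    for var in ref_means.index:
        out[var] = (E[var].astype(float) - ref_means[var]) / ref_sds[var]
    return out


def prune_correlated(
    E: pd.DataFrame,
    r_abs_max: float = 0.70,
    variables: list[str] | None = None,
    method: str = "pearson",
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy pruning of variable pairs with |correlation| > ``r_abs_max``.

    Pairs are visited in descending |r|; within a pair the member with the
    larger mean |r| against all other remaining variables is dropped. The
    surviving set has all pairwise |r| <= ``r_abs_max``. Returns
    ``(kept, dropped)`` where dropped records ``(dropped_var, kept_var, r)``.
    """
    variables = variables or variable_columns(E)
    if len(variables) < 2 or len(E) < 3:
        raise ValueError("need >= 2 variables and >= 3 sites to prune")
    corr = E[variables].astype(float).corr(method=method)
    kept = list(variables)
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = corr.loc[kept, kept].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_abs_max:
            break
        a, b = kept[i], kept[j]
        mean_a = sub[i].sum() / (len(kept) - 1)
        mean_b = sub[j].sum() / (len(kept) - 1)
        # drop the variable more entangled with everything else; tie -> later column
        victim, keeper = (a, b) if mean_a > mean_b or (mean_a == mean_b and i > j) else (b, a)
        dropped.append((victim, keeper, float(corr.loc[a, b])))
        kept.remove(victim)
        if len(kept) < 1:
            raise ValueError("pruning removed all variables")
    return kept, dropped


def vif(E: pd.DataFrame, variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per variable: 1/(1 - R2_j) from an OLS of
    variable j on all others (with intercept). Perfect collinearity is
    reported as +inf. Flag values >= 5 downstream."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    variables = variables or variable_columns(E)
    if len(E) <= len(variables) + 1:
        raise ValueError("need n_sites > n_variables + 1 for VIF")
    X = E[variables].astype(float).to_numpy()
    X = np.column_stack([np.ones(len(X)), X])
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, var in enumerate(variables):
            v = variance_inflation_factor(X, j + 1)
            out[var] = np.inf if (not np.isfinite(v) or v > 1e12) else float(v)
    return pd.Series(out, name="vif")


def env_pca(
    E: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA of the environmental variables.

    Variables are standardized internally (bioclim units are
    incommensurate), then decomposed by SVD. Returns
    ``(scores, loadings, percent_variance)`` with eigenvalues descending
    and percent variance summing to 100.
    """
    variables = variables or variable_columns(E)
    if len(variables) < 2:
        raise ValueError("env_pca needs >= 2 variables")
    X = E[variables].astype(float).to_numpy()
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s): {', '.join(bad)}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (len(E) - 1)
    pct = 100.0 * eigvals / eigvals.sum()
    comps = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, columns=comps, index=E.index)
    loadings = pd.DataFrame(Vt.T, index=variables, columns=comps)
    return scores, loadings, pct


# ---------------------------------------------------------------------------
# Grid CSV I/O
# ---------------------------------------------------------------------------

def read_grid_csv(path: str) -> pd.DataFrame:
    grid = pd.read_csv(path)
    for col in ("row", "col", "lat", "lon"):
        if col not in grid.columns:
            raise ValueError(f"grid CSV missing required column {col!r}")
    if grid.duplicated(["row", "col"]).any():
        raise ValueError("grid CSV has duplicate (row, col) pixels")
    return grid


def write_grid_csv(grid: pd.DataFrame, path: str) -> None:
    grid.to_csv(path, index=False)
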