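"""Constrained ordination core: RDA, partial RDA, variance partitioning,
permutation ANOVA, loading-tail outlier calls, and predictor assignment.

RDA regresses the centered allele-count matrix Y on standardized
environmental predictors X (multivariate least squares), then takes the
SVD of the fitted values: constrained eigenvalues are s_k^2/(n-1), R^2 is
the fraction of total variance captured by the fit, and locus loadings are
the right singular vectors scaled by the singular values ("species
scores"). Conditioning (partial RDA) residualizes both Y and X on the
conditioning matrix Z (with intercept) first. Adjusted R^2 follows
Ezekiel: 1 - (1 - R^2)(n - 1)/(n - m - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RDAModel",
    "VariancePartition",
    "fit_rda",
    "adjusted_r2",
    "anova_permutation",
    "variance_partition",
    "detect_outlier_loci",
    "assign_env_driver",
]


@dataclass
class RDAModel:
    n: int
    m: int
    predictor_names: list[str]
    eigenvalues: np.ndarray
    percent_constrained: np.ndarray  # share of constrained inertia per axis
    loadings: np.ndarray = field(repr=False)  # loci x axes, V * s
    site_scores: np.ndarray = field(repr=False)  # n x axes, U columns
    biplot_scores: np.ndarray  # predictors x axes (correlations)
    r2: float
    adj_r2: float
    conditioned: bool

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class VariancePartition:
    adj_full: float
    adj_climate_only: float
    adj_structure_only: float
    pure_climate: float
    pure_structure: float
    confounded: float
    residual: float
    p_values: dict[str, float]


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, Z] by least squares."""
    A = np.column_stack([np.ones(len(M)), Z])
    beta, *_ = np.linalg.lstsq(A, M, rcond=None)
    return M - A @ beta


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(j)
        raise ValueError(f"predictors collinear after conditioning: {', '.join(bad)}")


def fit_rda(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    predictor_names: list[str] | None = None,
) -> RDAModel:
    """Fit an RDA of response matrix Y on predictors X, optionally
    conditioned on Z (partial RDA).

    Y must be imputed (no missing values); rows of Y, X, Z are aligned.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(Y)
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
    m = X.shape[1]
    names = predictor_names or [f"x{j + 1}" for j in range(m)]
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 samples (n={n}, m={m})")
    if np.isnan(Y).any():
        raise ValueError("Y contains missing values; impute first")

    Yw = _center(Y)
    Xw = _center(X)
    conditioned = Z is not None
    if conditioned:
        Yw = _residualize(Yw, Z)
        Xw = _residualize(Xw, Z)
        # conditioning can absorb X entirely (e.g. Z = X): nothing left to fit
        if np.linalg.norm(Xw) <= 1e-10 * max(1.0, np.linalg.norm(X)):
            L = Y.shape[1]
            return RDAModel(
                n=n, m=m, predictor_names=names,
                eigenvalues=np.zeros(1),
                percent_constrained=np.zeros(1),
                loadings=np.zeros((L, 1)),
                site_scores=np.zeros((n, 1)),
                biplot_scores=np.zeros((m, 1)),
                r2=0.0, adj_r2=adjusted_r2(0.0, n, m), conditioned=True,
            )
    _check_full_rank(Xw, names)

    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    Yhat = Xw @ beta
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(m, n - 1)
    tol = max(s[0], 1.0) * 1e-12 if s.size else 0.0
    k = min(k, int((s > tol).sum())) or 1
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    eig = s**2 / (n - 1)
    total = (Yw**2).sum()
    ss_fit = (Yhat**2).sum()
    r2 = float(ss_fit / total) if total > 0 else 0.0
    pct = 100.0 * eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
    loadings = Vt.T * s
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = Xw.std(axis=0)
        us = U.std(axis=0)
        num = (Xw - Xw.mean(axis=0)).T @ (U - U.mean(axis=0)) / n
        biplot = num / np.outer(np.where(xs > 0, xs, np.nan), np.where(us > 0, us, 1.0))
    return RDAModel(
        n=n,
        m=m,
        predictor_names=names,
        eigenvalues=eig,
        percent_constrained=pct,
        loadings=loadings,
        site_scores=U,
        biplot_scores=biplot,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, m),
        conditioned=conditioned,
    )


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def anova_permutation(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of the (partial) RDA constrained variance.

    pseudo-F = (SS_fit/m) / (SS_resid/(n - m - 1 - rank(Z))); the null
    permutes rows of the residualized predictors; p = (1 + #{F_perm >=
    F_obs})/(1 + n_perm). Returns ``(F, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    rank_z = 0
    Yw = _center(Y)
    Xw = _center(X)
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        rank_z = int(np.linalg.matrix_rank(_center(Z)))
        Yw = _residualize(Yw, Z)
        Xw = _residualize(Xw, Z)
    df_res = n - m - 1 - rank_z
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    def pseudo_f(Xp: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xp, Yw, rcond=None)
        ss_fit = (Xp @ beta) ** 2
        total = (Yw**2).sum()
        fit = ss_fit.sum()
        return (fit / m) / ((total - fit) / df_res)

    f_obs = pseudo_f(Xw)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Xw[perm]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def variance_partition(
    Y: np.ndarray,
    X_climate: np.ndarray,
    Z_structure: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> VariancePartition:
    """Partial-RDA variance partitioning of Y into climate and structure.

    Fits full (climate + structure), climate-only, structure-only, and
    the two partial models, then derives:
    pure_climate = adj(full) - adj(structure_only),
    pure_structure = adj(full) - adj(climate_only),
    confounded = adj(climate_only) + adj(structure_only) - adj(full),
    residual = 1 - adj(full). Confounded may be slightly negative and is
    reported as computed. Permutation p-values per testable model.
    """
    X_climate = np.asarray(X_climate, dtype=float)
    Z_structure = np.asarray(Z_structure, dtype=float)
    X_full = np.column_stack([X_climate, Z_structure])
    n = len(Y)
    adj_full = fit_rda(Y, X_full).adj_r2
    adj_climate = fit_rda(Y, X_climate).adj_r2
    adj_structure = fit_rda(Y, Z_structure).adj_r2

    pure_climate = adj_full - adj_structure
    pure_structure = adj_full - adj_climate
    confounded = adj_climate + adj_structure - adj_full
    residual = 1.0 - adj_full

    rng = np.random.default_rng(seed)

    def seed_for_model() -> int:
        return int(rng.integers(0, 2**31 - 1))

    p_values = {
        "full": anova_permutation(Y, X_full, n_perm=n_perm, seed=seed_for_model())[1],
        "climate_only": anova_permutation(
            Y, X_climate, n_perm=n_perm, seed=seed_for_model()
        )[1],
        "structure_only": anova_permutation(
            Y, Z_structure, n_perm=n_perm, seed=seed_for_model()
        )[1],
        "climate_given_structure": anova_permutation(
            Y, X_climate, Z=Z_structure, n_perm=n_perm, seed=seed_for_model()
        )[1],
        "structure_given_climate": anova_permutation(
            Y, Z_structure, Z=X_climate, n_perm=n_perm, seed=seed_for_model()
        )[1],
    }
    return VariancePartition(
        adj_full=adj_full,
        adj_climate_only=adj_climate,
        adj_structure_only=adj_structure,
        pure_climate=pure_climate,
        pure_structure=pure_structure,
        confounded=confounded,
        residual=residual,
        p_values=p_values,
    )


def detect_outlier_loci(
    model: RDAModel, n_axes: int = 2, sd_mult: float = 3.29
) -> pd.DataFrame:
    """Loading-tail outliers: loci more than ``sd_mult`` SD from the mean
    loading on any of the first ``n_axes`` constrained axes.

    3.29 SD corresponds to a two-tailed standard-normal tail mass of 0.001.
    Returns one row per (locus, axis) exceedance with the loading and its
    z-score; a locus may appear on several axes.
    """
    if n_axes > model.n_axes:
        raise ValueError(f"requested {n_axes} axes, model has {model.n_axes}")
    rows = []
    for ax in range(n_axes):
        load = model.loadings[:, ax]
        mu, sd = load.mean(), load.std()
        if sd == 0:
            raise ValueError(f"zero SD of loadings on axis {ax + 1}")
        z = (load - mu) / sd
        for j in np.flatnonzero(np.abs(z) > sd_mult):
            rows.append((int(j), ax + 1, float(load[j]), float(z[j])))
    return pd.DataFrame(rows, columns=["locus_index", "axis", "loading", "z_score"])


def assign_env_driver(
    outliers: pd.DataFrame,
    Y: np.ndarray,
    X: np.ndarray,
    predictor_names: list[str],
) -> pd.DataFrame:
    """Assign each outlier locus the predictor with the highest |Pearson r|
    against its allele counts (ties break toward the first predictor in
    model order). Adds ``assigned_predictor`` and signed ``r_with_predictor``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    out = outliers.copy()
    preds, rs = [], []
    Xc = X - X.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    for j in out["locus_index"].astype(int):
        y = Y[:, j] - Y[:, j].mean()
        yn = np.linalg.norm(y)
        if yn == 0:
            raise ValueError(f"locus {j} is constant; correlation undefined")
        r = (Xc.T @ y) / (xn * yn)
        best = int(np.argmax(np.abs(r)))  # argmax takes first on ties
        preds.append(predictor_names[best])
        rs.append(float(r[best]))
    out["assigned_predictor"] = preds
    out["r_with_predictor"] = rs
    return out
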