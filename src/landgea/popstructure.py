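"""Population-structure diagnostics.

Genetic PCA, K-means cluster inference with discriminant axes (a reduced
DAPC: PCA then LDA on retained components), Spearman axis-environment
correlations, great-circle / environmental / FST distance matrices, and
Mantel tests for isolation by distance and by environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genotype_io import MISSING, GenotypeMatrix
from .selection_scan import wc84_components

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClusterModel:
    K: int
    assignments: np.ndarray  # values in 1..K
    retained_pcs: int
    criterion: pd.DataFrame  # per-K criterion curve

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments)
        if not np.isin(self.assignments, np.arange(1, self.K + 1)).all():
            raise ValueError("assignments must lie in 1..K")


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------

def genetic_pca(
    G: GenotypeMatrix, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the imputed allele-count matrix via SVD of centered loci.

    Returns ``(scores, percent_variance)``; scores are U*s so component
    variances equal the eigenvalues.
    """
    if G.n_samples < 2:
        raise ValueError("genetic_pca needs >= 2 samples")
    if (G.calls == MISSING).any():
        raise ValueError("genotypes must be imputed (no MISSING) before PCA")
    X = G.calls.astype(float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (G.n_samples - 1)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return U * s, pct


def _kmeans_bic(X: np.ndarray, labels: np.ndarray, K: int) -> float:
    # spherical-Gaussian (x-means) BIC of a k-means solution; lower better
    n, d = X.shape
    if n <= K:
        return np.inf
    wss = 0.0
    for k in range(K):
        pts = X[labels == k]
        if len(pts):
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
    sigma2 = max(wss / (d * (n - K)), 1e-12)
    ll = 0.0
    for k in range(K):
        nk = int((labels == k).sum())
        if nk:
            ll += nk * np.log(nk / n)
    ll -= (n * d / 2) * np.log(2 * np.pi * sigma2)
    ll -= (n - K) * d / 2
    n_params = (K - 1) + K * d + 1
    return -2 * ll + n_params * np.log(n)


def find_clusters(
    scores: np.ndarray,
    k_range: range = range(1, 11),
    seed: int = 0,
    retained_pcs: int | None = None,
    criterion: str = "bic",
    n_init: int = 10,
) -> ClusterModel:
    """K-means over ``k_range`` on retained PCs with model selection.

    ``criterion='bic'`` (default) minimizes n*log(WSS/n) + K*log(n);
    ``criterion='silhouette'`` maximizes the mean silhouette (K >= 2 only).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    X = np.asarray(scores, dtype=float)
    if retained_pcs is not None:
        X = X[:, :retained_pcs]
    n = len(X)
    if max(k_range) >= n:
        raise ValueError("K_max must be < n samples")
    n_distinct = len(np.unique(X, axis=0))

    rows = []
    fits = {}
    for K in k_range:
        if K > n_distinct:
            break
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
            labels = km.fit_predict(X)
        fits[K] = labels
        bic = _kmeans_bic(X, labels, K)
        sil = silhouette_score(X, labels) if 1 < K < n else np.nan
        rows.append((K, bic, sil))
    curve = pd.DataFrame(rows, columns=["K", "bic", "silhouette"])

    if criterion == "bic":
        best = int(curve.loc[curve["bic"].idxmin(), "K"])
    elif criterion == "silhouette":
        valid = curve.dropna(subset=["silhouette"])
        best = int(valid.loc[valid["silhouette"].idxmax(), "K"]) if len(valid) else 1
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ClusterModel(
        K=best,
        assignments=fits[best] + 1,
        retained_pcs=X.shape[1],
        criterion=curve,
    )


def dapc_axes(
    scores: np.ndarray,
    assignments: np.ndarray,
    pct_variance: np.ndarray | None = None,
    var_target: float = 0.80,
) -> np.ndarray:
    """Linear discriminant axes on retained PCs (reduced DAPC).

    Retains enough leading PCs to cover ``var_target`` of the variance
    (all, if ``pct_variance`` is not given), capped at n - K - 1; the PC
    count is reduced further if the within-class scatter is singular.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X = np.asarray(scores, dtype=float)
    y = np.asarray(assignments)
    K = len(np.unique(y))
    if K < 2:
        raise ValueError("discriminant axes require K >= 2 clusters")
    n = len(X)
    cap = max(1, n - K - 1)
    if pct_variance is not None:
        cum = np.cumsum(pct_variance[: X.shape[1]])
        n_pc = int(np.searchsorted(cum, 100.0 * var_target) + 1)
    else:
        n_pc = X.shape[1]
    n_pc = min(n_pc, cap, X.shape[1])
    while n_pc >= 1:
        try:
            lda = LinearDiscriminantAnalysis(solver="eigen")
            axes = lda.fit_transform(X[:, :n_pc], y)
            return axes
        except np.linalg.LinAlgError:
            n_pc -= 1
            logger.info("dapc_axes: singular scatter, reducing to %d PCs", n_pc)
    raise ValueError("within-class scatter singular for every PC count")


def axis_env_correlation(
    axes: np.ndarray, E: pd.DataFrame, variables: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Spearman correlation of each axis with each variable."""
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.shape[0] != len(E):
        raise ValueError("env rows must match samples")
    rows = []
    for a in range(axes.shape[1]):
        for var in variables:
            r, p = spearmanr(axes[:, a], E[var].to_numpy(dtype=float))
            rows.append((f"LD{a + 1}", var, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["axis", "variable", "r", "p", "significant"])


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def haversine_matrix(
    lat: np.ndarray, lon: np.ndarray, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Great-circle distance matrix (km) from degree coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates outside [-90,90] lat / [-180,180] lon")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi[:, None]) * np.cos(phi[None, :]) * np.sin(dlam / 2) ** 2
    )
    D = 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(D, 0.0)
    return D


def env_distance_matrix(
    E: pd.DataFrame, variables: list[str], standardized: bool = True
) -> np.ndarray:
    """Euclidean distances between per-site environmental vectors."""
    from scipy.spatial.distance import pdist, squareform

    X = E[variables].astype(float).to_numpy()
    if np.isnan(X).any():
        raise ValueError("missing environmental values")
    if standardized:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return squareform(pdist(X, metric="euclidean"))


def pairwise_fst_matrix(
    G: GenotypeMatrix,
    site_of_sample: np.ndarray,
    min_per_site: int = 2,
) -> tuple[np.ndarray, list]:
    """Multi-locus Weir-Cockerham theta between every pair of sites.

    Only sites with at least ``min_per_site`` samples enter; per pair,
    theta = sum(a) / sum(a+b+c) over loci with defined components, and
    negative estimates are clamped to zero. Returns ``(D, site_labels)``.
    """
    site_of_sample = np.asarray(site_of_sample)
    labels = [s for s in pd.unique(site_of_sample)
              if (site_of_sample == s).sum() >= min_per_site]
    if len(labels) < 2:
        raise ValueError("need >= 2 sites with enough samples")
    D = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi = G.calls[site_of_sample == labels[i]]
            gj = G.calls[site_of_sample == labels[j]]
            a, b, c = wc84_components(gi, gj)
            denom = np.nansum(a + b + c)
            if denom == 0 or not np.isfinite(denom):
                theta = 0.0
            else:
                theta = float(np.nansum(a) / denom)
            D[i, j] = D[j, i] = max(theta, 0.0)
    return D, labels


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    D1: np.ndarray,
    D2: np.ndarray,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    r is the rank (or Pearson) correlation of the off-diagonal entries;
    the null is built by jointly permuting rows and columns of the second
    matrix; p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), two-tailed.
    """
    from skbio.stats.distance import mantel as _mantel

    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape or D1.shape[0] < 4:
        raise ValueError("matrices must match and have >= 4 sites")
    for D in (D1, D2):
        tri = D[np.triu_indices_from(D, k=1)]
        if np.ptp(tri) == 0:
            raise ValueError("constant off-diagonal distances: correlation undefined")
    r, p, _ = _mantel(
        D1, D2, method=method, permutations=n_perm,
        alternative="two-sided", seed=seed,
    )
    return float(r), float(p)
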