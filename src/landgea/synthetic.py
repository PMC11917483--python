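"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_env_landscape` — smooth, spatially autocorrelated
  environmental surfaces on a raster grid plus a site table sampled from
  the pixels (stands in for bioclimatic layers).
* :func:`simulate_structured_genotypes` — diploid genotypes under the
  Balding–Nichols island model (per-population allele frequencies Beta
  distributed with variance governed by a neutral FST), with a planted
  subset of loci whose allele frequencies follow an environmental gradient
  through a logistic link at the individual level.
* :func:`simulate_sweep_haplotypes` — phased binary haplotypes carrying a
  hard selective sweep: a fraction of haplotypes share one identical allele
  string over a core region, the rest are i.i.d. Bernoulli(0.5).

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "HaplotypeSet",
    "simulate_env_landscape",
    "simulate_structured_genotypes",
    "simulate_sweep_haplotypes",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the structured-genotype simulation.

    ``fst_neutral`` is the Balding–Nichols differentiation parameter;
    ``beta_env`` is the logit-scale slope of adaptive allele frequency on
    the standardized driving environmental variable.
    """

    n_pops: int = 3
    n_per_pop: int = 30
    n_loci: int = 5000
    fst_neutral: float = 0.05
    n_adaptive: int = 50
    beta_env: float = 2.0
    maf_floor: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive must be <= n_loci")
        if not 0.0 <= self.fst_neutral < 1.0:
            raise ValueError("fst_neutral must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes with physical marker coordinates."""

    haplotypes: np.ndarray  # (2N, L) values in {0, 1}
    positions: np.ndarray  # 1-based bp, strictly increasing
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions length must match marker count")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# Environmental landscape
# ---------------------------------------------------------------------------

def simulate_env_landscape(
    grid_rows: int,
    grid_cols: int,
    n_vars: int,
    seed: int,
    n_sites: int = 75,
    noise_scale: float = 0.3,
    gradient_axis: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Smooth environmental surfaces and a site table sampled from pixels.

    Each variable is a linear spatial gradient (random direction, or fixed
    along rows/columns with ``gradient_axis``) plus Gaussian-smoothed
    low-frequency noise of relative amplitude ``noise_scale``, then shifted
    and scaled to a plausible per-variable range.

    Returns ``(grid, sites)``: the grid has one row per pixel with columns
    ``row, col, lat, lon, var_1..var_k``; the site table samples
    ``n_sites`` distinct pixels and adds ``site_id``.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid dimensions must be >= 2 to build a gradient")
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    rng = np.random.default_rng(seed)

    rows, cols = np.meshgrid(
        np.arange(grid_rows), np.arange(grid_cols), indexing="ij"
    )
    rfrac = rows / (grid_rows - 1)
    cfrac = cols / (grid_cols - 1)
    # crude geographic frame: latitudes decrease down rows
    lat = 14.0 - 10.0 * rfrac
    lon = 33.0 + 15.0 * cfrac

    data = {
        "row": rows.ravel(),
        "col": cols.ravel(),
        "lat": lat.ravel(),
        "lon": lon.ravel(),
    }
    for j in range(n_vars):
        if gradient_axis == "col":
            wr, wc = 0.0, 1.0
        elif gradient_axis == "row":
            wr, wc = 1.0, 0.0
        else:
            theta = rng.uniform(0, 2 * np.pi)
            wr, wc = np.cos(theta), np.sin(theta)
        surface = wr * rfrac + wc * cfrac
        if noise_scale > 0:
            rough = rng.standard_normal((grid_rows, grid_cols))
            smooth = gaussian_filter(
                rough, sigma=max(1.0, min(grid_rows, grid_cols) / 6.0), mode="reflect"
            )
            sd = smooth.std()
            if sd > 0:
                surface = surface + noise_scale * smooth / sd
        scale = rng.uniform(5.0, 50.0)
        offset = rng.uniform(-10.0, 25.0)
        data[f"var_{j + 1}"] = (offset + scale * surface).ravel()
    grid = pd.DataFrame(data)

    var_cols = [f"var_{j + 1}" for j in range(n_vars)]
    if grid[var_cols].std().min() <= 0:
        raise ValueError("degenerate grid: a variable has zero spatial variance")

    n_sites = min(n_sites, len(grid))
    pick = rng.choice(len(grid), size=n_sites, replace=False)
    sites = grid.iloc[np.sort(pick)].reset_index(drop=True).copy()
    sites.insert(0, "site_id", [f"site_{i + 1:03d}" for i in range(n_sites)])
    return grid, sites


# ---------------------------------------------------------------------------
# Structured genotypes
# ---------------------------------------------------------------------------

def simulate_structured_genotypes(
    cfg: SimConfig,
    env: pd.DataFrame,
    env_vars: list[str] | None = None,
    chrom: str = "1A",
    chrom_length: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Balding–Nichols genotypes with planted environment-associated loci.

    ``env`` must have one row per simulated individual (its site's
    environmental values). Neutral loci: ancestral frequency
    p0 ~ U(max(0.1, maf_floor), 1 - max(0.1, maf_floor)); per-population
    frequency ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F = ``fst_neutral``
    (panmixia when F = 0). Adaptive loci: per-individual frequency
    ``expit(logit(p0) + beta_env * z)`` where z is the individual's
    standardized driving variable. Genotypes are Binomial(2, freq); a
    ``missing_rate`` fraction of calls is masked uniformly at random.

    Returns the genotype matrix and a truth table with columns
    ``locus_index, chrom, pos, driver, beta``.
    """
    n = cfg.n_pops * cfg.n_per_pop
    if len(env) != n:
        raise ValueError(
            f"env has {len(env)} rows but the design implies {n} individuals"
        )
    if env_vars is None:
        env_vars = [c for c in env.columns if c.startswith("var_") or c.startswith("bio")]
    if cfg.n_adaptive > 0 and not env_vars:
        raise ValueError("no environmental variable columns found for adaptive loci")

    rng = np.random.default_rng(cfg.seed)
    pop_of = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)

    lo = max(0.1, cfg.maf_floor)
    p0 = rng.uniform(lo, 1.0 - lo, size=cfg.n_loci)

    freq = np.empty((n, cfg.n_loci))
    F = cfg.fst_neutral
    if F > 0:
        shape = (1.0 - F) / F
        pop_freq = rng.beta(p0 * shape, (1.0 - p0) * shape, size=(cfg.n_pops, cfg.n_loci))
        # keep loci polymorphic in expectation
        pop_freq = np.clip(pop_freq, 1e-4, 1.0 - 1e-4)
        freq[:] = pop_freq[pop_of]
    else:
        freq[:] = p0[None, :]

    adaptive_idx = rng.choice(cfg.n_loci, size=cfg.n_adaptive, replace=False)
    adaptive_idx.sort()
    drivers = rng.choice(env_vars, size=cfg.n_adaptive)
    for k, (j, var) in enumerate(zip(adaptive_idx, drivers)):
        z = env[var].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        freq[:, j] = expit(logit(p0[j]) + cfg.beta_env * z)

    calls = rng.binomial(2, freq).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    length = chrom_length or max(10_000, cfg.n_loci * 200)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=cfg.n_loci, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=cfg.n_loci)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    loci = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    samples = [f"ind_{pop_of[i] + 1}_{i + 1:03d}" for i in range(n)]
    G = GenotypeMatrix(samples, loci, calls)

    truth = pd.DataFrame(
        {
            "locus_index": adaptive_idx,
            "chrom": chrom,
            "pos": pos[adaptive_idx],
            "driver": drivers,
            "beta": cfg.beta_env,
        }
    )
    return G, truth


# ---------------------------------------------------------------------------
# Sweep haplotypes
# ---------------------------------------------------------------------------

def simulate_sweep_haplotypes(
    n_hap: int,
    n_loci: int,
    sweep_freq: float,
    sweep_core: int,
    sweep_span: int,
    seed: int,
    spacing_bp: int = 1000,
    chrom: str = "1",
) -> HaplotypeSet:
    """Binary haplotypes with a hard sweep shared by ``sweep_freq`` of them.

    Markers sit at ``spacing_bp, 2*spacing_bp, ...``. Within
    ``[sweep_core - sweep_span/2, sweep_core + sweep_span/2]`` a random
    subset of round(sweep_freq * n_hap) haplotypes carries one identical
    allele string; all other entries are i.i.d. Bernoulli(0.5).
    """
    if n_hap < 4:
        raise ValueError("n_hap must be >= 4 for haplotype-homozygosity statistics")
    if not 0.0 < sweep_freq <= 1.0:
        raise ValueError("sweep_freq must be in (0, 1]")
    positions = np.arange(1, n_loci + 1, dtype=np.int64) * spacing_bp
    if not positions[0] <= sweep_core <= positions[-1]:
        raise ValueError("sweep_core outside the marker coordinate range")
    rng = np.random.default_rng(seed)
    hap = rng.integers(0, 2, size=(n_hap, n_loci), dtype=np.int8)

    half = sweep_span / 2.0
    in_span = (positions >= sweep_core - half) & (positions <= sweep_core + half)
    n_carriers = int(round(sweep_freq * n_hap))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    template = rng.integers(0, 2, size=int(in_span.sum()), dtype=np.int8)
    hap[np.ix_(carriers, np.flatnonzero(in_span))] = template
    return HaplotypeSet(hap, positions, chrom=chrom)
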