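"""Selection scans: environment-stratified FST and haplotype homozygosity.

Two complementary statistics:

* Weir & Cockerham (1984) two-population variance components (a, b, c) per
  site, aggregated into 20-kb windows as weighted FST = sum(a)/sum(a+b+c),
  contrasting samples from the lower vs upper quartile of an environmental
  variable (divergent selection along that gradient).
* EHH12 — extended haplotype homozygosity with the two most frequent
  extended haplotype classes pooled — integrated over physical distance
  from a core site (iHH12), z-normalized genome-wide, and windowed
  (recent hard and soft sweeps shared by the whole sample).

Windows are fixed 1-based inclusive tiles (step = size); only the BED
export uses 0-based half-open coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ScanResult",
    "quartile_groups",
    "wc84_components",
    "wc84_site",
    "windowed_weighted_fst",
    "ehh12_profile",
    "ihh12_score",
    "normalize_and_window",
]


@dataclass
class ScanResult:
    """Per-window statistic track with top-fraction flags."""

    windows: pd.DataFrame  # chrom, start, end, stat, n_sites, top_flag
    stat_name: str

    def to_bed(self, path: str) -> None:
        """BED-like TSV; start converted to 0-based half-open here only."""
        out = self.windows.copy()
        out["start"] = out["start"] - 1
        out[["chrom", "start", "end", "stat", "top_flag"]].to_csv(
            path, sep="\t", index=False, header=False
        )


def _flag_top(windows: pd.DataFrame, top_frac: float) -> pd.DataFrame:
    windows = windows.reset_index(drop=True)
    n_top = math.ceil(top_frac * len(windows)) if len(windows) else 0
    windows["top_flag"] = False
    if n_top:
        order = windows["stat"].to_numpy().argsort()[::-1][:n_top]
        windows.loc[order, "top_flag"] = True
    return windows


# ---------------------------------------------------------------------------
# Environmental quartile grouping
# ---------------------------------------------------------------------------

def quartile_groups(
    E: pd.DataFrame, variable: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices in the lower (<= Q1) and upper (>= Q3) quartile.

    Quartiles are the 25th/75th percentiles with linear interpolation;
    boundary values are included in their group, middle samples excluded.
    """
    values = E[variable].to_numpy(dtype=float)
    if len(values) < 8:
        raise ValueError("quartile grouping needs >= 8 samples")
    q1, q3 = np.percentile(values, [25, 75])
    if q1 == q3:
        raise ValueError(f"degenerate quartiles for {variable!r} (massive ties)")
    low = np.flatnonzero(values <= q1)
    high = np.flatnonzero(values >= q3)
    if low.size == 0 or high.size == 0:
        raise ValueError("empty quartile group")
    return low, high


# ---------------------------------------------------------------------------
# Weir-Cockerham (1984) two-population components
# ---------------------------------------------------------------------------

def wc84_components(
    geno_low: np.ndarray, geno_high: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for two groups.

    Inputs are allele-count matrices (samples x loci, values 0/1/2 with
    MISSING allowed). With per-group genotyped sizes n_i, ALT frequencies
    p_i and heterozygote fractions h_i (r = 2 populations):

        n_bar = mean(n_i);  n_c = sum(n) - sum(n^2)/sum(n)
        p_bar = weighted mean of p_i;  s2 = sum n_i (p_i - p_bar)^2 / n_bar
        h_bar = weighted mean of h_i
        a = (n_bar/n_c) [s2 - (1/(n_bar-1)) (p_bar(1-p_bar) - s2/2 - h_bar/4)]
        b = (n_bar/(n_bar-1)) [p_bar(1-p_bar) - s2/2 - ((2 n_bar - 1)/(4 n_bar)) h_bar]
        c = h_bar / 2

    Loci with fewer than 2 genotyped samples in either group yield NaN.
    """
    stats = []
    for g in (np.asarray(geno_low), np.asarray(geno_high)):
        obs = g != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
            h = (g == 1).sum(axis=0) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats

    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n1 + n2
        n_bar = n_sum / 2.0
        n_c = n_sum - (n1**2 + n2**2) / n_sum
        p_bar = (n1 * p1 + n2 * p2) / n_sum
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / n_sum

        inner = p_bar * (1 - p_bar) - s2 / 2.0 - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 / 2.0 - ((2 * n_bar - 1.0) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    nan = np.where(valid, 0.0, np.nan)
    return a + nan, b + nan, c + nan


def wc84_site(
    geno_low: np.ndarray, geno_high: np.ndarray
) -> tuple[float, float, float, float]:
    """Single-site WC84 components and theta (NaN when denominator is 0)."""
    a, b, c = wc84_components(
        np.asarray(geno_low).reshape(len(geno_low), 1),
        np.asarray(geno_high).reshape(len(geno_high), 1),
    )
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if denom != 0 and np.isfinite(denom) else float("nan")
    return a, b, c, theta


def windowed_weighted_fst(
    G: GenotypeMatrix,
    groups: tuple[np.ndarray, np.ndarray],
    window_bp: int = 20_000,
    step_bp: int = 20_000,
    top_frac: float = 0.01,
) -> ScanResult:
    """Weighted FST = sum(a)/sum(a+b+c) per fixed window.

    Windows with no usable sites or with statistic <= 0 are omitted before
    the top fraction (ceiling) is flagged.
    """
    low, high = groups
    a, b, c = wc84_components(G.calls[low], G.calls[high])
    denom_site = a + b + c
    rows = []
    for chrom, sub in G.loci.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        start = 1
        last = int(pos.max())
        while start <= last:
            end = start + window_bp - 1
            in_w = idx[(pos >= start) & (pos <= end)]
            ok = in_w[np.isfinite(denom_site[in_w])]
            if ok.size:
                denom = denom_site[ok].sum()
                if denom != 0:
                    stat = a[ok].sum() / denom
                    if stat > 0:
                        rows.append((chrom, start, end, float(stat), int(ok.size)))
            start += step_bp
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "stat", "n_sites"]
    )
    windows = _flag_top(windows, top_frac)
    return ScanResult(windows=windows, stat_name="weighted_fst")


# ---------------------------------------------------------------------------
# EHH12 / iHH12
# ---------------------------------------------------------------------------

def _ehh12_from_counts(counts: np.ndarray, n: int) -> float:
    counts = np.sort(counts)[::-1]
    n12 = counts[:2].sum()
    rest = counts[2:]
    return float((n12 * (n12 - 1) + (rest * (rest - 1)).sum()) / (n * (n - 1)))


def ehh12_profile(
    H, core_index: int, stop_below: float | None = None
) -> dict[str, np.ndarray]:
    """EHH12 at every marker extending left/right from the core.

    Haplotypes are partitioned by their allele string over the interval
    from the core to the current marker; EHH12 pools the two largest
    classes: [n12(n12-1) + sum_{i>2} n_i(n_i-1)] / [n(n-1)]. The profile
    is monotone non-increasing with distance, so an optional
    ``stop_below`` threshold truncates each side at the first marker
    whose value falls below it without changing earlier values. Returns
    arrays of marker indices and EHH12 values per side, starting at the
    core.
    """
    hap = H.haplotypes
    n, L = hap.shape
    if n < 4:
        raise ValueError("EHH12 needs >= 4 haplotypes")
    if not 0 <= core_index < L:
        raise ValueError("core index out of range")

    def side(step: int) -> tuple[np.ndarray, np.ndarray]:
        ids = hap[:, core_index].astype(np.int64)
        _, ids = np.unique(ids, return_inverse=True)
        idx = [core_index]
        vals = [_ehh12_from_counts(np.bincount(ids), n)]
        j = core_index + step
        while 0 <= j < L:
            ids = ids * 2 + hap[:, j]
            _, ids = np.unique(ids, return_inverse=True)
            idx.append(j)
            vals.append(_ehh12_from_counts(np.bincount(ids), n))
            if stop_below is not None and vals[-1] < stop_below:
                break
            j += step
        return np.array(idx), np.array(vals)

    left_idx, left_vals = side(-1)
    right_idx, right_vals = side(+1)
    return {
        "left_index": left_idx,
        "left_ehh12": left_vals,
        "right_index": right_idx,
        "right_ehh12": right_vals,
    }


def ihh12_score(
    H,
    core_index: int,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> tuple[float, bool]:
    """Integrated EHH12 against physical distance around a core marker.

    Trapezoidal integration proceeds outward on each side while EHH12 at
    the far marker stays >= ``cutoff``; the segment reaching the first
    sub-cutoff marker is excluded. A marker gap larger than ``max_gap_bp``
    terminates that side. Sides that run to the chromosome edge without
    decaying below the cutoff are flagged as edge-truncated. Returns
    ``(left + right integral in bp, truncated_flag)``.
    """
    prof = ehh12_profile(H, core_index, stop_below=cutoff)
    pos = H.positions
    truncated = False
    total = 0.0
    for which in ("left", "right"):
        idx = prof[f"{which}_index"]
        vals = prof[f"{which}_ehh12"]
        side_sum = 0.0
        reached_cutoff = False
        for k in range(1, len(idx)):
            gap = abs(int(pos[idx[k]]) - int(pos[idx[k - 1]]))
            if gap > max_gap_bp:
                reached_cutoff = True  # terminated, not edge-truncated
                break
            if vals[k] < cutoff:
                reached_cutoff = True
                break
            side_sum += 0.5 * (vals[k] + vals[k - 1]) * gap
        if not reached_cutoff:
            truncated = True
        total += side_sum
    return total, truncated


def normalize_and_window(
    chrom: np.ndarray,
    positions: np.ndarray,
    scores: np.ndarray,
    window_bp: int = 20_000,
    top_frac: float = 0.01,
    aggregator: str = "max",
) -> ScanResult:
    """Z-normalize per-site scores genome-wide and window the result.

    z = (score - mean)/SD over all sites; the window statistic is the max
    (default) or mean z among the sites in each fixed tile; the top
    ceiling(top_frac * n_windows) windows are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    positions = np.asarray(positions)
    chrom = np.asarray(chrom)
    if scores.size < 2:
        raise ValueError("need >= 2 scores to normalize")
    sd = scores.std()
    if sd == 0:
        raise ValueError("zero variance in scores: z-normalization undefined")
    z = (scores - scores.mean()) / sd

    agg = {"max": np.max, "mean": np.mean}[aggregator]
    rows = []
    for ch in pd.unique(chrom):
        sel = chrom == ch
        pos = positions[sel]
        zz = z[sel]
        start = 1
        last = int(pos.max())
        while start <= last:
            end = start + window_bp - 1
            in_w = (pos >= start) & (pos <= end)
            if in_w.any():
                rows.append((ch, start, end, float(agg(zz[in_w])), int(in_w.sum())))
            start += window_bp
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "n_sites"])
    windows = _flag_top(windows, top_frac)
    return ScanResult(windows=windows, stat_name=f"{aggregator}_norm_ihh12")
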