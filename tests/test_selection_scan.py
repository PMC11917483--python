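"""Quartile grouping, Weir-Cockerham components, windowed FST, and
EHH12/iHH12 — with independent formula and string-partition oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landgea import selection_scan as ss
from landgea import synthetic
from landgea.genotype_io import MISSING, GenotypeMatrix
from landgea.synthetic import HaplotypeSet


def _geno(calls, positions=None, chrom="1A"):
    calls = np.asarray(calls, dtype=np.int8)
    L = calls.shape[1]
    positions = positions if positions is not None else range(100, 100 + L * 10, 10)
    loci = pd.DataFrame({"chrom": chrom, "pos": list(positions), "ref": "A", "alt": "G"})
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], loci, calls)


class TestQuartileGroups:
    def test_boundaries_inclusive(self):
        E = pd.DataFrame({"v": np.arange(1.0, 9.0)})
        low, high = ss.quartile_groups(E, "v")
        assert list(E["v"].iloc[low]) == [1.0, 2.0]
        assert list(E["v"].iloc[high]) == [7.0, 8.0]

    def test_constant_variable_is_error(self):
        E = pd.DataFrame({"v": np.ones(10)})
        with pytest.raises(ValueError):
            ss.quartile_groups(E, "v")

    def test_group_sizes_near_quarter(self):
        E = pd.DataFrame({"v": np.random.default_rng(0).normal(size=400)})
        low, high = ss.quartile_groups(E, "v")
        assert abs(len(low) - 100) <= 2 and abs(len(high) - 100) <= 2


def _wc84_oracle(g1, g2):
    """Textbook two-population formula, written independently (scalars,
    explicit loops over genotyped samples)."""
    def pop_stats(g):
        g = [x for x in g if x != MISSING]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h

    n1, p1, h1 = pop_stats(g1)
    n2, p2, h2 = pop_stats(g2)
    r = 2
    nbar = (n1 + n2) / r
    nc = ((n1 + n2) - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWc84:
    def test_identical_groups_nonpositive_theta(self):
        g = np.array([0, 1, 2, 1, 0, 1])
        a, b, c, theta = ss.wc84_site(g, g.copy())
        assert theta <= 0 or math.isnan(theta)

    def test_fixed_alternative_alleles_theta_one(self):
        a, b, c, theta = ss.wc84_site([0, 0, 0, 0], [2, 2, 2, 2])
        assert theta == pytest.approx(1.0)

    def test_monomorphic_identical_sites_undefined(self):
        a, b, c, theta = ss.wc84_site([0, 0, 0], [0, 0, 0])
        assert math.isnan(theta)

    def test_matches_independent_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n1, n2 = rng.integers(3, 15, size=2)
            g1 = rng.integers(0, 3, size=n1)
            g2 = rng.integers(0, 3, size=n2)
            if len(set(g1) | set(g2)) == 1:
                continue
            a, b, c, _ = ss.wc84_site(g1, g2)
            ao, bo, co = _wc84_oracle(list(g1), list(g2))
            assert a == pytest.approx(ao, abs=1e-10)
            assert b == pytest.approx(bo, abs=1e-10)
            assert c == pytest.approx(co, abs=1e-10)

    def test_missing_calls_excluded(self):
        g1 = [0, 0, 2, MISSING]
        g2 = [2, 2, 0, 0]
        a1, b1, c1, t1 = ss.wc84_site(g1, g2)
        a2, b2, c2, t2 = ss.wc84_site([0, 0, 2], g2)
        assert t1 == pytest.approx(t2)


class TestWindowedFst:
    def test_single_site_window_equals_site_theta(self):
        calls = np.vstack([np.zeros((4, 1)), np.full((4, 1), 2)]).astype(np.int8)
        calls[0, 0] = 1
        G = _geno(calls, positions=[5000])
        res = ss.windowed_weighted_fst(G, (np.arange(4), np.arange(4, 8)))
        _, _, _, theta = ss.wc84_site(calls[:4, 0], calls[4:, 0])
        assert len(res.windows) == 1
        assert res.windows["stat"].iloc[0] == pytest.approx(theta)

    def test_identical_groups_all_windows_omitted(self):
        rng = np.random.default_rng(1)
        half = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        G = _geno(np.vstack([half, half]))
        res = ss.windowed_weighted_fst(G, (np.arange(6), np.arange(6, 12)))
        assert res.windows.empty

    def test_fully_divergent_windows_stat_one(self):
        calls = np.vstack([np.zeros((4, 60)), np.full((4, 60), 2)]).astype(np.int8)
        G = _geno(calls, positions=range(1000, 1000 + 60 * 1000, 1000))
        res = ss.windowed_weighted_fst(G, (np.arange(4), np.arange(4, 8)))
        assert np.allclose(res.windows["stat"], 1.0)
        assert res.windows["top_flag"].sum() == math.ceil(0.01 * len(res.windows))


def _ehh12_string_oracle(hap, core, j):
    """Exhaustive partition of haplotypes by their allele string over the
    inclusive marker interval [min(core,j), max(core,j)] restricted to the
    core-to-j direction."""
    lo, hi = min(core, j), max(core, j)
    strings = ["".join(map(str, row[lo:hi + 1])) for row in hap]
    counts = sorted((strings.count(s) for s in set(strings)), reverse=True)
    n = len(hap)
    n12 = sum(counts[:2])
    tail = sum(x * (x - 1) for x in counts[2:])
    return (n12 * (n12 - 1) + tail) / (n * (n - 1))


class TestEhh12:
    def test_identical_haplotypes_stay_at_one(self):
        H = HaplotypeSet(np.tile([1, 0, 1, 1, 0], (6, 1)), [10, 20, 30, 40, 50])
        prof = ss.ehh12_profile(H, 2)
        assert np.allclose(prof["left_ehh12"], 1.0)
        assert np.allclose(prof["right_ehh12"], 1.0)

    def test_all_distinct_extension_hits_pooled_floor(self):
        # 4 haplotypes all distinct after one extension: n12 = 2, others 1
        hap = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        H = HaplotypeSet(hap, [10, 20])
        prof = ss.ehh12_profile(H, 0)
        n = 4
        floor = (2 * 1) / (n * (n - 1))
        assert prof["right_ehh12"][1] == pytest.approx(floor)

    def test_matches_string_partition_oracle(self):
        rng = np.random.default_rng(2)
        hap = rng.integers(0, 2, size=(20, 50))
        H = HaplotypeSet(hap, np.arange(1, 51) * 100)
        core = 25
        prof = ss.ehh12_profile(H, core)
        for k, j in enumerate(prof["right_index"]):
            assert prof["right_ehh12"][k] == pytest.approx(
                _ehh12_string_oracle(hap, core, int(j)), abs=1e-12
            )
        for k, j in enumerate(prof["left_index"]):
            assert prof["left_ehh12"][k] == pytest.approx(
                _ehh12_string_oracle(hap, core, int(j)), abs=1e-12
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 30), st.integers(4, 16))
    def test_profile_monotone_non_increasing(self, seed, L, n):
        rng = np.random.default_rng(seed)
        hap = rng.integers(0, 2, size=(n, L))
        H = HaplotypeSet(hap, np.arange(1, L + 1) * 10)
        prof = ss.ehh12_profile(H, L // 2)
        assert (np.diff(prof["left_ehh12"]) <= 1e-12).all()
        assert (np.diff(prof["right_ehh12"]) <= 1e-12).all()


class TestIhh12:
    def test_identical_haplotypes_integrate_full_span(self):
        H = synthetic.simulate_sweep_haplotypes(
            10, 50, sweep_freq=1.0, sweep_core=25_000, sweep_span=10**7, seed=0
        )
        score, truncated = ss.ihh12_score(H, 24)
        span = H.positions[-1] - H.positions[0]
        assert truncated  # ran to both chromosome edges
        assert score == pytest.approx(span)

    def test_invariant_to_allele_relabeling_off_core(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, size=(12, 40))
        H1 = HaplotypeSet(hap, np.arange(1, 41) * 500)
        flipped = hap.copy()
        flipped[:, :20] = 1 - flipped[:, :20]  # core at 25 untouched
        H2 = HaplotypeSet(flipped, np.arange(1, 41) * 500)
        s1, _ = ss.ihh12_score(H1, 25)
        s2, _ = ss.ihh12_score(H2, 25)
        assert s1 == pytest.approx(s2)

    def test_large_gap_terminates_side(self):
        hap = np.tile([1, 0, 1, 1], (6, 1))
        H = HaplotypeSet(hap, [1000, 2000, 500_000, 501_000])
        score, _ = ss.ihh12_score(H, 1, max_gap_bp=200_000)
        assert score == pytest.approx(1000.0)  # only the left interval

    def test_sweep_scores_above_neutral(self):
        wins = 0
        for rep in range(20):
            Hs = synthetic.simulate_sweep_haplotypes(
                40, 300, 0.9, 150_000, 80_000, seed=rep
            )
            Hn = synthetic.simulate_sweep_haplotypes(
                40, 300, 1 / 40, 150_000, 80_000, seed=1000 + rep
            )
            core = int(np.argmin(np.abs(Hs.positions - 150_000)))
            wins += ss.ihh12_score(Hs, core)[0] > ss.ihh12_score(Hn, core)[0]
        assert wins >= 19


class TestNormalizeAndWindow:
    def test_scores_standardized(self):
        rng = np.random.default_rng(4)
        scores = rng.gamma(2, 5, size=500)
        pos = np.arange(1, 501) * 1000
        res = ss.normalize_and_window(np.repeat("1", 500), pos, scores)
        z = (scores - scores.mean()) / scores.std()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)
        assert res.windows["top_flag"].sum() == math.ceil(0.01 * len(res.windows))

    def test_extreme_site_window_flagged(self):
        scores = np.ones(200)
        scores[137] = 50.0
        pos = np.arange(1, 201) * 1000
        res = ss.normalize_and_window(np.repeat("1", 200), pos, scores)
        w = res.windows[(res.windows["start"] <= 138_000) & (res.windows["end"] >= 138_000)]
        assert w["top_flag"].all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ss.normalize_and_window(
                np.repeat("1", 5), np.arange(1, 6) * 1000, np.ones(5)
            )


def test_divergence_and_sweep_top_windows_disjoint(env_landscape):
    """High-FST windows (environment-stratified divergence) and iHH12 sweep
    windows live on separate simulated chromosomes, so their top-window
    sets must not overlap."""
    _, sites = env_landscape
    cfg = synthetic.SimConfig(n_pops=2, n_per_pop=45, n_loci=400,
                              fst_neutral=0.15, n_adaptive=0, seed=41)
    G, _ = synthetic.simulate_structured_genotypes(cfg, sites, chrom="div")
    groups = (np.arange(45), np.arange(45, 90))
    fst_scan = ss.windowed_weighted_fst(G, groups)
    H = synthetic.simulate_sweep_haplotypes(
        40, 500, 0.9, 250_000, 20_000, seed=42, chrom="sweep"
    )
    scores = np.array([ss.ihh12_score(H, j)[0] for j in range(H.n_markers)])
    hh_scan = ss.normalize_and_window(
        np.repeat("sweep", H.n_markers), H.positions, scores
    )
    fst_top = set(map(tuple, fst_scan.windows.loc[fst_scan.windows.top_flag,
                                                  ["chrom", "start"]].to_numpy()))
    hh_top = set(map(tuple, hh_scan.windows.loc[hh_scan.windows.top_flag,
                                                ["chrom", "start"]].to_numpy()))
    assert fst_top and hh_top and not (fst_top & hh_top)
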