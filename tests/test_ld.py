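"""Two-locus EM, r2 / D' equations, adjacent-pair and decay summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldscape.genotype import MISSING
from ldscape.ld import (
    HaplotypeFreqs,
    UndefinedLDError,
    adjacent_pair_summary,
    compute_dprime,
    compute_pair_ld,
    compute_r2,
    em_haplotype_freqs,
    ld_decay,
    panel_density,
    threshold_distance,
)
from ldscape.simulate import SimConfig, make_ld_fixture, simulate_population

from conftest import grid_haplotype_freqs, make_matrix, two_locus_loglik


def freqs(p_ab, p_a_b, p_ab2, p_a2b2, n=100):
    return HaplotypeFreqs(p_AB=p_ab, p_Ab=p_a_b, p_aB=p_ab2, p_ab=p_a2b2, n_eff=n)


# ---------------------------------------------------------------------------
# r2 / D' equations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vec,r2,dp",
    [
        ((0.5, 0.0, 0.0, 0.5), 1.0, 1.0),       # complete LD
        ((0.25, 0.25, 0.25, 0.25), 0.0, 0.0),   # equilibrium
        ((0.4, 0.1, 0.1, 0.4), 0.36, 0.6),      # hand case: D=0.15, Dmax=0.25
    ],
)
def test_r2_and_dprime_reference_cases(vec, r2, dp):
    h = freqs(*vec)
    assert compute_r2(h) == pytest.approx(r2, abs=1e-12)
    assert compute_dprime(h) == pytest.approx(dp, abs=1e-12)


def test_zero_allele_frequency_is_undefined():
    h = freqs(0.5, 0.5, 0.0, 0.0)  # locus 2 monomorphic (P_b ... P_B = 1)
    with pytest.raises(UndefinedLDError):
        compute_r2(h)
    with pytest.raises(UndefinedLDError):
        compute_dprime(h)


@st.composite
def haplotype_vectors(draw):
    raw = [draw(st.floats(0.01, 1.0)) for _ in range(4)]
    total = sum(raw)
    return tuple(v / total for v in raw)


@settings(max_examples=300, derandomize=True)
@given(haplotype_vectors())
def test_r2_identity_and_dprime_bound(vec):
    """The printed r2 formula equals D^2/(P_A P_a P_B P_b); r2 <= D'^2;
    swapping allele labels keeps r2 and flips the sign of D'."""
    h = freqs(*vec)
    d = h.D
    denom = h.p_A * h.p_a * h.p_B * h.p_b
    assert compute_r2(h) == pytest.approx(d * d / denom, abs=1e-12)
    dp = compute_dprime(h)
    assert abs(dp) <= 1.0 + 1e-9
    assert compute_r2(h) <= dp * dp + 1e-9
    swapped = freqs(vec[2], vec[3], vec[0], vec[1])  # relabel locus-1 alleles
    assert compute_r2(swapped) == pytest.approx(compute_r2(h), abs=1e-12)
    assert compute_dprime(swapped) == pytest.approx(-dp, abs=1e-12)


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def test_em_exact_when_no_double_heterozygotes():
    g1 = np.array([0] * 10 + [2] * 10, dtype=np.int8)
    g2 = np.array([0] * 10 + [2] * 10, dtype=np.int8)
    h = em_haplotype_freqs(g1, g2)
    assert (h.p_AB, h.p_ab) == (0.5, 0.5)
    assert (h.p_Ab, h.p_aB) == (0.0, 0.0)


def test_em_ignores_missing_pairs():
    g1 = np.array([0, 1, 2, 1, MISSING], dtype=np.int8)
    g2 = np.array([0, 1, 2, MISSING, 1], dtype=np.int8)
    h = em_haplotype_freqs(g1, g2)
    h2 = em_haplotype_freqs(g1[:3], g2[:3])
    assert h.n_eff == 3
    assert h.p_AB == pytest.approx(h2.p_AB, abs=1e-9)


def test_em_monomorphic_raises():
    with pytest.raises(UndefinedLDError):
        em_haplotype_freqs(np.zeros(10, dtype=np.int8),
                           np.array([0, 1] * 5, dtype=np.int8))


def test_em_all_double_heterozygotes_reaches_ml_boundary():
    """All-double-het data: the ML solution is complete LD (either
    phase); EM must reach likelihood parity with the grid oracle."""
    g = np.ones(10, dtype=np.int8)
    h = em_haplotype_freqs(g, g)
    counts = np.zeros((3, 3))
    counts[1, 1] = 10
    _, ll_grid = grid_haplotype_freqs(g, g)
    ll_em = two_locus_loglik(counts, (h.p_AB, h.p_Ab, h.p_aB, h.p_ab))
    assert ll_em >= ll_grid - 1e-6
    assert compute_r2(h) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("seed", range(12))
def test_em_matches_grid_search_oracle(seed):
    """On <=20-individual fixtures the EM solution matches a 1e-4-grid
    brute-force likelihood maximisation (frequencies within 1e-3, or
    likelihood parity when the maximum is not unique)."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
    g1, g2 = make_ld_fixture(tuple(p), 20, seed=rng)
    try:
        h = em_haplotype_freqs(g1, g2)
    except UndefinedLDError:
        pytest.skip("fixture monomorphic at this seed")
    grid_vec, ll_grid = grid_haplotype_freqs(g1, g2)
    em_vec = np.array([h.p_AB, h.p_Ab, h.p_aB, h.p_ab])
    if np.abs(em_vec - grid_vec).max() >= 1e-3:
        counts = np.zeros((3, 3))
        for a, b in zip(g1, g2):
            counts[a, b] += 1
        assert two_locus_loglik(counts, em_vec) >= ll_grid - 1e-6
    # invariants of the returned solution
    assert em_vec.sum() == pytest.approx(1.0, abs=1e-9)
    assert em_vec.min() >= -1e-12


def test_em_loglik_nondecreasing():
    rng = np.random.default_rng(3)
    g1, g2 = make_ld_fixture((0.4, 0.1, 0.2, 0.3), 30, seed=rng)
    ok = np.ones(len(g1), dtype=bool)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    # re-run the EM manually one sweep at a time and track the likelihood
    from ldscape.ld import _em_batch

    lls = []
    for iters in (1, 2, 5, 20, 100):
        f, _, _ = _em_batch(counts[None], max_iter=iters)
        lls.append(two_locus_loglik(counts, f[0]))
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_em_appending_missing_pair_is_invariant():
    rng = np.random.default_rng(5)
    g1, g2 = make_ld_fixture((0.3, 0.2, 0.2, 0.3), 25, seed=rng)
    h = em_haplotype_freqs(g1, g2)
    g1x = np.append(g1, MISSING).astype(np.int8)
    g2x = np.append(g2, MISSING).astype(np.int8)
    hx = em_haplotype_freqs(g1x, g2x)
    assert hx.p_AB == pytest.approx(h.p_AB, abs=1e-12)
    assert hx.n_eff == h.n_eff


def test_sampled_fixture_recovers_r2():
    """n=10,000 draws from (0.4,0.1,0.1,0.4): EM r2 within 0.02 of 0.36."""
    g1, g2 = make_ld_fixture((0.4, 0.1, 0.1, 0.4), 10_000, seed=11)
    h = em_haplotype_freqs(g1, g2)
    assert compute_r2(h) == pytest.approx(0.36, abs=0.02)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _perfect_ld_matrix(n_snps=5, n=20, contig="chr1", pos0=1000):
    """All SNPs share one haplotype pattern -> every pair in complete LD."""
    col = np.array([0] * (n // 2) + [2] * (n - n // 2), dtype=np.int8)
    calls = np.tile(col[:, None], (1, n_snps))
    return calls, [pos0 + 10_000 * k for k in range(n_snps)], [contig] * n_snps


def test_adjacent_summary_perfect_ld_row():
    calls, pos, contigs = _perfect_ld_matrix()
    gm = make_matrix(calls, positions=pos, contigs=contigs)
    t = adjacent_pair_summary(gm)
    row = t[t["scaffold"] == "chr1"].iloc[0]
    assert row["n_pairs"] == 4  # k SNPs -> k-1 adjacent pairs
    assert row["mean_r2"] == pytest.approx(1.0)
    assert row["mean_dprime"] == pytest.approx(1.0)
    assert row["pct_r2_gt_0.2"] == 100.0
    assert row["pct_r2_gt_0.8"] == 100.0


def test_overall_row_pools_over_pairs_not_scaffolds(rng):
    cfg = SimConfig(seed=5, n_samples=30,
                    contigs=(("c1", 2_000_000), ("c2", 4_000_000)),
                    snp_density=10, ne_trajectory=((100, 50),),
                    missing_rate=0.0, genotype_error_rate=0.0)
    gm, _ = simulate_population(cfg)
    t = adjacent_pair_summary(gm)
    pairs = compute_pair_ld(gm, adjacent_only=True)
    overall = t[t["scaffold"] == "Overall"].iloc[0]
    assert overall["n_pairs"] == len(pairs)
    assert overall["mean_r2"] == pytest.approx(pairs["r2"].mean())


def test_decay_bin_boundary_is_half_open():
    """A pair at exactly 10,000 bp falls in the first (0, 10k] bin."""
    calls, _, _ = _perfect_ld_matrix(n_snps=2)
    gm = make_matrix(calls, positions=[1000, 11_000])
    decay = ld_decay(gm, 100_000, 10_000)
    assert decay.loc[0, "n_pairs"] == 1
    assert decay.loc[1:, "n_pairs"].sum() == 0
    assert np.isnan(decay.loc[1, "mean_r2"])  # empty bin reported


def test_decay_bin_means_match_brute_force(rng):
    cfg = SimConfig(seed=9, n_samples=25, contigs=(("c1", 3_000_000),),
                    snp_density=15, ne_trajectory=((100, 60),),
                    missing_rate=0.05, genotype_error_rate=0.0)
    gm, _ = simulate_population(cfg)
    pairs = compute_pair_ld(gm, max_dist=3_000_000)
    decay = ld_decay(gm, 3_000_000, 500_000)
    # brute force: enumerate pairs directly and bin by (lower, upper]
    for _, row in decay.iterrows():
        sel = pairs[(pairs["distance"] > row["bin_lower"])
                    & (pairs["distance"] <= row["bin_upper"])]
        assert row["n_pairs"] == len(sel)
        if len(sel):
            assert row["mean_r2"] == pytest.approx(sel["r2"].mean(), abs=1e-12)


def test_decay_requires_multiple_of_bin_width():
    gm = make_matrix([[0, 1], [1, 2], [2, 0]])
    with pytest.raises(ValueError):
        ld_decay(gm, 95_000, 10_000)


def test_equilibrium_decay_is_monotone_in_aggregate():
    """Constant-Ne populations: mean r2 per distance bin non-increasing
    (within Monte-Carlo tolerance, pooled over replicates)."""
    bins = None
    for seed in range(5):
        cfg = SimConfig(seed=40 + seed, n_samples=40,
                        contigs=(("c1", 5_000_000),), snp_density=15,
                        ne_trajectory=((150, 80),), target_maf_mean=0.3,
                        missing_rate=0.0, genotype_error_rate=0.0)
        gm, _ = simulate_population(cfg)
        pairs = compute_pair_ld(gm, max_dist=5_000_000)
        pairs["bin"] = np.ceil(pairs["distance"] / 1_000_000).astype(int)
        g = pairs.groupby("bin")["r2"].agg(["sum", "count"])
        bins = g if bins is None else bins.add(g, fill_value=0)
    means = bins["sum"] / bins["count"]
    assert means.iloc[0] > means.iloc[-1]
    assert (np.diff(means.to_numpy()) < 0.05).all()  # small MC wiggle allowed


def test_composite_estimator_close_to_em_on_strong_ld():
    g1, g2 = make_ld_fixture((0.45, 0.05, 0.05, 0.45), 500, seed=2)
    gm = make_matrix(np.stack([g1, g2], axis=1), positions=[1000, 2000])
    em = compute_pair_ld(gm, estimator="em")
    comp = compute_pair_ld(gm, estimator="composite")
    assert comp.loc[0, "r2"] == pytest.approx(em.loc[0, "r2"], abs=0.05)


# ---------------------------------------------------------------------------
# panel density
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "genome,spacing,expected",
    [(2.4e9, 40_000, 60_000), (2.4e9, 20_000, 120_000), (1e6, 1_000, 1_000)],
)
def test_panel_density(genome, spacing, expected):
    assert panel_density(genome, spacing) == expected


def test_threshold_distance_reports_lower_edge():
    import pandas as pd

    decay = pd.DataFrame(
        {"bin_lower": [0, 10_000, 20_000], "bin_upper": [10_000, 20_000, 30_000],
         "mean_r2": [0.4, 0.25, 0.15]}
    )
    assert threshold_distance(decay, 0.2) == 20_000
    assert threshold_distance(decay, 0.3) == 10_000
    assert threshold_distance(decay, 0.05) is None
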