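"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force —
enumeration, grid search, naive scanning — and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ldscape.genotype import MISSING, GenotypeMatrix


def make_matrix(calls, positions=None, contig="chr1", samples=None,
                contigs=None, info=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a (samples x variants) list."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if contigs is None:
        contigs = [contig] * m
    if positions is None:
        positions = list(range(1000, 1000 * (m + 1), 1000))
    variants = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )
    if info:
        for k, v in info.items():
            variants[k] = v
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # alt-presence at (locus1, locus2)


def two_locus_loglik(counts3x3: np.ndarray, p_ab_vec) -> float:
    """Log-likelihood of a 3x3 genotype-pair table under random mating."""
    p = np.clip(np.asarray(p_ab_vec, dtype=float), 1e-300, 1.0)
    geno = np.zeros((3, 3))
    for i, (x1, y1) in enumerate(_HAPS):
        for j, (x2, y2) in enumerate(_HAPS):
            geno[x1 + x2, y1 + y2] += p[i] * p[j]
    return float((counts3x3 * np.log(np.clip(geno, 1e-300, 1.0))).sum())


def grid_haplotype_freqs(g1, g2, step=1e-4):
    """Brute-force ML haplotype frequencies over a grid of P_AB.

    Allele frequencies are fixed at their (fully informative) genotype
    counts; only the one free parameter P_AB is scanned.  Returns the
    (P_AB, P_Ab, P_aB, P_ab) vector in reference-allele coding and its
    log-likelihood.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    p_a_ref = 1.0 - g1.sum() / (2 * n)
    p_b_ref = 1.0 - g2.sum() / (2 * n)
    lo = max(0.0, p_a_ref + p_b_ref - 1.0)
    hi = min(p_a_ref, p_b_ref)
    best, best_ll = None, -np.inf
    for p_ab in np.arange(lo, hi + step / 2, step):
        vec = (
            p_ab,
            p_a_ref - p_ab,
            p_b_ref - p_ab,
            1.0 - p_a_ref - p_b_ref + p_ab,
        )
        if min(vec) < -1e-12:
            continue
        ll = two_locus_loglik(counts, vec)
        if ll > best_ll:
            best_ll, best = ll, vec
    return np.array(best), best_ll


def naive_hom_stretches(g: np.ndarray, pos: np.ndarray, min_snps: int,
                        min_len: int) -> list[tuple[int, int]]:
    """Maximal stretches of consecutive homozygous genotypes (no missing,
    no error allowance): the reference scanner for ROH detection."""
    out = []
    start = None
    for i, v in enumerate(list(g) + [1]):  # sentinel het terminates
        if v in (0, 2):
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_snps and pos[i - 1] - pos[start] + 1 >= min_len:
                    out.append((int(pos[start]), int(pos[i - 1])))
                start = None
    return out


def homozygous_closure(g: np.ndarray, pos: np.ndarray, start: int,
                       end: int) -> tuple[int, int]:
    """Extend a tract outward while flanking genotypes stay homozygous.

    A detector cannot distinguish chance homozygosity adjacent to an
    implanted tract from the tract itself, so recovered boundaries are
    judged against this closure.
    """
    inside = np.flatnonzero((pos >= start) & (pos <= end))
    if len(inside) == 0:
        return start, end
    lo, hi = int(inside[0]), int(inside[-1])
    while lo > 0 and g[lo - 1] in (0, 2):
        lo -= 1
    while hi < len(g) - 1 and g[hi + 1] in (0, 2):
        hi += 1
    return int(pos[lo]), int(pos[hi])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
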