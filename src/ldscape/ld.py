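"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by maximum likelihood
under Hardy-Weinberg random mating with an EM iteration: for biallelic
SNPs only double heterozygotes are phase-ambiguous, and their expected
cis/trans split given the current frequencies is iterated to a fixed
point.  From the haplotype frequencies the classical measures follow:

    D   = P_AB - P_A P_B
    D'  = D / Dmax,  Dmax = min(P_A P_B, P_a P_b)  if D < 0
                            min(P_A P_b, P_a P_B)  if D >= 0
    r^2 = (P_Ab P_aB - P_AB P_ab)^2 / (P_A P_B P_a P_b)

where A/B denote the reference alleles at the two loci.  A composite
genotypic correlation (Rogers-Huff style) is available as an
alternative estimator that needs no random-mating assumption.

The batch engine vectorises the EM over many pairs at once, which keeps
genome-wide decay scans fast in pure numpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class UndefinedLDError(ValueError):
    """LD is undefined for this pair (a locus is monomorphic in the
    pairwise-complete subset, or too few complete individuals)."""


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequency solution.

    ``A``/``a`` are the reference/alternate alleles at the first locus,
    ``B``/``b`` at the second.  ``n_eff`` counts individuals with both
    genotypes non-missing.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n_eff: int

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_a(self) -> float:
        return self.p_aB + self.p_ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    @property
    def p_b(self) -> float:
        return self.p_Ab + self.p_ab

    @property
    def D(self) -> float:
        return self.p_AB - self.p_A * self.p_B


@dataclass
class PairLD:
    """LD summary for one syntenic SNP pair."""

    contig: str
    pos_i: int
    pos_j: int
    distance: int
    D: float
    d_max: float
    d_prime: float
    r2: float


# ---------------------------------------------------------------------------
# Batch EM engine
# ---------------------------------------------------------------------------

def _pair_count_tables(
    calls: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray
) -> np.ndarray:
    """3x3 genotype-pair count tables for each (i, j) variant pair.

    Returns an array of shape (n_pairs, 3, 3) where entry [p, a, b]
    counts individuals with dosage a at variant idx_i[p] and dosage b at
    idx_j[p]; missing genotypes are excluded (pairwise-complete).
    """
    n_pairs = len(idx_i)
    counts = np.empty((n_pairs, 3, 3), dtype=np.int64)
    ind = [calls == g for g in (0, 1, 2)]  # (n_samples, n_variants) booleans
    for a in range(3):
        ia = ind[a][:, idx_i]
        for b in range(3):
            jb = ind[b][:, idx_j]
            counts[:, a, b] = (ia & jb).sum(axis=0)
    return counts


def _em_batch(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over a batch of 3x3 genotype-pair count tables.

    Returns ``(freqs, n_eff, defined)`` where ``freqs`` has shape
    (n_pairs, 4) ordered (P_AB, P_Ab, P_aB, P_ab) with A/B the reference
    alleles, ``n_eff`` the pairwise-complete sample counts, and
    ``defined`` flags pairs where both loci are polymorphic and
    ``n_eff >= 2``.  Undefined pairs carry NaN frequencies.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 2:
        counts = counts[None]
    n = counts  # alias: n[p, g1, g2]
    n_eff = n.sum(axis=(1, 2))

    # unambiguous haplotype contributions (alt-presence coding x,y in {0,1}):
    # every genotype pair except the double heterozygote resolves uniquely.
    b00 = 2 * n[:, 0, 0] + n[:, 0, 1] + n[:, 1, 0]
    b01 = 2 * n[:, 0, 2] + n[:, 0, 1] + n[:, 1, 2]
    b10 = 2 * n[:, 2, 0] + n[:, 1, 0] + n[:, 2, 1]
    b11 = 2 * n[:, 2, 2] + n[:, 2, 1] + n[:, 1, 2]
    n_dh = n[:, 1, 1]
    two_n = 2.0 * n_eff

    alt1 = b10 + b11 + n_dh  # alt-allele haplotype count, locus 1
    alt2 = b01 + b11 + n_dh
    defined = (n_eff >= 2) & (alt1 > 0) & (alt1 < two_n) & (alt2 > 0) & (alt2 < two_n)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / two_n
        p2 = alt2 / two_n
        # start at linkage equilibrium, with a tiny cis tilt: the exact LE
        # point is a stationary saddle for perfectly symmetric data (e.g.
        # every individual doubly heterozygous) and EM would sit on it
        # instead of reaching a maximum
        p = np.stack(
            [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2], axis=1
        )
        tilt = 1e-8
        p[:, [0, 3]] += tilt
        p[:, [1, 2]] -= tilt
        np.clip(p, 0.0, 1.0, out=p)
        active = defined.copy()
        for _ in range(max_iter):
            if not active.any():
                break
            pa = p[active]
            cis_w = pa[:, 0] * pa[:, 3]
            trans_w = pa[:, 1] * pa[:, 2]
            denom = cis_w + trans_w
            p_cis = np.where(denom > 0, cis_w / np.where(denom > 0, denom, 1.0), 0.5)
            dh = n_dh[active]
            new = np.stack(
                [
                    b00[active] + dh * p_cis,
                    b01[active] + dh * (1 - p_cis),
                    b10[active] + dh * (1 - p_cis),
                    b11[active] + dh * p_cis,
                ],
                axis=1,
            ) / two_n[active, None]
            delta = np.abs(new - pa).max(axis=1)
            p[active] = new
            still = delta >= tol
            idx = np.flatnonzero(active)
            active[idx[~still]] = False

    p[~defined] = np.nan
    return p, n_eff.astype(np.int64), defined


def em_haplotype_freqs(
    g_i: np.ndarray,
    g_j: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeFreqs:
    """ML haplotype frequencies for one pair of genotype vectors.

    Missing entries are excluded pairwise; raises
    :class:`UndefinedLDError` when a locus is monomorphic among the
    complete individuals or fewer than two remain.
    """
    g_i = np.asarray(g_i, dtype=np.int8)
    g_j = np.asarray(g_j, dtype=np.int8)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (g_i != MISSING) & (g_j != MISSING)
    counts = np.zeros((1, 3, 3), dtype=np.int64)
    for a in range(3):
        for b in range(3):
            counts[0, a, b] = int(((g_i[ok] == a) & (g_j[ok] == b)).sum())
    freqs, n_eff, defined = _em_batch(counts, tol=tol, max_iter=max_iter)
    if not defined[0]:
        raise UndefinedLDError(
            "monomorphic locus or <2 pairwise-complete individuals"
        )
    p_AB, p_Ab, p_aB, p_ab = (float(v) for v in freqs[0])
    return HaplotypeFreqs(p_AB=p_AB, p_Ab=p_Ab, p_aB=p_aB, p_ab=p_ab,
                          n_eff=int(n_eff[0]))


# ---------------------------------------------------------------------------
# LD statistics from haplotype frequencies
# ---------------------------------------------------------------------------

def compute_r2(h: HaplotypeFreqs) -> float:
    """r^2 = (P_Ab P_aB - P_AB P_ab)^2 / (P_A P_B P_a P_b)."""
    denom = h.p_A * h.p_B * h.p_a * h.p_b
    if denom <= 0:
        raise UndefinedLDError("allele frequency of 0: r^2 undefined")
    num = h.p_Ab * h.p_aB - h.p_AB * h.p_ab
    return float(num * num / denom)


def compute_dprime(h: HaplotypeFreqs) -> float:
    """D' = D / Dmax with Dmax = min(P_A P_B, P_a P_b) if D < 0 else
    min(P_A P_b, P_a P_B); sign of D is preserved."""
    D = h.D
    if D < 0:
        d_max = min(h.p_A * h.p_B, h.p_a * h.p_b)
    else:
        d_max = min(h.p_A * h.p_b, h.p_a * h.p_B)
    if d_max <= 0:
        raise UndefinedLDError("Dmax = 0: D' undefined")
    return float(D / d_max)


def _batch_ld_stats(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (r2, D, d_prime) from an (n_pairs, 4) frequency array."""
    p_AB, p_Ab, p_aB, p_ab = freqs[:, 0], freqs[:, 1], freqs[:, 2], freqs[:, 3]
    p_A = p_AB + p_Ab
    p_a = p_aB + p_ab
    p_B = p_AB + p_aB
    p_b = p_Ab + p_ab
    D = p_AB - p_A * p_B
    denom = p_A * p_B * p_a * p_b
    with np.errstate(invalid="ignore", divide="ignore"):
        num = p_Ab * p_aB - p_AB * p_ab
        r2 = np.where(denom > 0, num * num / np.where(denom > 0, denom, 1.0), np.nan)
        d_max = np.where(
            D < 0, np.minimum(p_A * p_B, p_a * p_b), np.minimum(p_A * p_b, p_a * p_B)
        )
        d_prime = np.where(d_max > 0, D / np.where(d_max > 0, d_max, 1.0), np.nan)
    return r2, D, d_prime


def _composite_ld_stats(
    calls: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rogers-Huff composite statistics: r is the pairwise-complete
    genotype correlation (r2 = r^2); the composite D = cov(g_i, g_j)/2
    is normalised by the EM-free Dmax from genotypic allele frequencies."""
    n_pairs = len(idx_i)
    r2 = np.full(n_pairs, np.nan)
    D = np.full(n_pairs, np.nan)
    d_prime = np.full(n_pairs, np.nan)
    for p in range(n_pairs):
        gi = calls[:, idx_i[p]].astype(float)
        gj = calls[:, idx_j[p]].astype(float)
        ok = (gi != MISSING) & (gj != MISSING)
        gi, gj = gi[ok], gj[ok]
        if len(gi) < 2 or gi.std() == 0 or gj.std() == 0:
            continue
        r = np.corrcoef(gi, gj)[0, 1]
        r2[p] = r * r
        # composite D in reference-allele coding
        d = np.cov(gi, gj, ddof=1)[0, 1] / 2.0
        p_a_alt, p_b_alt = gi.mean() / 2.0, gj.mean() / 2.0
        p_A, p_B = 1 - p_a_alt, 1 - p_b_alt
        D[p] = d
        if d < 0:
            d_max = min(p_A * p_B, p_a_alt * p_b_alt)
        else:
            d_max = min(p_A * p_b_alt, p_a_alt * p_B)
        if d_max > 0:
            d_prime[p] = d / d_max
    return r2, D, d_prime


# ---------------------------------------------------------------------------
# Pair enumeration and summaries
# ---------------------------------------------------------------------------

def _syntenic_pairs(
    gm: GenotypeMatrix, max_dist: int | None = None, adjacent_only: bool = False
) -> pd.DataFrame:
    """Enumerate syntenic (same-contig) variant index pairs with distances."""
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    for _, sub in gm.variants.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        m = len(idx)
        if m < 2:
            continue
        if adjacent_only:
            rows_i.append(idx[:-1])
            rows_j.append(idx[1:])
            continue
        for k in range(m - 1):
            if max_dist is None:
                hi = m
            else:
                hi = k + 1 + int(np.searchsorted(
                    pos[k + 1:], pos[k] + max_dist, side="right"
                ))
            if hi > k + 1:
                rows_i.append(np.full(hi - k - 1, idx[k]))
                rows_j.append(idx[k + 1: hi])
    if not rows_i:
        return pd.DataFrame(columns=["i", "j", "contig", "pos_i", "pos_j", "distance"])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    pos = gm.variants["pos"].to_numpy()
    contig = gm.variants["contig"].to_numpy()
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "contig": contig[i],
            "pos_i": pos[i],
            "pos_j": pos[j],
            "distance": pos[j] - pos[i],
        }
    )


def compute_pair_ld(
    gm: GenotypeMatrix,
    max_dist: int | None = None,
    adjacent_only: bool = False,
    estimator: str = "em",
    chunk: int = 50_000,
) -> pd.DataFrame:
    """LD statistics for all syntenic pairs (optionally distance-capped).

    Returns a DataFrame with one row per pair: contig, pos_i, pos_j,
    distance, r2, D, d_prime, n_eff.  Pairs with undefined LD
    (monomorphic in the pairwise-complete subset) are dropped and their
    count logged.

    estimator : "em" (haplotype EM, default) or "composite"
        (Rogers-Huff genotypic correlation).
    """
    if estimator not in ("em", "composite"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pairs = _syntenic_pairs(gm, max_dist=max_dist, adjacent_only=adjacent_only)
    if pairs.empty:
        return pairs.assign(r2=[], D=[], d_prime=[], n_eff=[])
    out_r2 = np.empty(len(pairs))
    out_D = np.empty(len(pairs))
    out_dp = np.empty(len(pairs))
    out_ne = np.empty(len(pairs), dtype=np.int64)
    ii = pairs["i"].to_numpy()
    jj = pairs["j"].to_numpy()
    for lo in range(0, len(pairs), chunk):
        hi = min(lo + chunk, len(pairs))
        if estimator == "em":
            counts = _pair_count_tables(gm.calls, ii[lo:hi], jj[lo:hi])
            freqs, n_eff, defined = _em_batch(counts)
            r2, D, dp = _batch_ld_stats(freqs)
        else:
            r2, D, dp = _composite_ld_stats(gm.calls, ii[lo:hi], jj[lo:hi])
            obs = gm.calls != MISSING
            n_eff = (obs[:, ii[lo:hi]] & obs[:, jj[lo:hi]]).sum(axis=0)
        out_r2[lo:hi], out_D[lo:hi], out_dp[lo:hi] = r2, D, dp
        out_ne[lo:hi] = n_eff
    pairs = pairs.assign(r2=out_r2, D=out_D, d_prime=out_dp, n_eff=out_ne)
    n_undef = int(pairs["r2"].isna().sum())
    if n_undef:
        log.info("compute_pair_ld: %d pairs with undefined LD skipped", n_undef)
    return pairs.dropna(subset=["r2"]).reset_index(drop=True).drop(columns=["i", "j"])


def adjacent_pair_summary(
    gm: GenotypeMatrix, estimator: str = "em"
) -> pd.DataFrame:
    """Per-scaffold LD between consecutive SNPs, plus a pooled Overall row.

    For each scaffold with >= 2 SNPs: number of SNPs and adjacent pairs,
    mean +/- SD of r2 and D', percentage of pairs with r2 > 0.2 and
    r2 > 0.8, and the mean adjacent distance.  The Overall row pools
    over pairs (not over scaffold means).
    """
    pairs = compute_pair_ld(gm, adjacent_only=True, estimator=estimator)
    counts = gm.snps_per_contig()
    skipped = [str(c) for c, n in counts.items() if n < 2]
    if skipped:
        log.warning("adjacent_pair_summary: scaffolds with <2 SNPs omitted: %s",
                    ", ".join(skipped))
    if pairs.empty:
        raise ValueError("no adjacent pairs with defined LD")

    def _row(name: str, sub: pd.DataFrame, n_snps: int) -> dict:
        return {
            "scaffold": name,
            "n_snps": n_snps,
            "n_pairs": len(sub),
            "mean_r2": sub["r2"].mean(),
            "sd_r2": sub["r2"].std(ddof=1) if len(sub) > 1 else np.nan,
            "mean_dprime": sub["d_prime"].abs().mean(),
            "sd_dprime": sub["d_prime"].abs().std(ddof=1) if len(sub) > 1 else np.nan,
            "pct_r2_gt_0.2": 100.0 * (sub["r2"] > 0.2).mean(),
            "pct_r2_gt_0.8": 100.0 * (sub["r2"] > 0.8).mean(),
            "mean_adjacent_distance": sub["distance"].mean(),
        }

    rows = [
        _row(str(contig), sub, int(counts[contig]))
        for contig, sub in pairs.groupby("contig", sort=False)
    ]
    rows.append(_row("Overall", pairs, int(counts[counts >= 2].sum())))
    return pd.DataFrame(rows)


def all_pair_summary(gm: GenotypeMatrix, estimator: str = "em") -> pd.DataFrame:
    """Per-scaffold mean r2 / D' over *all* syntenic pairs (not just adjacent).

    Emitted alongside the adjacent-pair table because per-scaffold LD
    levels are sometimes reported as all-pairs means.
    """
    pairs = compute_pair_ld(gm, estimator=estimator)
    if pairs.empty:
        raise ValueError("no syntenic pairs with defined LD")
    rows = [
        {
            "scaffold": str(contig),
            "n_pairs": len(sub),
            "mean_r2": sub["r2"].mean(),
            "mean_dprime": sub["d_prime"].abs().mean(),
        }
        for contig, sub in pairs.groupby("contig", sort=False)
    ]
    rows.append(
        {
            "scaffold": "Overall",
            "n_pairs": len(pairs),
            "mean_r2": pairs["r2"].mean(),
            "mean_dprime": pairs["d_prime"].abs().mean(),
        }
    )
    return pd.DataFrame(rows)


#: the three canonical decay schemes: (max distance bp, bin width bp)
DECAY_SCHEMES: dict[str, tuple[int, int]] = {
    "100kb": (100_000, 10_000),
    "1000kb": (1_000_000, 100_000),
    "10Mb": (10_000_000, 1_000_000),
}


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int,
    bin_width: int,
    estimator: str = "em",
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Distance-binned LD decay pooled across scaffolds.

    Bins are half-open intervals (lower, upper] of width ``bin_width``
    up to ``max_dist`` (which must be a multiple of the width); a pair
    at exactly the upper edge falls in that bin.  Reports per bin the
    pair count and mean +/- SD of r2 and D'; empty bins keep
    ``n_pairs = 0`` with NaN means.

    Precomputed ``pairs`` (from :func:`compute_pair_ld`) may be passed
    to avoid re-estimating when several schemes are tabulated.
    """
    if max_dist % bin_width != 0:
        raise ValueError("max_dist must be a multiple of bin_width")
    if pairs is None:
        pairs = compute_pair_ld(gm, max_dist=max_dist, estimator=estimator)
    pairs = pairs[(pairs["distance"] > 0) & (pairs["distance"] <= max_dist)]
    n_bins = max_dist // bin_width
    # (lower, upper]: distance d -> bin ceil(d / width) - 1
    bin_idx = np.ceil(pairs["distance"].to_numpy() / bin_width).astype(int) - 1
    rows = []
    for b in range(n_bins):
        sel = pairs[bin_idx == b]
        lower, upper = b * bin_width, (b + 1) * bin_width
        rows.append(
            {
                "bin_lower": lower,
                "bin_upper": upper,
                "midpoint": (lower + upper) / 2.0,
                "n_pairs": len(sel),
                "mean_r2": sel["r2"].mean() if len(sel) else np.nan,
                "sd_r2": sel["r2"].std(ddof=1) if len(sel) > 1 else np.nan,
                "mean_dprime": sel["d_prime"].abs().mean() if len(sel) else np.nan,
                "sd_dprime": sel["d_prime"].abs().std(ddof=1) if len(sel) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP-panel density
# ---------------------------------------------------------------------------

def panel_density(genome_size: float, max_spacing: float) -> int:
    """SNPs needed to cover ``genome_size`` bp at one per ``max_spacing`` bp.

    E.g. a 2.4 Gb assembly at 40 kb spacing needs 60,000 SNPs.
    """
    if genome_size <= 0 or max_spacing <= 0:
        raise ValueError("genome_size and max_spacing must be > 0")
    return int(round(genome_size / max_spacing))


def threshold_distance(decay: pd.DataFrame, r2_threshold: float) -> int | None:
    """Lower edge (bp) of the first decay bin whose mean r2 drops below
    the threshold; None when LD never decays below it."""
    for _, row in decay.iterrows():
        if not np.isnan(row["mean_r2"]) and row["mean_r2"] < r2_threshold:
            return int(row["bin_lower"])
    return None
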