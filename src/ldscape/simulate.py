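"""Synthetic genotype data with known truth.

The population generator is a forward Wright-Fisher simulation of
``2 Ne`` haploid genomes per generation.  Biallelic candidate sites are
placed uniformly at an oversampled density and evolve under genetic
drift, Poisson recombination, and a low symmetric recurrent mutation
rate (scaled rate ``site_theta = 4 Ne mu`` per site) that balances the
loss of variation to fixation, so the population reaches a genuine
mutation-drift-recombination equilibrium during a burn-in of ``4 x Ne``
generations at the oldest epoch size; the configured Ne trajectory is
then played forward to the present.  At sampling time the segregating
sites form a pool whose minor-allele frequencies are matched against
draws from the target spectrum, so the emitted panel has the
configured MAF profile (the ascertainment a genotyping panel applies),
while linkage disequilibrium — the quantity under study — emerges
mechanically from drift and matches finite-population expectations
(Sved-type decay in ``c`` and ``Ne``).

On top of the population process the module provides autozygous-tract
implanting (copying one haplotype over the other), exact and sampled
two-locus fixtures for the EM estimator, an i.i.d. Hardy-Weinberg
cohort generator, and a plain-text VCF writer that round-trips through
:func:`ldscape.genotype.read_vcf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, ContigTable, GenotypeMatrix

log = logging.getLogger(__name__)

#: sites simulated per site requested: absorbs sites monomorphic in the
#: sampled cohort and leaves surplus for MAF-spectrum matching
_OVERSAMPLE = 4

_NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters of the population generator.

    Defaults emulate a GBS panel on a draft carnivore assembly: 260
    diploids, scaffolds of 10-37 Mb, ~18.5 SNPs per Mb, a mean minor
    allele frequency near 0.185, and a population whose effective size
    declined from ~1,000 two hundred generations ago to ~116 five
    generations ago.
    """

    seed: int = 0
    n_samples: int = 260
    contigs: tuple[tuple[str, int], ...] | None = None  # None -> bundled panel
    snp_density: float = 18.5  # SNPs per Mb
    ne_trajectory: tuple[tuple[int, int], ...] = (
        (200, 1000), (100, 500), (50, 250), (10, 150), (5, 116)
    )
    recomb_rate: float = 1e-8  # per bp per generation (1 cM/Mb)
    site_theta: float = 0.2  # scaled mutation rate 4*Ne*mu per candidate site
    target_maf_mean: float = 0.185
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.005

    def __post_init__(self) -> None:
        traj = tuple(sorted(self.ne_trajectory, key=lambda x: -x[0]))
        if any(ne < 2 for _, ne in traj):
            raise ValueError("Ne values must be >= 2")
        for r in (self.missing_rate, self.genotype_error_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must be in [0, 1)")
        self.ne_trajectory = traj

    def resolved_contigs(self) -> tuple[tuple[str, int], ...]:
        if self.contigs is not None:
            return self.contigs
        panel = load_scaffold_panel()
        return tuple(
            (row["scaffold"], int(row["length_mb"] * 1e6))
            for _, row in panel.iterrows()
        )


@dataclass
class TruthSet:
    """Ground truth recorded alongside a simulated genotype matrix."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    haplotypes: dict[str, np.ndarray] = field(default_factory=dict)  # (2n, m) uint8
    tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    ne_per_generation: list[tuple[int, int]] = field(default_factory=list)
    missing_mask: dict[str, np.ndarray] = field(default_factory=dict)
    error_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def true_genotypes(self, contig: str) -> np.ndarray:
        """Noise-free genotype dosage matrix (n, m) for one contig."""
        h = self.haplotypes[contig]
        return (h[0::2] + h[1::2]).astype(np.int8)


def load_scaffold_panel() -> pd.DataFrame:
    """Bundled per-scaffold summary of the American mink GBS SNP panel
    (scaffold, length in Mb, SNP count)."""
    from importlib.resources import files

    path = files("ldscape.data").joinpath("mink_scaffold_panel.tsv")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Wright-Fisher core
# ---------------------------------------------------------------------------

def _next_generation(
    rng: np.random.Generator,
    pop: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    n_next: int,
    recomb_rate: float,
) -> np.ndarray:
    """One generation of random mating with Poisson recombination.

    ``pop`` holds 2N haplotype rows (individual i owns rows 2i, 2i+1);
    returns the 2 * n_next gamete rows of the next generation.
    """
    n_prev = pop.shape[0] // 2
    n_gam = 2 * n_next
    parent = rng.integers(n_prev, size=n_gam)
    side = rng.integers(2, size=n_gam)
    n_x = rng.poisson(recomb_rate * length_bp, size=n_gam)
    new = pop[2 * parent + side]  # zero-crossover outcome for everyone
    xover = np.flatnonzero(n_x > 0)
    if len(xover) == 0:
        return new
    # crossover gametes: alternate between the parent's two haplotypes,
    # switching at each breakpoint; parity computed with a difference array
    m = pop.shape[1]
    a = pop[2 * parent[xover] + side[xover]]
    b = pop[2 * parent[xover] + 1 - side[xover]]
    delta = np.zeros((len(xover), m + 1), dtype=np.int64)
    total = int(n_x[xover].sum())
    bp = rng.integers(1, length_bp, size=total)
    rows = np.repeat(np.arange(len(xover)), n_x[xover])
    cuts = np.searchsorted(positions, bp, side="right")
    np.add.at(delta, (rows, cuts), 1)
    parity = np.cumsum(delta[:, :m], axis=1) % 2
    new[xover] = np.where(parity == 0, a, b)
    return new


def _draw_positions(rng: np.random.Generator, length_bp: int, m: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(m * 1.05) + 8))
    while len(pos) < m:
        extra = rng.integers(1, length_bp + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def _draw_minor_freqs(
    rng: np.random.Generator, m: int, target_mean: float
) -> np.ndarray:
    """Minor-allele frequencies on (0, 0.5) with exactly the target mean,
    L-shaped (rare variants common): 0.5 * Beta(a, 1)."""
    if not (0 < target_mean < 0.5):
        raise ValueError("target MAF mean must be in (0, 0.5)")
    a = 2 * target_mean / (1 - 2 * target_mean)  # mean of 0.5*Beta(a,1)
    return 0.5 * rng.beta(a, 1.0, size=m)


def _select_spectrum(
    rng: np.random.Generator, maf: np.ndarray, m: int, target_mean: float
) -> np.ndarray:
    """Indices of up to ``m`` pool sites whose MAFs best match draws from
    the target spectrum (greedy nearest-match on sorted values)."""
    if len(maf) <= m:
        return np.arange(len(maf))
    order = np.argsort(maf, kind="stable")
    pool = maf[order]
    targets = np.sort(_draw_minor_freqs(rng, m, target_mean))
    # nearest pool rank per target, then force strictly increasing ranks
    # (monotone assignment; runs of duplicate MAFs are consumed one by one)
    j = np.searchsorted(pool, targets)
    left = np.clip(j - 1, 0, len(pool) - 1)
    right = np.clip(j, 0, len(pool) - 1)
    cand = np.where(
        np.abs(pool[left] - targets) <= np.abs(pool[right] - targets), left, right
    )
    k = np.arange(m)
    chosen = np.maximum.accumulate(cand - k) + k
    chosen = np.minimum(chosen, len(pool) - m + k)
    return np.sort(order[chosen])


def _ne_at(traj: tuple[tuple[int, int], ...], g: int) -> int:
    """Ne at g generations ago: the breakpoint with the smallest start >= g."""
    ne = traj[0][1]
    for start, n in traj:
        if start >= g:
            ne = n
    return ne


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Forward Wright-Fisher simulation with a piecewise Ne trajectory.

    Each contig is simulated independently (unlinked scaffolds): sites
    start at linkage equilibrium with U-shaped ancestral frequencies,
    burn in for 4 x Ne generations at the oldest epoch size, then the
    trajectory runs forward to the present and ``n_samples`` diploids
    are drawn.  Loci monomorphic in the sampled cohort are dropped, as
    a variant caller would drop them, and survivors are thinned to the
    configured density.  Missingness and genotype error are applied
    last and recorded in the truth set.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs = cfg.resolved_contigs()
    traj = cfg.ne_trajectory
    ne_old = traj[0][1]
    oldest = traj[0][0]
    if cfg.n_samples > _ne_at(traj, 1):
        raise ValueError("n_samples exceeds the final-generation population size")

    truth = TruthSet(
        ne_per_generation=[(g, _ne_at(traj, g)) for g in range(oldest, 0, -1)]
    )
    samples = [f"ind{i:04d}" for i in range(cfg.n_samples)]
    var_frames = []
    call_blocks = []
    for name, length_bp in contigs:
        m = int(round(cfg.snp_density * length_bp / 1e6))
        if m < 2:
            raise ValueError(
                f"contig {name}: density {cfg.snp_density}/Mb on {length_bp} bp "
                f"gives {m} sites"
            )
        m_sim = _OVERSAMPLE * m
        positions = _draw_positions(rng, length_bp, m_sim)
        q0 = rng.random(m_sim)  # burn-in relaxes to the stationary spectrum
        pop = (rng.random((2 * ne_old, m_sim)) < q0[None, :]).astype(np.uint8)
        mu = cfg.site_theta / (4.0 * ne_old)
        sizes = [ne_old] * (4 * ne_old) + [
            _ne_at(traj, g) for g in range(oldest, 0, -1)
        ]
        for n_next in sizes:
            pop = _next_generation(
                rng, pop, positions, length_bp, n_next, cfg.recomb_rate
            )
            n_flip = rng.poisson(mu * pop.shape[0] * m_sim)
            if n_flip:
                fr = rng.integers(pop.shape[0], size=n_flip)
                fc = rng.integers(m_sim, size=n_flip)
                pop[fr, fc] ^= 1
        n_final = pop.shape[0] // 2
        chosen = rng.choice(n_final, size=cfg.n_samples, replace=False)
        rows = np.empty(2 * cfg.n_samples, dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * chosen, 2 * chosen + 1
        haps = pop[rows]

        alt = haps.sum(axis=0)
        poly = np.flatnonzero((alt > 0) & (alt < 2 * cfg.n_samples))
        if len(poly) < m:
            log.warning(
                "simulate_population: %s retained %d/%d segregating sites",
                name, len(poly), m,
            )
        pool_maf = np.minimum(alt[poly], 2 * cfg.n_samples - alt[poly]) / (
            2.0 * cfg.n_samples
        )
        keep = poly[_select_spectrum(rng, pool_maf, m, cfg.target_maf_mean)]
        positions, haps = positions[keep], haps[:, keep]
        geno = (haps[0::2] + haps[1::2]).astype(np.int8)
        truth.positions[name] = positions
        truth.haplotypes[name] = haps

        ref_alt = np.stack(
            [rng.permutation(4)[:2] for _ in range(len(positions))]
        ) if len(positions) else np.empty((0, 2), dtype=int)
        var_frames.append(
            pd.DataFrame(
                {
                    "contig": name,
                    "pos": positions.astype(np.int64),
                    "ref": _NUC[ref_alt[:, 0]] if len(positions) else [],
                    "alt": _NUC[ref_alt[:, 1]] if len(positions) else [],
                }
            )
        )
        call_blocks.append(geno)

    gm = GenotypeMatrix(
        samples=samples,
        variants=pd.concat(var_frames, ignore_index=True),
        calls=np.concatenate(call_blocks, axis=1),
    ).sorted()
    gm = apply_noise(gm, truth, cfg.missing_rate, cfg.genotype_error_rate, rng)
    return gm, truth


def apply_noise(
    gm: GenotypeMatrix,
    truth: TruthSet,
    missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Apply genotype error (symmetric hom <-> het flips) then missingness.

    Masks are recorded in the truth set per contig.  Error flips a
    homozygote to the heterozygote and a heterozygote to a random
    homozygote.
    """
    calls = gm.calls.copy()
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        err &= calls != MISSING
        flipped = calls.copy()
        flipped[err & (calls != 1)] = 1
        het_err = err & (calls == 1)
        flipped[het_err] = rng.choice([0, 2], size=int(het_err.sum()))
        calls = flipped
    else:
        err = np.zeros(calls.shape, dtype=bool)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = MISSING
    else:
        miss = np.zeros(calls.shape, dtype=bool)
    contig_col = gm.variants["contig"].to_numpy()
    for name in gm.contigs():
        sel = contig_col == name
        truth.error_mask[name] = err[:, sel]
        truth.missing_mask[name] = miss[:, sel]
    return GenotypeMatrix(samples=gm.samples, variants=gm.variants, calls=calls)


# ---------------------------------------------------------------------------
# Autozygous tract implanting
# ---------------------------------------------------------------------------

def implant_roh(
    gm: GenotypeMatrix,
    truth: TruthSet,
    tracts: dict[str, list[tuple[str, int, int]]],
) -> tuple[GenotypeMatrix, TruthSet]:
    """Overwrite the second haplotype with the first inside each tract.

    All genotypes within a tract become homozygous (before any later
    noise injection); tract coordinates are appended to the truth set.
    Overlapping tracts of one sample are merged with a warning.
    """
    calls = gm.calls.copy()
    contig_col = gm.variants["contig"].to_numpy()
    pos_col = gm.variants["pos"].to_numpy()
    for sample, tr_list in tracts.items():
        if sample not in gm.samples:
            raise ValueError(f"unknown sample {sample!r}")
        s_i = gm.samples.index(sample)
        merged: dict[str, list[list[int]]] = {}
        for contig, start, end in sorted(tr_list):
            if contig not in truth.positions:
                raise ValueError(f"unknown contig {contig!r}")
            if start < 1 or start > end:
                raise ValueError(f"bad tract ({contig}, {start}, {end})")
            runs = merged.setdefault(contig, [])
            if runs and start <= runs[-1][1]:
                log.warning("implant_roh: merging overlapping tracts for %s on %s",
                            sample, contig)
                runs[-1][1] = max(runs[-1][1], end)
            else:
                runs.append([start, end])
        for contig, runs in merged.items():
            hap = truth.haplotypes[contig]
            pos = truth.positions[contig]
            for start, end in runs:
                in_tract = (pos >= start) & (pos <= end)
                hap[2 * s_i + 1, in_tract] = hap[2 * s_i, in_tract]
                sel = (contig_col == contig) & (pos_col >= start) & (pos_col <= end)
                calls[s_i, sel] = 2 * hap[2 * s_i, in_tract].astype(np.int8)
                truth.tracts.setdefault(sample, []).append((contig, start, end))
    return (
        GenotypeMatrix(samples=gm.samples, variants=gm.variants, calls=calls),
        truth,
    )


# ---------------------------------------------------------------------------
# Small fixtures
# ---------------------------------------------------------------------------

def make_ld_fixture(
    freqs: tuple[float, float, float, float],
    n: int,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two genotype vectors drawn from an exact two-locus haplotype law.

    ``freqs`` is (P_AB, P_Ab, P_aB, P_ab) in reference-allele coding.
    Sampled mode draws 2n haplotypes multinomially and pairs them at
    random (random mating).  With ``exact=True`` the haplotype counts
    are the rounded ``2n x P`` products (an error lists the residuals if
    those are not integers) and like haplotypes are paired together, so
    phase is unambiguous and the EM recovers the frequencies exactly.
    """
    p = np.asarray(freqs, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if exact:
        counts = 2 * n * p
        rounded = np.rint(counts).astype(int)
        resid = counts - rounded
        if np.abs(resid).max() > 1e-9 or rounded.sum() != 2 * n:
            raise ValueError(
                f"exact mode: 2n*P not integral, residuals {resid.tolist()}"
            )
        hap_idx = np.repeat(np.arange(4), rounded)
    else:
        hap_idx = rng.choice(4, size=2 * n, p=p)
        rng.shuffle(hap_idx)
    # haplotype categories -> alt-allele presence at (locus1, locus2)
    alt1 = np.array([0, 0, 1, 1])[hap_idx]
    alt2 = np.array([0, 1, 0, 1])[hap_idx]
    g1 = (alt1[0::2] + alt1[1::2]).astype(np.int8)
    g2 = (alt2[0::2] + alt2[1::2]).astype(np.int8)
    return g1, g2


def simulate_hwe_cohort(
    n_samples: int,
    n_variants: int,
    seed: int | np.random.Generator = 0,
    maf_mean: float = 0.185,
    maf_range: tuple[float, float] | None = None,
    spacing_bp: int = 1000,
    contig: str = "chr1",
    return_truth: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, TruthSet]:
    """I.i.d. Hardy-Weinberg cohort: two independent haplotypes per sample.

    Per-variant allele frequencies come from the Beta-shaped minor-
    frequency spectrum with the given mean (or uniformly from
    ``maf_range`` when provided), with a random major/minor side.
    Markers sit every ``spacing_bp`` on one contig.  With
    ``return_truth`` the underlying haplotypes come along, so tracts
    can be implanted (:func:`implant_roh`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if maf_range is not None:
        q_minor = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    else:
        q_minor = np.clip(_draw_minor_freqs(rng, n_variants, maf_mean), 1e-3, 0.5)
    flip = rng.random(n_variants) < 0.5
    p_alt = np.where(flip, q_minor, 1.0 - q_minor)
    haps = (
        rng.random((2 * n_samples, n_variants)) < p_alt[None, :]
    ).astype(np.uint8)
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)
    positions = np.arange(1, n_variants + 1, dtype=np.int64) * spacing_bp
    ref_alt = np.stack([rng.permutation(4)[:2] for _ in range(n_variants)])
    variants = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": _NUC[ref_alt[:, 0]],
            "alt": _NUC[ref_alt[:, 1]],
        }
    )
    gm = GenotypeMatrix(
        samples=[f"ind{i:04d}" for i in range(n_samples)],
        variants=variants,
        calls=calls,
    )
    if not return_truth:
        return gm
    truth = TruthSet(positions={contig: positions}, haplotypes={contig: haps})
    return gm, truth


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path,
    contigs: ContigTable | None = None,
) -> None:
    """Write a minimal VCF 4.2 (GT only) that read_vcf round-trips exactly.

    ##contig header lines carry the given lengths, falling back to the
    max observed position per contig.
    """
    if contigs is None:
        lengths = {
            str(c): int(sub["pos"].max())
            for c, sub in gm.variants.groupby("contig", sort=False)
        }
    else:
        lengths = dict(contigs)
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldscape-simulate\n")
        for name, length in lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_variants):
            v = gm.variants.iloc[j]
            gts = "\t".join(_GT_CODE[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{v['contig']}\t{int(v['pos'])}\t.\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
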