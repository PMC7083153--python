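"""Runs of homozygosity and genomic inbreeding coefficients.

ROH detection is a sliding-window scan: per sample and contig, every
window of ``min_snps_window`` consecutive SNPs (slid one SNP at a time)
is homozygous-compatible when its heterozygote count stays within the
genotyping-error allowance ``floor(error_rate * window)`` and its
missing fraction within ``max_missing_fraction``.  Maximal unions of
overlapping compatible windows become candidate runs; a run is emitted
when its physical span reaches the smallest configured length class and
its total heterozygote count stays within ``floor(error_rate * n_snps)``.
Run coordinates span the first to last SNP of the run (no extension
into unmarked flanking sequence).

Inbreeding coefficients:

    F_ROH(>= L) = sum of the sample's ROH lengths at least L  /  L_genome

with ``L_genome`` the marker-covered genome length, and F_HOM the
method-of-moments excess-homozygosity coefficient

    F_HOM = (O_hom - E_hom) / (m - E_hom)

with the small-sample-corrected Hardy-Weinberg expectation
``E_hom = sum_i [1 - 2 p_i (1 - p_i) * 2n_i/(2n_i - 1)]`` over the
sample's non-missing variants.  F_HOM can be negative (an excess of
heterozygotes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

#: default ROH length classes (bp)
DEFAULT_MIN_LENGTHS: tuple[int, ...] = (
    500_000, 1_000_000, 2_000_000, 4_000_000, 8_000_000, 16_000_000
)


@dataclass
class ROHConfig:
    min_lengths: tuple[int, ...] = DEFAULT_MIN_LENGTHS
    min_snps_window: int = 20
    error_rate: float = 0.01
    max_missing_fraction: float = 0.05
    genome_covered_l: int | None = None  # bp; None -> marker-covered spans

    def __post_init__(self) -> None:
        self.min_lengths = tuple(sorted(int(v) for v in self.min_lengths))
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_snps_window < 2:
            raise ValueError("min_snps_window must be >= 2")


@dataclass
class ROHSegment:
    sample: str
    contig: str
    start: int  # bp of first SNP, 1-based inclusive
    end: int    # bp of last SNP, 1-based inclusive
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class InbreedingRecord:
    sample: str
    f_roh: dict[int, float] = field(default_factory=dict)   # threshold bp -> F
    roh_count: dict[int, int] = field(default_factory=dict)
    mean_roh_length: dict[int, float] = field(default_factory=dict)
    f_hom: float = float("nan")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _runs_for_vector(
    g: np.ndarray, pos: np.ndarray, cfg: ROHConfig
) -> list[tuple[int, int, int, int]]:
    """Candidate runs for one sample on one contig.

    Returns (start_idx, end_idx, n_het, n_miss) tuples of maximal unions
    of overlapping homozygous-compatible windows, before the run-level
    length / allowance checks.
    """
    w = cfg.min_snps_window
    n = len(g)
    het = (g == 1).astype(np.int32)
    miss = (g == MISSING).astype(np.int32)
    # rolling sums over windows of w
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    het_w = ch[w:] - ch[:-w]
    miss_w = cm[w:] - cm[:-w]
    allow_w = int(np.floor(cfg.error_rate * w))
    compatible = (het_w <= allow_w) & (miss_w <= cfg.max_missing_fraction * w)
    if not compatible.any():
        return []
    # union of covered SNP indices via a difference array
    delta = np.zeros(n + 1, dtype=np.int32)
    starts = np.flatnonzero(compatible)
    delta[starts] += 1
    delta[starts + w] -= 1
    covered = np.cumsum(delta[:-1]) > 0
    # maximal contiguous covered stretches
    edges = np.diff(covered.astype(np.int8), prepend=0, append=0)
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1) - 1
    out = []
    for s, e in zip(run_starts, run_ends):
        out.append((int(s), int(e), int(ch[e + 1] - ch[s]), int(cm[e + 1] - cm[s])))
    return out


def detect_roh(gm: GenotypeMatrix, cfg: ROHConfig | None = None) -> list[ROHSegment]:
    """Sliding-window ROH scan over every sample and contig.

    Contigs with fewer SNPs than one window are skipped with a warning.
    Output order (and content) is invariant to sample and contig order:
    segments are sorted by (sample, contig, start).
    """
    cfg = cfg or ROHConfig()
    min_len = min(cfg.min_lengths)
    segments: list[ROHSegment] = []
    short: set[str] = set()
    for contig, sub in gm.variants.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(idx) < cfg.min_snps_window:
            short.add(str(contig))
            continue
        calls = gm.calls[:, idx]
        for s_i, sample in enumerate(gm.samples):
            for s_idx, e_idx, n_het, n_miss in _runs_for_vector(
                calls[s_i], pos, cfg
            ):
                n_snps = e_idx - s_idx + 1
                length = int(pos[e_idx] - pos[s_idx] + 1)
                if length < min_len:
                    continue
                if n_het > int(np.floor(cfg.error_rate * n_snps)):
                    continue
                if n_miss > cfg.max_missing_fraction * n_snps:
                    continue
                segments.append(
                    ROHSegment(
                        sample=sample,
                        contig=str(contig),
                        start=int(pos[s_idx]),
                        end=int(pos[e_idx]),
                        n_snps=n_snps,
                        n_het=n_het,
                    )
                )
    if short:
        log.warning("detect_roh: contigs with < %d SNPs skipped: %s",
                    cfg.min_snps_window, ", ".join(sorted(short)))
    segments.sort(key=lambda s: (s.sample, s.contig, s.start))
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """ROH segments as a tidy table (one row per segment)."""
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
                "length": s.length,
            }
            for s in segments
        ],
        columns=["sample", "contig", "start", "end", "n_snps", "n_het", "length"],
    )


def segments_to_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    """BED export (0-based half-open; conversion happens only here)."""
    return pd.DataFrame(
        [
            {"chrom": s.contig, "chromStart": s.start - 1, "chromEnd": s.end,
             "name": s.sample}
            for s in segments
        ],
        columns=["chrom", "chromStart", "chromEnd", "name"],
    )


# ---------------------------------------------------------------------------
# Classification and inbreeding coefficients
# ---------------------------------------------------------------------------

def classify_roh(
    segments: list[ROHSegment],
    samples: list[str],
    cfg: ROHConfig | None = None,
) -> pd.DataFrame:
    """Per-length-class descriptive statistics across individuals.

    For each threshold L: mean +/- SD of the per-individual count of
    segments with length >= L, mean segment length in the class, the
    min / max per-individual counts, and the percentage of all detected
    segments at or above L (cumulative frequency).  The share of short
    segments (>= min threshold but below the next) is reported in the
    companion column ``pct_shortest_class``.
    """
    cfg = cfg or ROHConfig()
    seg = segments_frame(segments)
    n_total = len(seg)
    rows = []
    for i, thr in enumerate(cfg.min_lengths):
        sel = seg[seg["length"] >= thr] if n_total else seg
        per_ind = (
            sel.groupby("sample").size().reindex(samples, fill_value=0)
            if n_total
            else pd.Series(0, index=samples)
        )
        row = {
            "min_length": thr,
            "mean_count": float(per_ind.mean()),
            "sd_count": float(per_ind.std(ddof=1)) if len(per_ind) > 1 else np.nan,
            "mean_length": float(sel["length"].mean()) if len(sel) else np.nan,
            "sd_length": float(sel["length"].std(ddof=1)) if len(sel) > 1 else np.nan,
            "min_count": int(per_ind.min()),
            "max_count": int(per_ind.max()),
            "cumulative_pct": 100.0 * len(sel) / n_total if n_total else np.nan,
        }
        if i == 0 and len(cfg.min_lengths) > 1:
            nxt = cfg.min_lengths[1]
            n_short = int((seg["length"] < nxt).sum()) if n_total else 0
            row["pct_shortest_class"] = (
                100.0 * n_short / n_total if n_total else np.nan
            )
        else:
            row["pct_shortest_class"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def genome_covered_length(gm: GenotypeMatrix) -> int:
    """Marker-covered genome length: per-contig (last - first SNP) spans summed."""
    total = 0
    for _, sub in gm.variants.groupby("contig", sort=False):
        total += int(sub["pos"].max() - sub["pos"].min())
    return total


def f_roh(
    segments: list[ROHSegment],
    samples: list[str],
    genome_l: int,
    threshold: int,
) -> pd.Series:
    """Per-sample F_ROH: summed segment length >= threshold over genome_l."""
    if genome_l <= 0:
        raise ValueError("genome_l must be > 0")
    total = dict.fromkeys(samples, 0)
    for s in segments:
        if s.length >= threshold and s.sample in total:
            total[s.sample] += s.length
    return pd.Series({k: v / genome_l for k, v in total.items()}, name=f"f_roh_{threshold}")


def f_hom(gm: GenotypeMatrix) -> pd.Series:
    """Per-sample excess-homozygosity inbreeding coefficient.

    F = (O_hom - E_hom) / (m - E_hom) with the small-sample-corrected
    expectation; variants with fewer than 2 genotyped individuals are
    excluded.  A fully homozygous individual gives 1; negative values
    mean an excess of heterozygotes.
    """
    obs = gm.calls != MISSING
    n_i = obs.sum(axis=0)
    usable = n_i >= 2
    p = gm.alt_freq()
    # per-variant expected homozygosity with 2n/(2n-1) correction
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_het = 2.0 * p * (1.0 - p) * (2.0 * n_i) / (2.0 * n_i - 1.0)
    exp_hom_var = 1.0 - exp_het
    hom = (gm.calls == 0) | (gm.calls == 2)
    use = obs & usable[None, :]
    m = use.sum(axis=1).astype(float)
    o_hom = (hom & use).sum(axis=1).astype(float)
    e_hom = np.where(use, exp_hom_var[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(m - e_hom != 0, (o_hom - e_hom) / (m - e_hom), np.nan)
    return pd.Series(f, index=gm.samples, name="f_hom")


def inbreeding_records(
    gm: GenotypeMatrix,
    segments: list[ROHSegment],
    cfg: ROHConfig | None = None,
) -> list[InbreedingRecord]:
    """Assemble per-individual F_ROH (all classes) and F_HOM."""
    cfg = cfg or ROHConfig()
    genome_l = cfg.genome_covered_l or genome_covered_length(gm)
    fh = f_hom(gm)
    seg = segments_frame(segments)
    records = []
    for sample in gm.samples:
        rec = InbreedingRecord(sample=sample, f_hom=float(fh[sample]))
        mine = seg[seg["sample"] == sample] if len(seg) else seg
        for thr in cfg.min_lengths:
            sel = mine[mine["length"] >= thr] if len(mine) else mine
            rec.f_roh[thr] = float(sel["length"].sum()) / genome_l if len(sel) else 0.0
            rec.roh_count[thr] = len(sel)
            rec.mean_roh_length[thr] = (
                float(sel["length"].mean()) if len(sel) else np.nan
            )
        records.append(rec)
    return records


def inbreeding_frame(records: list[InbreedingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample": r.sample, "f_hom": r.f_hom}
        for thr, v in r.f_roh.items():
            row[f"f_roh_{thr}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_inbreeding(
    records: list[InbreedingRecord], thresholds: tuple[int, ...] | None = None
) -> pd.DataFrame:
    """Pearson correlation of F_ROH(>= L) with F_HOM per length class.

    Needs at least three individuals; a zero-variance vector yields a
    missing (NaN) correlation for that class.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 individuals to correlate")
    thresholds = thresholds or tuple(records[0].f_roh.keys())
    fh = np.array([r.f_hom for r in records], dtype=float)
    rows = []
    for thr in thresholds:
        fr = np.array([r.f_roh.get(thr, np.nan) for r in records], dtype=float)
        ok = np.isfinite(fr) & np.isfinite(fh)
        if ok.sum() < 3 or fr[ok].std() == 0 or fh[ok].std() == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(fr[ok], fh[ok])[0, 1])
        rows.append({"min_length": thr, "pearson_r": corr})
    return pd.DataFrame(rows)
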