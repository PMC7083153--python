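"""Genotype quality control.

Filter chain (fixed order): GATK-style hard filters on INFO annotations,
variant filters (MAF, call rate), sample filter (call rate), and a
scaffold filter (minimum SNP count and physical length) that applies
only to the LD / Ne stages.  ROH and excess-homozygosity inbreeding run
on the pre-scaffold-filter set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MISSING, ContigTable, GenotypeMatrix

log = logging.getLogger(__name__)

#: removal conditions: annotation -> (direction, threshold); a variant is
#: removed when annotation < threshold ("lt") or > threshold ("gt").
DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": ("lt", 2.0),
    "MQ": ("lt", 40.0),
    "FS": ("gt", 60.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass
class QCConfig:
    """Thresholds for the QC chain.

    maf_min : variants kept need minor allele frequency strictly above this.
    variant_call_rate_min : variants kept need call rate at or above this.
    sample_call_rate_min : samples kept need call rate at or above this.
    scaffold_min_snps / scaffold_min_length : a scaffold enters the LD
        analysis only with at least this many SNPs and a length strictly
        greater than this (bp).
    """

    maf_min: float = 0.05
    variant_call_rate_min: float = 0.85
    sample_call_rate_min: float = 0.50
    scaffold_min_snps: int = 50
    scaffold_min_length: int = 10_000_000
    hard_filter_thresholds: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_HARD_FILTERS)
    )

    def __post_init__(self) -> None:
        for name in ("maf_min", "variant_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0 < v <= 1) and name != "maf_min":
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for _, (_, thr) in self.hard_filter_thresholds.items():
            if not np.isfinite(thr):
                raise ValueError("hard-filter thresholds must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})


@dataclass
class QCReport:
    """Bookkeeping of drops per rule plus descriptive statistics."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    n_variants_out: int = 0
    n_samples_out: int = 0
    maf_mean: float = float("nan")
    maf_sd: float = float("nan")
    het_mean: float = float("nan")
    het_sd: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        flat = asdict(self)
        drops = flat.pop("dropped")
        flat.update({f"dropped_{k}": v for k, v in drops.items()})
        return pd.DataFrame([flat])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_hard_filters(gm: GenotypeMatrix, cfg: QCConfig | None = None) -> GenotypeMatrix:
    """Drop variants violating any present INFO-annotation threshold.

    A variant is removed when QD < 2, MQ < 40, FS > 60, MQRankSum < -12.5
    or ReadPosRankSum < -8 (defaults; all configurable).  Variants
    lacking a given annotation are not judged by that rule; a matrix
    with no annotations at all passes through unchanged with a warning.
    """
    cfg = cfg or QCConfig()
    present = [k for k in cfg.hard_filter_thresholds if k in gm.variants.columns]
    if not present:
        log.warning("apply_hard_filters: no INFO annotations present; no-op")
        return gm
    remove = np.zeros(gm.n_variants, dtype=bool)
    for key in present:
        direction, thr = cfg.hard_filter_thresholds[key]
        vals = gm.variants[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hit = vals < thr if direction == "lt" else vals > thr
        remove |= np.nan_to_num(hit, nan=False).astype(bool)
    if remove.any():
        log.info("apply_hard_filters: removed %d variants", int(remove.sum()))
    return gm.take_variants(~remove)


def filter_variants(
    gm: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep variants with MAF strictly > ``maf_min`` and call rate >= minimum.

    Variants with zero non-missing calls are dropped and counted
    separately (their MAF is undefined).
    """
    cfg = cfg or QCConfig()
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    call_rate = gm.variant_call_rate()
    maf = gm.maf()
    no_calls = (gm.calls != MISSING).sum(axis=0) == 0
    low_maf = ~no_calls & ~(maf > cfg.maf_min)
    low_cr = ~no_calls & ~low_maf & (call_rate < cfg.variant_call_rate_min)
    keep = ~(no_calls | low_maf | low_cr)
    frag = {
        "variants_no_calls": int(no_calls.sum()),
        "variants_low_maf": int(low_maf.sum()),
        "variants_low_call_rate": int(low_cr.sum()),
    }
    return gm.take_variants(keep), frag


def filter_samples(
    gm: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove samples whose genotype call rate falls below the minimum."""
    cfg = cfg or QCConfig()
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    keep = gm.sample_call_rate() >= cfg.sample_call_rate_min
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    frag = {"samples_low_call_rate": int((~keep).sum())}
    return gm.take_samples(keep), frag


def filter_scaffolds(
    gm: GenotypeMatrix, contigs: ContigTable, cfg: QCConfig | None = None
) -> GenotypeMatrix:
    """Retain scaffolds with >= ``scaffold_min_snps`` SNPs and length > minimum.

    This subset feeds the LD and Ne stages only.
    """
    cfg = cfg or QCConfig()
    counts = gm.snps_per_contig()
    keep_names = {
        str(name)
        for name, n in counts.items()
        if n >= cfg.scaffold_min_snps
        and contigs.get(str(name), 0) > cfg.scaffold_min_length
    }
    mask = gm.variants["contig"].isin(keep_names).to_numpy()
    return gm.take_variants(mask)


def describe(gm: GenotypeMatrix) -> QCReport:
    """Descriptive statistics: MAF mean +/- SD over variants and observed
    heterozygosity mean +/- SD over individuals (het calls / non-missing calls)."""
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    maf = gm.maf()
    maf = maf[~np.isnan(maf)]
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=1)
    het = np.where(gm.calls == 1, 1, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_obs > 0, het / n_obs, np.nan)
    het_rate = het_rate[~np.isnan(het_rate)]
    return QCReport(
        n_variants_in=gm.n_variants,
        n_samples_in=gm.n_samples,
        n_variants_out=gm.n_variants,
        n_samples_out=gm.n_samples,
        maf_mean=float(np.mean(maf)) if maf.size else float("nan"),
        maf_sd=float(np.std(maf, ddof=1)) if maf.size > 1 else float("nan"),
        het_mean=float(np.mean(het_rate)) if het_rate.size else float("nan"),
        het_sd=float(np.std(het_rate, ddof=1)) if het_rate.size > 1 else float("nan"),
    )


def run_qc(
    gm: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full chain hard -> sample -> variant filters and describe the result.

    Samples are filtered before variant frequencies are computed so MAF
    reflects the analysed cohort.  Scaffold filtering is separate
    (:func:`filter_scaffolds`) because it applies only to LD / Ne.
    """
    cfg = cfg or QCConfig()
    n_var_in, n_samp_in = gm.n_variants, gm.n_samples
    dropped: dict[str, int] = {}
    gm1 = apply_hard_filters(gm, cfg)
    dropped["variants_hard_filter"] = n_var_in - gm1.n_variants
    gm2, frag_s = filter_samples(gm1, cfg)
    dropped.update(frag_s)
    gm3, frag_v = filter_variants(gm2, cfg)
    dropped.update(frag_v)
    report = describe(gm3)
    report.n_variants_in = n_var_in
    report.n_samples_in = n_samp_in
    report.dropped = dropped
    report.n_variants_out = gm3.n_variants
    report.n_samples_out = gm3.n_samples
    return gm3, report
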