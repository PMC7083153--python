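"""Genotype containers and VCF / table I/O.

The central data structure is :class:`GenotypeMatrix`: an unphased
samples x variants matrix of alt-allele dosages (0, 1, 2) with ``-1``
marking missing calls, plus a variant table (contig, 1-based position,
alleles, optional INFO annotations).  Everything downstream — QC, LD,
Ne, ROH — operates on this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -1

#: INFO annotations recognised for hard filtering
INFO_FIELDS = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum")

_NUCS = frozenset("ACGT")


class ContigTable(dict):
    """Mapping of contig name -> length in bp (lengths strictly positive)."""

    def __init__(self, *args, **kwargs):
        super().__init__()
        for key, value in dict(*args, **kwargs).items():
            self[key] = value

    def __setitem__(self, key: str, value: int) -> None:
        value = int(value)
        if value <= 0:
            raise ValueError(f"contig {key!r}: length must be > 0, got {value}")
        super().__setitem__(key, value)


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes for biallelic SNPs.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers.
    variants : pandas.DataFrame
        One row per variant with columns ``contig``, ``pos`` (1-based),
        ``ref``, ``alt`` and optionally any of the INFO annotation
        columns (QD, MQ, FS, MQRankSum, ReadPosRankSum).
    calls : numpy.ndarray
        ``(n_samples, n_variants)`` int8 array of alt-allele dosages;
        ``MISSING`` (-1) marks a missing call.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def contigs(self) -> list[str]:
        """Contig names in variant order (first appearance)."""
        return list(dict.fromkeys(self.variants["contig"]))

    # -- subsetting -----------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            calls=self.calls[index, :],
        )

    def sorted(self) -> "GenotypeMatrix":
        """Return a copy sorted by (contig, pos); ties broken by alleles."""
        order = self.variants.sort_values(
            ["contig", "pos", "ref", "alt"], kind="mergesort"
        ).index.to_numpy()
        return self.take_variants(order)

    # -- per-variant / per-sample summaries -----------------------------
    def variant_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def snps_per_contig(self) -> pd.Series:
        return self.variants.groupby("contig", sort=False).size()


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, region_filter: set[str] | None = None) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (counts logged).  Phase
    is ignored: ``0|1`` and ``0/1`` both code 1.  Half-missing calls
    (``./1``) are treated as missing because their dosage is undefined.

    Parameters
    ----------
    path : str or Path
        Plain or bgzipped VCF with per-sample GT fields.
    region_filter : set of str, optional
        Restrict to these contigs; unknown names raise ``ValueError``.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    if "ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    if len(vcf.samples) == 0:
        raise ValueError(f"{path}: VCF has no samples (GT genotypes required)")

    known = set(vcf.seqnames)
    if region_filter is not None:
        unknown = set(region_filter) - known if known else set()
        if unknown:
            raise ValueError(f"region_filter contigs not in VCF: {sorted(unknown)}")

    samples = list(vcf.samples)
    rows: list[tuple] = []
    cols: list[np.ndarray] = []
    n_multi = n_nonsnp = 0
    for rec in vcf:
        if region_filter is not None and rec.CHROM not in region_filter:
            continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
            n_nonsnp += 1
            continue
        if ref == alt:
            n_nonsnp += 1
            continue
        gt = np.asarray(rec.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gt], dtype=np.int64)
        a1 = np.array([g[1] for g in gt], dtype=np.int64)
        dose = a0 + a1
        dose[(a0 < 0) | (a1 < 0)] = MISSING
        info = tuple(rec.INFO.get(k) for k in INFO_FIELDS)
        rows.append((rec.CHROM, rec.POS, ref, alt) + info)
        cols.append(dose.astype(np.int8))
    vcf.close()

    if n_multi or n_nonsnp:
        log.info(
            "read_vcf(%s): dropped %d multiallelic and %d non-SNP records",
            path, n_multi, n_nonsnp,
        )
    variants = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", *INFO_FIELDS]
    )
    # keep INFO columns only when at least one record carries them
    for k in INFO_FIELDS:
        if variants.empty or variants[k].isna().all():
            variants = variants.drop(columns=k)
        else:
            variants[k] = variants[k].astype(float)
    if not variants.empty:
        variants["pos"] = variants["pos"].astype(np.int64)
    calls = (
        np.stack(cols, axis=1) if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls).sorted()


# ---------------------------------------------------------------------------
# Contig lengths
# ---------------------------------------------------------------------------

def read_contig_table(path: str | Path) -> ContigTable:
    """Read contig lengths from a two-column TSV or the ##contig lines of a VCF."""
    path = Path(path)
    table = ContigTable()
    with open(path, "rt") as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##fileformat=VCF") or path.suffix in (".vcf", ".gz"):
            import re

            for line in fh:
                if not line.startswith("##"):
                    break
                if line.startswith("##contig"):
                    m_id = re.search(r"ID=([^,>]+)", line)
                    m_len = re.search(r"length=(\d+)", line)
                    if m_id and m_len:
                        if m_id.group(1) in table:
                            raise ValueError(f"duplicate contig {m_id.group(1)!r}")
                        table[m_id.group(1)] = int(m_len.group(1))
            return table
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            name, length = parts[0], parts[1]
            try:
                length_i = int(float(length))
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-numeric length {length!r}") from err
            if name in table:
                raise ValueError(f"duplicate contig {name!r}")
            table[name] = length_i
    return table


def contig_lengths_from_matrix(gm: GenotypeMatrix) -> ContigTable:
    """Fallback contig lengths: max observed position per contig (warns)."""
    log.warning("no contig-length table given; falling back to max(pos) per contig")
    table = ContigTable()
    for contig, sub in gm.variants.groupby("contig", sort=False):
        table[str(contig)] = int(sub["pos"].max())
    return table


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 TSV ('.' decimal separator, stable columns).

    Floats are written with 6 significant digits so a read-back
    round-trips to the printed precision.  A header-only file is valid
    for empty results.
    """
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
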