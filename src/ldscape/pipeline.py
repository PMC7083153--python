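"""Pipeline orchestration: qc -> ld -> ne -> roh with a run manifest.

A single YAML config drives the whole analysis.  Top-level blocks
select stages: ``input`` (a VCF) or ``simulate`` (a generator config)
provide the genotypes; optional ``qc``, ``ld``, ``ne`` and ``roh``
blocks run the corresponding stages with their parameters.  Every run
writes a ``manifest.json`` (version, config snapshot, input checksum,
per-stage row counts, seeds) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import (
    ContigTable,
    GenotypeMatrix,
    contig_lengths_from_matrix,
    read_contig_table,
    read_vcf,
    write_table,
)
from .ld import (
    DECAY_SCHEMES,
    adjacent_pair_summary,
    all_pair_summary,
    compute_pair_ld,
    ld_decay,
    panel_density,
    threshold_distance,
)
from .ne import NeConfig, SvedNeModel
from .qc import QCConfig, filter_scaffolds, run_qc
from .roh import (
    ROHConfig,
    classify_roh,
    correlate_inbreeding,
    detect_roh,
    inbreeding_frame,
    inbreeding_records,
    segments_frame,
)
from .simulate import SimConfig, simulate_population, write_vcf

log = logging.getLogger(__name__)

TABLE_FILES = (
    "qc_report.tsv",
    "table1_adjacent.tsv",
    "table1_allpairs.tsv",
    "decay_100kb.tsv",
    "decay_1000kb.tsv",
    "decay_10Mb.tsv",
    "ne_trajectory.tsv",
    "roh_segments.tsv",
    "inbreeding.tsv",
    "table3_roh_classes.tsv",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, out_dir: Path, name: str, manifest: dict) -> None:
    write_table(df, out_dir / name)
    manifest["row_counts"][name] = len(df)


def run_pipeline(config: str | Path | dict, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the configured stages in order and write all tables.

    Returns the output directory.  On a stage failure the outputs
    written so far are renamed with a ``.partial`` suffix and the error
    re-raised (nonzero exit at the CLI).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "inputs": {},
        "row_counts": {},
        "seed": seed,
    }
    try:
        _run_stages(cfg, out_dir, seed, manifest)
    except Exception:
        for name in TABLE_FILES:
            p = out_dir / name
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir


def _load_genotypes(cfg: dict, out_dir: Path, seed: int | None,
                    manifest: dict) -> tuple[GenotypeMatrix, ContigTable]:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        if "contigs" in sim_kwargs and sim_kwargs["contigs"] is not None:
            sim_kwargs["contigs"] = tuple(
                (str(n), int(l)) for n, l in sim_kwargs["contigs"]
            )
        sim_cfg = SimConfig(**sim_kwargs)
        manifest["seed"] = sim_cfg.seed
        gm, _truth = simulate_population(sim_cfg)
        contigs = ContigTable(dict(sim_cfg.resolved_contigs()))
        write_vcf(gm, out_dir / "simulated.vcf", contigs)
        manifest["inputs"]["simulate"] = asdict(sim_cfg)
        return gm, contigs
    if "input" not in cfg or "vcf" not in (cfg["input"] or {}):
        raise ValueError("config needs an 'input: {vcf: ...}' or 'simulate:' block")
    vcf_path = Path(cfg["input"]["vcf"])
    gm = read_vcf(vcf_path, region_filter=None)
    manifest["inputs"]["vcf"] = {"path": str(vcf_path), "sha256": _sha256(vcf_path)}
    ct_path = cfg["input"].get("contig_table")
    if ct_path:
        contigs = read_contig_table(ct_path)
    else:
        try:
            contigs = read_contig_table(vcf_path)
        except Exception:
            contigs = ContigTable()
        if not contigs:
            contigs = contig_lengths_from_matrix(gm)
    return gm, contigs


def _run_stages(cfg: dict, out_dir: Path, seed: int | None, manifest: dict) -> None:
    gm, contigs = _load_genotypes(cfg, out_dir, seed, manifest)

    qc_cfg = QCConfig(**(cfg.get("qc") or {})) if "qc" in cfg else QCConfig()
    gm_qc, report = run_qc(gm, qc_cfg)
    _write(report.to_frame(), out_dir, "qc_report.tsv", manifest)

    ld_block = cfg.get("ld")
    ne_block = cfg.get("ne")
    if ld_block is not None or ne_block is not None:
        gm_ld = filter_scaffolds(gm_qc, contigs, qc_cfg)
        if gm_ld.n_variants < 2:
            raise ValueError("scaffold filter left <2 variants for LD analysis")
        estimator = (ld_block or {}).get("estimator", "em")
        if ld_block is not None:
            _write(adjacent_pair_summary(gm_ld, estimator=estimator),
                   out_dir, "table1_adjacent.tsv", manifest)
            _write(all_pair_summary(gm_ld, estimator=estimator),
                   out_dir, "table1_allpairs.tsv", manifest)
            max_scheme = max(d for d, _ in DECAY_SCHEMES.values())
            pairs = compute_pair_ld(gm_ld, max_dist=max_scheme, estimator=estimator)
            for name, (max_dist, width) in DECAY_SCHEMES.items():
                decay = ld_decay(gm_ld, max_dist, width, pairs=pairs)
                _write(decay, out_dir, f"decay_{name}.tsv", manifest)
        if ne_block is not None:
            ne_kwargs = {k: v for k, v in (ne_block or {}).items()}
            if "generations" in ne_kwargs:
                ne_kwargs["generations"] = tuple(ne_kwargs["generations"])
            model = SvedNeModel.from_genotypes(gm_ld, NeConfig(**ne_kwargs))
            res = model.fit()
            traj = res.trajectory.copy()
            traj["ne_present_t1"] = res.ne_present
            _write(traj, out_dir, "ne_trajectory.tsv", manifest)
            (out_dir / "ne_summary.txt").write_text(res.summary() + "\n")

    roh_block = cfg.get("roh")
    if roh_block is not None:
        kwargs = dict(roh_block or {})
        if "min_lengths_mb" in kwargs:
            kwargs["min_lengths"] = tuple(
                int(v * 1e6) for v in kwargs.pop("min_lengths_mb")
            )
        roh_cfg = ROHConfig(**kwargs)
        segments = detect_roh(gm_qc, roh_cfg)
        _write(segments_frame(segments), out_dir, "roh_segments.tsv", manifest)
        records = inbreeding_records(gm_qc, segments, roh_cfg)
        _write(inbreeding_frame(records), out_dir, "inbreeding.tsv", manifest)
        classes = classify_roh(segments, gm_qc.samples, roh_cfg)
        corr = correlate_inbreeding(records, roh_cfg.min_lengths)
        _write(classes.merge(corr, on="min_length"), out_dir,
               "table3_roh_classes.tsv", manifest)


def summarize(out_dir: str | Path, genome_size: float = 2.4e9,
              r2_thresholds: tuple[float, ...] = (0.2, 0.3)) -> str:
    """Plain-text report of the headline quantities of a completed run.

    Reports mean adjacent-pair LD, the distances where mean r2 first
    drops below each threshold (lower bin edge) with the implied SNP
    panel sizes for the given genome, the Ne trajectory, and the
    inbreeding summaries.  Missing stage outputs are listed as absent.
    """
    out_dir = Path(out_dir)
    lines = [f"ldscape run summary: {out_dir}", "=" * 50]

    def absent(name: str) -> bool:
        if not (out_dir / name).exists():
            lines.append(f"[{name}: absent]")
            return True
        return False

    if not absent("table1_adjacent.tsv"):
        t1 = pd.read_csv(out_dir / "table1_adjacent.tsv", sep="\t")
        overall = t1[t1["scaffold"] == "Overall"].iloc[0]
        lines += [
            f"adjacent-pair LD: mean r2 = {overall['mean_r2']:.2f} "
            f"+/- {overall['sd_r2']:.2f}, mean D' = {overall['mean_dprime']:.2f}",
            f"  {overall['pct_r2_gt_0.2']:.2f}% of pairs r2 > 0.2, "
            f"{overall['pct_r2_gt_0.8']:.2f}% r2 > 0.8",
            f"  mean adjacent distance = {overall['mean_adjacent_distance'] / 1e3:.0f} kb",
        ]
    if not absent("decay_100kb.tsv"):
        decay = pd.read_csv(out_dir / "decay_100kb.tsv", sep="\t")
        for thr in r2_thresholds:
            d = threshold_distance(decay, thr)
            if d is None:
                lines.append(f"mean r2 never drops below {thr} within 100 kb")
            else:
                edge = max(d, int(decay["bin_upper"].iloc[0]))
                lines.append(
                    f"mean r2 < {thr} beyond {d / 1e3:.0f} kb -> "
                    f"~{panel_density(genome_size, edge):,} SNPs for a "
                    f"{genome_size / 1e9:.1f} Gb genome"
                )
    if not absent("ne_trajectory.tsv"):
        traj = pd.read_csv(out_dir / "ne_trajectory.tsv", sep="\t")
        for _, row in traj.iterrows():
            ne = row["ne"]
            ne_s = f"{int(ne)}" if np.isfinite(ne) else "n/a"
            lines.append(f"Ne at t={int(row['t'])}: {ne_s} ({int(row['n_pairs'])} pairs)")
        if "ne_present_t1" in traj.columns and np.isfinite(traj["ne_present_t1"].iloc[0]):
            lines.append(f"present-day Ne (regression): {int(traj['ne_present_t1'].iloc[0])}")
    if not absent("table3_roh_classes.tsv"):
        t3 = pd.read_csv(out_dir / "table3_roh_classes.tsv", sep="\t")
        for _, row in t3.iterrows():
            mb = row["min_length"] / 1e6
            corr = row.get("pearson_r", float("nan"))
            corr_s = f"{corr:.2f}" if np.isfinite(corr) else "n/a"
            lines.append(
                f"ROH >= {mb:g} Mb: mean {row['mean_count']:.1f}/individual, "
                f"F_ROH-F_HOM r = {corr_s}"
            )
    if not absent("inbreeding.tsv"):
        inb = pd.read_csv(out_dir / "inbreeding.tsv", sep="\t")
        lines.append(
            f"F_HOM: mean {inb['f_hom'].mean():.3f}, "
            f"range [{inb['f_hom'].min():.3f}, {inb['f_hom'].max():.3f}]"
        )
        froh_cols = [c for c in inb.columns if c.startswith("f_roh_")]
        if froh_cols:
            col = min(froh_cols, key=lambda c: int(c.split("_")[-1]))
            lines.append(f"mean {col}: {inb[col].mean():.3f}")
    return "\n".join(lines)
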