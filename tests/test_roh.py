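"""ROH sliding-window detection, length classes, F_ROH and F_HOM."""

import numpy as np
import pytest

from ldscape.genotype import MISSING
from ldscape.roh import (
    ROHConfig,
    ROHSegment,
    classify_roh,
    correlate_inbreeding,
    detect_roh,
    f_hom,
    f_roh,
    genome_covered_length,
    inbreeding_records,
    segments_frame,
    segments_to_bed,
)
from ldscape.simulate import implant_roh, simulate_hwe_cohort

from conftest import make_matrix, naive_hom_stretches


def hom_track(n_snps=30, spacing=70_000, het_at=None, missing_at=None):
    """One-sample matrix of homozygous SNPs with optional het/missing."""
    g = np.zeros(n_snps, dtype=np.int8)
    g[::2] = 2  # alternate hom classes; no heterozygotes
    if het_at is not None:
        g[het_at] = 1
    if missing_at is not None:
        g[missing_at] = MISSING
    pos = [1 + k * spacing for k in range(n_snps)]
    return make_matrix(g[None, :], positions=pos), np.array(pos)


def test_single_clean_run_detected():
    """30 consecutive homozygous SNPs spanning ~2 Mb give one segment."""
    gm, pos = hom_track(30)
    segs = detect_roh(gm, ROHConfig())
    assert len(segs) == 1
    s = segs[0]
    assert (s.start, s.end, s.n_snps) == (pos[0], pos[-1], 30)
    assert s.length == pos[-1] - pos[0] + 1


def test_one_heterozygote_breaks_the_run_at_default_error_rate():
    """floor(0.01 * 20) = 0 het allowance: the het SNP splits the track
    and neither flank alone reaches 20 SNPs."""
    gm, _ = hom_track(30, het_at=15)
    assert detect_roh(gm, ROHConfig()) == []
    # with 45 SNPs each flank of the het reaches a window on its own
    gm2, pos = hom_track(45, het_at=22)
    segs = detect_roh(gm2, ROHConfig())
    assert len(segs) == 2
    assert all(
        not (s.start <= pos[22] <= s.end) for s in segs
    )  # no segment contains the het


def test_missing_tolerated_within_fraction():
    """One missing call in a 20-SNP window (5%) does not break the run."""
    gm, pos = hom_track(30, missing_at=14)
    segs = detect_roh(gm, ROHConfig())
    assert len(segs) == 1
    assert segs[0].start == pos[0] and segs[0].end == pos[-1]


def test_short_contig_skipped(caplog):
    gm, _ = hom_track(10)
    with caplog.at_level("WARNING"):
        assert detect_roh(gm, ROHConfig()) == []
    assert "skipped" in caplog.text


def test_detect_matches_naive_scanner_without_error_allowance(rng):
    """error_rate=0, no missing: detection equals the maximal
    homozygous-stretch oracle exactly."""
    for seed in range(4):
        gm = simulate_hwe_cohort(8, 200, seed=1000 + seed,
                                 maf_range=(0.2, 0.5), spacing_bp=50_000)
        cfg = ROHConfig(error_rate=0.0, min_lengths=(500_000,))
        segs = detect_roh(gm, cfg)
        pos = gm.variants["pos"].to_numpy()
        for i, sample in enumerate(gm.samples):
            expected = naive_hom_stretches(gm.calls[i], pos,
                                           cfg.min_snps_window, 500_000)
            got = [(s.start, s.end) for s in segs if s.sample == sample]
            assert got == expected


def test_detection_invariant_to_sample_and_contig_order(rng):
    gm = simulate_hwe_cohort(6, 150, seed=77, maf_range=(0.2, 0.5),
                             spacing_bp=60_000)
    segs = segments_frame(detect_roh(gm, ROHConfig()))
    perm = rng.permutation(gm.n_samples)
    gm2 = gm.take_samples(perm)
    segs2 = segments_frame(detect_roh(gm2, ROHConfig()))
    merged = segs.merge(segs2, on=["sample", "contig", "start", "end"])
    assert len(merged) == len(segs) == len(segs2)


def test_classify_counts_per_threshold():
    """Segments of 0.6/1.5/3/9 Mb count {4,3,2,1,1,0} at the defaults."""
    mk = lambda length: ROHSegment("s0", "c1", 1, length, 30, 0)
    segs = [mk(600_000), mk(1_500_000), mk(3_000_000), mk(9_000_000)]
    table = classify_roh(segs, ["s0"], ROHConfig())
    assert table["mean_count"].tolist() == [4, 3, 2, 1, 1, 0]
    # the 0.5-1 Mb share: 1 of 4 segments
    assert table.loc[0, "pct_shortest_class"] == pytest.approx(25.0)
    assert table.loc[0, "cumulative_pct"] == 100.0


def test_classify_boundary_inclusive_and_empty():
    segs = [ROHSegment("s0", "c1", 1, 1_000_000, 25, 0)]  # exactly 1 Mb
    table = classify_roh(segs, ["s0"], ROHConfig())
    assert table.loc[0, "mean_count"] == table.loc[1, "mean_count"] == 1
    empty = classify_roh([], ["s0"], ROHConfig())
    assert (empty["mean_count"] == 0).all()


def test_f_roh_arithmetic():
    """175 Mb of ROH against L = 1.75 Gb gives F_ROH = 0.10."""
    segs = [ROHSegment("s0", "c1", 1, 175_000_000, 999, 0)]
    f = f_roh(segs, ["s0", "s1"], genome_l=1_750_000_000, threshold=1_000_000)
    assert f["s0"] == pytest.approx(0.10, abs=1e-6)
    assert f["s1"] == 0.0


def test_f_roh_extremes():
    assert f_roh([], ["s0"], 1_000_000, 500_000)["s0"] == 0.0
    seg = [ROHSegment("s0", "c1", 1, 1_000_000, 30, 0)]
    assert f_roh(seg, ["s0"], 1_000_000, 500_000)["s0"] == pytest.approx(1.0)


def test_f_hom_extremes():
    gm = simulate_hwe_cohort(50, 400, seed=4, maf_range=(0.2, 0.5))
    hom = gm.calls.copy()
    hom[0] = np.where(hom[0] == 1, 0, hom[0])  # sample 0 fully homozygous
    gm_hom = make_matrix(hom, positions=gm.variants["pos"].tolist())
    assert f_hom(gm_hom).iloc[0] == pytest.approx(1.0)
    # an individual heterozygous everywhere with p ~ 0.5 goes negative
    half = np.ones((40, 60), dtype=np.int8)
    half[::2] = 0
    half[1::2] = 2
    half[0] = 1
    gm_het = make_matrix(half)
    assert f_hom(gm_het).iloc[0] < 0


def test_f_hom_hwe_cohort_centred_at_zero():
    gm = simulate_hwe_cohort(300, 2000, seed=8)
    assert abs(float(f_hom(gm).mean())) < 0.01


def test_f_roh_monotone_in_threshold_and_correlations(rng):
    """Every sample's F_ROH is non-increasing in the length threshold;
    in a mixed outbred/inbred cohort the F_ROH-F_HOM correlation at the
    smallest threshold exceeds the largest-threshold correlation."""
    gm, truth = simulate_hwe_cohort(30, 400, seed=99, maf_range=(0.35, 0.5),
                                    spacing_bp=50_000, return_truth=True)
    tracts = {}
    for i in range(15):  # half the cohort carries tracts of varied sizes
        sid = gm.samples[i]
        start = 1 + (i % 5) * 3_000_000
        length = [700_000, 1_500_000, 3_000_000, 6_000_000, 12_000_000][i % 5]
        tracts[sid] = [("chr1", start, start + length)]
    gm, truth = implant_roh(gm, truth, tracts)
    cfg = ROHConfig()
    segs = detect_roh(gm, cfg)
    records = inbreeding_records(gm, segs, cfg)
    for rec in records:
        vals = [rec.f_roh[t] for t in cfg.min_lengths]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    corr = correlate_inbreeding(records, cfg.min_lengths)
    first = corr.loc[corr["min_length"] == 500_000, "pearson_r"].iloc[0]
    last = corr.loc[corr["min_length"] == 16_000_000, "pearson_r"].iloc[0]
    assert np.isnan(last) or first > last


def test_correlate_requires_three_samples():
    recs = inbreeding_records(
        simulate_hwe_cohort(2, 50, seed=1), [], ROHConfig()
    )
    with pytest.raises(ValueError):
        correlate_inbreeding(recs)


def test_correlation_of_proportional_vectors_is_one():
    gm = simulate_hwe_cohort(5, 50, seed=2)
    recs = inbreeding_records(gm, [], ROHConfig())
    for k, r in enumerate(recs):
        r.f_hom = 0.1 * k
        for thr in r.f_roh:
            r.f_roh[thr] = 0.05 * k  # exactly proportional
    corr = correlate_inbreeding(recs)
    assert corr["pearson_r"].iloc[0] == pytest.approx(1.0)


def test_genome_covered_length_and_bed_export():
    gm = make_matrix(
        np.zeros((1, 4), dtype=np.int8),
        positions=[100, 900, 50, 250],
        contigs=["c1", "c1", "c2", "c2"],
    )
    assert genome_covered_length(gm) == 800 + 200
    bed = segments_to_bed([ROHSegment("s0", "c1", 100, 900, 4, 0)])
    assert bed.iloc[0].tolist() == ["c1", 99, 900, "s0"]  # 0-based half-open
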