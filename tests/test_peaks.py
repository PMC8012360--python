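"""Peak I/O, normalization, profiles, filters, clustering, annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grescan.peaks import (
    Peak,
    SampleMeta,
    Transcript,
    aggregate_profile,
    annotate_region,
    assign_clusters,
    call_peak_filter,
    differential_enriched,
    extract_windows,
    nearest_distance,
    nearest_gene_lfc,
    normalize_to_10M,
    poisson_tail,
    read_gene_model,
    read_peaks,
    sample_random_sites,
    write_peaks,
)

from conftest import random_seq


def make_peak(i, start, width=200, **kw):
    return Peak("chr1", start, start + width, start + width // 2, f"p{i}", **kw)


# ---------------------------------------------------------------------------
# I/O and windows
# ---------------------------------------------------------------------------

def test_peak_round_trip(tmp_path):
    peaks = [
        make_peak(0, 100, tag_counts={"GRwt": 80.0, "GRdim": 3.0},
                  control_count=2.0, local_background_count=5.0),
        make_peak(1, 900, tag_counts={"GRwt": 10.0, "GRdim": 200.0}),
    ]
    path = tmp_path / "peaks.tsv"
    write_peaks(peaks, path)
    back = read_peaks(path)
    assert [(p.chrom, p.start, p.end, p.summit, p.id) for p in back] == [
        (p.chrom, p.start, p.end, p.summit, p.id) for p in peaks
    ]
    assert back[0].tag_counts == peaks[0].tag_counts
    assert back[0].control_count == 2.0


def test_empty_peak_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert read_peaks(path) == []


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        Peak("chr1", 100, 100, 100, "bad")
    with pytest.raises(ValueError):
        Peak("chr1", 100, 200, 250, "bad_summit")


def test_extract_windows_arithmetic_and_boundary(rng, caplog):
    genome = {"chr1": random_seq(rng, 10_000)}
    inside = Peak("chr1", 4900, 5100, 5000, "in")
    near_edge = Peak("chr1", 200, 400, 300, "edge")
    windows = extract_windows(genome, [inside, near_edge], flank=1000)
    assert set(windows) == {"in"}
    assert windows["in"] == genome["chr1"][4000:6000].upper()
    # re-locate the extracted window by exact string search
    assert genome["chr1"].upper().find(windows["in"]) == 4000
    with pytest.raises(KeyError):
        extract_windows(genome, [Peak("chrX", 4900, 5100, 5000, "x")])


# ---------------------------------------------------------------------------
# normalization and profiles
# ---------------------------------------------------------------------------

def test_normalize_to_10M_values_and_linearity():
    assert normalize_to_10M(50, 25_000_000) == pytest.approx(20.0)
    assert normalize_to_10M(123.0, 10_000_000) == pytest.approx(123.0)
    a, b, total = 37.0, 91.0, 31_234_567
    assert normalize_to_10M(a + b, total) == pytest.approx(
        normalize_to_10M(a, total) + normalize_to_10M(b, total)
    )
    with pytest.raises(ValueError):
        normalize_to_10M(1, 0)


def test_aggregate_profile_center_bin_example():
    events = [(f"s{i}", 0) for i in range(100)]
    prof = aggregate_profile(events, n_sites=100, bin_width=10)
    center = np.flatnonzero(prof.bin_centers == 5.0)[0]
    assert prof.values[center] == pytest.approx(0.1)
    assert prof.values.sum() == pytest.approx(prof.values[center])


def test_aggregate_profile_conserves_event_mass(rng):
    events = [("s", int(o)) for o in rng.integers(-1000, 1000, size=5000)]
    for bw in (10, 20):
        prof = aggregate_profile(events, n_sites=123, bin_width=bw)
        assert prof.total_events() == pytest.approx(len(events), abs=1e-9)


def test_aggregate_profile_flat_for_uniform_offsets(rng):
    n = 20_000
    events = [("s", int(o)) for o in rng.integers(-1000, 1000, size=n)]
    prof = aggregate_profile(events, n_sites=100, bin_width=10)
    counts = prof.values * 100 * 10
    chi2 = ((counts - n / 200) ** 2 / (n / 200)).sum()
    assert chi2 < stats.chi2.ppf(1 - 1e-6, df=199)


def test_aggregate_profile_rejects_zero_sites():
    with pytest.raises(ValueError):
        aggregate_profile([], n_sites=0)


# ---------------------------------------------------------------------------
# peak filter chain and differential test
# ---------------------------------------------------------------------------

def _filter_oracle(peaks, sample, control, fc_control=4, fc_local=4,
                   min_tags=75, fdr=0.001):
    """Independent four-gate reimplementation with its own Poisson tail
    (term-wise pmf summation) and manual Benjamini-Hochberg."""

    def tail(k, lam):
        k = int(math.ceil(k))
        if k <= 0:
            return 1.0
        if lam == 0:
            return 0.0
        terms = [
            math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))
            for i in range(k)
        ]
        return max(0.0, 1.0 - math.fsum(terms))

    scale = sample.total_mapped_reads / control.total_mapped_reads
    rows = []
    for p in peaks:
        t = p.tag_counts.get(sample.name, 0.0)
        c = p.control_count * scale
        rows.append((p.id, t, c, p.local_background_count, tail(t, c)))
    m = len(rows)
    order = sorted(range(m), key=lambda i: rows[i][4])
    padj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m - 1, -1, -1):
        i = order[rank_from_end]
        prev = min(prev, rows[i][4] * m / (rank_from_end + 1))
        padj[i] = prev
    survivors = set()
    for (pid, t, c, local, _p), adj in zip(rows, padj):
        if (
            t > min_tags
            and t / max(c, 1.0) > fc_control
            and t / max(local, 1.0) > fc_local
            and adj < fdr
        ):
            survivors.add(pid)
    return survivors


def test_filter_single_gate_examples():
    sample = SampleMeta("GRwt", 10_000_000)
    control = SampleMeta("ctl", 10_000_000)
    passing = make_peak(0, 100, tag_counts={"GRwt": 80.0},
                        control_count=10.0, local_background_count=15.0)
    tag_floor = make_peak(1, 900, tag_counts={"GRwt": 70.0},
                          control_count=1.0, local_background_count=1.0)
    got = {p.id for p in call_peak_filter([passing, tag_floor], sample, control)}
    assert got == {"p0"}


def test_filter_matches_independent_oracle(rng):
    sample = SampleMeta("GRwt", 20_000_000)
    control = SampleMeta("ctl", 10_000_000)
    peaks = []
    for i in range(1000):
        peaks.append(
            make_peak(
                i, i * 500,
                tag_counts={"GRwt": float(rng.integers(0, 300))},
                control_count=float(rng.integers(0, 40)),
                local_background_count=float(rng.integers(0, 40)),
            )
        )
    got = {p.id for p in call_peak_filter(peaks, sample, control)}
    assert got == _filter_oracle(peaks, sample, control)


def test_differential_symmetry_and_scale_invariance():
    fc, p, flag = differential_enriched(40, 40, 1e7, 1e7)
    assert not flag and fc <= 4
    fc1, p1, f1 = differential_enriched(30, 5, 1e7, 2e7)
    fc2, p2, f2 = differential_enriched(60, 10, 2e7, 4e7)
    assert fc1 == pytest.approx(fc2)


def test_differential_exact_tail_oracle():
    fc, p, flag = differential_enriched(20, 2, 1e7, 1e7)
    exact = 1.0 - math.fsum(
        math.exp(-2.0 + k * math.log(2.0) - math.lgamma(k + 1)) for k in range(20)
    )
    assert p == pytest.approx(exact, rel=1e-9)
    assert flag


def test_differential_matches_oracle_on_random_candidates(rng):
    for _ in range(1000):
        a, b = int(rng.integers(0, 200)), int(rng.integers(0, 200))
        ta, tb = float(rng.integers(5, 30)) * 1e6, float(rng.integers(5, 30)) * 1e6
        fc, p, flag = differential_enriched(a, b, ta, tb)
        lam = b * ta / tb
        p_oracle = (
            1.0
            if a <= 0
            else (0.0 if lam == 0 else max(0.0, 1.0 - math.fsum(
                math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
                for k in range(a)
            )))
        )
        fc_oracle = (a * 1e7 / ta) / (b * 1e7 / tb + 1.0)
        assert flag == (fc_oracle > 4 and p_oracle < 1e-4)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_assign_clusters_definitions(caplog):
    peaks = [make_peak(i, i * 500) for i in range(5)]
    called = {
        "GRwt": {"p0", "p1", "p3"},
        "GRdim": {"p0", "p1", "p2", "p3"},
        "GRmon": {"p3"},
    }
    diff = {"p0": True, "p1": False}
    labels = assign_clusters(peaks, called, diff)
    assert labels == {"p0": "C1", "p1": "C2", "p2": "C3", "p3": "C4"}
    assert "p4" not in labels  # called nowhere -> excluded with warning


def test_cluster_recovery_from_tag_templates(rng):
    from grescan import synthetic as syn

    peaks, cluster_of = [], {}
    for i, c in enumerate(["C1", "C2", "C3", "C4"] * 125):
        p = make_peak(i, i * 500)
        peaks.append(p)
        cluster_of[p.id] = c
    syn.gen_tag_counts(peaks, cluster_of, seed=5)
    samples = {r: SampleMeta(r, 10_000_000, receptor=r)
               for r in ("GRwt", "GRdim", "GRmon")}
    control = SampleMeta("GRKO", 10_000_000, receptor="control")
    called = {
        r: {p.id for p in call_peak_filter(peaks, samples[r], control)}
        for r in samples
    }
    diff = {
        p.id: differential_enriched(
            p.tag_counts["GRwt"], p.tag_counts["GRdim"], 1e7, 1e7
        )[2]
        for p in peaks
    }
    labels = assign_clusters(peaks, called, diff)
    agreement = np.mean([labels.get(p.id) == cluster_of[p.id] for p in peaks])
    assert agreement >= 0.95


# ---------------------------------------------------------------------------
# background sampling and distances
# ---------------------------------------------------------------------------

def test_sample_random_sites_determinism_and_pool():
    pool = [("chr1", i * 1000, i * 1000 + 300) for i in range(50)]
    a = sample_random_sites(pool, n=20, width=200, seed=7)
    b = sample_random_sites(pool, n=20, width=200, seed=7)
    assert [(p.start, p.end) for p in a] == [(p.start, p.end) for p in b]
    allp = sample_random_sites(pool, n=50, width=200, seed=7)
    assert {p.start + 100 for p in allp} == {s + 150 for _, s, e in pool}
    with pytest.raises(ValueError):
        sample_random_sites(pool, n=51)


def test_sample_random_sites_uniform_frequencies():
    pool = [("chr1", i * 1000, i * 1000 + 300) for i in range(20)]
    counts = np.zeros(20)
    for seed in range(2000):
        for p in sample_random_sites(pool, n=5, width=100, seed=seed):
            counts[(p.summit - 150) // 1000] += 1
    expected = 2000 * 5 / 20
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(1 - 1e-6, df=19)


def test_nearest_distance_examples():
    peaks = [Peak("chr1", 550, 560, 555, "inside"),
             Peak("chr1", 100, 200, 150, "left")]
    dists, median, cdf = nearest_distance(peaks, [("chr1", 500, 600)])
    assert dists[0] == 0
    assert dists[1] == 300
    assert median == 150
    assert cdf["cdf"].iloc[-1] == 1.0
    with pytest.raises(ValueError):
        nearest_distance(peaks, [])


def test_nearest_distance_matches_bruteforce(rng):
    feats = [
        ("chr1", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 100_000, 1000), rng.integers(1, 500, 1000))
    ]
    peaks = [
        Peak("chr1", int(s), int(s) + 50, int(s) + 25, f"q{i}")
        for i, s in enumerate(rng.integers(0, 100_000, 300))
    ]
    dists, _, _ = nearest_distance(peaks, feats)
    for p, d in zip(peaks, dists):
        brute = min(
            0 if (p.start < fe and fs < p.end)
            else (fs - p.end if p.end <= fs else p.start - fe)
            for _, fs, fe in feats
        )
        assert d == brute


# ---------------------------------------------------------------------------
# gene association and region annotation
# ---------------------------------------------------------------------------

def test_nearest_gene_single_and_tiebreak():
    genes = pd.DataFrame(
        {
            "gene": ["b_gene", "a_gene"],
            "chrom": ["chr1", "chr1"],
            "tss": [1000, 3000],
            "lfc": [1.5, -0.5],
        }
    )
    single = nearest_gene_lfc([make_peak(0, 100)], genes.iloc[:1])
    assert single["gene"].iloc[0] == "b_gene"
    # summit at 2000 is equidistant: tie breaks to the smaller TSS
    tied = nearest_gene_lfc([Peak("chr1", 1900, 2100, 2000, "t")], genes)
    assert tied["gene"].iloc[0] == "b_gene"
    with pytest.raises(ValueError):
        nearest_gene_lfc([make_peak(0, 100)], genes.iloc[:0])


def test_nearest_gene_matches_bruteforce(rng):
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(200)],
            "chrom": "chr1",
            "tss": rng.integers(0, 50_000, 200),
            "lfc": rng.normal(size=200),
        }
    )
    peaks = [Peak("chr1", int(s), int(s) + 10, int(s) + 5, f"q{i}")
             for i, s in enumerate(rng.integers(0, 50_000, 100))]
    got = nearest_gene_lfc(peaks, genes)
    for p, (_, row) in zip(peaks, got.iterrows()):
        dmin = (genes["tss"] - p.summit).abs().min()
        assert row["distance"] == dmin


GTF = """\
chr1\ttest\ttranscript\t5001\t9000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t5001\t5200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t8801\t9000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""


def test_annotate_region_precedence(tmp_path):
    gtf = tmp_path / "genes.gtf"
    gtf.write_text(GTF)
    transcripts = read_gene_model(gtf)
    assert len(transcripts) == 1 and transcripts[0].strand == "+"
    peaks = [
        Peak("chr1", 4750, 4850, 4800, "promoter"),  # 200 bp upstream of TSS
        Peak("chr1", 5100, 5160, 5150, "exonic"),
        Peak("chr1", 7000, 7100, 7050, "intronic"),
        Peak("chr1", 20_000, 20_100, 20_050, "desert"),
    ]
    labels = annotate_region(peaks, transcripts)
    assert labels == {
        "promoter": "promoter",
        "exonic": "misc",
        "intronic": "intron",
        "desert": "intergenic",
    }
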