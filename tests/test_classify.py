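"""Four-way GRE classification, overlap correction and degenerate rescue."""

import numpy as np
import pandas as pd
import pytest

from grescan.classify import (
    DEFAULT_HALF_CORE,
    RESCUE_PRESETS,
    SiteClass,
    SiteMotifProfile,
    adjusted_half_percentage,
    classify_peaks,
    classify_site,
    correct_overlap,
    full_side_intervals,
    half_core_interval,
    overall_partition,
    rescue_motifs,
    rescue_site,
    round_half_away,
    summarize,
)
from grescan.motifs import MotifHit

FULL_W = 15
HALF_W = 8


def full_hit(start, strand="+"):
    return MotifHit(start=start, strand=strand, motif_name="full", width=FULL_W,
                    score=10.0)


def half_hit(start, strand="+"):
    return MotifHit(start=start, strand=strand, motif_name="half", width=HALF_W,
                    score=5.0)


def profile(full=(), half=()):
    return SiteMotifProfile(
        site_id="s", full_hits=list(full), half_hits=list(half),
        search_start=0, search_end=500,
    )


# ---------------------------------------------------------------------------
# classification truth table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "full,half,expected",
    [
        ((), (), "none"),
        ((full_hit(10),), (), "full_only"),
        ((), (half_hit(10),), "half_only"),
        ((full_hit(10),), (half_hit(100),), "both"),
    ],
)
def test_classify_site_truth_table(full, half, expected):
    assert classify_site(profile(full, half)).value == expected


# ---------------------------------------------------------------------------
# overlap correction
# ---------------------------------------------------------------------------

def test_coincident_core_is_corrected():
    # half-site aligned with the full GRE start: ACA core inside left hexamer
    prof = profile((full_hit(50),), (half_hit(50),))
    sc = correct_overlap(prof, classify_site(prof))
    assert sc.value == "full_only" and sc.corrected


def test_distant_half_site_stays_both():
    prof = profile((full_hit(50),), (half_hit(120),))
    sc = correct_overlap(prof, classify_site(prof))
    assert sc.value == "both" and not sc.corrected


def test_one_unexplained_half_keeps_both():
    prof = profile((full_hit(50),), (half_hit(50), half_hit(200)))
    sc = correct_overlap(prof, classify_site(prof))
    assert sc.value == "both"


def test_correction_is_idempotent_and_noop_for_other_classes():
    prof = profile((full_hit(50),), (half_hit(50),))
    once = correct_overlap(prof, classify_site(prof))
    assert correct_overlap(prof, once) == once
    for cls in ("full_only", "half_only", "none"):
        assert correct_overlap(profile(), SiteClass(cls)) == SiteClass(cls)


def test_correction_decisions_match_interval_oracle():
    """All relative placements of a half-site around one full hit must agree
    with a brute-force interval-intersection oracle."""
    fh = full_hit(100)
    sides = full_side_intervals(fh)
    assert sides == ((100, 106), (109, 115))
    for strand in "+-":
        for start in range(70, 140):
            hh = half_hit(start, strand)
            core = half_core_interval(hh, DEFAULT_HALF_CORE)
            explained = any(
                core[0] < side[1] and side[0] < core[1] for side in sides
            )
            prof = profile((fh,), (hh,))
            sc = correct_overlap(prof, classify_site(prof))
            assert (sc.value == "full_only") == explained, (strand, start)


def test_minus_strand_core_interval_mapping():
    # pattern index i maps to forward position start + width - 1 - i
    hh = half_hit(20, "-")
    lo, hi = half_core_interval(hh, (3, 4, 5))
    assert (lo, hi) == (20 + 8 - 1 - 5, 20 + 8 - 3)


def test_correction_never_increases_half_sites(rng):
    """Monotonicity: post-correction full_only count >= pre-correction."""
    for _ in range(200):
        n_full = int(rng.integers(0, 3))
        n_half = int(rng.integers(0, 3))
        prof = profile(
            tuple(full_hit(int(rng.integers(0, 200))) for _ in range(n_full)),
            tuple(half_hit(int(rng.integers(0, 200))) for _ in range(n_half)),
        )
        pre = classify_site(prof)
        post = correct_overlap(prof, pre)
        pre_half = pre.value in ("both", "half_only")
        post_half = post.value in ("both", "half_only")
        assert post_half <= pre_half


# ---------------------------------------------------------------------------
# rescue arithmetic
# ---------------------------------------------------------------------------

def test_adjusted_half_percentage_published_worked_examples():
    """The printed cluster arithmetic: 65 half-only sites of 144 with 26
    rescued gives 27%; 102 of 300 with 36 rescued gives 22%."""
    exact_c3, rounded_c3 = adjusted_half_percentage(144, 65, 26)
    assert rounded_c3 == 27
    assert exact_c3 == pytest.approx(27.083, abs=1e-3)
    exact_c4, rounded_c4 = adjusted_half_percentage(300, 102, 36)
    assert rounded_c4 == 22
    assert exact_c4 == pytest.approx(22.0)


def test_no_rescue_keeps_original_percentage():
    exact, _ = adjusted_half_percentage(200, 50, 0)
    assert exact == pytest.approx(100 * 50 / 200)


def test_rescue_bounds_validated():
    with pytest.raises(ValueError):
        adjusted_half_percentage(100, 10, 20)
    with pytest.raises(ValueError):
        adjusted_half_percentage(0, 0, 0)


def test_round_half_away():
    assert round_half_away(26.5) == 27
    assert round_half_away(27.083) == 27
    assert round_half_away(22.0) == 22
    assert round_half_away(-2.5) == -3


def test_rescue_site_matches_either_strand():
    motifs = rescue_motifs("results_acannntnt")
    assert rescue_site("GG" + "ACAGGGTCT" + "GG", motifs)  # ACAnnnTnT
    assert rescue_site("GG" + "AGATCCTGT" + "GG", motifs)  # revcomp match
    assert not rescue_site("GGGGGGGGGGGGGG", motifs)
    with pytest.raises(ValueError):
        rescue_site("ACGT", [])


def test_rescue_presets_cover_both_spellings():
    assert RESCUE_PRESETS["results_acannntnt"] == ("ACAnnnTnT",)
    assert "AGAnnnTnT" in RESCUE_PRESETS["methods_agann_set"]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _table(rows):
    return pd.DataFrame(
        rows, columns=["site_id", "cluster", "class", "corrected", "rescued"]
    )


def test_summarize_all_full_only():
    t = _table([(f"s{i}", "C1", "full_only", False, False) for i in range(10)])
    s = summarize(t).set_index("cluster")
    assert s.loc["C1", "pct_full_only"] == 100.0
    assert s.loc["C1", ["pct_half_only", "pct_both", "pct_none"]].sum() == 0.0


def test_summarize_percentages_sum_to_100(rng):
    classes = ["full_only", "half_only", "both", "none"]
    t = _table(
        [
            (f"s{i}", rng.choice(["C1", "C2"]), rng.choice(classes), False, False)
            for i in range(97)
        ]
    )
    s = summarize(t)
    total = s[["pct_full_only", "pct_half_only", "pct_both", "pct_none"]].sum(axis=1)
    assert np.allclose(total, 100.0)


def test_summarize_background_column_and_rescue_counts():
    t = _table(
        [("a", "C3", "half_only", False, True),
         ("b", "C3", "half_only", False, False),
         ("c", "C3", "full_only", False, False),
         ("d", "C3", "none", False, False)]
    )
    bg = _table([("r0", "NA", "none", False, False)])
    s = summarize(t, background=bg).set_index("cluster")
    assert s.loc["C3", "n_rescued"] == 1
    assert s.loc["C3", "adjusted_half_pct"] == pytest.approx(100 * (2 - 1) / 4)
    assert s.loc["R", "n_sites"] == 1
    assert s.loc["all", "n_sites"] == 4  # background excluded from 'all'


def test_overall_partition_pools_full_and_both():
    t = _table(
        [("a", "C1", "full_only", False, False),
         ("b", "C1", "both", False, False),
         ("c", "C1", "half_only", False, False),
         ("d", "C1", "none", False, False)]
    )
    part = overall_partition(t)
    assert part["pct_full"] == 50.0
    assert sum(part.values()) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# planted-truth recovery (noise-free)
# ---------------------------------------------------------------------------

def test_summary_equals_planted_composition(planted_sites_200_per_class, motif_set):
    spec, peaks, truth, genome = planted_sites_200_per_class
    table = classify_peaks(
        peaks,
        {spec.chrom: genome},
        motif_set["full_well"],
        motif_set["full_degen"],
        motif_set["half"],
        consensus_list=motif_set["rescue"],
        clusters=dict(zip(truth["site_id"], truth["cluster_template"])),
    )
    merged = table.merge(truth, on="site_id")
    assert (merged["class"] == merged["expected_class"]).all()
    comp = table["class"].value_counts().to_dict()
    assert comp == {"full_only": 200, "half_only": 200, "both": 200, "none": 200}
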