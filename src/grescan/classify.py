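"""Four-way GRE classification of ChIP peaks with correction and rescue.

Each peak is scanned across its own breadth with three motif models: a
well-defined full GRE, a degenerate full GRE (their hits are pooled as
"full"), and a half-GRE.  The peak is then placed in one of four classes:

* ``full_only``  - a full GRE without any half-GRE hit
* ``half_only``  - a half-GRE hit without a full GRE
* ``both``       - at least one of each
* ``none``       - neither

Two refinements follow.  *Misclassification correction*: a ``both`` site
is moved to ``full_only`` when every half-GRE hit is explained by a full
GRE, i.e. the ACA (or TGT on the minus strand) core of the half-site
overlaps one terminal hexamer of a detected full GRE - such "half-sites"
are just one arm of the palindrome re-detected by the shorter model.
*Degenerate rescue*: ``half_only`` sites are re-scanned with relaxed
full-GRE consensus patterns (e.g. ACAnnnTnT); sites containing one are
plausibly weak full GREs, and the adjusted half-site percentage of a
cluster is ``100 * (h - r) / n`` for ``h`` half-only sites of which
``r`` were rescued among ``n`` peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import (
    PWM,
    ConsensusMotif,
    MotifHit,
    dedupe_hits,
    scan_consensus,
    scan_window,
)
from .peaks import Peak, peak_sequence

SITE_CLASSES = ("full_only", "half_only", "both", "none")

#: ACA core of the default 8-bp half-GRE model AGAACAnn (0-based indices)
DEFAULT_HALF_CORE = (3, 4, 5)

#: hexamer length of one palindrome arm of the full GRE
_SIDE = 6

#: degenerate consensus presets for the rescue scan
RESCUE_PRESETS: dict[str, tuple[str, ...]] = {
    "results_acannntnt": ("ACAnnnTnT",),
    "methods_agann_set": (
        "AGAnnnTnn",
        "AGAnnnnGn",
        "AGAnnnnnT",
        "AGAnnnTnT",
        "AGAnnnTGn",
        "AGAnnnnGT",
    ),
}


def rescue_motifs(preset: str = "results_acannntnt") -> list[ConsensusMotif]:
    """Named degenerate-consensus set used for the rescue scan."""
    return [
        ConsensusMotif(name=f"rescue_{p}", pattern=p.upper())
        for p in RESCUE_PRESETS[preset]
    ]


@dataclass
class SiteMotifProfile:
    """Per-peak motif hits within the peak's own breadth."""

    site_id: str
    full_hits: list[MotifHit]
    half_hits: list[MotifHit]
    search_start: int
    search_end: int
    cluster: str | None = None
    sequence: str = ""


@dataclass(frozen=True)
class SiteClass:
    """Four-way class with correction and rescue bookkeeping flags."""

    value: str
    corrected: bool = False
    rescued: bool = False

    def __post_init__(self) -> None:
        if self.value not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.value!r}")
        if self.corrected and self.value != "full_only":
            raise ValueError("corrected sites must be full_only")


def build_profile(
    peak: Peak,
    genome,
    pwm_full_well: PWM,
    pwm_full_degen: PWM,
    pwm_half: PWM,
    cluster: str | None = None,
) -> SiteMotifProfile:
    """Scan the peak's breadth with the three PWMs.

    Full hits are the union of well-defined and degenerate full-GRE hits,
    deduplicated by (interval, strand).
    """
    seq = peak_sequence(genome, peak)
    full = dedupe_hits(
        scan_window(seq, pwm_full_well, site_id=peak.id)
        + scan_window(seq, pwm_full_degen, site_id=peak.id)
    )
    half = scan_window(seq, pwm_half, site_id=peak.id)
    return SiteMotifProfile(
        site_id=peak.id,
        full_hits=full,
        half_hits=half,
        search_start=peak.start,
        search_end=peak.end,
        cluster=cluster,
        sequence=seq,
    )


def classify_site(profile: SiteMotifProfile) -> SiteClass:
    """Four-way class from full/half hit presence."""
    has_full = bool(profile.full_hits)
    has_half = bool(profile.half_hits)
    if has_full and has_half:
        return SiteClass("both")
    if has_full:
        return SiteClass("full_only")
    if has_half:
        return SiteClass("half_only")
    return SiteClass("none")


def half_core_interval(
    hit: MotifHit, core_positions: Sequence[int] = DEFAULT_HALF_CORE
) -> tuple[int, int]:
    """Window-coordinate interval of the half-site's ACA/TGT core.

    On the minus strand pattern position ``i`` maps to forward position
    ``start + width - 1 - i``.
    """
    if not core_positions:
        raise ValueError("half PWM has no core positions defined")
    lo, hi = min(core_positions), max(core_positions)
    if hit.strand == "+":
        return hit.start + lo, hit.start + hi + 1
    return hit.start + hit.width - 1 - hi, hit.start + hit.width - lo


def full_side_intervals(hit: MotifHit) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two terminal hexamer arms of a full-GRE hit, forward coords."""
    return (
        (hit.start, hit.start + _SIDE),
        (hit.end - _SIDE, hit.end),
    )


def _intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contained(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return b[0] <= a[0] and a[1] <= b[1]


def correct_overlap(
    profile: SiteMotifProfile,
    site_class: SiteClass,
    core_positions: Sequence[int] = DEFAULT_HALF_CORE,
    mode: str = "intersect",
    require_strand_concordance: bool = False,
) -> SiteClass:
    """Move a ``both`` site to ``full_only`` when its half hits are spurious.

    A half hit is *explained* when the interval of its ACA/TGT core
    overlaps (>= 1 bp; or is fully contained, ``mode='contain'``) either
    terminal hexamer of any full hit.  Only if every half hit is explained
    does the site become ``full_only`` with ``corrected=True``; an
    unexplained independent half-site keeps the site in ``both``.
    Idempotent, and a no-op for classes other than ``both``.
    """
    if site_class.value != "both":
        return site_class
    check = _contained if mode == "contain" else _intersects
    sides = [
        (side, fh.strand)
        for fh in profile.full_hits
        for side in full_side_intervals(fh)
    ]
    for hh in profile.half_hits:
        core = half_core_interval(hh, core_positions)
        explained = any(
            check(core, side)
            and (not require_strand_concordance or hh.strand == strand)
            for side, strand in sides
        )
        if not explained:
            return site_class
    return SiteClass("full_only", corrected=True)


def rescue_site(sequence: str, consensus_list: Sequence[ConsensusMotif]) -> bool:
    """True when any degenerate consensus matches (either strand)."""
    if not consensus_list:
        raise ValueError("empty consensus list")
    return any(scan_consensus(sequence, m) for m in consensus_list)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed style)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def adjusted_half_percentage(
    n_sites: int, n_half_only: int, n_rescued: int
) -> tuple[float, int]:
    """Cluster-level half-GRE percentage after degenerate rescue.

    ``100 * (h - r) / n`` for ``h`` half-only sites of which ``r`` carry a
    degenerate full-GRE consensus, among ``n`` sites.  Returns the exact
    value and its integer rounding.
    """
    if n_sites <= 0:
        raise ValueError("cluster has no sites")
    if not 0 <= n_rescued <= n_half_only <= n_sites:
        raise ValueError("need 0 <= rescued <= half_only <= n_sites")
    exact = 100.0 * (n_half_only - n_rescued) / n_sites
    return exact, round_half_away(exact)


def rescue_degenerate(
    profiles: Mapping[str, SiteMotifProfile],
    classes: Mapping[str, SiteClass],
    consensus_list: Sequence[ConsensusMotif],
) -> dict[str, SiteClass]:
    """Flag half_only sites whose breadth contains a degenerate consensus."""
    if not consensus_list:
        raise ValueError("empty consensus list")
    out: dict[str, SiteClass] = {}
    for sid, sc in classes.items():
        if sc.value == "half_only" and rescue_site(
            profiles[sid].sequence, consensus_list
        ):
            out[sid] = replace(sc, rescued=True)
        else:
            out[sid] = sc
    return out


@dataclass
class ClusterSummary:
    """Per-cluster class percentages and rescue arithmetic."""

    cluster: str
    n_sites: int
    pct_full_only: float
    pct_half_only: float
    pct_both: float
    pct_none: float
    n_corrected: int
    n_half_only: int
    n_rescued: int
    adjusted_half_pct: float
    adjusted_half_pct_rounded: int
    pct_with_motif: dict[str, float] = field(default_factory=dict)


def summarize(
    table: pd.DataFrame,
    background: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-level summary of a classification table.

    ``table`` needs columns ``site_id``, ``cluster``, ``class``,
    ``corrected``, ``rescued``.  An optional ``background`` table of the
    same shape (random accessible sites) is appended as cluster ``R``.
    Returns one row per cluster plus an ``all`` row pooling every site in
    ``table``.
    """
    frames = [table]
    if background is not None:
        frames.append(background.assign(cluster="R"))
    rows = []
    pooled = pd.concat(frames, ignore_index=True)
    clusters = sorted(table["cluster"].unique()) + (
        ["R"] if background is not None else []
    )
    for name in clusters + ["all"]:
        sub = table if name == "all" else pooled[pooled["cluster"] == name]
        n = len(sub)
        if n == 0:
            raise ValueError(f"cluster {name!r} is empty")
        counts = sub["class"].value_counts()
        h = int(counts.get("half_only", 0))
        r = int(sub["rescued"].sum())
        exact, rounded = adjusted_half_percentage(n, h, r)
        rows.append(
            {
                "cluster": name,
                "n_sites": n,
                "pct_full_only": 100.0 * counts.get("full_only", 0) / n,
                "pct_half_only": 100.0 * h / n,
                "pct_both": 100.0 * counts.get("both", 0) / n,
                "pct_none": 100.0 * counts.get("none", 0) / n,
                "n_corrected": int(sub["corrected"].sum()),
                "n_half_only": h,
                "n_rescued": r,
                "adjusted_half_pct": exact,
                "adjusted_half_pct_rounded": rounded,
            }
        )
    return pd.DataFrame(rows)


def overall_partition(table: pd.DataFrame) -> dict[str, float]:
    """Overall full / half-only / none partition over all sites.

    "Full" pools ``full_only`` and ``both`` (sites with a full GRE).
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty classification table")
    counts = table["class"].value_counts()
    full = counts.get("full_only", 0) + counts.get("both", 0)
    return {
        "pct_full": 100.0 * full / n,
        "pct_half_only": 100.0 * counts.get("half_only", 0) / n,
        "pct_none": 100.0 * counts.get("none", 0) / n,
    }


def classify_peaks(
    peaks: Sequence[Peak],
    genome,
    pwm_full_well: PWM,
    pwm_full_degen: PWM,
    pwm_half: PWM,
    consensus_list: Sequence[ConsensusMotif] | None = None,
    clusters: Mapping[str, str] | None = None,
    core_positions: Sequence[int] = DEFAULT_HALF_CORE,
) -> pd.DataFrame:
    """End-to-end classification driver: scan, classify, correct, rescue.

    Returns a table with columns ``site_id``, ``cluster``, ``class``,
    ``corrected``, ``rescued``.
    """
    profiles: dict[str, SiteMotifProfile] = {}
    classes: dict[str, SiteClass] = {}
    for p in peaks:
        prof = build_profile(
            p, genome, pwm_full_well, pwm_full_degen, pwm_half,
            cluster=(clusters or {}).get(p.id),
        )
        profiles[p.id] = prof
        classes[p.id] = correct_overlap(
            prof, classify_site(prof), core_positions=core_positions
        )
    if consensus_list:
        classes = rescue_degenerate(profiles, classes, consensus_list)
    return pd.DataFrame(
        {
            "site_id": list(classes),
            "cluster": [profiles[s].cluster or "NA" for s in classes],
            "class": [classes[s].value for s in classes],
            "corrected": [classes[s].corrected for s in classes],
            "rescued": [classes[s].rescued for s in classes],
        }
    )
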