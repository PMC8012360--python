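"""Peak I/O, normalization, profiles, filtering, clustering and annotation.

Operations on ChIP/ATAC peak tables for the receptor-occupancy analysis:
the stated peak filter chain (FDR, fold change over control and local
background, a raw-tag floor), Poisson differential enrichment between
receptors, assignment of union peaks to occupancy clusters C1-C4,
aggregate tag/motif density profiles around summits, random background
sampling from accessible chromatin, nearest-feature distances, nearest
gene association and genomic-region annotation.

Coordinates are 0-based, half-open (BED convention) throughout.  Summits
are absolute coordinates.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RECEPTORS = ("GRwt", "GRdim", "GRmon")
CLUSTERS = ("C1", "C2", "C3", "C4")


@dataclass
class Peak:
    """A genomic interval with summit and per-sample tag counts."""

    chrom: str
    start: int
    end: int
    summit: int
    id: str
    tag_counts: dict[str, float] = field(default_factory=dict)
    control_count: float = 0.0
    local_background_count: float = 0.0
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.id}: start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"peak {self.id}: summit outside [start, end)")
        for s, c in self.tag_counts.items():
            if c < 0:
                raise ValueError(f"peak {self.id}: negative count for {s}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleMeta:
    """Library-level metadata for one ChIP/ATAC sample."""

    name: str
    total_mapped_reads: int
    condition: str = "Dex"  # NT or Dex
    receptor: str = "GRwt"

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")


@dataclass(frozen=True)
class AggregateProfile:
    """Binned event density per site per bp around peak summits."""

    bin_centers: np.ndarray
    values: np.ndarray
    bin_width: int
    n_sites: int
    mode: str = "tags"

    def total_events(self) -> float:
        return float(self.values.sum() * self.bin_width * self.n_sites)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIXED_COLS = [
    "chrom", "start", "end", "id", "score", "strand",
    "summit", "control_count", "local_bg_count",
]


def write_peaks(peaks: Sequence[Peak], path) -> None:
    """Write peaks as a BED6+ TSV with summit, control/local and count columns."""
    samples = sorted({s for p in peaks for s in p.tag_counts})
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_FIXED_COLS + samples) + "\n")
        for p in peaks:
            row = [
                p.chrom, str(p.start), str(p.end), p.id, f"{p.score:g}",
                p.strand, str(p.summit),
                f"{p.control_count:g}", f"{p.local_background_count:g}",
            ] + [f"{p.tag_counts.get(s, 0):g}" for s in samples]
            fh.write("\t".join(row) + "\n")


def read_peaks(path) -> list[Peak]:
    """Read a peak table written by :func:`write_peaks`."""
    peaks: list[Peak] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}: line {lineno}: missing header line")
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            rec = dict(zip(header, fields))
            try:
                samples = header[len(_FIXED_COLS):]
                peaks.append(
                    Peak(
                        chrom=rec["chrom"],
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        summit=int(rec["summit"]),
                        id=rec["id"],
                        score=float(rec["score"]),
                        strand=rec["strand"],
                        control_count=float(rec["control_count"]),
                        local_background_count=float(rec["local_bg_count"]),
                        tag_counts={s: float(rec[s]) for s in samples},
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def extract_windows(
    fasta, peaks: Sequence[Peak], flank: int = 1000
) -> dict[str, str]:
    """Summit-centered windows of length 2*flank, uppercased.

    ``fasta`` is a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta`` or a
    plain dict of strings).  Windows that would run past a chromosome end
    are dropped with a logged warning.
    """
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in fasta:
            raise KeyError(f"unknown chromosome {p.chrom!r}")
        chrom_seq = fasta[p.chrom]
        lo, hi = p.summit - flank, p.summit + flank
        if lo < 0 or hi > len(chrom_seq):
            logger.warning("peak %s: window clipped at chromosome end; dropped", p.id)
            continue
        out[p.id] = str(chrom_seq[lo:hi]).upper()
    return out


def peak_sequence(fasta, peak: Peak) -> str:
    """The peak's own breadth [start, end), uppercased."""
    if peak.chrom not in fasta:
        raise KeyError(f"unknown chromosome {peak.chrom!r}")
    return str(fasta[peak.chrom][peak.start:peak.end]).upper()


# ---------------------------------------------------------------------------
# Normalization and profiles
# ---------------------------------------------------------------------------

def normalize_to_10M(count: float, total_mapped_reads: float) -> float:
    """Scale a tag count to a library depth of 10 million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return count * 1e7 / total_mapped_reads


def aggregate_profile(
    events: Iterable[tuple[str, int]],
    n_sites: int,
    bin_width: int = 10,
    flank: int = 1000,
    mode: str = "tags",
) -> AggregateProfile:
    """Aggregate (site_id, offset) events into density per site per bp.

    Offsets are relative to the summit and must lie in [-flank, flank).
    ``value[b] = count(events in bin b) / (n_sites * bin_width)``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if (2 * flank) % bin_width != 0:
        raise ValueError("bin_width must divide the window span")
    n_bins = 2 * flank // bin_width
    counts = np.zeros(n_bins)
    for _sid, off in events:
        if not -flank <= off < flank:
            raise ValueError(f"offset {off} outside [-{flank}, {flank})")
        counts[(off + flank) // bin_width] += 1
    centers = np.arange(n_bins) * bin_width - flank + bin_width / 2
    return AggregateProfile(
        bin_centers=centers,
        values=counts / (n_sites * bin_width),
        bin_width=bin_width,
        n_sites=n_sites,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Peak filter chain and differential enrichment
# ---------------------------------------------------------------------------

def poisson_tail(count: float, lam: float) -> float:
    """Upper tail P(X >= count) for X ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    k = int(np.ceil(count))
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def call_peak_filter(
    candidates: Sequence[Peak],
    sample: SampleMeta,
    control: SampleMeta,
    fc_control: float = 4.0,
    fc_local: float = 4.0,
    min_tags: float = 75.0,
    fdr: float = 0.001,
) -> list[Peak]:
    """Peak filter chain: FDR, FC over control, FC over local, tag floor.

    A candidate survives iff all four gates hold: raw tags > ``min_tags``,
    depth-matched fold change over the control library > ``fc_control``,
    fold change over the local background > ``fc_local``, and the
    Benjamini-Hochberg adjusted Poisson upper-tail p-value (with lambda the
    depth-matched control count) < ``fdr``.  Denominators are floored at 1
    tag to keep fold changes finite.
    """
    if not candidates:
        return []
    scale = sample.total_mapped_reads / control.total_mapped_reads
    tags = np.array([p.tag_counts.get(sample.name, 0.0) for p in candidates])
    ctrl = np.array([p.control_count for p in candidates]) * scale
    local = np.array([p.local_background_count for p in candidates])
    pvals = np.array([poisson_tail(t, lam) for t, lam in zip(tags, ctrl)])
    padj = multipletests(pvals, method="fdr_bh")[1]
    keep = (
        (tags > min_tags)
        & (tags / np.maximum(ctrl, 1.0) > fc_control)
        & (tags / np.maximum(local, 1.0) > fc_local)
        & (padj < fdr)
    )
    return [p for p, k in zip(candidates, keep) if k]


def differential_enriched(
    count_a: float,
    count_b: float,
    total_a: float,
    total_b: float,
    fc_threshold: float = 4.0,
    p_threshold: float = 1e-4,
) -> tuple[float, float, bool]:
    """Poisson differential enrichment of a over b.

    Fold change is the ratio of depth-normalized counts with a pseudocount
    of 1 on the denominator; the p-value is the Poisson upper tail
    P(X >= count_a) with lambda = count_b scaled to library a's depth.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    a_norm = normalize_to_10M(count_a, total_a)
    b_norm = normalize_to_10M(count_b, total_b)
    fc = a_norm / (b_norm + 1.0)
    lam = count_b * total_a / total_b
    p = poisson_tail(count_a, lam)
    return fc, p, bool(fc > fc_threshold and p < p_threshold)


def assign_clusters(
    peaks: Sequence[Peak],
    called: Mapping[str, set[str]],
    diff_wt_over_dim: Mapping[str, bool],
) -> dict[str, str]:
    """Assign union peaks to occupancy clusters C1-C4.

    C4: called in all three receptors.  C3: called in GRdim only.  Among
    the remaining peaks called in GRwt: C1 if GRwt is significantly more
    enriched than GRdim (``diff_wt_over_dim``), else C2.  Peaks called in
    no receptor (or in GRmon alone) are excluded with a warning.
    """
    labels: dict[str, str] = {}
    for p in peaks:
        in_wt = p.id in called.get("GRwt", set())
        in_dim = p.id in called.get("GRdim", set())
        in_mon = p.id in called.get("GRmon", set())
        if in_wt and in_dim and in_mon:
            labels[p.id] = "C4"
        elif in_dim and not in_wt and not in_mon:
            labels[p.id] = "C3"
        elif in_wt:
            labels[p.id] = "C1" if diff_wt_over_dim.get(p.id, False) else "C2"
        elif in_dim:
            # dim + mon without wt: still a GRdim-bound, GRwt-absent site
            labels[p.id] = "C3"
        else:
            logger.warning("peak %s called in no receptor (or GRmon only); excluded",
                           p.id)
    return labels


# ---------------------------------------------------------------------------
# Background sampling, distances, gene association, annotation
# ---------------------------------------------------------------------------

def sample_random_sites(
    accessible: Sequence[tuple[str, int, int]],
    n: int = 2000,
    width: int = 200,
    seed: int | np.random.Generator = 0,
) -> list[Peak]:
    """Sample ``n`` accessible intervals without replacement.

    Each selected interval is re-centered and resized to ``width``;
    deterministic under the seed.
    """
    if n > len(accessible):
        raise ValueError(f"pool of {len(accessible)} smaller than n={n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.choice(len(accessible), size=n, replace=False)
    out = []
    for j, i in enumerate(idx):
        chrom, s, e = accessible[int(i)]
        mid = (s + e) // 2
        start = max(0, mid - width // 2)
        out.append(
            Peak(
                chrom=chrom,
                start=start,
                end=start + width,
                summit=mid if start <= mid < start + width else start,
                id=f"random_{j}",
            )
        )
    return out


def _interval_gap(a_start, a_end, b_start, b_end) -> int:
    if a_start < b_end and b_start < a_end:
        return 0
    if a_end <= b_start:
        return b_start - a_end
    return a_start - b_end


def nearest_distance(
    peaks: Sequence[Peak],
    features: Sequence[tuple[str, int, int]],
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Edge-to-edge distance from each peak to its nearest feature.

    Overlapping intervals have distance 0.  Returns the per-peak distance
    vector, the median, and an empirical CDF table.
    """
    if not features:
        raise ValueError("feature set is empty")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in features:
        by_chrom.setdefault(chrom, []).append((s, e))
    index: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, iv in by_chrom.items():
        iv.sort()
        starts = [s for s, _ in iv]
        prefix_maxend = np.maximum.accumulate([e for _, e in iv])
        index[chrom] = (starts, prefix_maxend)

    dists = np.empty(len(peaks), dtype=float)
    for i, p in enumerate(peaks):
        if p.chrom not in index:
            dists[i] = np.inf
            continue
        starts, prefix_maxend = index[p.chrom]
        # features with start < p.end are the only overlap/left candidates;
        # the first feature with start >= p.end is the right candidate
        j = bisect_left(starts, p.end)
        best = np.inf
        if j > 0:
            left_end = prefix_maxend[j - 1]
            best = 0 if left_end > p.start else p.start - left_end
        if j < len(starts):
            best = min(best, starts[j] - p.end)
        dists[i] = best
    order = np.sort(dists)
    cdf = pd.DataFrame(
        {"distance": order, "cdf": np.arange(1, len(order) + 1) / len(order)}
    )
    return dists, float(np.median(dists)), cdf


def nearest_gene_lfc(
    peaks: Sequence[Peak], gene_table: pd.DataFrame
) -> pd.DataFrame:
    """Associate each peak with the nearest TSS and that gene's log2 FC.

    ``gene_table`` needs columns ``gene``, ``chrom``, ``tss``, ``lfc``.
    Ties on |summit - TSS| break to the smaller TSS coordinate, then to
    the lexicographically smaller gene id.
    """
    if gene_table.empty:
        raise ValueError("gene table is empty")
    gt = gene_table.sort_values(["chrom", "tss", "gene"]).reset_index(drop=True)
    rows = []
    for p in peaks:
        sub = gt[gt["chrom"] == p.chrom]
        if sub.empty:
            sub = gt
        d = (sub["tss"] - p.summit).abs()
        best = sub.assign(_d=d).sort_values(["_d", "tss", "gene"]).iloc[0]
        rows.append(
            {
                "peak_id": p.id,
                "gene": best["gene"],
                "tss": int(best["tss"]),
                "distance": int(abs(best["tss"] - p.summit)),
                "lfc": float(best["lfc"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Transcript:
    """Minimal transcript model: span, strand and exon structure."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]


def read_gene_model(gtf_path) -> list[Transcript]:
    """Load transcripts with exon structure from a GTF file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    transcripts: list[Transcript] = []
    for t in db.features_of_type("transcript"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
        )
        transcripts.append(
            Transcript(
                id=t.id,
                chrom=t.seqid,
                start=t.start - 1,  # GTF is 1-based closed
                end=t.end,
                strand=t.strand,
                exons=exons,
            )
        )
    return transcripts


def annotate_region(
    peaks: Sequence[Peak],
    transcripts: Sequence[Transcript],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
) -> dict[str, str]:
    """Classify each peak summit as promoter, misc, intron or intergenic.

    Precedence: promoter (strand-aware window around the TSS) > misc
    (within an exon, covering UTR/exon/ncRNA content) > intron (within a
    transcript span but not an exon) > intergenic.
    """
    out: dict[str, str] = {}
    for p in peaks:
        label = "intergenic"
        in_exon = in_body = in_promoter = False
        for t in transcripts:
            if t.chrom != p.chrom:
                continue
            if t.strand == "-":
                lo, hi = t.end - promoter_downstream, t.end + promoter_upstream
            else:
                lo, hi = t.start - promoter_upstream, t.start + promoter_downstream
            if lo <= p.summit < hi:
                in_promoter = True
                break
            if t.start <= p.summit < t.end:
                in_body = True
                if any(s <= p.summit < e for s, e in t.exons):
                    in_exon = True
        if in_promoter:
            label = "promoter"
        elif in_exon:
            label = "misc"
        elif in_body:
            label = "intron"
        out[p.id] = label
    return out
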