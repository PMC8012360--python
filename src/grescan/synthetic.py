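"""Seedable synthetic data with machine-readable planted ground truth.

Generates the inputs the GRE-classification and RUV analyses expect,
with a truth table for every random choice:

* random genomes of configurable GC content;
* peak windows carrying planted motif configurations - a full GRE
  (PWM-sampled above the detection threshold), a half-GRE, overlapping
  or independent full+half combinations, degenerate-consensus-only
  sites, and motif-free windows;
* per-sample negative-binomial tag counts following the receptor
  occupancy templates of clusters C1-C4 (C1 GRwt-specific, C2 shared by
  GRwt/GRdim, C3 GRdim-specific, C4 shared by all three);
* accessible-region pools for background sampling;
* genes x samples NB count matrices with planted treatment effects and
  two planted orthogonal unwanted factors.

Planted windows are *verified*: the background flank is rejection-
sampled to contain no hit of any provided motif, and the assembled
window is re-scanned so that its noise-free classification equals the
intended class by construction.  Half-site insertions use the half-PWM
consensus; full-site insertions are sampled from the PWM and rejected
until they reach the detection threshold, so every planted site is
re-detectable by the scanner at mutation rate zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as _cls
from .motifs import PWM, ConsensusMotif, MotifHit, dedupe_hits, scan_consensus, scan_window
from .peaks import Peak

BASES = "ACGT"

PLANTED_CLASSES = ("full_only", "half_only", "both", "none", "degenerate_only")

_RETRY_CAP = 2000


class RejectionError(RuntimeError):
    """Rejection sampling exceeded its retry cap."""


# ---------------------------------------------------------------------------
# Synthetic motif set
# ---------------------------------------------------------------------------

def _pwm_from_consensus(
    consensus: str, p_major: float, name: str, threshold: float
) -> PWM:
    """PWM with probability ``p_major`` at each defined consensus base and
    uniform columns at N positions."""
    rows = []
    for c in consensus.upper():
        if c == "N":
            rows.append([0.25] * 4)
        else:
            row = [(1.0 - p_major) / 3.0] * 4
            row[BASES.index(c)] = p_major
            rows.append(row)
    return PWM(name=name, matrix=np.array(rows), threshold=threshold,
               consensus=consensus.upper())


def default_motif_set() -> dict:
    """Synthetic GRE motif models (not the published matrices).

    A stand-in set constructed from the canonical GRE architecture
    AGAACAnnnTGTTCT: a sharp well-defined full GRE, a relaxed degenerate
    full GRE, and an 8-bp half-site AGAACAnn whose ACA core sits at
    positions 3-5.  Thresholds tolerate roughly two mismatches for the
    full models (via the degenerate backup) and one for the half-site.
    """
    return {
        "full_well": _pwm_from_consensus(
            "AGAACANNNTGTTCT", 0.90, "GRE_full_synthetic", 8.0
        ),
        "full_degen": _pwm_from_consensus(
            "AGAACANNNTGTTCT", 0.65, "GRE_degen_synthetic", 4.6
        ),
        "half": _pwm_from_consensus("AGAACANN", 0.90, "GRE_half_synthetic", 4.3),
        "half_core": _cls.DEFAULT_HALF_CORE,
        "rescue": _cls.rescue_motifs("results_acannntnt"),
    }


# ---------------------------------------------------------------------------
# Spec and truth containers
# ---------------------------------------------------------------------------

#: Fig. 4c-flavoured class mix per occupancy cluster (fractions) and the
#: rescued share of half-only sites, used by :func:`default_site_plan`.
DEFAULT_CLUSTER_COMPOSITION: dict[str, dict[str, float]] = {
    "C1": {"full_only": 0.70, "both": 0.285, "half_only": 0.011, "none": 0.004},
    "C2": {"full_only": 0.471, "both": 0.291, "half_only": 0.230, "none": 0.008},
    "C3": {"full_only": 0.250, "both": 0.097, "half_only": 0.451, "none": 0.202},
    "C4": {"full_only": 0.240, "both": 0.100, "half_only": 0.340, "none": 0.320},
}
DEFAULT_RESCUED_SHARE = {"C1": 0.3, "C2": 0.3, "C3": 0.40, "C4": 0.35}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic ChIP-seq experiment."""

    genome_length: int = 400_000
    gc_fraction: float = 0.42
    n_sites_per_class: dict[str, dict[str, int]] = field(default_factory=dict)
    peak_width: int = 200
    spacing: int = 300
    motif_mutation_rate: float = 0.0
    overlap_fraction: float = 0.3
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for frac in (self.gc_fraction, self.motif_mutation_rate, self.overlap_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not self.n_sites_per_class:
            self.n_sites_per_class = default_site_plan(50)
        n_sites = sum(
            c for per in self.n_sites_per_class.values() for c in per.values()
        )
        if self.genome_length < n_sites * (self.peak_width + self.spacing) + self.spacing:
            raise ValueError("genome too short for requested sites and spacing")


def default_site_plan(n_per_cluster: int) -> dict[str, dict[str, int]]:
    """Integer per-cluster class counts from the default composition."""
    plan: dict[str, dict[str, int]] = {}
    for cluster, comp in DEFAULT_CLUSTER_COMPOSITION.items():
        counts = {cls: int(round(f * n_per_cluster)) for cls, f in comp.items()}
        # keep cluster sizes exact after rounding
        drift = n_per_cluster - sum(counts.values())
        counts["full_only"] += drift
        h = counts.pop("half_only")
        r = int(round(h * DEFAULT_RESCUED_SHARE[cluster]))
        counts["half_only"] = h - r
        counts["degenerate_only"] = r
        plan[cluster] = counts
    return plan


@dataclass
class CountTruth:
    """Generative parameters behind one synthetic count matrix."""

    beta: np.ndarray  # per-gene treatment log-fold effect
    control_flag: np.ndarray  # True where beta == 0
    W_true: np.ndarray  # samples x 2, orthonormal columns
    alpha: np.ndarray  # genes x 2 loadings
    dispersion: float
    size_factor_true: np.ndarray
    condition: np.ndarray  # 0/1 per sample

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if np.any(np.abs(self.beta[self.control_flag]) > 0):
            raise ValueError("control genes must have beta == 0")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def gen_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> str:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction."""
    rng = rng or np.random.default_rng(spec.seed)
    return _random_bases(rng, spec.genome_length, spec.gc_fraction)


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def sample_pwm_instance(
    pwm: PWM,
    rng: np.random.Generator,
    min_score: float | None = None,
    retry_cap: int = _RETRY_CAP,
) -> str:
    """Sample a sequence from the PWM, rejected until score >= min_score
    (the detection threshold by default)."""
    floor = pwm.threshold if min_score is None else min_score
    lom = np.log(pwm.matrix / 0.25)
    for _ in range(retry_cap):
        idx = np.array(
            [rng.choice(4, p=pwm.matrix[i]) for i in range(pwm.width)]
        )
        score = lom[np.arange(pwm.width), idx].sum()
        if score >= floor:
            return "".join(BASES[i] for i in idx)
    raise RejectionError(f"no instance of {pwm.name} reached score {floor}")


def _consensus_instance(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.integers(4)] if c == "N" else c for c in motif.pattern
    )


def _window_class(seq: str, motifs: Mapping) -> tuple[str, bool, bool]:
    """(class, corrected, rescued) of a raw window under the noise-free
    classification chain - the generator's own acceptance check."""
    full = dedupe_hits(
        scan_window(seq, motifs["full_well"]) + scan_window(seq, motifs["full_degen"])
    )
    half = scan_window(seq, motifs["half"])
    prof = _cls.SiteMotifProfile(
        site_id="_", full_hits=full, half_hits=half,
        search_start=0, search_end=len(seq), sequence=seq,
    )
    sc = _cls.correct_overlap(
        prof, _cls.classify_site(prof), core_positions=motifs["half_core"]
    )
    rescued = sc.value == "half_only" and _cls.rescue_site(seq, motifs["rescue"])
    return sc.value, sc.corrected, rescued


def _clean_flank(
    rng: np.random.Generator, n: int, gc: float, motifs: Mapping,
    retry_cap: int = _RETRY_CAP,
) -> str:
    """Random sequence with no hit of any provided motif on either strand."""
    for _ in range(retry_cap):
        seq = _random_bases(rng, n, gc)
        if scan_window(seq, motifs["full_well"]):
            continue
        if scan_window(seq, motifs["full_degen"]):
            continue
        if scan_window(seq, motifs["half"]):
            continue
        if any(scan_consensus(seq, m) for m in motifs["rescue"]):
            continue
        return seq
    raise RejectionError("could not sample a motif-free window")


def _insert(window: str, pos: int, insert: str) -> str:
    return window[:pos] + insert + window[pos + len(insert):]


def _build_window(
    rng: np.random.Generator,
    planted_class: str,
    spec: SyntheticSpec,
    motifs: Mapping,
    overlap: bool,
) -> tuple[str, list[tuple[str, int, str]], tuple[str, bool, bool]]:
    """One verified peak window.

    Returns (sequence, planted motif coords, realized noise-free
    (class, corrected, rescued)).  Coords are (motif_name, start, strand)
    relative to the window.
    """
    width = spec.peak_width
    full_w = motifs["full_well"].width
    half_w = motifs["half"].width
    if width < full_w + half_w + 30:
        raise ValueError("peak window too small for the motif set")
    want_class = {
        "full_only": "full_only",
        "half_only": "half_only",
        "degenerate_only": "half_only",
        "both": "full_only" if overlap else "both",
        "none": "none",
    }[planted_class]
    want_rescued = planted_class == "degenerate_only"
    # corrected is the point of the overlap construction and must be False
    # for an independent half; a planted full's own arm hits make it a
    # don't-care for full_only (class 'both' already excludes corrected)
    want_corrected = True if (planted_class == "both" and overlap) else None

    def half_instance() -> str:
        return "".join(
            BASES[rng.integers(4)] if c == "N" else c
            for c in motifs["half"].consensus
        )

    for _ in range(_RETRY_CAP):
        seq = _clean_flank(rng, width, spec.gc_fraction, motifs)
        coords: list[tuple[str, int, str]] = []
        if planted_class == "full_only":
            pos = int(rng.integers(2, width - full_w - 2))
            ins = sample_pwm_instance(motifs["full_well"], rng)
            seq = _insert(seq, pos, ins)
            coords = [(motifs["full_well"].name, pos, "+")]
        elif planted_class in ("half_only", "degenerate_only"):
            pos = int(rng.integers(2, width // 2 - half_w))
            seq = _insert(seq, pos, half_instance())
            coords = [(motifs["half"].name, pos, "+")]
            if planted_class == "degenerate_only":
                m = motifs["rescue"][int(rng.integers(len(motifs["rescue"])))]
                dpos = int(rng.integers(width // 2 + 4, width - m.width - 2))
                seq = _insert(seq, dpos, _consensus_instance(m, rng))
                coords.append((m.name, dpos, "+"))
        elif planted_class == "both":
            fpos = int(rng.integers(2, width // 2 - full_w - 12))
            ins = sample_pwm_instance(motifs["full_well"], rng)
            seq = _insert(seq, fpos, ins)
            coords = [(motifs["full_well"].name, fpos, "+")]
            if overlap:
                # the half-site is the full GRE's own left arm: its ACA
                # core coincides with the left hexamer
                coords.append((motifs["half"].name, fpos, "+"))
            else:
                hpos = int(rng.integers(width // 2 + 12, width - half_w - 2))
                seq = _insert(seq, hpos, half_instance())
                coords.append((motifs["half"].name, hpos, "+"))
        # 'none': leave the clean window as is
        got_class, got_corr, got_resc = _window_class(seq, motifs)
        if (
            got_class == want_class
            and got_resc == want_rescued
            and (want_corrected is None or got_corr == want_corrected)
        ):
            return seq, coords, (got_class, got_corr, got_resc)
    raise RejectionError(
        f"could not construct a verified {planted_class} window"
    )


def _mutate_coords(
    rng: np.random.Generator,
    seq: str,
    coords: Sequence[tuple[str, int, str]],
    widths: Mapping[str, int],
    rate: float,
) -> str:
    """Per-base substitution at ``rate`` restricted to planted motif bases."""
    if rate <= 0 or not coords:
        return seq
    chars = list(seq)
    for name, pos, _strand in coords:
        for i in range(pos, pos + widths[name]):
            if rng.random() < rate:
                chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


def plant_sites(
    genome: str,
    spec: SyntheticSpec,
    motifs: Mapping | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peak], pd.DataFrame, str]:
    """Plant verified motif configurations into a genome.

    Returns the peak list, a truth table (one row per site: planted class,
    cluster template, expected post-correction class and flags, planted
    motif coordinates) and the edited genome.
    """
    motifs = motifs or default_motif_set()
    rng = rng or np.random.default_rng(spec.seed + 1)
    widths = {
        motifs["full_well"].name: motifs["full_well"].width,
        motifs["half"].name: motifs["half"].width,
    }
    for m in motifs["rescue"]:
        widths[m.name] = m.width
    plan = [
        (cluster, cls)
        for cluster, per in spec.n_sites_per_class.items()
        for cls, count in per.items()
        for _ in range(count)
    ]
    step = spec.peak_width + spec.spacing
    chars = list(genome)
    peaks: list[Peak] = []
    truth_rows = []
    for i, (cluster, planted_class) in enumerate(plan):
        start = spec.spacing + i * step
        end = start + spec.peak_width
        overlap = planted_class == "both" and rng.random() < spec.overlap_fraction
        seq, coords, realized = _build_window(rng, planted_class, spec, motifs, overlap)
        expected_class, expected_corrected, expected_rescued = realized
        seq = _mutate_coords(rng, seq, coords, widths, spec.motif_mutation_rate)
        chars[start:end] = list(seq)
        sid = f"site_{i:05d}"
        peaks.append(
            Peak(
                chrom=spec.chrom,
                start=start,
                end=end,
                summit=(start + end) // 2,
                id=sid,
            )
        )
        truth_rows.append(
            {
                "site_id": sid,
                "planted_class": planted_class,
                "cluster_template": cluster,
                "expected_class": expected_class,
                "expected_corrected": expected_corrected,
                "expected_rescued": expected_rescued,
                "motif_coords": ";".join(
                    f"{n}:{start + p}:{s}" for n, p, s in coords
                ),
            }
        )
    return peaks, pd.DataFrame(truth_rows), "".join(chars)


# ---------------------------------------------------------------------------
# Tag counts
# ---------------------------------------------------------------------------

#: receptor occupancy templates: mean tags per peak at 10M library depth
DEFAULT_CLUSTER_MEANS: dict[str, dict[str, float]] = {
    "C1": {"GRwt": 400.0, "GRdim": 15.0, "GRmon": 5.0},
    "C2": {"GRwt": 300.0, "GRdim": 300.0, "GRmon": 5.0},
    "C3": {"GRwt": 5.0, "GRdim": 300.0, "GRmon": 5.0},
    "C4": {"GRwt": 300.0, "GRdim": 300.0, "GRmon": 250.0},
}
DEFAULT_CONTROL_MEAN = 5.0
DEFAULT_LOCAL_BG_MEAN = 12.0


def _nb(
    rng: np.random.Generator, mean: float, dispersion: float, size=None
) -> np.ndarray:
    """NB draw with Var = mu + dispersion * mu^2; Poisson limit at 0."""
    if mean < 0:
        raise ValueError("negative mean")
    if dispersion < 1e-12:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def gen_tag_counts(
    peaks: Sequence[Peak],
    cluster_of: Mapping[str, str],
    library_totals: Mapping[str, int] | None = None,
    templates: Mapping[str, Mapping[str, float]] | None = None,
    dispersion: float = 0.1,
    seed: int | np.random.Generator = 0,
    control_mean: float = DEFAULT_CONTROL_MEAN,
    local_bg_mean: float = DEFAULT_LOCAL_BG_MEAN,
) -> None:
    """Fill per-sample NB tag counts (and control/local background) in place.

    Template means are expressed at a 10M-read depth and scaled by each
    library's total.
    """
    templates = templates or DEFAULT_CLUSTER_MEANS
    library_totals = library_totals or {
        "GRwt": 10_000_000, "GRdim": 10_000_000, "GRmon": 10_000_000
    }
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for p in peaks:
        tmpl = templates[cluster_of[p.id]]
        for sample, total in library_totals.items():
            mean = tmpl.get(sample, 0.0) * total / 1e7
            p.tag_counts[sample] = float(_nb(rng, mean, dispersion))
        p.control_count = float(rng.poisson(control_mean))
        p.local_background_count = float(rng.poisson(local_bg_mean))


# ---------------------------------------------------------------------------
# Accessible regions
# ---------------------------------------------------------------------------

def gen_accessible_bed(
    genome_length: int,
    peaks: Sequence[Peak],
    n_extra: int,
    width: int = 300,
    seed: int | np.random.Generator = 0,
    chrom: str = "chrS",
) -> list[tuple[str, int, int]]:
    """Merged peak intervals plus random non-overlapping intervals.

    Returned sorted and pairwise disjoint.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged: list[list[int]] = []
    for p in sorted(peaks, key=lambda q: (q.chrom, q.start)):
        if merged and p.start <= merged[-1][1] and p.chrom == chrom:
            merged[-1][1] = max(merged[-1][1], p.end)
        else:
            merged.append([p.start, p.end])
    intervals = [(chrom, s, e) for s, e in merged]
    taken = sorted(merged)
    placed = 0
    for _ in range(_RETRY_CAP * max(1, n_extra)):
        if placed == n_extra:
            break
        s = int(rng.integers(0, genome_length - width))
        e = s + width
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append([s, e])
        taken.sort()
        intervals.append((chrom, s, e))
        placed += 1
    if placed < n_extra:
        raise RejectionError("could not place accessible intervals without overlap")
    return sorted(intervals, key=lambda t: t[1])


def write_bed(intervals: Sequence[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split()[:3]
            out.append((chrom, int(s), int(e)))
    return out


# ---------------------------------------------------------------------------
# RNA-seq count matrices
# ---------------------------------------------------------------------------

def _default_design(n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """(condition, W_true) with W columns orthonormal and orthogonal to
    both the intercept and the condition contrast."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    half = n_samples // 2
    condition = np.array([0] * (half // 2) + [1] * (half - half // 2))
    condition = np.concatenate([condition, condition])[:n_samples]
    w1 = np.concatenate([np.ones(half), -np.ones(n_samples - half)])
    w2 = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_samples)])
    # Gram-Schmidt against intercept, condition and each other
    basis = [np.ones(n_samples), condition.astype(float)]
    W = []
    for w in (w1, w2):
        v = w.astype(float)
        for b in basis + W:
            v = v - (v @ b) / (b @ b) * b
        if np.linalg.norm(v) < 1e-9:
            raise ValueError("degenerate default design")
        W.append(v / np.linalg.norm(v))
    return condition, np.column_stack(W)


def gen_count_matrix(
    n_genes: int = 2000,
    n_samples: int = 12,
    seed: int | np.random.Generator = 0,
    frac_de: float = 0.1,
    beta_sd: float = 1.0,
    alpha_sd: float | tuple[float, float] = (0.9, 0.5),
    dispersion: float = 0.1,
    size_factor_sd: float = 0.15,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
    condition: np.ndarray | None = None,
    W_true: np.ndarray | None = None,
) -> tuple[pd.DataFrame, CountTruth]:
    """NB count matrix with planted treatment and unwanted variation.

    mu_gj = s_j * q_g * exp(x_j * beta_g + (W alpha^T)_jg), counts
    NB(mu, dispersion).  A ``frac_de`` share of genes carries a treatment
    effect beta ~ N(0, beta_sd^2); the rest (beta = 0) are flagged as
    empirical controls.  Two orthonormal unwanted factors load on all
    genes with alpha ~ N(0, alpha_sd^2); the default per-factor scales
    are distinct so the factors occupy separated singular-value ranks and
    are individually identifiable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if condition is None or W_true is None:
        d_cond, d_W = _default_design(n_samples)
        condition = d_cond if condition is None else np.asarray(condition)
        W_true = d_W if W_true is None else np.asarray(W_true)
    condition = np.asarray(condition)
    W_true = np.asarray(W_true, dtype=float)
    if condition.size != n_samples or W_true.shape != (n_samples, 2):
        raise ValueError("inconsistent sample-design dimensions")

    q = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    beta = np.zeros(n_genes)
    de = rng.random(n_genes) < frac_de
    beta[de] = rng.normal(0.0, beta_sd, size=int(de.sum()))
    alpha_scales = np.broadcast_to(np.asarray(alpha_sd, dtype=float), (2,))
    alpha = rng.normal(0.0, 1.0, size=(n_genes, 2)) * alpha_scales
    if np.all(alpha_scales == 0):
        alpha = np.zeros((n_genes, 2))
    s = np.exp(rng.normal(0.0, size_factor_sd, size=n_samples))
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1

    log_mu = (
        np.log(q)[:, None]
        + beta[:, None] * condition[None, :]
        + alpha @ W_true.T
        + np.log(s)[None, :]
    )
    mu = np.exp(log_mu)
    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    samples = [
        f"s{j:02d}_{'Dex' if condition[j] else 'NT'}" for j in range(n_samples)
    ]
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                          columns=samples)
    truth = CountTruth(
        beta=beta,
        control_flag=~de,
        W_true=W_true,
        alpha=alpha,
        dispersion=dispersion,
        size_factor_true=s,
        condition=condition,
    )
    return matrix, truth
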