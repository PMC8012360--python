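"""Position weight matrices, consensus motifs and two-strand scanning.

The scanner models a transcription-factor binding motif as a position
weight matrix (PWM) of per-position base probabilities, scored against a
sequence window by the natural-log likelihood ratio versus a uniform
0.25 background:

    score(kmer) = sum_i ln( p_i(kmer[i]) / 0.25 )

A hit is an offset (on either strand) whose score reaches the motif's
detection threshold.  Degenerate motifs with ``N`` wildcards are matched
exactly rather than scored.  Motif matrices are read from and written to
the HOMER-style text dialect: a ``>`` header carrying consensus, name and
log-odds threshold, followed by one row of four tab-separated
probabilities (A, C, G, T) per position.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: index used for any character outside A/C/G/T
_INVALID = 4

_ENCODE_TABLE = np.full(256, _INVALID, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

PSEUDOCOUNT = 1e-3
_COLUMN_TOL = 1e-3


class MotifParseError(ValueError):
    """Raised for malformed motif-matrix files."""


class InvalidWindowError(ValueError):
    """Raised when a k-mer handed to :func:`log_odds` contains non-ACGT bases."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int codes 0..3 (A,C,G,T); other characters -> 4."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Probability matrix over A/C/G/T with a log-odds detection threshold."""

    name: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    threshold: float
    consensus: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be (width, 4)")
        if np.any(m <= 0):
            raise ValueError(f"PWM {self.name!r}: probabilities must be positive")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1")
        if not math.isfinite(self.threshold):
            raise ValueError(f"PWM {self.name!r}: threshold must be finite")
        object.__setattr__(self, "matrix", m)
        if not self.consensus:
            object.__setattr__(
                self, "consensus", "".join(BASES[i] for i in m.argmax(axis=1))
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds_matrix(self) -> np.ndarray:
        """(width, 5) natural-log odds vs uniform background; column 4 = -inf."""
        lom = np.log(self.matrix / 0.25)
        return np.hstack([lom, np.full((self.width, 1), -np.inf)])

    def consensus_score(self) -> float:
        return float(np.log(self.matrix.max(axis=1) / 0.25).sum())


@dataclass(frozen=True)
class ConsensusMotif:
    """Exact-match degenerate motif over {A,C,G,T,N}; N matches any base.

    ``core_positions`` marks the indices of the ACA/TGT trinucleotide core
    used by the half-site overlap-correction logic.
    """

    name: str
    pattern: str
    core_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("consensus pattern must be non-empty")
        if not set(pat) <= set("ACGTN"):
            raise ValueError(
                f"consensus motif {self.name!r}: pattern characters must be A/C/G/T/N"
            )
        for i in self.core_positions:
            if not 0 <= i < len(pat):
                raise ValueError("core position outside pattern")
            if pat[i] == "N":
                raise ValueError("core positions must be non-N")
        object.__setattr__(self, "pattern", pat)

    @property
    def width(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in forward-window coordinates."""

    start: int
    strand: str  # "+" or "-"
    motif_name: str
    width: int
    score: float | None = None
    site_id: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def log_odds(pwm: PWM, kmer: str) -> float:
    """Natural-log odds of ``kmer`` under ``pwm`` versus uniform background."""
    if len(kmer) != pwm.width:
        raise ValueError(
            f"kmer length {len(kmer)} does not match PWM width {pwm.width}"
        )
    codes = encode(kmer)
    if np.any(codes == _INVALID):
        raise InvalidWindowError(f"non-ACGT base in kmer {kmer!r}")
    lom = pwm.log_odds_matrix
    return float(lom[np.arange(pwm.width), codes].sum())


def _strand_scores(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset scores on (+, -) strands; windows with non-ACGT get -inf."""
    W = pwm.width
    n = codes.size - W + 1
    if n <= 0:
        empty = np.empty(0)
        return empty, empty
    lom = pwm.log_odds_matrix
    # minus-strand score of window i equals scoring forward codes with the
    # reverse-complemented matrix: lom_rc[j, b] = lom[W-1-j, 3-b]
    lom_rc = np.empty_like(lom)
    lom_rc[:, :4] = lom[::-1, :4][:, ::-1]
    lom_rc[:, 4] = -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    idx = np.arange(W)
    plus = lom[idx, windows].sum(axis=1)
    minus = lom_rc[idx, windows].sum(axis=1)
    return plus, minus


def scan_window(
    seq: str, pwm: PWM, threshold: float | None = None, site_id: str | None = None
) -> list[MotifHit]:
    """All offsets on both strands scoring >= the detection threshold.

    Minus-strand hits are scored on the reverse complement but reported at
    their forward-window offset.  Windows containing non-ACGT characters
    are skipped.  Overlapping hits are all retained.
    """
    T = pwm.threshold if threshold is None else threshold
    codes = encode(seq)
    plus, minus = _strand_scores(codes, pwm)
    hits: list[MotifHit] = []
    for strand, scores in (("+", plus), ("-", minus)):
        for i in np.flatnonzero(scores >= T):
            hits.append(
                MotifHit(
                    start=int(i),
                    strand=strand,
                    motif_name=pwm.name,
                    width=pwm.width,
                    score=float(scores[i]),
                    site_id=site_id,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def best_score(seq: str, pwm: PWM) -> float:
    """Maximal log-odds over all valid offsets and strands; -inf if none."""
    codes = encode(seq)
    plus, minus = _strand_scores(codes, pwm)
    if plus.size == 0:
        return float("-inf")
    m = max(plus.max(), minus.max())
    return float(m)


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    return re.compile("(?=(" + pattern.replace("N", ".") + "))")


def scan_consensus(
    seq: str, motif: ConsensusMotif, site_id: str | None = None
) -> list[MotifHit]:
    """Exact matches of a degenerate consensus on both strands.

    A minus-strand hit is a forward-sequence match of the pattern's
    reverse complement, reported at its forward offset.
    """
    s = seq.upper()
    hits: list[MotifHit] = []
    for strand, pat in (
        ("+", motif.pattern),
        ("-", reverse_complement(motif.pattern)),
    ):
        for m in _pattern_regex(pat).finditer(s):
            hits.append(
                MotifHit(
                    start=m.start(),
                    strand=strand,
                    motif_name=motif.name,
                    width=motif.width,
                    site_id=site_id,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Motif-matrix file I/O (HOMER-style dialect)
# ---------------------------------------------------------------------------

def read_motif_file(path) -> list[PWM]:
    """Read PWMs from a HOMER-dialect motif file.

    Each record is ``>CONSENSUS<TAB>NAME<TAB>THRESHOLD`` followed by one
    row of four tab-separated base probabilities per motif position.
    Columns whose sum is off unity by at most 1e-3 are renormalized with a
    logged warning; rows containing zeros get a pseudocount of 1e-3 before
    renormalization.
    """
    pwms: list[PWM] = []
    header: tuple[str, str, float] | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        consensus, name, thr = header
        if not rows:
            raise MotifParseError(
                f"line {header_line}: motif {name!r} has no matrix rows"
            )
        m = np.array(rows, dtype=float)
        if np.any(m < 0):
            raise MotifParseError(f"motif {name!r}: negative probability")
        sums = m.sum(axis=1)
        off = np.abs(sums - 1.0)
        bad = off > _COLUMN_TOL
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise MotifParseError(
                f"line {header_line + 1 + i}: motif {name!r} row sums to "
                f"{sums[i]:.6f}, off by more than {_COLUMN_TOL}"
            )
        if np.any(off > 1e-6):
            logger.warning("motif %s: rows off unity by <=%g; renormalized",
                           name, _COLUMN_TOL)
            m = m / m.sum(axis=1, keepdims=True)
        if np.any(m == 0):
            m = m + PSEUDOCOUNT
            m = m / m.sum(axis=1, keepdims=True)
            logger.warning(
                "motif %s: zero cells; added pseudocount %g and renormalized",
                name,
                PSEUDOCOUNT,
            )
        pwms.append(PWM(name=name, matrix=m, threshold=thr, consensus=consensus))
        header, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                if len(parts) < 3:
                    raise MotifParseError(
                        f"line {lineno}: header needs consensus, name, threshold"
                    )
                try:
                    thr = float(parts[2])
                except ValueError as exc:
                    raise MotifParseError(
                        f"line {lineno}: non-numeric threshold {parts[2]!r}"
                    ) from exc
                header = (parts[0], parts[1], thr)
                header_line = lineno
            else:
                if header is None:
                    raise MotifParseError(f"line {lineno}: matrix row before header")
                fields = line.split()
                if len(fields) != 4:
                    raise MotifParseError(
                        f"line {lineno}: expected 4 probabilities, got {len(fields)}"
                    )
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise MotifParseError(
                        f"line {lineno}: non-numeric cell in matrix row"
                    ) from exc
    flush()
    return pwms


def write_motif_file(pwms: Iterable[PWM], path) -> None:
    """Write PWMs in the same dialect :func:`read_motif_file` parses."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.consensus}\t{pwm.name}\t{pwm.threshold:.6g}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{p:.9f}" for p in row) + "\n")


def dedupe_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Collapse hits sharing (start, end, strand), keeping the best score."""
    best: dict[tuple[int, int, str], MotifHit] = {}
    for h in hits:
        key = (h.start, h.end, h.strand)
        prev = best.get(key)
        if prev is None or (h.score or 0.0) > (prev.score or 0.0):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.start, h.strand))
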