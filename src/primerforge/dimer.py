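"""Rule-based hairpin, self-dimer and pair-dimer detection.

Extension by the polymerase is nucleated at the primer's 3' end, so the
scoring window is the 3'-terminal tail of the primer (user-definable length,
default 12 bases).  The tail is slid, ungapped and antiparallel, along the
partner sequence at every offset; at each offset Watson-Crick complementary
positions score ``weight_gc`` per G:C and ``weight_at`` per A:T, and the
maximum over offsets (capped at ``max_score``) is reported.  Scoring a 3'
window rather than the whole primer is what keeps the method meaningful for
long (up to ~100-base) primers as well as conventional ones.

N pairs with nothing and contributes 0.  Gapped alignment and
thermodynamic (free-energy) evaluation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqcore import SequenceError, validate_bases

_PAIRS_GC = {("G", "C"), ("C", "G")}
_PAIRS_AT = {("A", "T"), ("T", "A")}

# Base encoding for the vectorised scorer: A,C,G,T -> 0..3, N -> 4.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(s: str) -> np.ndarray:
    return _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DimerParams:
    """Weights and window for 3'-tail complementarity scoring."""

    tail_length: int = 12
    weight_gc: float = 2.0
    weight_at: float = 1.0
    max_score: float | None = None  # default 2 * tail_length
    hairpin_min_loop: int = 3
    threshold: float | None = None  # default 0.55 * cap

    def __post_init__(self) -> None:
        if self.tail_length < 1:
            raise ValueError("tail_length must be >= 1")
        if self.weight_gc <= 0 or self.weight_at <= 0:
            raise ValueError("weights must be positive")
        if self.cap < self.weight_gc:
            raise ValueError("max_score must be >= weight_gc")
        if self.rejection_threshold > self.cap:
            raise ValueError("threshold must be <= max_score")

    @property
    def cap(self) -> float:
        return self.max_score if self.max_score is not None else 2.0 * self.tail_length

    @property
    def rejection_threshold(self) -> float:
        return self.threshold if self.threshold is not None else 0.55 * self.cap


@dataclass(frozen=True)
class DimerResult:
    """Best tail alignment found: score, its offset, and pair count."""

    score: float
    offset: int
    matched_pairs: int
    status: str = "ok"


def _weight_matrix(p: DimerParams) -> np.ndarray:
    w = np.zeros((5, 5))
    w[0, 3] = w[3, 0] = p.weight_at  # A:T
    w[1, 2] = w[2, 1] = p.weight_gc  # C:G
    return w


def _best_tail_alignment(tail: str, other_3to5: str, p: DimerParams) -> DimerResult:
    """Slide *tail* (5'->3') along *other_3to5* (the partner read 3'->5')
    at every offset allowing partial overlap; return the best scoring one."""
    t = _encode(tail)
    o = _encode(other_3to5)
    nt = len(t)
    pad = np.full(nt - 1, 4, dtype=np.uint8)  # N sentinel: pairs with nothing
    padded = np.concatenate([pad, o, pad])
    windows = sliding_window_view(padded, nt)
    w = _weight_matrix(p)
    per_pos = w[t[None, :], windows]
    scores = per_pos.sum(axis=1)
    i = int(np.argmax(scores))  # first maximum = lowest offset, as scanned
    best = float(scores[i])
    if best == 0.0:
        return DimerResult(0.0, 0, 0)
    pairs = int((per_pos[i] > 0).sum())
    return DimerResult(min(best, p.cap), i - (nt - 1), pairs)


def _one_way_pair_score(a: str, b: str, p: DimerParams) -> DimerResult:
    tail = a[-p.tail_length :]
    return _best_tail_alignment(tail, b[::-1], p)


def pair_dimer_score(a: str, b: str, p: DimerParams | None = None) -> DimerResult:
    """Dimerisation potential between two different primers.

    Scores a's 3' tail against b and b's 3' tail against a (both
    antiparallel, every ungapped offset) and reports the larger.
    """
    p = p or DimerParams()
    a = validate_bases(a)
    b = validate_bases(b)
    if not a or not b:
        raise SequenceError("pair_dimer_score requires two non-empty primers")
    r1 = _one_way_pair_score(a, b, p)
    r2 = _one_way_pair_score(b, a, p)
    return r1 if r1.score >= r2.score else r2


def self_dimer_score(a: str, p: DimerParams | None = None) -> DimerResult:
    """Dimerisation potential between two copies of the same primer."""
    p = p or DimerParams()
    a = validate_bases(a)
    if not a:
        raise SequenceError("self_dimer_score requires a non-empty primer")
    return _one_way_pair_score(a, a, p)


def hairpin_score(a: str, p: DimerParams | None = None) -> DimerResult:
    """Intramolecular fold potential: the 3' tail pairing back onto the
    primer's own upstream sequence across a loop of at least
    ``hairpin_min_loop`` unpaired bases.

    A sequence too short to fold returns score 0 with status "too short"
    rather than raising.
    """
    p = p or DimerParams()
    a = validate_bases(a)
    if not a:
        raise SequenceError("hairpin_score requires a non-empty primer")
    n = len(a)
    if n < p.tail_length + p.hairpin_min_loop + 1:
        return DimerResult(0.0, 0, 0, status="too short")
    tail_start = n - p.tail_length
    # Antiparallel stem: tail position q pairs with upstream position j
    # where q + j = c for a fold "diagonal" c; loop size is q - j - 1.
    e = _encode(a)
    w = _weight_matrix(p)
    q = np.arange(tail_start, n)
    j = np.arange(n)
    m = w[e[q][:, None], e[j][None, :]]
    m *= j[None, :] <= q[:, None] - p.hairpin_min_loop - 1
    diag = (q[:, None] + j[None, :]).ravel()
    scores = np.bincount(diag, weights=m.ravel(), minlength=2 * n - 1)
    c = int(np.argmax(scores))
    best = float(scores[c])
    if best == 0.0:
        return DimerResult(0.0, 0, 0)
    pairs = np.bincount(diag, weights=(m > 0).ravel(), minlength=2 * n - 1)
    return DimerResult(min(best, p.cap), c, int(pairs[c]))
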