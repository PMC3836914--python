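"""Microsatellite (SSR) detection and flanking-primer design.

The repeat finder is a Sputnik-style scanner: at every read position and
for every unit length (2, 3 or 4 by default) it extends a candidate repeat
by comparing each base to the base one unit upstream, scoring +1 per match
and -6 per mismatch, and reports maximal non-overlapping repeats whose
total length and score pass the mode thresholds.  Strict mode (total
length >= 21) drives marker discovery; relaxed mode (total length >= 12)
is re-used recursively during primer design to reject primers and flanks
that themselves contain weaker repeats.

Flanking-primer design enforces, for each returned pair:

1. primer length 20-30 bases;
2. product length 80-300 bases, spanning the repeat;
3. no Ns anywhere in the product;
4. forward and reverse GC content equal within a tolerance, with Tm scored
   against a configured preferred annealing temperature;
5. neither primer contains the repeat unit as >= 2 tandem copies
   (a single dinucleotide occurrence is unavoidable and allowed);
6. neither primer nor the flank between primer and repeat contains a
   relaxed-mode microsatellite;
7. each primer has exactly one binding site within the read.

Absence of a feasible pair is a legitimate outcome and returns None.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from . import binding, candidates, selection, thermo
from .candidates import GenerationSpec, PairCandidate, PrimerCandidate
from .dimer import DimerParams
from .seqcore import Sequence, reverse_complement


@dataclass(frozen=True)
class Microsatellite:
    read_id: str
    start: int
    end: int  # half-open
    unit: str
    unit_count: int
    total_length: int
    score: int


@dataclass(frozen=True)
class SsrParams:
    """Repeat-finder thresholds.

    min_score defaults (when None) to ``min_total_length - unit_length``,
    the score of a perfect repeat of exactly the minimum length; longer
    repeats can then absorb a small number of mismatches.
    """

    mode: str = "strict"
    unit_lengths: tuple[int, ...] = (2, 3, 4)
    min_total_length: int = 21
    match_score: int = 1
    mismatch_penalty: int = -6
    min_score: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ValueError("mode must be 'strict' or 'relaxed'")
        object.__setattr__(self, "unit_lengths", tuple(sorted(self.unit_lengths)))

    @classmethod
    def strict(cls) -> "SsrParams":
        return cls(mode="strict", min_total_length=21)

    @classmethod
    def relaxed(cls) -> "SsrParams":
        return cls(mode="relaxed", min_total_length=12)

    def score_floor(self, unit_length: int) -> int:
        if self.min_score is not None:
            return self.min_score
        return self.min_total_length - unit_length


def _has_smaller_period(unit: str) -> bool:
    """True if the unit is itself a repetition of a shorter unit (e.g. 'AA',
    'ACAC'); such units are found at their fundamental period instead."""
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return True
    return False


def find_microsatellites(read: Sequence, p: SsrParams | None = None) -> list[Microsatellite]:
    """Scan every position and unit length; extend Sputnik-style; report
    maximal non-overlapping repeats meeting the mode thresholds.

    Deterministic: candidates are taken left to right; at equal start the
    longer and higher-scoring extent wins, then the shorter unit.
    """
    p = p or SsrParams.strict()
    seq = read.bases
    n = len(seq)
    found: list[Microsatellite] = []
    for u in p.unit_lengths:
        for i in range(n - 2 * u + 1):
            unit = seq[i : i + u]
            if "N" in unit or _has_smaller_period(unit):
                continue
            # A repeat must open with two clean units; mismatch tolerance
            # applies only to the subsequent extension.
            if seq[i + u : i + 2 * u] != unit:
                continue
            # Skip starts that merely continue a run already startable one
            # base to the left, so each run is reported once, maximally.
            if i >= 1 and seq[i - 1] == seq[i - 1 + u]:
                prev_unit = seq[i - 1 : i - 1 + u]
                if "N" not in prev_unit and not _has_smaller_period(prev_unit):
                    continue
            score = 0
            best_score = -1
            best_j = i + u - 1
            j = i + u
            while j < n:
                if seq[j] != "N" and seq[j] == seq[j - u]:
                    score += p.match_score
                else:
                    score += p.mismatch_penalty
                if score > best_score:
                    best_score = score
                    best_j = j
                if score < best_score + 3 * p.mismatch_penalty:
                    break
                j += 1
            total = best_j + 1 - i
            if total >= p.min_total_length and best_score >= p.score_floor(u):
                found.append(
                    Microsatellite(
                        read_id=read.id,
                        start=i,
                        end=best_j + 1,
                        unit=unit,
                        unit_count=total // u,
                        total_length=total,
                        score=best_score,
                    )
                )
    found.sort(key=lambda m: (m.start, -m.total_length, -m.score, len(m.unit)))
    accepted: list[Microsatellite] = []
    cursor = 0
    for m in found:
        if m.start >= cursor:
            accepted.append(m)
            cursor = m.end
    return accepted


def contains_microsatellite(bases: str, p: SsrParams) -> bool:
    if len(bases) < p.min_total_length:
        return False
    return bool(find_microsatellites(Sequence(id="_q", bases=bases), p))


def _contains_tandem_unit(bases: str, unit: str) -> bool:
    """>= 2 tandem copies of the repeat unit (or its reverse complement)."""
    return (unit * 2) in bases or reverse_complement(unit * 2) in bases


@dataclass(frozen=True)
class SsrDesignConfig:
    """Tunables for flanking-primer design around one microsatellite."""

    length_min: int = 20
    length_max: int = 30
    product_min: int = 80
    product_max: int = 300
    preferred_tm: float = 60.0
    gc_tolerance: float = 0.05
    tm_params: thermo.TmParams = field(default_factory=thermo.TmParams)
    dimer_params: DimerParams = field(default_factory=DimerParams)
    match_params: binding.MatchParams = field(default_factory=binding.MatchParams)
    relaxed: SsrParams = field(default_factory=SsrParams.relaxed)
    shortlist: int = 40  # top-N singles per side taken into pairing


def _single_ok_cheap(c: PrimerCandidate, ms: Microsatellite, cfg: SsrDesignConfig) -> bool:
    if _contains_tandem_unit(c.bases, ms.unit):
        return False
    return not contains_microsatellite(c.bases, cfg.relaxed)


def _flank_clean(read: Sequence, lo: int, hi: int, cfg: SsrDesignConfig) -> bool:
    if hi <= lo:
        return True
    return not contains_microsatellite(read.bases[lo:hi], cfg.relaxed)


_SINGLE_RANK = selection.SelectionSpec(
    characteristics=(
        selection.Characteristic("self_dimer", priority=1),
        selection.Characteristic("hairpin", priority=2),
        selection.Characteristic("tm", priority=3),
        selection.Characteristic("gc", priority=4),
    ),
    method="prioritised",
)

_PAIR_RANK = selection.SelectionSpec(
    characteristics=(
        selection.Characteristic("pair_dimer", priority=1, weight=1.0),
        selection.Characteristic("tm", priority=2, weight=1.0),
        selection.Characteristic("gc_difference", priority=3, weight=1.0),
        selection.Characteristic("tm_difference", priority=4, weight=1.0),
        selection.Characteristic("self_dimer", priority=5, weight=1.0),
        selection.Characteristic("hairpin", priority=6, weight=1.0),
    ),
    method="prioritised",
)


def _shortlist(
    cands: list[PrimerCandidate], read: Sequence, ms: Microsatellite, cfg: SsrDesignConfig
) -> list[PrimerCandidate]:
    """Filter, evaluate and rank one side's candidates; keep the top
    ``cfg.shortlist`` of them.

    The sequence-content constraints (repeat unit, relaxed-mode repeats)
    are cheap and run on every candidate; the within-read uniqueness scan
    runs in ranked order and stops once the shortlist is full.
    """
    ok = [c for c in cands if _single_ok_cheap(c, ms, cfg)]
    evaluated = [
        candidates.evaluate_candidate(
            c, read, tm_params=cfg.tm_params, dimer_params=cfg.dimer_params,
            match_params=cfg.match_params, count_binding=False,
        )
        for c in ok
    ]
    pens = [
        candidates.candidate_penalties(c, preferred_tm=cfg.preferred_tm)
        for c in evaluated
    ]
    order = selection.sort_candidates(pens, _SINGLE_RANK)
    idx = {id(p): i for i, p in enumerate(pens)}
    ranked = [evaluated[idx[id(r.item)]] for r in order]
    # Spread the shortlist across position bins so the product-length
    # bounds can always be met: the best singles alone may all cluster at
    # one end of the window.
    bin_size = 50
    bins = {c.start // bin_size for c in ranked}
    quota = max(3, -(-cfg.shortlist // max(1, len(bins))))
    shortlisted: list[PrimerCandidate] = []
    taken: dict[int, int] = {}
    unique_cache: dict[str, bool] = {}

    def unique_in_read(c: PrimerCandidate) -> bool:
        if c.bases not in unique_cache:
            unique_cache[c.bases] = (
                binding.count_binding_sites(c.bases, read, cfg.match_params) == 1
            )
        return unique_cache[c.bases]

    for pass_quota in (quota, None):  # second pass tops up ignoring quotas
        for c in ranked:
            if len(shortlisted) >= cfg.shortlist:
                return shortlisted
            b = c.start // bin_size
            if pass_quota is not None and taken.get(b, 0) >= pass_quota:
                continue
            if any(s.start == c.start and s.bases == c.bases for s in shortlisted):
                continue
            if unique_in_read(c):
                shortlisted.append(replace(c, binding_count=1))
                taken[b] = taken.get(b, 0) + 1
    return shortlisted


def design_flanking_primers(
    read: Sequence, ms: Microsatellite, cfg: SsrDesignConfig | None = None
) -> Optional[PairCandidate]:
    """Best primer pair flanking *ms* under the seven design constraints,
    or None when no feasible pair exists."""
    cfg = cfg or SsrDesignConfig()
    n = len(read)
    fwd_window_start = max(0, ms.end - cfg.product_max)
    rev_window_end = min(n, ms.start + cfg.product_max)
    if ms.start - fwd_window_start < cfg.length_min:
        return None
    if rev_window_end - ms.end < cfg.length_min:
        return None

    fwd_spec = GenerationSpec(
        window_start=fwd_window_start, window_end=ms.start,
        length_min=cfg.length_min, length_max=cfg.length_max,
    )
    rev_spec = GenerationSpec(
        window_start=ms.end, window_end=rev_window_end,
        length_min=cfg.length_min, length_max=cfg.length_max,
    )
    forwards = _shortlist(candidates.generate_candidates(read, fwd_spec, "+"), read, ms, cfg)
    reverses = _shortlist(candidates.generate_candidates(read, rev_spec, "-"), read, ms, cfg)
    if not forwards or not reverses:
        return None

    pairs = candidates.make_pairs(
        forwards, reverses, read, cfg.product_min, cfg.product_max, cfg.dimer_params
    )
    feasible = []
    for p in pairs:
        product = read.bases[p.forward.start : p.reverse.end]
        if "N" in product:
            continue
        if p.gc_difference > cfg.gc_tolerance + 1e-12:
            continue
        if not _flank_clean(read, p.forward.end, ms.start, cfg):
            continue
        if not _flank_clean(read, ms.end, p.reverse.start, cfg):
            continue
        feasible.append(p)
    if not feasible:
        return None
    pens = [candidates.pair_penalties(p, preferred_tm=cfg.preferred_tm) for p in feasible]
    order = selection.sort_candidates(pens, _PAIR_RANK)
    idx = {id(pe): i for i, pe in enumerate(pens)}
    return feasible[idx[id(order[0].item)]]
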