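"""Primer candidate generation, evaluation and pairing.

Candidates are enumerated exhaustively within a template window (every
start, every length in range) and hard sequence filters (no N, no C / no G
designs, excluded motifs) are applied up front.  Evaluation then fills the
characteristics that selection ranks on: GC fraction, Tm under the chosen
method, hairpin and self-dimer scores, and binding-site counts against the
template and optional background sequences.

Long chimaeric primers (segments concatenated from different sources, up
to 120 bases) flow through exactly the same evaluation code paths as
conventional 18-30-mers; there is no separate long-primer scorer.

Pairing is the exhaustive Cartesian product of evaluated forward and
reverse candidates filtered by product-length bounds; "similar length and
GC content" is expressed as soft penalty characteristics
(length_difference, gc_difference, tm_difference) for selection rather
than as hard cutoffs, which compensates for the reduced reliability of Tm
estimates on long primers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from . import binding, dimer, thermo
from .dimer import DimerParams, DimerResult
from .seqcore import Sequence, SequenceError, reverse_complement

MAX_PRIMER_LENGTH = 120


@dataclass(frozen=True)
class PrimerCandidate:
    """One oligo plus its computed characteristics.

    ``start`` is the 0-based plus-strand template coordinate of the
    template slice the primer derives from.  For a minus-strand (reverse)
    primer, ``bases`` is the reverse complement of that slice.  Chimaeric
    primers have start = -1 (not a template slice).
    """

    bases: str
    start: int
    strand: str = "+"
    gc: float | None = None
    tm: float | None = None
    hairpin: DimerResult | None = None
    self_dimer: DimerResult | None = None
    binding_count: int | None = None
    products_count: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.bases) <= MAX_PRIMER_LENGTH:
            raise SequenceError(
                f"primer length {len(self.bases)} outside 1..{MAX_PRIMER_LENGTH}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """Half-open plus-strand end coordinate of the source slice."""
        return self.start + len(self.bases)


@dataclass(frozen=True)
class PairCandidate:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    pair_dimer: DimerResult
    product_length: int
    tm_difference: float
    gc_difference: float
    length_difference: int
    products_count: int | None = None  # amplicons on the template, filled on demand

    def __post_init__(self) -> None:
        if self.product_length <= 0:
            raise ValueError("product_length must be positive")


@dataclass(frozen=True)
class GenerationSpec:
    """Window, length range and hard sequence filters for enumeration."""

    window_start: int
    window_end: int
    length_min: int = 18
    length_max: int = 27
    length_optimum: int | None = None
    gc_min: float = 0.0
    gc_max: float = 1.0
    forbid_c: bool = False
    forbid_g: bool = False
    forbid_n: bool = True
    excluded_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.window_start < 0 or self.window_end < self.window_start:
            raise ValueError("invalid window")
        if not 1 <= self.length_min <= self.length_max <= MAX_PRIMER_LENGTH:
            raise ValueError("invalid length range")
        opt = self.length_optimum
        if opt is not None and not self.length_min <= opt <= self.length_max:
            raise ValueError("length_optimum outside [length_min, length_max]")
        object.__setattr__(self, "excluded_motifs", tuple(self.excluded_motifs))


def _passes_filters(bases: str, spec: GenerationSpec) -> bool:
    if spec.forbid_n and "N" in bases:
        return False
    if spec.forbid_c and "C" in bases:
        return False
    if spec.forbid_g and "G" in bases:
        return False
    gc = (bases.count("G") + bases.count("C")) / len(bases)
    if not spec.gc_min <= gc <= spec.gc_max:
        return False
    return not any(m in bases for m in spec.excluded_motifs)


def generate_candidates(
    template: Sequence, spec: GenerationSpec, strand: str = "+"
) -> list[PrimerCandidate]:
    """Enumerate every substring fully inside the window with length in
    [length_min, length_max], passing the hard filters, in deterministic
    (start, length) order.

    For ``strand='-'`` the returned bases are the reverse complement of the
    template slice (a reverse primer annealing at that locus); filters are
    applied to the primer bases as synthesised.
    """
    if spec.window_end > len(template):
        raise ValueError("window extends beyond template")
    out: list[PrimerCandidate] = []
    for start in range(spec.window_start, spec.window_end):
        for length in range(spec.length_min, spec.length_max + 1):
            end = start + length
            if end > spec.window_end:
                break
            slice_ = template.bases[start:end]
            bases = slice_ if strand == "+" else reverse_complement(slice_)
            if _passes_filters(bases, spec):
                out.append(PrimerCandidate(bases=bases, start=start, strand=strand))
    return out


def evaluate_candidate(
    c: PrimerCandidate,
    template: Sequence,
    background: Optional[Iterable[Sequence]] = None,
    tm_params: thermo.TmParams | None = None,
    dimer_params: DimerParams | None = None,
    match_params: binding.MatchParams | None = None,
    count_binding: bool = True,
) -> PrimerCandidate:
    """Fill gc, tm, hairpin and self-dimer scores, and (optionally) the
    binding-site count against the template plus any background sequences.
    Idempotent: re-evaluating returns an identical record."""
    tm_params = tm_params or thermo.TmParams()
    dimer_params = dimer_params or DimerParams()
    gc = (c.bases.count("G") + c.bases.count("C")) / len(c.bases)
    try:
        tm = thermo.melting_temperature(c.bases, tm_params)
    except thermo.ThermoError as exc:
        raise thermo.ThermoError(
            f"candidate at {c.start} ({c.bases[:12]}...): {exc}"
        ) from exc
    hp = dimer.hairpin_score(c.bases, dimer_params)
    sd = dimer.self_dimer_score(c.bases, dimer_params)
    bc = None
    if count_binding:
        bc = binding.count_binding_sites(c.bases, template, match_params)
        for bg in background or ():
            bc += binding.count_binding_sites(c.bases, bg, match_params)
    return replace(c, gc=gc, tm=tm, hairpin=hp, self_dimer=sd, binding_count=bc)


def make_pairs(
    forwards: Iterable[PrimerCandidate],
    reverses: Iterable[PrimerCandidate],
    template: Sequence,
    product_min: int,
    product_max: int,
    dimer_params: DimerParams | None = None,
) -> list[PairCandidate]:
    """Cartesian pairing filtered to product_min <= length <= product_max.

    Product length is reverse.end - forward.start on the plus strand; the
    reverse candidate must lie downstream of the forward one.
    """
    dimer_params = dimer_params or DimerParams()
    pairs: list[PairCandidate] = []
    for f in forwards:
        for r in reverses:
            product_length = r.end - f.start
            if r.start < f.end or not product_min <= product_length <= product_max:
                continue
            pd = dimer.pair_dimer_score(f.bases, r.bases, dimer_params)
            pairs.append(
                PairCandidate(
                    forward=f,
                    reverse=r,
                    pair_dimer=pd,
                    product_length=product_length,
                    tm_difference=abs((f.tm or 0.0) - (r.tm or 0.0)),
                    gc_difference=abs((f.gc or 0.0) - (r.gc or 0.0)),
                    length_difference=abs(f.length - r.length),
                )
            )
    return pairs


def concatenate_chimaeric(head: str, tail: str) -> PrimerCandidate:
    """Join two segments into one long chimaeric primer.

    The result is an ordinary :class:`PrimerCandidate` (start = -1) and is
    evaluable by every dimer/thermo/binding operation without special-casing.
    """
    bases = head + tail
    if len(bases) > MAX_PRIMER_LENGTH:
        raise SequenceError(
            f"chimaeric primer of {len(bases)} bases exceeds the "
            f"{MAX_PRIMER_LENGTH}-base limit"
        )
    if not bases:
        raise SequenceError("chimaeric primer is empty")
    return PrimerCandidate(bases=bases, start=-1)


def candidate_penalties(
    c: PrimerCandidate,
    preferred_tm: float = 60.0,
    preferred_gc: float = 0.5,
    length_optimum: int | None = None,
) -> dict[str, float]:
    """Normalise a single candidate's characteristics to penalties
    (0 = ideal) for the selection module."""
    pen = {
        "tm": abs((c.tm or 0.0) - preferred_tm),
        "gc": abs((c.gc or 0.0) - preferred_gc),
        "hairpin": c.hairpin.score if c.hairpin else 0.0,
        "self_dimer": c.self_dimer.score if c.self_dimer else 0.0,
        "binding": max(0, (c.binding_count or 1) - 1),
    }
    if length_optimum is not None:
        pen["length"] = abs(c.length - length_optimum)
    return pen


def pair_penalties(
    p: PairCandidate,
    preferred_tm: float = 60.0,
    preferred_gc: float = 0.5,
    length_optimum: int | None = None,
) -> dict[str, float]:
    """Penalty dict for a candidate pair: the worse of the two primers on
    each single-primer characteristic, plus the pair-level ones."""
    fp = candidate_penalties(p.forward, preferred_tm, preferred_gc, length_optimum)
    rp = candidate_penalties(p.reverse, preferred_tm, preferred_gc, length_optimum)
    pen = {k: max(fp[k], rp[k]) for k in fp}
    pen["binding"] = fp["binding"] + rp["binding"]
    pen["pair_dimer"] = p.pair_dimer.score
    pen["tm_difference"] = p.tm_difference
    pen["gc_difference"] = p.gc_difference
    pen["length_difference"] = float(p.length_difference)
    if p.products_count is not None:
        pen["products"] = max(0, p.products_count - 1)
    return pen
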