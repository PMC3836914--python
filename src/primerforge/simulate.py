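"""Seeded synthetic templates and reads with known ground truth.

Test inputs for the whole toolkit are generated, never downloaded: random
templates with primer binding sites planted at known positions (exact
copies, clustered-mismatch copies, or copies with evenly spaced mismatches
— the pattern heuristic aligners are most prone to miss), and 454-style
~500-base reads carrying a centred microsatellite with clean or
deliberately contaminated flanks.

Each generator returns the sequence together with a manifest recording the
exact expected outcome (binding sites, repeat span, design feasibility),
and verifies by exhaustive scan that the random background contains no
accidental matches — redrawing the background when it does — so manifests
are the single source of expected values in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import binding
from .binding import BindingSite, MatchParams
from .seqcore import Sequence, reverse_complement
from .ssr import SsrParams, find_microsatellites

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised when a requested fixture cannot be constructed."""


@dataclass(frozen=True)
class Plant:
    """One primer copy to embed in a template.

    spacing is 'clustered' (mismatches in a run near the middle) or 'even'
    (mismatches spread uniformly along the primer).
    """

    sequence: str
    position: int
    strand: str = "+"
    mismatches: int = 0
    spacing: str = "even"


@dataclass(frozen=True)
class TemplateManifest:
    seed: int
    length: int
    sites: tuple[BindingSite, ...]  # expected sites per planted primer copy


def _mutate(seq: str, k: int, spacing: str) -> str:
    """Introduce k substitutions, never touching position parity of the
    original base (each mutated base cycles A->C->G->T->A)."""
    if k == 0:
        return seq
    n = len(seq)
    if k > n:
        raise SimulationError("more mismatches than bases")
    if spacing == "even":
        idx = [round((i + 0.5) * n / k - 0.5) for i in range(k)]
        idx = sorted(set(min(n - 1, max(0, i)) for i in idx))
        while len(idx) < k:  # collisions on very short primers
            idx.append(next(j for j in range(n) if j not in idx))
    elif spacing == "clustered":
        lo = max(0, n // 2 - k // 2)
        idx = list(range(lo, lo + k))
    else:
        raise SimulationError(f"unknown spacing {spacing!r}")
    order = "ACGT"
    out = list(seq)
    for i in idx:
        out[i] = order[(order.index(out[i]) + 1) % 4]
    return "".join(out)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_template(
    length: int,
    seed: int,
    plants: list[Plant] | tuple[Plant, ...] = (),
    template_id: str = "synthetic_template",
    verify_params: MatchParams | None = None,
    max_redraws: int = 20,
) -> tuple[Sequence, TemplateManifest]:
    """Uniform-random template with each plant inserted at its position.

    The background is verified (exhaustive scan with ``verify_params``,
    default pure-Hamming with each plant's own mismatch budget) to contain
    no binding sites beyond the planted ones, redrawing the background up
    to ``max_redraws`` times; so the manifest's site list is exact.
    """
    plants = tuple(plants)
    spans = sorted((p.position, p.position + len(p.sequence)) for p in plants)
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if c < b:
            raise SimulationError("planted sites overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > length):
        raise SimulationError("plant outside template")

    plant_sites: list[tuple[Plant, BindingSite]] = []
    inserts = {}
    for p in plants:
        site_seq = _mutate(p.sequence, p.mismatches, p.spacing)
        if p.strand == "-":
            site_seq = reverse_complement(site_seq)
        inserts[p.position] = site_seq
        plant_sites.append(
            (
                p,
                BindingSite(
                    template_id=template_id,
                    start=p.position,
                    end=p.position + len(p.sequence),
                    strand=p.strand,
                    mismatches=p.mismatches,
                ),
            )
        )
    expected = sorted((s for _, s in plant_sites), key=lambda s: (s.start, s.strand))

    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        bases = list(_random_bases(rng, length))
        for pos, site_seq in inserts.items():
            bases[pos : pos + len(site_seq)] = site_seq
        seq = Sequence(id=template_id, bases="".join(bases))
        if _background_clean(seq, plant_sites, verify_params):
            return seq, TemplateManifest(seed=seed, length=length, sites=tuple(expected))
    raise SimulationError("could not draw a background free of accidental matches")


def _background_clean(
    seq: Sequence,
    plant_sites: list[tuple[Plant, BindingSite]],
    verify_params: MatchParams | None,
) -> bool:
    """Exhaustive-scan check: each planted primer matches the template at
    exactly its planted sites under its own mismatch budget."""
    for p, _ in plant_sites:
        params = verify_params or MatchParams(
            max_mismatches=p.mismatches, three_prime_exact=0
        )
        budget = params.resolve_max_mismatches(len(p.sequence))
        found = [
            s
            for s in binding.find_binding_sites(p.sequence, seq, params)
            if s.mismatches <= budget
        ]
        wanted = sorted(
            (
                s
                for q, s in plant_sites
                if q.sequence == p.sequence and q.mismatches <= budget
            ),
            key=lambda s: (s.start, s.strand),
        )
        if found != wanted:
            return False
    return True


@dataclass(frozen=True)
class SsrReadManifest:
    seed: int
    repeat_start: int
    repeat_end: int
    unit: str
    unit_count: int
    n_run: Optional[tuple[int, int]]  # (start, length) of an inserted N run
    flank_repeat: Optional[tuple[str, int, str]]  # (unit, count, side)
    feasible: bool  # clean flanks on both sides => flanking design expected


def make_ssr_read(
    unit: str,
    unit_count: int,
    seed: int,
    length: int = 500,
    read_id: str = "synthetic_read",
    n_run: Optional[tuple[int, int]] = None,
    flank_repeat: Optional[tuple[str, int, str]] = None,
    max_redraws: int = 50,
) -> tuple[Sequence, SsrReadManifest]:
    """A ~500-base read with a centred (unit x unit_count) microsatellite.

    Contaminants: ``n_run=(offset, run_len)`` inserts a run of Ns starting
    *offset* bases downstream of the repeat; ``flank_repeat=(unit, count,
    side)`` embeds a relaxed-mode repeat in the 'upstream' or 'downstream'
    flank.  Flanks are otherwise verified free of relaxed-mode repeats, and
    boundary bases are constrained so the planted run cannot extend.
    """
    repeat = unit * unit_count
    total = len(repeat)
    if total + 2 * 40 > length:
        raise SimulationError("repeat too long for the requested read length")
    start = (length - total) // 2
    end = start + total

    rng = np.random.default_rng(seed)
    relaxed = SsrParams.relaxed()
    for _ in range(max_redraws):
        bases = list(_random_bases(rng, length))
        bases[start:end] = repeat
        # Boundary constraint: the run must not extend into the flanks.
        if start > 0 and bases[start - 1] == unit[-1]:
            bases[start - 1] = _other_base(rng, unit[-1])
        if end < length and bases[end] == unit[0]:
            bases[end] = _other_base(rng, unit[0])
        if flank_repeat is not None:
            fr_unit, fr_count, side = flank_repeat
            block = fr_unit * fr_count
            if side == "upstream":
                pos = max(0, start - len(block) - 30)
            else:
                pos = min(length - len(block), end + 30)
            bases[pos : pos + len(block)] = block
        if n_run is not None:
            off, run_len = n_run
            pos = end + off
            if pos + run_len > length:
                raise SimulationError("N run outside read")
            bases[pos : pos + run_len] = "N" * run_len
        seq = Sequence(id=read_id, bases="".join(bases))
        found = [(m.start, m.end, m.unit) for m in find_microsatellites(seq, SsrParams.strict())]
        if flank_repeat is None:
            if found != [(start, end, unit)]:
                continue
        elif (start, end, unit) not in found:
            continue
        flanks_clean = _flanks_relaxed_clean(seq, start, end, relaxed)
        if flank_repeat is None and not flanks_clean:
            continue  # accidental relaxed repeat in a flank: redraw
        manifest = SsrReadManifest(
            seed=seed,
            repeat_start=start,
            repeat_end=end,
            unit=unit,
            unit_count=unit_count,
            n_run=None if n_run is None else (end + n_run[0], n_run[1]),
            flank_repeat=flank_repeat,
            feasible=(flank_repeat is None and n_run is None),
        )
        return seq, manifest
    raise SimulationError("could not draw clean flanks for the SSR read")


def _other_base(rng: np.random.Generator, not_this: str) -> str:
    choices = [b for b in "ACGT" if b != not_this]
    return choices[int(rng.integers(0, 3))]


def _flanks_relaxed_clean(seq: Sequence, start: int, end: int, relaxed: SsrParams) -> bool:
    up = seq.bases[:start]
    down = seq.bases[end:]
    for flank in (up, down):
        if len(flank) >= relaxed.min_total_length and find_microsatellites(
            Sequence(id="_f", bases=flank), relaxed
        ):
            return False
    return True
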