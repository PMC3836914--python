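"""Exhaustive, non-heuristic primer binding-site and PCR-product search.

Heuristic aligners (BLAST-style seeding) can miss short, low-identity
primer binding sites — in particular sites whose mismatches are evenly
spaced, which defeats exact-seed heuristics.  The finder here scans every
offset on both strands, so it is guaranteed to return every site satisfying
the match parameters.  The inner comparison is vectorised with numpy sliding
windows, but there is no seeding or indexing step: the scan is exhaustive
by construction.

Match rule (ungapped): at most ``max_mismatches`` substitutions over the
full primer length, and an exactly matching ``three_prime_exact`` block at
the primer's 3' end (3' fidelity governs polymerase extension).  Setting
``three_prime_exact=0`` gives a pure Hamming criterion.  A template N never
matches anything.

Product enumeration pairs every forward-primer plus-strand site with every
reverse-primer minus-strand site downstream within the extension window
(default 3500 bases, roughly 3.5 min of extension at ~1000 bases/min).
More than one product signals potential secondary amplification; one of the
products is normally the intended target amplicon.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqcore import Sequence, SequenceError, reverse_complement, validate_bases

DEFAULT_MAX_PRODUCT_LENGTH = 3500


@dataclass(frozen=True)
class MatchParams:
    """Mismatch tolerance for binding-site detection.

    max_mismatches defaults to floor(primer_length / 5) when None.
    """

    max_mismatches: int | None = None
    three_prime_exact: int = 5
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches is not None and self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.three_prime_exact < 0:
            raise ValueError("three_prime_exact must be >= 0")

    def resolve_max_mismatches(self, primer_length: int) -> int:
        if self.max_mismatches is None:
            return primer_length // 5
        return self.max_mismatches


@dataclass(frozen=True, order=True)
class BindingSite:
    """One primer/template match in plus-strand, 0-based half-open coords."""

    template_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class PcrProduct:
    """A convergent forward/reverse site pair defining a potential amplicon."""

    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int


class BindingSiteFinder(ABC):
    """Abstract interface any secondary-binding detector must implement.

    The exhaustive scanner below is the native implementation; adapters
    around external alignment tools would implement the same two methods.
    """

    @abstractmethod
    def find_binding_sites(
        self, primer: str, template: Sequence, params: MatchParams
    ) -> list[BindingSite]: ...

    def count_binding_sites(
        self, primer: str, template: Sequence, params: MatchParams
    ) -> int:
        return len(self.find_binding_sites(primer, template, params))


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _scan_mismatch_counts(template: np.ndarray, primer: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every template offset (ungapped).

    Positions where either side is N always count as mismatches.
    """
    windows = sliding_window_view(template, len(primer))
    n_code = ord("N")
    neq = (windows != primer) | (windows == n_code) | (primer == n_code)
    return neq.sum(axis=1)


class ExhaustiveFinder(BindingSiteFinder):
    """Scans every offset on both strands; no heuristics, no seeding."""

    def find_binding_sites(
        self, primer: str, template: Sequence, params: MatchParams | None = None
    ) -> list[BindingSite]:
        params = params or MatchParams()
        primer = validate_bases(primer)
        if not primer:
            raise SequenceError("empty primer")
        m = len(primer)
        if m > len(template):
            return []
        max_mm = params.resolve_max_mismatches(m)
        tpe = min(params.three_prime_exact, m)
        tarr = _encode(template.bases)
        sites: list[BindingSite] = []

        # Plus strand: primer 5'->3' equals template slice; 3' end is the
        # high-coordinate side.
        parr = _encode(primer)
        counts = _scan_mismatch_counts(tarr, parr)
        ok = counts <= max_mm
        if tpe:
            ok &= _tail_clean_block(tarr, parr, tpe, three_prime_side="high")
        for i in np.flatnonzero(ok):
            sites.append(
                BindingSite(template.id, int(i), int(i) + m, "+", int(counts[i]))
            )

        if params.both_strands:
            # Minus strand: the primer anneals to the minus strand, i.e. its
            # reverse complement appears on the plus strand; the primer's 3'
            # end sits at the low-coordinate side of the site.
            rc = _encode(reverse_complement(primer))
            counts_m = _scan_mismatch_counts(tarr, rc)
            ok_m = counts_m <= max_mm
            if tpe:
                ok_m &= _tail_clean_block(tarr, rc, tpe, three_prime_side="low")
            for i in np.flatnonzero(ok_m):
                sites.append(
                    BindingSite(template.id, int(i), int(i) + m, "-", int(counts_m[i]))
                )

        sites.sort(key=lambda s: (s.start, s.strand))
        return sites


def _tail_clean_block(
    tarr: np.ndarray, parr: np.ndarray, tpe: int, three_prime_side: str
) -> np.ndarray:
    """Exact-match requirement for the primer's 3'-terminal block.

    On the plus strand the 3' block is the last *tpe* bases of the oriented
    primer; on the minus strand (primer given already reverse-complemented)
    it is the first *tpe* bases.
    """
    m = len(parr)
    n = len(tarr)
    nwin = n - m + 1
    n_code = ord("N")
    if three_prime_side == "high":
        block = parr[m - tpe :]
        starts_off = m - tpe
    else:
        block = parr[:tpe]
        starts_off = 0
    windows = sliding_window_view(tarr, tpe)
    neq = (windows != block) | (windows == n_code) | (block == n_code)
    clean = neq.sum(axis=1) == 0
    return clean[starts_off : starts_off + nwin]


_DEFAULT_FINDER = ExhaustiveFinder()


def find_binding_sites(
    primer: str, template: Sequence, params: MatchParams | None = None
) -> list[BindingSite]:
    """All template locations (both strands) the primer can anneal to under
    *params*; exhaustive, sorted by start then strand."""
    return _DEFAULT_FINDER.find_binding_sites(primer, template, params)


def count_binding_sites(
    primer: str, template: Sequence, params: MatchParams | None = None
) -> int:
    return len(find_binding_sites(primer, template, params))


def search_for_pcr_products(
    forward: str,
    reverse: str,
    template: Sequence,
    max_product_length: int = DEFAULT_MAX_PRODUCT_LENGTH,
    params: MatchParams | None = None,
    same_primer_products: bool = False,
) -> list[PcrProduct]:
    """Enumerate every potential amplicon on *template*.

    Pairs each forward-primer plus-strand site with each reverse-primer
    minus-strand site lying downstream within ``max_product_length``.  The
    intended target amplicon appears as one of the products; more than one
    product indicates potential secondary amplification.  With
    ``same_primer_products`` enabled, convergent sites of the same primer
    (forward x forward, reverse x reverse) are also paired.
    """
    params = params or MatchParams()
    f_sites = find_binding_sites(forward, template, params)
    r_sites = find_binding_sites(reverse, template, params)
    combos = [
        ([s for s in f_sites if s.strand == "+"], [s for s in r_sites if s.strand == "-"])
    ]
    if same_primer_products:
        combos.append(
            ([s for s in f_sites if s.strand == "+"], [s for s in f_sites if s.strand == "-"])
        )
        combos.append(
            ([s for s in r_sites if s.strand == "+"], [s for s in r_sites if s.strand == "-"])
        )
    products: dict[tuple[BindingSite, BindingSite], PcrProduct] = {}
    for plus_sites, minus_sites in combos:
        for fs in plus_sites:
            for rs in minus_sites:
                length = rs.end - fs.start
                if 0 < length <= max_product_length:
                    products.setdefault((fs, rs), PcrProduct(fs, rs, length))
    return sorted(
        products.values(),
        key=lambda p: (p.forward_site.start, p.reverse_site.end),
    )


def sites_to_rows(sites: list[BindingSite]) -> list[dict]:
    """Flat dict rows (template_id, start, end, strand, mismatches) for CSV."""
    return [
        {
            "template_id": s.template_id,
            "start": s.start,
            "end": s.end,
            "strand": s.strand,
            "mismatches": s.mismatches,
        }
        for s in sites
    ]


def products_to_rows(products: list[PcrProduct]) -> list[dict]:
    return [
        {
            "forward_start": p.forward_site.start,
            "reverse_end": p.reverse_site.end,
            "length": p.product_length,
        }
        for p in products
    ]
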