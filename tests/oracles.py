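"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from first principles — per-offset
character loops, direct hand-summation of published thermodynamic tables —
and shares no code with the package, so agreement between the two routes
is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


# ---------------------------------------------------------------- binding

def naive_binding_sites(
    primer: str,
    template: str,
    max_mismatches: int,
    three_prime_exact: int = 0,
    both_strands: bool = True,
):
    """All-offsets Hamming scan; returns (start, end, strand, mismatches)."""
    m = len(primer)
    out = []

    def matches(window: str, oriented: str, tpe_low: bool):
        mm = sum(
            1
            for a, b in zip(window, oriented)
            if a != b or a == "N" or b == "N"
        )
        if mm > max_mismatches:
            return None
        tpe = min(three_prime_exact, m)
        block = oriented[:tpe] if tpe_low else oriented[m - tpe :]
        wblock = window[:tpe] if tpe_low else window[m - tpe :]
        for a, b in zip(wblock, block):
            if a != b or a == "N" or b == "N":
                return None
        return mm

    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        mm = matches(window, primer, tpe_low=False)
        if mm is not None:
            out.append((i, i + m, "+", mm))
        if both_strands:
            mm = matches(window, rc(primer), tpe_low=True)
            if mm is not None:
                out.append((i, i + m, "-", mm))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


def naive_products(forward_sites, reverse_sites, max_len):
    """Exhaustive convergent pairing of (start,end,strand,mm) tuples."""
    prods = set()
    for f in forward_sites:
        if f[2] != "+":
            continue
        for r in reverse_sites:
            if r[2] != "-":
                continue
            length = r[1] - f[0]
            if 0 < length <= max_len:
                prods.add((f[0], r[1], length))
    return sorted(prods)


# ------------------------------------------------------------------ dimer

def _w(a: str, b: str, wgc: float, wat: float) -> float:
    if {a, b} == {"G", "C"}:
        return wgc
    if {a, b} == {"A", "T"}:
        return wat
    return 0.0


def naive_tail_score(tail: str, other: str, wgc: float, wat: float) -> float:
    """Best ungapped antiparallel alignment score of *tail* (5'->3')
    against *other*, trying every offset."""
    o = other[::-1]  # read the partner 3'->5'
    best = 0.0
    for off in range(-(len(tail) - 1), len(o)):
        s = 0.0
        for i, t in enumerate(tail):
            j = off + i
            if 0 <= j < len(o):
                s += _w(t, o[j], wgc, wat)
        best = max(best, s)
    return best


def naive_pair_dimer(a: str, b: str, tail_len: int, wgc=2.0, wat=1.0, cap=None):
    s = max(
        naive_tail_score(a[-tail_len:], b, wgc, wat),
        naive_tail_score(b[-tail_len:], a, wgc, wat),
    )
    return min(s, cap) if cap is not None else s


def naive_self_dimer(a: str, tail_len: int, wgc=2.0, wat=1.0, cap=None):
    s = naive_tail_score(a[-tail_len:], a, wgc, wat)
    return min(s, cap) if cap is not None else s


def naive_hairpin(a: str, tail_len: int, min_loop: int = 3, wgc=2.0, wat=1.0, cap=None):
    """Enumerate every antiparallel fold of the 3' tail onto the upstream
    sequence with >= min_loop unpaired loop bases."""
    n = len(a)
    if n < tail_len + min_loop + 1:
        return 0.0
    tail_start = n - tail_len
    best = 0.0
    for c in range(2 * n - 1):
        s = 0.0
        for q in range(tail_start, n):
            j = c - q
            if 0 <= j <= q - min_loop - 1:
                s += _w(a[q], a[j], wgc, wat)
        best = max(best, s)
    return min(best, cap) if cap is not None else best


# ----------------------------------------------------------------- thermo
# Independent copies of the published stack tables, transcribed separately
# from the package (dinucleotides on one strand only; the oracle derives
# the rest by reverse complement).

_ORACLE_SL98 = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_ORACLE_BRES86 = {
    "AA": (-9.1, -24.0), "AT": (-8.6, -23.9), "TA": (-6.0, -16.9),
    "CA": (-5.8, -12.9), "GT": (-6.5, -17.3), "CT": (-7.8, -20.8),
    "GA": (-5.6, -13.5), "CG": (-11.9, -27.8), "GC": (-11.1, -26.7),
    "GG": (-11.0, -26.6),
}
_ORACLE_FREIER86 = {
    "AA": (-6.6, -18.4), "AT": (-5.7, -15.5), "TA": (-8.1, -22.6),
    "CA": (-10.5, -27.8), "GT": (-10.2, -26.2), "CT": (-7.6, -19.2),
    "GA": (-13.3, -35.5), "CG": (-8.0, -19.4), "GC": (-14.2, -34.9),
    "GG": (-12.2, -29.7),
}


def _stack_params(table: dict, dinuc: str):
    if dinuc in table:
        return table[dinuc]
    return table[rc(dinuc)]


def oracle_wallace(s: str) -> float:
    return 2.0 * sum(c in "AT" for c in s) + 4.0 * sum(c in "GC" for c in s)


def oracle_nn_tm(
    s: str,
    method: str,
    c_t: float = 5e-8,
    na: float = 0.05,
) -> float:
    """Direct hand-summation of the published dH/dS values plus the
    16.6 log10[Na+] salt term."""
    table = {
        "santalucia_nn": _ORACLE_SL98,
        "breslauer_nn": _ORACLE_BRES86,
        "freier_nn": _ORACLE_FREIER86,
    }[method]
    dh = ds = 0.0
    for i in range(len(s) - 1):
        h, sv = _stack_params(table, s[i : i + 2])
        dh += h
        ds += sv
    selfcomp = s == rc(s)
    if method == "santalucia_nn":
        for end in (s[0], s[-1]):
            h, sv = ((2.3, 4.1) if end in "AT" else (0.1, -2.8))
            dh += h
            ds += sv
        if selfcomp:
            ds += -1.4
    elif method == "breslauer_nn":
        ds += -16.8 if ("G" in s or "C" in s) else -20.1
        if selfcomp:
            ds += -1.3
    else:
        ds += -10.8
        if selfcomp:
            ds += -1.4
    x = 1 if selfcomp else 4
    tm = (dh * 1000.0) / (ds + 1.987 * math.log(c_t / x)) - 273.15
    return tm + 16.6 * math.log10(na)


# ------------------------------------------------------------------- misc

def random_oligo(rng, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
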