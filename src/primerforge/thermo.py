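"""Annealing-temperature estimation behind one abstract contract.

Four interchangeable methods are registered by name:

``wallace``
    The Wallace rule Tm = 2(A+T) + 4(G+C), a length-2..~14 rule of thumb
    that degrades gracefully for longer oligos.
``breslauer_nn``, ``santalucia_nn``, ``freier_nn``
    Nearest-neighbor thermodynamics: Tm = dH / (dS + R ln(C_T/x)) - 273.15
    plus the monovalent-salt correction 16.6 log10([Na+]), with the
    dinucleotide stack dH/dS summed from the named published parameter set
    (Breslauer 1986; the SantaLucia 1998 unified set; Freier 1986) together
    with that set's own initiation and symmetry terms.

``santalucia_nn`` is the default, matching the oligoTm-style calculation
commonly used for PCR primers.  New methods can be added with
:func:`register_method` without touching existing ones.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass

from .seqcore import reverse_complement, validate_bases

#: Gas constant in cal/(mol*K), the unit system of the published tables.
GAS_CONSTANT = 1.987

DEFAULT_METHOD = "santalucia_nn"

# Published dinucleotide stack parameters as (dH kcal/mol, dS cal/(mol*K)),
# keyed by the top-strand dinucleotide read 5'->3'.  Each table carries its
# own duplex-initiation convention, applied in _initiation().

# Breslauer, Marky & Breslauer 1986 set (the original oligoTm table).
BRESLAUER_1986 = {
    "AA": (-9.1, -24.0), "TT": (-9.1, -24.0),
    "AT": (-8.6, -23.9),
    "TA": (-6.0, -16.9),
    "CA": (-5.8, -12.9), "TG": (-5.8, -12.9),
    "GT": (-6.5, -17.3), "AC": (-6.5, -17.3),
    "CT": (-7.8, -20.8), "AG": (-7.8, -20.8),
    "GA": (-5.6, -13.5), "TC": (-5.6, -13.5),
    "CG": (-11.9, -27.8),
    "GC": (-11.1, -26.7),
    "GG": (-11.0, -26.6), "CC": (-11.0, -26.6),
}
# Initiation: dS -16.8 if the duplex contains at least one G:C pair,
# dS -20.1 for an all-A:T duplex; symmetry dS -1.3.
_BRESLAUER_INIT = {"oneGC": (0.0, -16.8), "allAT": (0.0, -20.1), "sym": (0.0, -1.3)}

# SantaLucia 1998 "unified" set (Allawi & SantaLucia parameters).
SANTALUCIA_1998 = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Initiation: per-terminal terms (A:T end 2.3/4.1, G:C end 0.1/-2.8);
# symmetry dS -1.4.
_SANTALUCIA_INIT = {"AT_end": (2.3, 4.1), "GC_end": (0.1, -2.8), "sym": (0.0, -1.4)}

# Freier et al. 1986 duplex parameters, applied to the DNA alphabet with
# T standing in for U, under the same Tm equation as the other NN sets.
FREIER_1986 = {
    "AA": (-6.6, -18.4), "TT": (-6.6, -18.4),
    "AT": (-5.7, -15.5),
    "TA": (-8.1, -22.6),
    "CA": (-10.5, -27.8), "TG": (-10.5, -27.8),
    "GT": (-10.2, -26.2), "AC": (-10.2, -26.2),
    "CT": (-7.6, -19.2), "AG": (-7.6, -19.2),
    "GA": (-13.3, -35.5), "TC": (-13.3, -35.5),
    "CG": (-8.0, -19.4),
    "GC": (-14.2, -34.9),
    "GG": (-12.2, -29.7), "CC": (-12.2, -29.7),
}
_FREIER_INIT = {"duplex": (0.0, -10.8), "sym": (0.0, -1.4)}


class ThermoError(ValueError):
    """Raised for oligos or parameters a Tm method cannot handle."""


@dataclass(frozen=True)
class TmParams:
    """Solution conditions and method selection for Tm calculation.

    oligo_concentration is the total oligonucleotide strand concentration
    C_T in mol/L; monovalent_salt is [Na+] in mol/L.
    """

    oligo_concentration: float = 5e-8
    monovalent_salt: float = 0.05
    method: str = DEFAULT_METHOD
    symmetry_factor: int | None = None  # None: 4, or 1 if self-complementary

    def __post_init__(self) -> None:
        if self.oligo_concentration <= 0 or self.monovalent_salt <= 0:
            raise ThermoError("concentrations must be strictly positive")
        if self.method not in METHODS:
            raise ThermoError(
                f"unknown Tm method {self.method!r}; "
                f"registered: {sorted(METHODS)}"
            )


def _check_oligo(s: str, min_len: int) -> str:
    s = validate_bases(s)
    if len(s) < min_len:
        raise ThermoError(f"oligo too short for this method (need >= {min_len} bases)")
    if "N" in s:
        raise ThermoError("N has no defined thermodynamic contribution")
    return s


def is_self_complementary(s: str) -> bool:
    return s == reverse_complement(s)


class TmMethod(ABC):
    """Abstract contract every annealing-temperature method implements."""

    name: str

    @abstractmethod
    def tm(self, s: str, params: TmParams) -> float:
        """Melting temperature in deg C for oligo *s* under *params*."""


class WallaceRule(TmMethod):
    name = "wallace"

    def tm(self, s: str, params: TmParams) -> float:
        return tm_wallace(s)


class NearestNeighbor(TmMethod):
    """Tm from dH/dS summation over dinucleotide stacks."""

    def __init__(self, name: str, table: dict, init: dict):
        self.name = name
        self.table = table
        self.init = init

    def _sum_stacks(self, s: str) -> tuple[float, float]:
        dh = ds = 0.0
        for i in range(len(s) - 1):
            h, sv = self.table[s[i : i + 2]]
            dh += h
            ds += sv
        return dh, ds

    def _initiation(self, s: str) -> tuple[float, float]:
        dh = ds = 0.0
        if "AT_end" in self.init:  # per-terminal convention (SantaLucia)
            for end in (s[0], s[-1]):
                h, sv = self.init["AT_end" if end in "AT" else "GC_end"]
                dh += h
                ds += sv
        elif "oneGC" in self.init:  # composition convention (Breslauer)
            key = "oneGC" if ("G" in s or "C" in s) else "allAT"
            h, sv = self.init[key]
            dh += h
            ds += sv
        else:  # flat duplex-initiation term (Freier)
            h, sv = self.init["duplex"]
            dh += h
            ds += sv
        if is_self_complementary(s):
            h, sv = self.init["sym"]
            dh += h
            ds += sv
        return dh, ds

    def tm(self, s: str, params: TmParams) -> float:
        s = _check_oligo(s, 2)
        dh, ds = self._sum_stacks(s)
        ih, is_ = self._initiation(s)
        dh += ih
        ds += is_
        x = params.symmetry_factor
        if x is None:
            x = 1 if is_self_complementary(s) else 4
        tm_k = (dh * 1000.0) / (
            ds + GAS_CONSTANT * math.log(params.oligo_concentration / x)
        )
        return tm_k - 273.15 + 16.6 * math.log10(params.monovalent_salt)


def tm_wallace(s: str) -> float:
    """Wallace rule: 2(A+T) + 4(G+C) in deg C."""
    s = _check_oligo(s, 1)
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    return 2.0 * at + 4.0 * gc


METHODS: dict[str, TmMethod] = {}


def register_method(method: TmMethod) -> None:
    """Register a Tm method under ``method.name``.

    Adding a method never alters existing registrations; re-registering an
    existing name is an error.
    """
    if method.name in METHODS:
        raise ThermoError(f"method {method.name!r} already registered")
    METHODS[method.name] = method


register_method(WallaceRule())
register_method(NearestNeighbor("breslauer_nn", BRESLAUER_1986, _BRESLAUER_INIT))
register_method(NearestNeighbor("santalucia_nn", SANTALUCIA_1998, _SANTALUCIA_INIT))
register_method(NearestNeighbor("freier_nn", FREIER_1986, _FREIER_INIT))


def melting_temperature(s: str, params: TmParams | None = None) -> float:
    """Tm of *s* in deg C using the method named in *params* (default
    ``santalucia_nn``)."""
    params = params or TmParams()
    return METHODS[params.method].tm(s, params)


def tm_nearest_neighbor(s: str, params: TmParams | None = None) -> float:
    """Nearest-neighbor Tm; *params.method* must name one of the NN sets."""
    params = params or TmParams()
    method = METHODS[params.method]
    if not isinstance(method, NearestNeighbor):
        raise ThermoError(f"{params.method!r} is not a nearest-neighbor method")
    return method.tm(s, params)
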