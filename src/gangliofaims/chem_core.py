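"""Elemental-formula arithmetic, monoisotopic masses and isotope envelopes.

All mass bookkeeping in the package goes through :class:`ElementalFormula`.
Negative-ion m/z values follow the deprotonation convention used throughout
shotgun lipidomics software: ``[M - zH]z-`` is placed at
``(M - z * m(H)) / z`` with the hydrogen *atom* mass (no electron-mass
correction).  This reproduces the canonical sialic-acid diagnostic fragment
at m/z 290.0876.

Isotope envelopes are aggregated (nominal) isotopologue distributions —
every +1 Da isotope substitution lands in the same bin, which is the right
granularity for Orbitrap isotopologue quantitation; fine isotopic structure
is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementalFormula",
    "IsotopeEnvelope",
    "monoisotopic_mass",
    "mz_negative",
    "isotope_envelope",
    "HYDROGEN_MASS",
    "PROTON_MASS",
    "C13_SPACING",
    "ATOMIC_MASSES",
    "ISOTOPE_ABUNDANCES",
]

# Monoisotopic atomic masses (Da), IUPAC/CODATA values. Versioned constants:
# outputs must be bit-stable across environments.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370649,
}

# Relative natural abundances per nominal mass shift (index 0 = lightest).
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Na": (1.0,),
    "K": (0.932581, 0.000117, 0.067302),
}

HYDROGEN_MASS = ATOMIC_MASSES["H"]
#: Physical proton mass, kept for reference; m/z placement uses HYDROGEN_MASS.
PROTON_MASS = 1.00727646
#: 13C-12C mass difference: the isotopologue spacing of CHNO-dominated analytes.
C13_SPACING = 1.0033548

MAX_CHARGE = 8
MAX_ISOTOPOLOGUES = 6  # m+0 .. m+5

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class UnsupportedElementError(ValueError):
    """Raised when a formula contains an element without constants."""


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts; supports element-wise arithmetic.

    ``signed=True`` marks a delta formula (used for neutral losses), where
    negative counts are legal.  In the default unsigned context any
    operation that would produce a negative count raises ``ValueError``.
    """

    counts: tuple[tuple[str, int], ...]
    signed: bool = False

    def __init__(self, counts=None, signed: bool = False, **elements: int):
        merged: dict[str, int] = {}
        if counts:
            items = counts.items() if isinstance(counts, dict) else counts
            for el, n in items:
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in elements.items():
            merged[el] = merged.get(el, 0) + int(n)
        for el in merged:
            if el not in ATOMIC_MASSES:
                raise UnsupportedElementError(f"unsupported element: {el!r}")
        merged = {el: n for el, n in merged.items() if n != 0}
        if not signed and any(n < 0 for n in merged.values()):
            neg = [el for el, n in merged.items() if n < 0]
            raise ValueError(f"negative count for {neg} in unsigned formula")
        object.__setattr__(self, "counts", tuple(sorted(merged.items())))
        object.__setattr__(self, "signed", signed)

    @classmethod
    def parse(cls, text: str, signed: bool = False) -> "ElementalFormula":
        """Parse a Hill-style string such as ``"C11H19NO9"``."""
        text = text.strip()
        if not text:
            return cls({})
        pos = 0
        counts: dict[str, int] = {}
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in ATOMIC_MASSES:
                raise UnsupportedElementError(f"unsupported element: {el!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls(counts, signed=signed)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula(d, signed=self.signed or other.signed)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return ElementalFormula(d, signed=self.signed)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.counts}, signed=self.signed)

    __rmul__ = __mul__

    def hill(self) -> str:
        """Hill-order string: C, H, then alphabetical."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(_fmt(el, d.pop(el)))
        parts.extend(_fmt(el, d[el]) for el in sorted(d))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def _fmt(el: str, n: int) -> str:
    if n == 1:
        return el
    return f"{el}{n}"


# Water and proton-level deltas used all over the glycan bookkeeping.
WATER = ElementalFormula(H=2, O=1)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da (sum of count x atomic monoisotopic mass)."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return float(sum(n * ATOMIC_MASSES[el] for el, n in formula.counts))


def mz_negative(neutral_mass: float, z: int) -> float:
    """m/z of the ``[M - zH]z-`` ion of a neutral of the given mass.

    Subtracts ``z`` hydrogen-atom masses and divides by ``z`` — the standard
    lipidomics software placement for deprotonated anions (see module
    docstring).  ``z`` must be in 1..8, the range relevant for gangliosides.
    """
    if not isinstance(z, (int, np.integer)) or isinstance(z, bool):
        raise TypeError(f"charge must be an integer, got {z!r}")
    if not 1 <= z <= MAX_CHARGE:
        raise ValueError(f"charge {z} outside supported range 1..{MAX_CHARGE}")
    return (neutral_mass - z * HYDROGEN_MASS) / z


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative isotopologue intensities r0..r(k), normalized so r0 = 1.

    ``spacing`` is the nominal Da gap between consecutive isotopologues of
    the *neutral*; divide by charge for an ion's m/z spacing.
    """

    ratios: tuple[float, ...]
    spacing: float = C13_SPACING

    def __post_init__(self):
        if not self.ratios or abs(self.ratios[0] - 1.0) > 1e-12:
            raise ValueError("envelope must be normalized to r0 = 1")
        if len(self.ratios) > MAX_ISOTOPOLOGUES:
            raise ValueError(f"at most {MAX_ISOTOPOLOGUES} isotopologues (m+0..m+5)")
        if any(r < 0 for r in self.ratios):
            raise ValueError("negative relative intensity")

    def __len__(self) -> int:
        return len(self.ratios)

    def __getitem__(self, i: int) -> float:
        return self.ratios[i]


def isotope_envelope(formula: ElementalFormula | str, n: int = MAX_ISOTOPOLOGUES) -> IsotopeEnvelope:
    """Theoretical aggregated isotopologue distribution of ``formula``.

    Convolves per-element nominal isotope distributions (each element's
    distribution raised to its atom count by repeated squaring), truncated
    to ``n`` isotopologues and normalized to the monoisotopic peak.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if not 1 <= n <= MAX_ISOTOPOLOGUES:
        raise ValueError(f"n must be in 1..{MAX_ISOTOPOLOGUES}")
    if any(c < 0 for _, c in formula.counts):
        raise ValueError("isotope envelope requires a non-negative formula")
    dist = np.zeros(n)
    dist[0] = 1.0
    for el, count in formula.counts:
        p = np.asarray(ISOTOPE_ABUNDANCES[el], dtype=float)
        p = p / p.sum()
        dist = _convolve_trunc(dist, _power_trunc(p, count, n), n)
    if dist[0] <= 0.0:
        raise ValueError("vanishing monoisotopic abundance")
    return IsotopeEnvelope(tuple(dist / dist[0]))


def _convolve_trunc(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(a, b)[:n]


def _power_trunc(p: np.ndarray, count: int, n: int) -> np.ndarray:
    """p(x)**count truncated to n terms, by binary exponentiation."""
    result = np.zeros(n)
    result[0] = 1.0
    base = np.zeros(n)
    base[: min(n, p.size)] = p[:n]
    while count:
        if count & 1:
            result = _convolve_trunc(result, base, n)
        count >>= 1
        if count:
            base = _convolve_trunc(base, base, n)
    return result
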