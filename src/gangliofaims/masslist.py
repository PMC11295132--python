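"""Combinatorial ganglioside target mass list and TSV round-trip.

A ganglioside is a ceramide carrying a sialylated glycan headgroup.  The
target space is the cross product

    class (glycan composition)  x  ceramide sum composition  x  charge state

with the charge range per class tied to its sialic-acid count: multiply
deprotonated anions up to ``[M - 8H]8-`` are observed, and the preferred
charge correlates with the number of NeuAc residues.

Glycan bookkeeping uses dehydrated residue formulas (Hex C6H10O5, HexNAc
C8H13NO5, NeuAc C11H17NO8, dHex/Fuc C6H10O4, O-acetyl C2H2O): the neutral
species formula is simply ceramide + sum of residues, because the water
released per glycosidic bond is already accounted for in the residue masses
and the free-oligosaccharide water is consumed by the ceramide-glycan bond.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .chem_core import (
    ElementalFormula,
    monoisotopic_mass,
    mz_negative,
    MAX_CHARGE,
)

__all__ = [
    "GangliosideClass",
    "CeramideSpace",
    "MassListEntry",
    "class_table_default",
    "ceramide_formula",
    "parse_sum_composition",
    "species_formula",
    "enumerate_masslist",
    "write_masslist",
    "read_masslist",
    "RESIDUES",
    "DEFAULT_CLASS_NAMES",
]

# Dehydrated monosaccharide residue formulas.
RESIDUES: dict[str, ElementalFormula] = {
    "Hex": ElementalFormula(C=6, H=10, O=5),
    "HexNAc": ElementalFormula(C=8, H=13, N=1, O=5),
    "NeuAc": ElementalFormula(C=11, H=17, N=1, O=8),
    "dHex": ElementalFormula(C=6, H=10, O=4),
    "Ac": ElementalFormula(C=2, H=2, O=1),
}

# Svennerholm series letter -> NeuAc count.
_SERIES_NEUAC = {"M": 1, "D": 2, "T": 3, "Q": 4, "P": 5, "H": 6, "S": 7, "O": 8}

# Trailing digit -> neutral core sugars (Hex, HexNAc). 1 = longest core.
_CORE_SUGARS = {1: (3, 1), 2: (2, 1), 3: (2, 0), 4: (1, 0)}

#: Default class inventory: the GM/GD/GT/GQ/GP/GH/GS/GO series with their
#: acetylated and fucosylated variants, 29 classes in total.
DEFAULT_CLASS_NAMES: tuple[str, ...] = (
    "GM1", "GM2", "GM3", "GM4", "GM1-Ac", "GM1-Fuc",
    "GD1", "GD2", "GD3", "GD1-Ac", "GD1-Fuc", "GD1-Fuc-Ac", "GD3-Ac",
    "GT1", "GT2", "GT3", "GT1-Ac", "GT1-Fuc", "GT1-Fuc-Ac", "GT3-Ac", "GT3-Fuc",
    "GQ1", "GQ1-Ac", "GQ1-Fuc",
    "GP1", "GH1", "GS1", "GS1-Fuc", "GO1",
)

_CLASS_NAME = re.compile(r"^G([MDTQPHSO])([1-4])((?:-(?:Ac|Fuc))*)$")


@dataclass(frozen=True)
class GangliosideClass:
    """One ganglioside class/modification: glycan composition + charge range."""

    name: str
    hex: int
    hexnac: int
    neuac: int
    dhex: int = 0
    acetyl: int = 0
    max_charge: int = 0  # 0 -> default min(neuac, 8)

    def __post_init__(self):
        if self.neuac < 0:
            raise ValueError("NeuAc count must be >= 0")
        if self.max_charge == 0:
            object.__setattr__(self, "max_charge", min(self.neuac, MAX_CHARGE))

    @property
    def charges(self) -> range:
        return range(1, self.max_charge + 1)

    def glycan_formula(self) -> ElementalFormula:
        f = ElementalFormula({})
        for res, count in (
            ("Hex", self.hex),
            ("HexNAc", self.hexnac),
            ("NeuAc", self.neuac),
            ("dHex", self.dhex),
            ("Ac", self.acetyl),
        ):
            if count:
                f = f + count * RESIDUES[res]
        return f

    @classmethod
    def from_name(cls, name: str) -> "GangliosideClass":
        m = _CLASS_NAME.match(name)
        if not m:
            raise ValueError(f"cannot parse ganglioside class name {name!r}")
        series, core, mods = m.group(1), int(m.group(2)), m.group(3)
        nhex, nhexnac = _CORE_SUGARS[core]
        return cls(
            name=name,
            hex=nhex,
            hexnac=nhexnac,
            neuac=_SERIES_NEUAC[series],
            dhex=mods.count("-Fuc"),
            acetyl=mods.count("-Ac"),
        )


def class_table_default() -> list[GangliosideClass]:
    """The default 29-class table (series x core x Ac/Fuc modifications)."""
    return [GangliosideClass.from_name(n) for n in DEFAULT_CLASS_NAMES]


@dataclass(frozen=True)
class CeramideSpace:
    """Ceramide sum-composition enumeration bounds.

    Defaults (C 28-48 including odd chains, 0-5 double bonds, di- and
    trihydroxylated backbones) span the search space of roughly 8500
    species over the 29 default classes.
    """

    c_min: int = 28
    c_max: int = 48
    db_min: int = 0
    db_max: int = 5
    o_states: tuple[int, ...] = (2, 3)
    even_only: bool = False

    def __post_init__(self):
        if self.c_min > self.c_max or self.db_min > self.db_max:
            raise ValueError("empty ceramide range")
        if any(o not in (2, 3) for o in self.o_states):
            raise ValueError("hydroxylation states limited to O2/O3")

    def labels(self):
        step = 2 if self.even_only else 1
        for c in range(self.c_min, self.c_max + 1, step):
            for db in range(self.db_min, self.db_max + 1):
                for o in self.o_states:
                    yield f"{c}:{db};O{o}"


_SUM_COMP = re.compile(r"^(\d+):(\d+);O(\d+)$")


def parse_sum_composition(label: str) -> tuple[int, int, int]:
    """Parse ``"36:1;O2"`` -> (carbons, double bonds, hydroxyls)."""
    m = _SUM_COMP.match(label.strip())
    if not m:
        raise ValueError(
            f"malformed sum composition {label!r}: expected C:DB;On "
            f"(error at position {_mismatch_pos(label)})"
        )
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def _mismatch_pos(label: str) -> int:
    for i, ch in enumerate(label):
        if ch not in "0123456789:;O":
            return i
    return len(label)


def ceramide_formula(sum_composition: str) -> ElementalFormula:
    """Neutral formula of a ceramide with the given sum composition.

    An N-acylated sphingoid backbone with c carbons, db C=C double bonds
    and n hydroxyls has formula ``C(c) H(2c+1-2db) N O(n+1)`` — sphingoid
    base CnH(2n+3)NO2-like + fatty acid CnH(2n-2db)O2 condensed with loss
    of one water; the amide oxygen accounts for the +1.
    """
    c, db, n_oh = parse_sum_composition(sum_composition)
    h = 2 * c + 1 - 2 * db
    if c < 2 or h < 1:
        raise ValueError(f"unphysical sum composition {sum_composition!r}")
    return ElementalFormula(C=c, H=h, N=1, O=n_oh + 1)


def species_formula(cls: GangliosideClass, sum_composition: str) -> ElementalFormula:
    """Neutral elemental formula of class + ceramide sum composition."""
    return ceramide_formula(sum_composition) + cls.glycan_formula()


_ION_LABEL = re.compile(r"^\[M-(\d*)H\](\d*)-$")


def ion_label(z: int) -> str:
    if z == 1:
        return "[M-H]-"
    return f"[M-{z}H]{z}-"


def parse_ion_label(label: str) -> int:
    m = _ION_LABEL.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse ion label {label!r}")
    z = int(m.group(1) or 1)
    if (m.group(2) or "1") != str(z):
        raise ValueError(f"inconsistent ion label {label!r}")
    return z


@dataclass(frozen=True)
class MassListEntry:
    """One target: ganglioside species x deprotonated ion species."""

    class_name: str
    species: str  # sum composition label, e.g. "36:1;O2"
    formula: ElementalFormula
    neutral_mass: float
    z: int
    mz: float

    @property
    def ion(self) -> str:
        return ion_label(self.z)

    @property
    def label(self) -> str:
        return f"{self.class_name} {self.species}"

    @classmethod
    def build(cls, gclass: GangliosideClass, species: str, z: int) -> "MassListEntry":
        f = species_formula(gclass, species)
        mass = monoisotopic_mass(f)
        return cls(
            class_name=gclass.name,
            species=species,
            formula=f,
            neutral_mass=mass,
            z=z,
            mz=mz_negative(mass, z),
        )


def enumerate_masslist(
    classes: list[GangliosideClass] | None = None,
    ceramide_space: CeramideSpace | None = None,
    charge_policy=None,
) -> list[MassListEntry]:
    """Enumerate the target list: one entry per (class, composition, z).

    ``charge_policy(cls) -> iterable of z`` overrides the per-class default
    range 1..min(NeuAc, 8).  Entries are m/z-sorted and deduplicated.
    """
    classes = class_table_default() if classes is None else classes
    ceramide_space = ceramide_space or CeramideSpace()
    if not classes:
        raise ValueError("no classes given")
    entries: dict[tuple, MassListEntry] = {}
    for gclass in classes:
        zs = list(charge_policy(gclass)) if charge_policy else list(gclass.charges)
        for species in ceramide_space.labels():
            for z in zs:
                key = (gclass.name, species, z)
                if key not in entries:
                    entries[key] = MassListEntry.build(gclass, species, z)
    out = sorted(entries.values(), key=lambda e: (e.mz, e.class_name, e.z))
    if not out:
        import warnings

        warnings.warn("mass-list enumeration produced no entries")
    return out


_COLUMNS = ["class", "species", "ion", "z", "formula", "neutral_mass", "mz"]


def write_masslist(entries: list[MassListEntry], path) -> None:
    """Write entries to a TSV with a header row (UTF-8)."""
    df = pd.DataFrame(
        {
            "class": [e.class_name for e in entries],
            "species": [e.species for e in entries],
            "ion": [e.ion for e in entries],
            "z": [e.z for e in entries],
            "formula": [e.formula.hill() for e in entries],
            "neutral_mass": [f"{e.neutral_mass:.6f}" for e in entries],
            "mz": [f"{e.mz:.6f}" for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_masslist(path) -> list[MassListEntry]:
    """Read a TSV mass list; extra user columns are tolerated and ignored."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mass list {path} missing required columns: {missing}")
    out = []
    for i in range(len(df)):
        z = int(df["z"].iat[i])
        ion = str(df["ion"].iat[i])
        if parse_ion_label(ion) != z:
            raise ValueError(f"ion label {ion!r} disagrees with z={z}")
        out.append(
            MassListEntry(
                class_name=str(df["class"].iat[i]),
                species=str(df["species"].iat[i]),
                formula=ElementalFormula.parse(str(df["formula"].iat[i])),
                neutral_mass=float(df["neutral_mass"].iat[i]),
                z=z,
                mz=float(df["mz"].iat[i]),
            )
        )
    return out
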