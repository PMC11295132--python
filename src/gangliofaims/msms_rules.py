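"""Decision-rule MS/MS evaluation of ganglioside candidates.

The evaluation combines CID/HCD/UVPD spectra of one precursor into a single
sum (or average) spectrum, matches class-applicable diagnostic fragments and
neutral losses at a ppm tolerance, and verifies a species-level annotation
when every mandatory fragment is present.  Molecular-lipid-species level
(resolved sphingoid base / fatty acid pairing) is assigned only from
UVPD-tagged evidence for the fatty-acyl neutral losses ("G" fragment) and
their G-NeuAc companions — in negative mode, CID/HCD fatty-acid signals
alone are not reliable enough to resolve the ceramide, so they never
promote the level.  Species quantities are split among matched fatty-acid
isomers in proportion to their distinct-fragment intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .chem_core import ElementalFormula, HYDROGEN_MASS, monoisotopic_mass, mz_negative
from .masslist import (
    GangliosideClass,
    MassListEntry,
    RESIDUES,
    parse_sum_composition,
)
from .spectra_io import Spectrum

__all__ = [
    "FragmentSpec",
    "FragmentMatch",
    "DecisionRuleSet",
    "Annotation",
    "Rejection",
    "combine_spectra",
    "match_fragment",
    "evaluate",
    "fa_candidates",
    "assign_molecular_species",
    "split_quantity",
]

KINDS = ("anion", "neutral_loss", "fa_loss", "fa_neuac_loss")


@dataclass(frozen=True)
class FragmentSpec:
    """One diagnostic fragment or neutral-loss rule."""

    name: str
    kind: str
    formula: ElementalFormula | None = None
    mandatory: bool = False
    min_neuac: int = 0
    requires: str | None = None  # 'Ac' | 'Fuc' modification gate
    activations: tuple[str, ...] = ("CID", "HCD", "UVPD")
    level: str = "species"  # 'molecular' marks ceramide-resolving evidence

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if self.kind in ("anion", "neutral_loss") and self.formula is None:
            raise ValueError(f"fragment {self.name!r} needs a formula")

    def applies_to(self, gclass: GangliosideClass) -> bool:
        if gclass.neuac < self.min_neuac:
            return False
        if self.requires == "Ac" and gclass.acetyl == 0:
            return False
        if self.requires == "Fuc" and gclass.dhex == 0:
            return False
        return True


@dataclass
class DecisionRuleSet:
    """Fragment rules, optional pairwise intensity relations, MS/MS tolerance.

    ``intensity_rules`` entries ``(greater, lesser)`` demand that, when both
    named fragments are matched, the first is at least as intense as the
    second; a violation rejects the candidate.
    """

    fragments: list[FragmentSpec]
    tolerance_ppm: float = 10.0
    intensity_rules: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, source) -> "DecisionRuleSet":
        """Load rules from a YAML path or already-read text."""
        text = str(source)
        if "\n" not in text:  # a path, not document text
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        doc = yaml.safe_load(text)
        frags = []
        for item in doc.get("fragments", []):
            frags.append(
                FragmentSpec(
                    name=item["name"],
                    kind=item["kind"],
                    formula=ElementalFormula.parse(item["formula"]) if "formula" in item else None,
                    mandatory=bool(item.get("mandatory", False)),
                    min_neuac=int(item.get("min_neuac", 0)),
                    requires=item.get("requires"),
                    activations=tuple(item.get("activations", ("CID", "HCD", "UVPD"))),
                    level=item.get("level", "species"),
                )
            )
        relations = [
            (str(r["greater"]), str(r["lesser"]))
            for r in doc.get("intensity_rules", [])
        ]
        return cls(
            fragments=frags,
            tolerance_ppm=float(doc.get("tolerance_ppm", 10.0)),
            intensity_rules=relations,
        )

    @classmethod
    def default(cls) -> "DecisionRuleSet":
        text = resources.files("gangliofaims.data").joinpath("rules.yaml").read_text()
        return cls.from_yaml(text)

    def for_class(self, gclass: GangliosideClass, mandatory_only: bool = False):
        out = [f for f in self.fragments if f.applies_to(gclass)]
        if mandatory_only:
            out = [f for f in out if f.mandatory]
        return out


@dataclass(frozen=True)
class FragmentMatch:
    """A matched fragment peak."""

    name: str
    mz_theoretical: float
    mz_observed: float
    ppm: float
    intensity: float
    activations: frozenset
    product_charge: int = 1


def combine_spectra(
    spectra: list[Spectrum], method: str = "sum", tol_ppm: float = 10.0
) -> Spectrum:
    """Merge same-precursor MS2 spectra onto a ppm tolerance grid.

    Peaks within tolerance coalesce: m/z becomes the intensity-weighted
    mean, intensity the sum (``method='sum'``) or the sum divided by the
    number of input spectra (``'average'``).  Per-peak activation
    provenance is retained so downstream rules can demand UVPD evidence.
    """
    if not spectra:
        raise ValueError("no spectra to combine")
    if method not in ("sum", "average"):
        raise ValueError(f"unknown combine method {method!r}")
    if any(s.ms_level != 2 for s in spectra):
        raise ValueError("combine_spectra expects MS2 scans")
    precursors = np.array([s.precursor_mz for s in spectra])
    half_iso = min(s.isolation_width for s in spectra) / 2.0
    if precursors.max() - precursors.min() > half_iso:
        raise ValueError("mixed precursors: spectra span more than one isolation window")
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    prov = []
    for s in spectra:
        tags = frozenset([s.activation]) if s.activation else frozenset()
        if s.provenance is not None:
            prov.extend(s.provenance)
        else:
            prov.extend([tags] * s.mz.size)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    prov = [prov[i] for i in order]

    out_mz, out_int, out_prov = [], [], []
    i = 0
    while i < mz.size:
        j = i + 1
        # grow cluster while the next peak is within tol of the running mean
        cm, ci = mz[i], inten[i]
        tags = set(prov[i])
        mean = cm
        while j < mz.size and abs(mz[j] - mean) <= mean * tol_ppm * 1e-6:
            new_ci = ci + inten[j]
            mean = (mean * ci + mz[j] * inten[j]) / new_ci if new_ci > 0 else mz[j]
            ci = new_ci
            tags |= prov[j]
            j += 1
        out_mz.append(mean)
        out_int.append(ci)
        out_prov.append(frozenset(tags))
        i = j
    intensity = np.array(out_int)
    if method == "average":
        intensity = intensity / len(spectra)
    return Spectrum(
        scan_id="+".join(s.scan_id for s in spectra),
        ms_level=2,
        mz=np.array(out_mz),
        intensity=intensity,
        activation=None,
        precursor_mz=float(np.average(precursors, weights=[max(s.tic, 1e-12) for s in spectra])),
        isolation_width=min(s.isolation_width for s in spectra),
        faims_cv=spectra[0].faims_cv
        if len({s.faims_cv for s in spectra}) == 1
        else None,
        provenance=out_prov,
    )


def _target_mzs(
    spec: FragmentSpec, entry: MassListEntry, fa_formula: ElementalFormula | None
) -> list[tuple[float, int]]:
    """(m/z, product charge) targets for one fragment rule on one precursor."""
    if spec.kind == "anion":
        return [(mz_negative(monoisotopic_mass(spec.formula), 1), 1)]
    if spec.kind == "neutral_loss":
        loss = monoisotopic_mass(spec.formula)
    elif spec.kind == "fa_loss":
        if fa_formula is None:
            raise ValueError("fa_loss rule needs a candidate fatty-acid formula")
        loss = monoisotopic_mass(fa_formula)
    elif spec.kind == "fa_neuac_loss":
        if fa_formula is None:
            raise ValueError("fa_neuac_loss rule needs a candidate fatty-acid formula")
        loss = monoisotopic_mass(fa_formula) + monoisotopic_mass(RESIDUES["NeuAc"])
    remaining = entry.neutral_mass - loss
    targets = []
    for zp in range(1, entry.z + 1):
        mz = (remaining - zp * HYDROGEN_MASS) / zp
        if mz > 0:
            targets.append((mz, zp))
    return targets


def _activation_ok(spec: FragmentSpec, spectrum: Spectrum, peak_idx: int) -> bool:
    if spectrum.provenance is not None:
        tags = spectrum.provenance[peak_idx]
        return (not tags) or bool(tags & set(spec.activations))
    if spectrum.activation is None:
        return True
    return spectrum.activation in spec.activations


def match_fragment(
    spectrum: Spectrum,
    spec: FragmentSpec,
    entry: MassListEntry,
    tol_ppm: float = 10.0,
    fa_formula: ElementalFormula | None = None,
) -> FragmentMatch | None:
    """Best in-tolerance peak for a fragment rule, or None.

    Neutral losses are searched at every product charge 1..z; the most
    intense in-tolerance peak (with acceptable activation provenance) wins.
    """
    best = None
    for target, zp in _target_mzs(spec, entry, fa_formula):
        half = target * tol_ppm * 1e-6
        lo = np.searchsorted(spectrum.mz, target - half, side="left")
        hi = np.searchsorted(spectrum.mz, target + half, side="right")
        for idx in range(lo, hi):
            if not _activation_ok(spec, spectrum, idx):
                continue
            inten = spectrum.intensity[idx]
            if best is None or inten > best.intensity:
                obs = spectrum.mz[idx]
                tags = (
                    spectrum.provenance[idx]
                    if spectrum.provenance is not None
                    else frozenset([spectrum.activation] if spectrum.activation else [])
                )
                best = FragmentMatch(
                    name=spec.name,
                    mz_theoretical=target,
                    mz_observed=float(obs),
                    ppm=float((obs - target) / target * 1e6),
                    intensity=float(inten),
                    activations=tags,
                    product_charge=zp,
                )
    return best


@dataclass
class Annotation:
    """A verified identification with its evidence."""

    entry: MassListEntry
    level: str  # 'species' | 'molecular species'
    fragments: list[FragmentMatch] = field(default_factory=list)
    partition: dict[str, float] = field(default_factory=dict)  # molecular label -> fraction
    quantity: float = 0.0
    molecular_quantities: dict[str, float] = field(default_factory=dict)
    cv_evidence: float | None = None
    cv_pass: bool | None = None
    cv_note: str = ""

    @property
    def activations(self) -> frozenset:
        tags: set = set()
        for m in self.fragments:
            tags |= m.activations
        return frozenset(tags)


@dataclass
class Rejection:
    entry: MassListEntry
    missing: list[str]


def evaluate(
    entry: MassListEntry,
    gclass: GangliosideClass,
    spectrum: Spectrum,
    rules: DecisionRuleSet,
) -> Annotation | Rejection:
    """Species-level verification: all class-mandatory fragments must match."""
    applicable = rules.for_class(gclass)
    if not applicable:
        raise ValueError(f"no decision rules apply to class {gclass.name}")
    matches, missing = [], []
    for spec in applicable:
        if spec.level != "species":
            continue  # molecular evidence handled by assign_molecular_species
        m = match_fragment(spectrum, spec, entry, rules.tolerance_ppm)
        if m is not None:
            matches.append(m)
        elif spec.mandatory:
            missing.append(spec.name)
    if missing:
        return Rejection(entry=entry, missing=missing)
    by_name = {m.name: m.intensity for m in matches}
    for greater, lesser in rules.intensity_rules:
        if greater in by_name and lesser in by_name:
            if by_name[greater] < by_name[lesser]:
                return Rejection(
                    entry=entry,
                    missing=[f"intensity({greater}) >= intensity({lesser})"],
                )
    return Annotation(entry=entry, level="species", fragments=matches)


def fa_candidates(
    sum_composition: str,
    spb_carbons: tuple[int, ...] = (18, 20),
    spb_double_bonds: tuple[int, ...] = (0, 1),
    fa_c_range: tuple[int, int] = (10, 36),
) -> list[tuple[str, ElementalFormula]]:
    """Enumerate (molecular-species label, fatty-acid formula) splits.

    Candidates pair a sphingoid base (default d18/d20 backbones, 0-1 double
    bonds, carrying the composition's hydroxyls) with the complementary free
    fatty acid CnH(2n-2db)O2.
    """
    c, db, o = parse_sum_composition(sum_composition)
    out = []
    for cs in spb_carbons:
        for dbs in spb_double_bonds:
            fc, fdb = c - cs, db - dbs
            if not (fa_c_range[0] <= fc <= fa_c_range[1]) or fdb < 0:
                continue
            fa = ElementalFormula(C=fc, H=2 * fc - 2 * fdb, O=2)
            label = f"{cs}:{dbs};O{o}/{fc}:{fdb}"
            out.append((label, fa))
    return out


def assign_molecular_species(
    annotation: Annotation,
    spectrum: Spectrum,
    rules: DecisionRuleSet,
    candidates: list[tuple[str, ElementalFormula]] | None = None,
) -> Annotation:
    """Promote to molecular-species level from UVPD G / G-NeuAc evidence.

    For each candidate chain split the fatty-acyl neutral loss (G) and the
    combined fatty-acyl + NeuAc loss (G-NeuAc) are searched among
    UVPD-tagged peaks; candidates with at least one match enter the
    partition with fractions proportional to their summed distinct-fragment
    intensities.  No match leaves the annotation at species level.
    """
    if annotation.level != "species":
        return annotation
    if candidates is None:
        candidates = fa_candidates(annotation.entry.species)
    g_specs = [f for f in rules.fragments if f.level == "molecular"]
    weights: dict[str, float] = {}
    evidence: dict[str, list[FragmentMatch]] = {}
    for label, fa in candidates:
        total = 0.0
        found = []
        for spec in g_specs:
            m = match_fragment(spectrum, spec, annotation.entry, rules.tolerance_ppm, fa_formula=fa)
            if m is not None:
                total += m.intensity
                found.append(
                    FragmentMatch(
                        name=f"{m.name}({label})",
                        mz_theoretical=m.mz_theoretical,
                        mz_observed=m.mz_observed,
                        ppm=m.ppm,
                        intensity=m.intensity,
                        activations=m.activations,
                        product_charge=m.product_charge,
                    )
                )
        if found:
            weights[label] = total
            evidence[label] = found
    if not weights:
        return annotation
    wsum = sum(weights.values())
    annotation.level = "molecular species"
    annotation.partition = {label: w / wsum for label, w in sorted(weights.items())}
    for found in evidence.values():
        annotation.fragments.extend(found)
    return annotation


def split_quantity(quantity: float, partition: dict[str, float]) -> dict[str, float]:
    """Distribute a species-level quantity over the molecular partition."""
    if not partition:
        return {}
    total = sum(partition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"partition fractions sum to {total}, expected 1")
    return {label: quantity * frac for label, frac in partition.items()}
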