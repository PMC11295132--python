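"""Synthetic shotgun/FAIMS scan sets with planted gangliosides.

The generator emulates a CV-ramped direct-infusion acquisition: per CV step
it emits MS1 scans containing each planted species' theoretical isotope
envelope (the same envelope code the analysis uses) scaled by a Gaussian CV
transmission curve per charge state, on top of a bulk-lipid background of
uniform-m/z, exponentially distributed noise peaks.  MS2 scans (CID, HCD,
UVPD) for each plant contain exactly the requested rule fragments at their
computed m/z; decoy plants get MS1 signal but no mandatory diagnostic
fragments, so a correct pipeline must reject them.  A ground-truth manifest
accompanies every run.

The Gaussian transmission shape and the default charge-CV coupling (higher
charge states transmitting at higher CV) are modeling choices documented in
the methods note; default plant intensities sit about three orders of
magnitude above the noise floor.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_core import (
    C13_SPACING,
    HYDROGEN_MASS,
    ElementalFormula,
    isotope_envelope,
    monoisotopic_mass,
)
from .masslist import (
    GangliosideClass,
    MassListEntry,
    RESIDUES,
)
from .msms_rules import fa_candidates
from .faims import CVSchedule
from .spectra_io import ScanSeries, Spectrum

__all__ = ["PlantSpec", "generate", "write_mzml", "default_cv_center"]


def default_cv_center(class_name: str, z: int) -> float:
    """Default planted transmission apex: higher charge -> higher CV.

    The two reference windows get centers inside them; other (class, z)
    pairs follow a linear charge coupling clipped to the 25-77 V ramp.
    """
    known = {("GD1", 2): 45.0, ("GT1", 3): 65.0}
    if (class_name, z) in known:
        return known[(class_name, z)]
    return float(min(77.0, max(25.0, 20.0 + 12.0 * z)))


@dataclass
class PlantSpec:
    """One planted ganglioside and how it should appear in the data."""

    class_name: str
    species: str  # sum composition, e.g. "36:1;O2"
    charges: dict[int, float] = field(default_factory=lambda: {1: 1.0})  # z -> rel abundance
    cv_center: dict[int, float] = field(default_factory=dict)  # z -> apex V
    cv_width: float = 6.0  # Gaussian sigma, V
    base_intensity: float = 1.0e6
    molecular: dict[str, float] = field(default_factory=dict)  # "18:1;O2/20:0" -> weight
    decoy: bool = False  # MS1 signal but no mandatory MS/MS fragments
    fragment_scale: float = 0.2  # fragment intensity relative to base

    def __post_init__(self):
        if not self.charges or any(a <= 0 for a in self.charges.values()):
            raise ValueError("charge abundances must be positive")
        if self.cv_width <= 0:
            raise ValueError("CV transmission width must be positive")
        for z in self.charges:
            self.cv_center.setdefault(z, default_cv_center(self.class_name, z))

    @property
    def gclass(self) -> GangliosideClass:
        return GangliosideClass.from_name(self.class_name)

    def entry(self, z: int) -> MassListEntry:
        return MassListEntry.build(self.gclass, self.species, z)

    @property
    def main_charge(self) -> int:
        return max(self.charges, key=lambda z: (self.charges[z], -z))


def _gauss(cv: float, center: float, width: float) -> float:
    return float(np.exp(-0.5 * ((cv - center) / width) ** 2))


def _noise(rng: np.random.Generator, n: int, mean: float, mz_lo=250.0, mz_hi=2000.0):
    if n <= 0:
        return np.empty(0), np.empty(0)
    return rng.uniform(mz_lo, mz_hi, size=n), rng.exponential(mean, size=n)


def _fragment_peaks(plant: PlantSpec, activation: str) -> tuple[list[float], list[float]]:
    """Rule-compliant fragment m/z values for one activation scan."""
    gclass = plant.gclass
    z = plant.main_charge
    entry = plant.entry(z)
    scale = plant.base_intensity * plant.fragment_scale
    mzs: list[float] = []
    ints: list[float] = []

    def anion(formula: ElementalFormula, inten: float):
        mzs.append(monoisotopic_mass(formula) - HYDROGEN_MASS)
        ints.append(inten)

    def neutral_loss(loss_mass: float, inten: float, zp: int | None = None):
        zp = zp or z
        mz = (entry.neutral_mass - loss_mass - zp * HYDROGEN_MASS) / zp
        if mz > 0:
            mzs.append(mz)
            ints.append(inten)

    if not plant.decoy:
        anion(RESIDUES["NeuAc"], scale)
        if gclass.neuac >= 2:
            anion(2 * RESIDUES["NeuAc"], 0.6 * scale)
    # optional evidence planted for everyone, decoys included
    neutral_loss(monoisotopic_mass(RESIDUES["NeuAc"]), 0.4 * scale)
    if gclass.acetyl:
        neutral_loss(monoisotopic_mass(RESIDUES["Ac"]), 0.3 * scale)
    if gclass.dhex:
        neutral_loss(monoisotopic_mass(RESIDUES["dHex"]), 0.3 * scale)
    if activation == "UVPD" and plant.molecular and not plant.decoy:
        candidates = dict(fa_candidates(plant.species))
        for label, weight in plant.molecular.items():
            fa = candidates.get(label)
            if fa is None:
                raise ValueError(f"{plant.class_name} {plant.species}: no chain split {label!r}")
            fa_mass = monoisotopic_mass(fa)
            neutral_loss(fa_mass, weight * 0.5 * scale)  # G
            neutral_loss(fa_mass + monoisotopic_mass(RESIDUES["NeuAc"]), weight * 0.25 * scale)
    return mzs, ints


def generate(
    plants: list[PlantSpec],
    schedule: CVSchedule,
    *,
    scans_per_cv: int = 1,
    noise_peaks: int = 200,
    noise_intensity_mean: float = 1.0e3,
    ms2_noise_peaks: int = 50,
    mz_jitter_ppm: float = 0.0,
    n_iso: int = 4,
    seed: int = 0,
    with_ms2: bool = True,
) -> tuple[ScanSeries, pd.DataFrame]:
    """Generate a CV-ramped MS1 series plus DDA MS2 scans and a manifest.

    With ``noise_peaks=0``, ``ms2_noise_peaks=0`` and ``mz_jitter_ppm=0``
    every MS1 peak sits exactly at a theoretical isotopologue m/z.  The same
    seed always yields a bit-identical series.
    """
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    t = 0.0
    scan_no = 0
    envelopes = {
        (p.class_name, p.species): isotope_envelope(
            p.entry(p.main_charge).formula, n=n_iso
        )
        for p in plants
    }
    for cv in schedule.values:
        for _ in range(scans_per_cv):
            mzs: list[float] = []
            ints: list[float] = []
            for plant in plants:
                env = envelopes[(plant.class_name, plant.species)]
                for z, abundance in sorted(plant.charges.items()):
                    amp = (
                        plant.base_intensity
                        * abundance
                        * _gauss(cv, plant.cv_center[z], plant.cv_width)
                    )
                    if amp <= 0:
                        continue
                    entry = plant.entry(z)
                    for i in range(len(env)):
                        mzs.append(entry.mz + i * C13_SPACING / z)
                        ints.append(amp * env[i])
            nm, ni = _noise(rng, noise_peaks, noise_intensity_mean)
            mz_arr = np.concatenate([np.asarray(mzs), nm])
            int_arr = np.concatenate([np.asarray(ints), ni])
            if mz_jitter_ppm > 0:
                mz_arr = mz_arr * (1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6, mz_arr.size))
            scan_no += 1
            spectra.append(
                Spectrum(
                    scan_id=f"scan={scan_no}",
                    ms_level=1,
                    mz=mz_arr,
                    intensity=int_arr,
                    faims_cv=float(cv),
                    scan_time=t,
                )
            )
            t += schedule.dwell / max(scans_per_cv, 1)
    if with_ms2:
        for plant in plants:
            z = plant.main_charge
            entry = plant.entry(z)
            cv = plant.cv_center[z]
            for activation in ("CID", "HCD", "UVPD"):
                fm, fi = _fragment_peaks(plant, activation)
                nm, ni = _noise(rng, ms2_noise_peaks, noise_intensity_mean, mz_lo=150.0)
                mz_arr = np.concatenate([np.asarray(fm), nm])
                int_arr = np.concatenate([np.asarray(fi), ni])
                if mz_jitter_ppm > 0:
                    mz_arr = mz_arr * (
                        1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6, mz_arr.size)
                    )
                scan_no += 1
                spectra.append(
                    Spectrum(
                        scan_id=f"scan={scan_no}",
                        ms_level=2,
                        mz=mz_arr,
                        intensity=int_arr,
                        activation=activation,
                        precursor_mz=entry.mz,
                        isolation_width=1.5,
                        faims_cv=float(cv),
                        scan_time=t,
                    )
                )
                t += 1.0
    manifest = pd.DataFrame(
        [
            {
                "class": p.class_name,
                "species": p.species,
                "label": f"{p.class_name} {p.species}",
                "charges": ";".join(str(z) for z in sorted(p.charges)),
                "main_z": p.main_charge,
                "mz_main": p.entry(p.main_charge).mz,
                "cv_center_main": p.cv_center[p.main_charge],
                "cv_width": p.cv_width,
                "base_intensity": p.base_intensity,
                "molecular": ";".join(sorted(p.molecular)) if p.molecular else "",
                "decoy": p.decoy,
            }
            for p in plants
        ]
    )
    return ScanSeries(spectra, source=f"synthetic(seed={seed})"), manifest


# ---------------------------------------------------------------------------
# Minimal mzML writer (centroid spectra, negative mode, per-scan FAIMS CV).
# Standards-conformant enough for pyteomics round trips; not a general
# exporter.

_ACTIVATION_CV = {
    "CID": ("MS:1000133", "collision-induced dissociation"),
    "HCD": ("MS:1000422", "beam-type collision-induced dissociation"),
    "UVPD": ("MS:1003247", "ultraviolet photodissociation"),
}


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _binary_xml(arr: np.ndarray, acc: str, name: str) -> str:
    data = _b64(arr)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
        f"<binary>{data}</binary></binaryDataArray>"
    )


def _spectrum_xml(spec: Spectrum, index: int) -> str:
    parts = [
        f'<spectrum index="{index}" id="{spec.scan_id}" defaultArrayLength="{spec.mz.size}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{spec.ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>',
        '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan"/>',
    ]
    parts.append("<scanList count=\"1\"><scan>")
    parts.append(
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{spec.scan_time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
    )
    if spec.faims_cv is not None:
        parts.append(
            f'<cvParam cvRef="MS" accession="MS:1001581" '
            f'name="FAIMS compensation voltage" value="{spec.faims_cv}"/>'
        )
    parts.append("</scan></scanList>")
    if spec.ms_level == 2:
        half = spec.isolation_width / 2.0
        acc, name = _ACTIVATION_CV.get(spec.activation or "HCD", _ACTIVATION_CV["HCD"])
        parts.append(
            '<precursorList count="1"><precursor>'
            "<isolationWindow>"
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{spec.precursor_mz}"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half}"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half}"/>'
            "</isolationWindow>"
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{spec.precursor_mz}"/>'
            "</selectedIon></selectedIonList>"
            f'<activation><cvParam cvRef="MS" accession="{acc}" name="{name}"/></activation>'
            "</precursor></precursorList>"
        )
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_xml(spec.mz, "MS:1000514", "m/z array"))
    parts.append(_binary_xml(spec.intensity, "MS:1000515", "intensity array"))
    parts.append("</binaryDataArrayList></spectrum>")
    return "".join(parts)


def write_mzml(series: ScanSeries, path) -> None:
    """Write a ScanSeries as centroid mzML with per-scan FAIMS CV metadata."""
    path = Path(path)
    body = "\n".join(_spectrum_xml(s, i) for i, s in enumerate(series))
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="gangliofaims" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="gangliofaims synthetic generator"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model"/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="gangliofaims">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML"/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(series)}" defaultDataProcessingRef="DP1">
{body}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(doc, encoding="utf-8")
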