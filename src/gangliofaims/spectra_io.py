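"""Scan model plus mzML and plain-text peak-list readers.

Everything downstream of I/O consumes only :class:`Spectrum` /
:class:`ScanSeries`.  Per-scan FAIMS compensation voltage, activation type
(CID/HCD/UVPD) and precursor m/z are first-class scan attributes because the
whole workflow pivots on them: MS1 extraction is CV-windowed, and MS/MS
evaluation combines activation-tagged spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "ScanSeries", "read_mzml", "read_peaklist"]

ACTIVATIONS = ("CID", "HCD", "UVPD")


@dataclass
class Spectrum:
    """One centroided scan."""

    scan_id: str
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    activation: str | None = None  # CID | HCD | UVPD | None
    precursor_mz: float | None = None
    isolation_width: float = 1.5
    faims_cv: float | None = None
    scan_time: float = 0.0  # seconds
    # provenance per peak (set of activations) — populated by combine_spectra
    provenance: list | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(self.mz.size)):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if self.provenance is not None:
                self.provenance = [self.provenance[i] for i in order]
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"MS2 scan {self.scan_id!r} without precursor m/z")
        if self.activation is not None and self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def window(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Peaks with lo <= m/z <= hi."""
        lo_i = np.searchsorted(self.mz, lo, side="left")
        hi_i = np.searchsorted(self.mz, hi, side="right")
        return self.mz[lo_i:hi_i], self.intensity[lo_i:hi_i]


@dataclass
class ScanSeries:
    """An ordered collection of scans from one acquisition."""

    spectra: list[Spectrum] = field(default_factory=list)
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [s.scan_time for s in self.spectra]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("scan times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def ms1(self, cv_range: tuple[float, float] | None = None) -> list[Spectrum]:
        """MS1 scans, optionally restricted to a CV window [lo, hi].

        Scans without CV metadata are kept regardless of the window
        (noFAIMS data passes through any CV restriction).
        """
        out = []
        for s in self.spectra:
            if s.ms_level != 1:
                continue
            if cv_range is not None and s.faims_cv is not None:
                if not (cv_range[0] <= s.faims_cv <= cv_range[1]):
                    continue
            out.append(s)
        return out

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    @property
    def has_cv(self) -> bool:
        return any(s.faims_cv is not None for s in self.spectra)

    def cv_values(self) -> list[float]:
        return sorted({s.faims_cv for s in self.spectra if s.faims_cv is not None})


# mzML activation terms -> internal labels (by accession and by name).
# Beam-type CID is HCD.
_ACTIVATION_BY_ACCESSION = {
    "MS:1000133": "CID",
    "MS:1000422": "HCD",
    "MS:1002481": "HCD",
    "MS:1003247": "UVPD",
    "MS:1000435": "UVPD",  # generic photodissociation
}
_ACTIVATION_BY_NAME = {
    "collision-induced dissociation": "CID",
    "beam-type collision-induced dissociation": "HCD",
    "higher energy beam-type collision-induced dissociation": "HCD",
    "ultraviolet photodissociation": "UVPD",
    "photodissociation": "UVPD",
}

_NS = "{http://psi.hupo.org/ms/mzml}"


def _params(elem) -> dict[str, str]:
    """cvParams of one element (non-recursive): name -> value, plus accessions."""
    out = {}
    for cv in elem.findall(f"{_NS}cvParam"):
        out[cv.get("name")] = cv.get("value", "")
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _decode_binary(bda) -> tuple[np.ndarray, dict]:
    import base64
    import zlib

    p = _params(bda)
    node = bda.find(f"{_NS}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in p or "zlib compression" in p:
        raw = zlib.decompress(raw)
    elif not ("MS:1000576" in p or "no compression" in p):
        unknown = [k for k in p if "compression" in k]
        if unknown:
            raise ValueError(f"unsupported binary compression: {unknown}")
    if "MS:1000521" in p or "32-bit float" in p:
        dtype = "<f4"
    else:
        dtype = "<f8"  # 64-bit float is the mzML default for m/z
    return np.frombuffer(raw, dtype=dtype).astype(float), p


def read_mzml(path) -> ScanSeries:
    """Read an mzML file into a :class:`ScanSeries`.

    A direct lxml-based reader: per-spectrum cvParams are resolved by
    accession (with name fallback).  FAIMS CV comes from the
    'FAIMS compensation voltage' cvParam (MS:1001581) at spectrum or scan
    level; activation from the precursor activation terms; binary arrays
    may be zlib-compressed 32- or 64-bit floats.  Profile spectra are
    centroided by local-maximum picking.  MS2 scans lacking a precursor
    are skipped (counted in ``metadata['skipped']``).
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    skipped = 0
    polarity = None
    try:
        context = etree.iterparse(str(path), events=("end",), tag=f"{_NS}spectrum")
        for _, elem in context:
            spec, pol = _spectrum_from_elem(elem)
            if pol and polarity is None:
                polarity = pol
            if spec is None:
                skipped += 1
            else:
                spectra.append(spec)
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise OSError(f"corrupt mzML file {path}: {exc}") from exc
    if not spectra:
        warnings.warn(f"{path}: no usable spectra")
    series = ScanSeries(spectra, source=str(path), metadata={"skipped": skipped})
    if polarity:
        series.metadata["polarity"] = polarity
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} MS2 scans without precursor")
    return series


def _get(params: dict, accession: str, name: str, default=None):
    if accession in params:
        return params[accession]
    return params.get(name, default)


def _spectrum_from_elem(elem) -> tuple[Spectrum | None, str | None]:
    p = _params(elem)
    ms_level = int(_get(p, "MS:1000511", "ms level", 1) or 1)
    polarity = "negative" if ("MS:1000129" in p or "negative scan" in p) else None
    cv = _get(p, "MS:1001581", "FAIMS compensation voltage")
    scan_time = 0.0
    for scan in elem.iter(f"{_NS}scan"):
        sp = _params(scan)
        t = _get(sp, "MS:1000016", "scan start time")
        if t is not None:
            scan_time = float(t)
            for cvp in scan.findall(f"{_NS}cvParam"):
                if cvp.get("accession") == "MS:1000016" and cvp.get("unitName") == "minute":
                    scan_time *= 60.0
        if cv is None:
            cv = _get(sp, "MS:1001581", "FAIMS compensation voltage")
    precursor = None
    activation = None
    iso_width = 1.5
    prec = elem.find(f"{_NS}precursorList/{_NS}precursor")
    if prec is not None:
        ion = prec.find(f"{_NS}selectedIonList/{_NS}selectedIon")
        if ion is not None:
            sel = _get(_params(ion), "MS:1000744", "selected ion m/z")
            if sel is not None:
                precursor = float(sel)
        iso = prec.find(f"{_NS}isolationWindow")
        if iso is not None:
            ip = _params(iso)
            lo = _get(ip, "MS:1000828", "isolation window lower offset")
            hi = _get(ip, "MS:1000829", "isolation window upper offset")
            if lo is not None and hi is not None:
                iso_width = float(lo) + float(hi)
        act = prec.find(f"{_NS}activation")
        if act is not None:
            ap = _params(act)
            for acc, label in _ACTIVATION_BY_ACCESSION.items():
                if acc in ap:
                    activation = label
                    break
            if activation is None:
                for name, label in _ACTIVATION_BY_NAME.items():
                    if name in ap:
                        activation = label
                        break
    if ms_level >= 2 and precursor is None:
        return None, polarity
    mz = np.empty(0)
    inten = np.empty(0)
    for bda in elem.iter(f"{_NS}binaryDataArray"):
        arr, bp = _decode_binary(bda)
        if "MS:1000514" in bp or "m/z array" in bp:
            mz = arr
        elif "MS:1000515" in bp or "intensity array" in bp:
            inten = arr
    if "MS:1000128" in p or "profile spectrum" in p:
        mz, inten = _centroid(mz, inten)
    return (
        Spectrum(
            scan_id=str(elem.get("id", elem.get("index", ""))),
            ms_level=ms_level,
            mz=mz,
            intensity=inten,
            activation=activation,
            precursor_mz=precursor,
            isolation_width=iso_width,
            faims_cv=None if cv in (None, "") else float(cv),
            scan_time=scan_time,
        ),
        polarity,
    )


def _centroid(mz: np.ndarray, inten: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking for profile data."""
    if mz.size < 3:
        keep = inten > floor
        return mz[keep], inten[keep]
    is_max = (inten[1:-1] >= inten[:-2]) & (inten[1:-1] > inten[2:]) & (inten[1:-1] > floor)
    idx = np.where(is_max)[0] + 1
    return mz[idx], inten[idx]


def read_peaklist(path) -> Spectrum:
    """Read a two-column (m/z, intensity) text peak list.

    Leading ``#key=value`` lines set scan attributes: ``level``,
    ``activation``, ``precursor``, ``cv``, ``scan_time``, ``id``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    mzs: list[float] = []
    intens: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip().lower()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'm/z intensity'")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if i < 0:
                raise ValueError(f"{path}:{lineno}: negative intensity")
            mzs.append(m)
            intens.append(i)
    return Spectrum(
        scan_id=meta.get("id", path.stem),
        ms_level=int(meta.get("level", 1)),
        mz=np.array(mzs),
        intensity=np.array(intens),
        activation=meta.get("activation", "").upper() or None,
        precursor_mz=float(meta["precursor"]) if "precursor" in meta else None,
        faims_cv=float(meta["cv"]) if "cv" in meta else None,
        scan_time=float(meta.get("scan_time", 0.0)),
    )
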