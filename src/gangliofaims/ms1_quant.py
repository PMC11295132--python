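"""Direct-infusion MS1 quantitation of mass-list targets.

For every target ion the extractor collects, in each MS1 scan, the summed
peak intensity inside a ppm window around the monoisotopic m/z and a
configurable number of isotopologues (spaced by the 13C mass defect over
the charge), then aggregates across scans with one of three surrogate
modes: median, mean or sum.  Peaks that co-fall in one window are summed
before aggregation, which is robust against split/merged centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_core import C13_SPACING, MAX_ISOTOPOLOGUES
from .masslist import MassListEntry
from .spectra_io import ScanSeries, Spectrum

__all__ = ["IsotopologueSet", "extract_isotopologues", "quantify_all"]

MODES = ("median", "mean", "sum")


@dataclass
class IsotopologueSet:
    """Measured (and later corrected) isotopologue intensities of one target."""

    entry: MassListEntry
    per_scan: np.ndarray  # shape (n_scans, n_iso): per-scan in-window sums
    surrogates: np.ndarray  # shape (n_iso,): aggregated across scans
    mode: str
    tol_ppm: float
    corrected: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_iso(self) -> int:
        return int(self.surrogates.size)

    def iso_mz(self, i: int) -> float:
        """Theoretical m/z of isotopologue m+i at the entry's charge."""
        return self.entry.mz + i * C13_SPACING / self.entry.z

    def value(self, i: int = 0) -> float:
        """Corrected (if available) else measured surrogate of m+i."""
        arr = self.corrected if self.corrected is not None else self.surrogates
        return float(arr[i])

    @property
    def quantity(self) -> float:
        """The reported analyte quantity: corrected m+0 surrogate."""
        return self.value(0)


def _aggregate(per_scan: np.ndarray, mode: str) -> np.ndarray:
    if mode == "median":
        return np.median(per_scan, axis=0)
    if mode == "mean":
        return per_scan.mean(axis=0)
    if mode == "sum":
        return per_scan.sum(axis=0)
    raise ValueError(f"unknown aggregation mode {mode!r}; pick one of {MODES}")


def extract_isotopologues(
    series: ScanSeries | list[Spectrum],
    entry: MassListEntry,
    n_iso: int = 2,
    tol_ppm: float = 5.0,
    mode: str = "sum",
    cv_range: tuple[float, float] | None = None,
) -> IsotopologueSet:
    """Extract m+0..m+(n_iso-1) intensity surrogates for one target.

    ``cv_range`` restricts the MS1 scans used (FAIMS mode); scans without
    CV metadata always participate.
    """
    if not 1 <= n_iso <= MAX_ISOTOPOLOGUES:
        raise ValueError(f"n_iso must be in 1..{MAX_ISOTOPOLOGUES}")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive (ppm)")
    if mode not in MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}; pick one of {MODES}")
    scans = series.ms1(cv_range) if isinstance(series, ScanSeries) else list(series)
    if not scans:
        raise ValueError("no MS1 scans to quantify from")
    targets = np.array([entry.mz + i * C13_SPACING / entry.z for i in range(n_iso)])
    half = targets * tol_ppm * 1e-6
    per_scan = np.zeros((len(scans), n_iso))
    for si, scan in enumerate(scans):
        for ii in range(n_iso):
            _, inten = scan.window(targets[ii] - half[ii], targets[ii] + half[ii])
            per_scan[si, ii] = inten.sum()
    return IsotopologueSet(
        entry=entry,
        per_scan=per_scan,
        surrogates=_aggregate(per_scan, mode),
        mode=mode,
        tol_ppm=tol_ppm,
    )


def quantify_all(
    series: ScanSeries,
    masslist: list[MassListEntry],
    n_iso: int = 2,
    tol_ppm: float = 5.0,
    mode: str = "sum",
    cv_table=None,
    faims: bool = False,
) -> list[IsotopologueSet]:
    """One IsotopologueSet per mass-list entry.

    With ``faims=True`` and a CV range table, each entry's extraction is
    restricted to the expected CV window of its (class, charge); entries
    absent from the table use all scans.
    """
    out = []
    for entry in masslist:
        cv_range = None
        if faims and cv_table is not None:
            cv_range = cv_table.get(entry.class_name, entry.z)
        out.append(
            extract_isotopologues(
                series, entry, n_iso=n_iso, tol_ppm=tol_ppm, mode=mode, cv_range=cv_range
            )
        )
    return out
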