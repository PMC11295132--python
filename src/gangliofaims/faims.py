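"""FAIMS compensation-voltage schedules, transmission profiles and filtering.

FAIMS transmits, at a given compensation voltage (CV), only ions whose
differential mobility matches — for gangliosides the transmitted window is
set by the glycan headgroup and the charge state, not the ceramide.  Ramping
the CV therefore yields, per analyte class and charge, a unimodal intensity
profile whose apex (CVmax) acts as an orthogonal identifier, much like
retention time in chromatography.  This module builds CV schedules, extracts
profiles from CV-tagged MS1 scan series, estimates CVmax and the transmission
range, and checks annotation evidence against expected CV ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masslist import MassListEntry
from .ms1_quant import extract_isotopologues
from .spectra_io import ScanSeries

__all__ = [
    "CVSchedule",
    "CVProfile",
    "CVRangeTable",
    "build_schedule",
    "profile",
    "cv_filter",
]


@dataclass(frozen=True)
class CVSchedule:
    """A stepped CV program: which voltages are visited and for how long."""

    values: tuple[float, ...]
    dwell: float  # seconds per step

    def __post_init__(self):
        if not self.values:
            raise ValueError("empty CV schedule")
        if self.dwell <= 0:
            raise ValueError("dwell time must be positive")

    @property
    def duration(self) -> float:
        """Total program time in seconds."""
        return len(self.values) * self.dwell

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_list(cls, values, dwell: float) -> "CVSchedule":
        return cls(tuple(float(v) for v in values), float(dwell))


def build_schedule(start: float, end: float, step: float, dwell: float) -> CVSchedule:
    """Arithmetic CV ramp from ``start`` to at most ``end`` (inclusive)."""
    if step <= 0:
        raise ValueError("CV step must be positive")
    if end < start:
        raise ValueError("end CV below start CV")
    n = int(np.floor((end - start) / step + 1e-9)) + 1
    return CVSchedule(tuple(start + i * step for i in range(n)), float(dwell))


@dataclass
class CVProfile:
    """Per-CV aggregated m+0 intensity of one analyte ion."""

    class_name: str
    z: int
    cvs: np.ndarray
    intensities: np.ndarray
    threshold_fraction: float = 0.1
    indeterminate_ratio: float = 2.0

    def __post_init__(self):
        self.cvs = np.asarray(self.cvs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        order = np.argsort(self.cvs)
        self.cvs, self.intensities = self.cvs[order], self.intensities[order]

    @property
    def empty(self) -> bool:
        return self.cvs.size == 0 or float(self.intensities.max(initial=0.0)) <= 0.0

    @property
    def indeterminate(self) -> bool:
        """Flat response (no usable apex), as seen for monosialylated classes.

        Declared when the profile maximum is less than ``indeterminate_ratio``
        times the median intensity.
        """
        if self.empty:
            return True
        med = float(np.median(self.intensities))
        if med <= 0:
            return False
        return float(self.intensities.max()) / med < self.indeterminate_ratio

    @property
    def cvmax(self) -> float | None:
        """CV of maximal transmission; None when flat or empty."""
        if self.empty or self.indeterminate:
            return None
        return float(self.cvs[int(np.argmax(self.intensities))])

    @property
    def cv_range(self) -> tuple[float, float] | None:
        """Maximal contiguous CV span with intensity >= threshold x max."""
        if self.empty:
            return None
        thr = self.threshold_fraction * float(self.intensities.max())
        above = self.intensities >= thr
        apex = int(np.argmax(self.intensities))
        lo = apex
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = apex
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        return float(self.cvs[lo]), float(self.cvs[hi])

    @property
    def weighted_cv(self) -> float | None:
        """Intensity-weighted mean CV of the profile."""
        if self.empty:
            return None
        return float(np.average(self.cvs, weights=self.intensities))


def profile(series: ScanSeries, entry: MassListEntry, tol_ppm: float = 5.0) -> CVProfile:
    """CV transmission profile of one mass-list entry from a CV-ramp run.

    The m+0 intensity is extracted per scan (summed in-window) and summed
    over the scans sharing each distinct CV.
    """
    if not series.has_cv:
        raise ValueError(
            "scan series carries no FAIMS CV metadata; run in noFAIMS mode instead"
        )
    ms1 = [s for s in series.ms1() if s.faims_cv is not None]
    cvs = sorted({s.faims_cv for s in ms1})
    if not cvs:
        raise ValueError("no CV-tagged MS1 scans to profile from")
    intensities = []
    for cv in cvs:
        scans = [s for s in ms1 if s.faims_cv == cv]
        iset = extract_isotopologues(scans, entry, n_iso=1, tol_ppm=tol_ppm, mode="sum")
        intensities.append(iset.surrogates[0])
    prof = CVProfile(
        class_name=entry.class_name, z=entry.z, cvs=np.array(cvs), intensities=np.array(intensities)
    )
    if prof.empty:
        warnings.warn(f"{entry.label} {entry.ion}: all-zero CV profile")
    return prof


@dataclass
class CVRangeTable:
    """Expected transmission CV windows per (class, charge state)."""

    ranges: dict[tuple[str, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for key, (lo, hi) in self.ranges.items():
            if lo >= hi:
                raise ValueError(f"invalid CV range for {key}: [{lo}, {hi}]")

    @classmethod
    def default(cls) -> "CVRangeTable":
        # The two windows established for the reference classes; extend via
        # set()/from_tsv with values measured on your own instrument.
        return cls({("GD1", 2): (37.0, 51.0), ("GT1", 3): (57.0, 73.0)})

    def get(self, class_name: str, z: int) -> tuple[float, float] | None:
        return self.ranges.get((class_name, z))

    def set(self, class_name: str, z: int, lo: float, hi: float) -> None:
        if lo >= hi:
            raise ValueError(f"invalid CV range [{lo}, {hi}]")
        self.ranges[(class_name, z)] = (float(lo), float(hi))

    @classmethod
    def from_tsv(cls, path) -> "CVRangeTable":
        df = pd.read_csv(path, sep="\t")
        need = {"class", "z", "lo_V", "hi_V"}
        if not need.issubset(df.columns):
            raise ValueError(f"CV table {path} missing columns {sorted(need - set(df.columns))}")
        return cls(
            {
                (str(df["class"].iat[i]), int(df["z"].iat[i])): (
                    float(df["lo_V"].iat[i]),
                    float(df["hi_V"].iat[i]),
                )
                for i in range(len(df))
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"class": c, "z": z, "lo_V": lo, "hi_V": hi}
            for (c, z), (lo, hi) in sorted(self.ranges.items())
        ]
        pd.DataFrame(rows, columns=["class", "z", "lo_V", "hi_V"]).to_csv(
            path, sep="\t", index=False
        )


def cv_filter(
    class_name: str,
    z: int,
    table: CVRangeTable,
    cv_evidence: list[tuple[float, float]],
) -> tuple[bool, str]:
    """Check CV consistency of an annotation's supporting evidence.

    ``cv_evidence`` is a list of (CV, weight) pairs (e.g. per-CV MS1
    intensities or MS2 scan CVs with unit weight).  Passes when the
    intensity-weighted mean CV lies inside the expected window; a class/charge
    absent from the table passes with an 'unvalidated' note.
    """
    rng = table.get(class_name, z)
    if rng is None:
        return True, "unvalidated: no expected CV range for this class/charge"
    if not cv_evidence:
        return True, "unvalidated: no CV-tagged evidence"
    cvs = np.array([c for c, _ in cv_evidence], dtype=float)
    w = np.array([max(wt, 0.0) for _, wt in cv_evidence], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    mean_cv = float(np.average(cvs, weights=w))
    ok = rng[0] <= mean_cv <= rng[1]
    note = f"weighted CV {mean_cv:.1f} V {'within' if ok else 'outside'} [{rng[0]:g}, {rng[1]:g}] V"
    return ok, note
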