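"""End-to-end orchestration: mass list -> MS1 quant -> isotope correction ->
MS/MS decision rules -> CV filtering -> report.

Defaults mirror the reference acquisition settings: MS1 tolerance 5 ppm,
MS/MS tolerance 10 ppm, m+0/m+1 isotopologues aggregated in 'sum' mode, and
combined (sum) CID/HCD/UVPD evaluation.  The run is deterministic for a
given configuration and input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import isotope_correction, ms1_quant
from .faims import CVRangeTable, cv_filter, profile
from .masslist import GangliosideClass, MassListEntry, read_masslist
from .msms_rules import (
    Annotation,
    DecisionRuleSet,
    Rejection,
    assign_molecular_species,
    combine_spectra,
    evaluate,
    split_quantity,
)
from .spectra_io import ScanSeries, read_mzml

__all__ = ["RunConfig", "RunResult", "run"]

# Sialylation tiers used for summary counting: mono-, di-, tri- and
# quadruply-or-higher sialylated.
_TIERS = ((1, "GM"), (2, "GD"), (3, "GT"), (4, "GQup"))


def _tier(neuac: int) -> str:
    if neuac >= 4:
        return "GQup"
    for n, name in _TIERS:
        if neuac == n:
            return name
    return "other"


@dataclass
class RunConfig:
    """Everything a run needs; paths or in-memory objects interchangeably."""

    mzml: str | Path | ScanSeries = ""
    masslist: str | Path | list[MassListEntry] = ""
    ms1_tol_ppm: float = 5.0
    msms_tol_ppm: float = 10.0
    n_iso: int = 2
    mode: str = "sum"
    faims: bool | None = None  # None -> auto-detect from CV metadata
    combine: str = "sum"
    rules: str | Path | DecisionRuleSet | None = None
    cv_table: str | Path | CVRangeTable | None = None


@dataclass
class RunResult:
    annotations: list[Annotation] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    report: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list[str] = field(default_factory=list)

    @property
    def species_count(self) -> int:
        """Distinct (class, sum composition) with level >= species."""
        return len({(a.entry.class_name, a.entry.species) for a in self.annotations})

    @property
    def id_count(self) -> int:
        """Species count plus molecular-species identifications."""
        molecular = {
            (a.entry.class_name, a.entry.species, label)
            for a in self.annotations
            for label in a.partition
        }
        return self.species_count + len(molecular)


def _load(config: RunConfig):
    series = config.mzml if isinstance(config.mzml, ScanSeries) else read_mzml(config.mzml)
    entries = (
        config.masslist
        if isinstance(config.masslist, list)
        else read_masslist(config.masslist)
    )
    if isinstance(config.rules, DecisionRuleSet):
        rules = config.rules
    elif config.rules:
        rules = DecisionRuleSet.from_yaml(config.rules)
    else:
        rules = DecisionRuleSet.default()
    rules.tolerance_ppm = config.msms_tol_ppm
    if isinstance(config.cv_table, CVRangeTable):
        table = config.cv_table
    elif config.cv_table:
        table = CVRangeTable.from_tsv(config.cv_table)
    else:
        table = CVRangeTable.default()
    return series, entries, rules, table


def run(config: RunConfig) -> RunResult:
    """Execute the full annotation workflow."""
    series, entries, rules, table = _load(config)
    result = RunResult()
    log = result.log
    faims_mode = series.has_cv if config.faims is None else config.faims
    if config.faims is None:
        log.append(f"FAIMS mode auto-detected: {'on' if faims_mode else 'off'}")
    if not faims_mode and series.has_cv:
        log.append("CV metadata present but FAIMS mode off: CV filter skipped")

    classes = {name: GangliosideClass.from_name(name) for name in {e.class_name for e in entries}}

    # MS1 quantitation, CV-windowed per entry when in FAIMS mode
    sets = ms1_quant.quantify_all(
        series,
        entries,
        n_iso=config.n_iso,
        tol_ppm=config.ms1_tol_ppm,
        mode=config.mode,
        cv_table=table if faims_mode else None,
        faims=faims_mode,
    )
    detected = [s for s in sets if s.surrogates[0] > 0]
    log.append(f"MS1: {len(detected)}/{len(sets)} targets with nonzero m+0 surrogate")

    isotope_correction.correct(detected, tol_ppm=config.ms1_tol_ppm)

    # MS2 scan assignment: each scan goes to the nearest detected precursor
    by_entry: dict[int, list] = {}
    mzs = np.array([s.entry.mz for s in detected])
    for scan in series.ms2():
        if mzs.size == 0:
            break
        idx = int(np.argmin(np.abs(mzs - scan.precursor_mz)))
        half = max(scan.isolation_width / 2.0, mzs[idx] * config.msms_tol_ppm * 1e-6)
        if abs(mzs[idx] - scan.precursor_mz) <= half:
            by_entry.setdefault(idx, []).append(scan)

    for idx, scans in sorted(by_entry.items()):
        iset = detected[idx]
        entry = iset.entry
        combined = combine_spectra(scans, method=config.combine, tol_ppm=config.msms_tol_ppm)
        outcome = evaluate(entry, classes[entry.class_name], combined, rules)
        if isinstance(outcome, Rejection):
            result.rejections.append(outcome)
            log.append(f"rejected {entry.label} {entry.ion}: missing {outcome.missing}")
            continue
        annotation = assign_molecular_species(outcome, combined, rules)
        annotation.quantity = iset.quantity
        if annotation.partition:
            annotation.molecular_quantities = split_quantity(
                annotation.quantity, annotation.partition
            )
        if faims_mode:
            prof = profile(series, entry, tol_ppm=config.ms1_tol_ppm)
            evidence = [(cv, i) for cv, i in zip(prof.cvs, prof.intensities) if i > 0]
            evidence.extend((s.faims_cv, 0.0) for s in scans if s.faims_cv is not None)
            annotation.cv_evidence = prof.weighted_cv
            ok, note = cv_filter(entry.class_name, entry.z, table, evidence)
            annotation.cv_pass, annotation.cv_note = ok, note
            if not ok:
                log.append(f"CV filter failed for {entry.label} {entry.ion}: {note}")
        result.annotations.append(annotation)

    passed = [a for a in result.annotations if a.cv_pass is not False]
    result.report = _report_frame(result.annotations)
    result.counts = _counts_frame(passed, classes)
    log.append(
        f"annotated {len(passed)} targets "
        f"({result.species_count} species, {result.id_count} IDs incl. molecular)"
    )
    return result


def _report_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "class": a.entry.class_name,
                "species": a.entry.species,
                "molecular_species": ";".join(
                    f"{label}:{frac:.4f}" for label, frac in a.partition.items()
                ),
                "ion": a.entry.ion,
                "z": a.entry.z,
                "level": a.level,
                "quantity": a.quantity,
                "cv_weighted": a.cv_evidence,
                "cv_pass": a.cv_pass,
                "cv_note": a.cv_note,
                "fragments": ";".join(f"{m.name}@{m.ppm:+.1f}ppm" for m in a.fragments),
            }
        )
    cols = [
        "class", "species", "molecular_species", "ion", "z", "level",
        "quantity", "cv_weighted", "cv_pass", "cv_note", "fragments",
    ]
    return pd.DataFrame(rows, columns=cols)


def _counts_frame(
    annotations: list[Annotation], classes: dict[str, GangliosideClass]
) -> pd.DataFrame:
    per_class: dict[str, set] = {}
    per_tier: dict[str, set] = {}
    for a in annotations:
        key = (a.entry.class_name, a.entry.species)
        per_class.setdefault(a.entry.class_name, set()).add(key)
        tier = _tier(classes[a.entry.class_name].neuac)
        per_tier.setdefault(tier, set()).add(key)
    rows = [
        {"group": "class", "name": name, "species": len(keys)}
        for name, keys in sorted(per_class.items())
    ]
    rows += [
        {"group": "tier", "name": name, "species": len(keys)}
        for name, keys in sorted(per_tier.items())
    ]
    return pd.DataFrame(rows, columns=["group", "name", "species"])
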