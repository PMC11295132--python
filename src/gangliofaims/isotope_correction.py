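"""Iterative isotope-overlap correction for co-isolated targets.

In direct infusion, the m+k isotopologues of one species routinely fall on
the monoisotopic peak of another (different charge states make fractional
spacings collide).  The correction walks the overlap graph starting from
species whose quantified isotopologues receive no contribution from any
not-yet-corrected species, projects each such species' theoretical envelope
(up to m+5) from a hybrid m+0 estimate, subtracts the projected intensities
from every overlapped isotopologue of the remaining species, and repeats.
The hybrid m+0 averages the measured m+0 with a back-calculation from m+1,
because m+1 is typically less contaminated by foreign envelopes.

Mutual-overlap cycles (not covered by the iterative rule) are broken by
correcting the member with the largest hybrid m+0 first; subtraction is
floored at zero.  Both events are flagged on the affected sets.
"""

from __future__ import annotations

import warnings

import numpy as np

from .chem_core import IsotopeEnvelope, isotope_envelope, MAX_ISOTOPOLOGUES
from .ms1_quant import IsotopologueSet

__all__ = ["hybrid_m0", "overlap_edges", "correct"]


def hybrid_m0(iset: IsotopologueSet, envelope: IsotopeEnvelope) -> float:
    """Estimated m+0 intensity: mean of measured m+0 and m+1/r1.

    Falls back to the (current) m+0 value when m+1 was not quantified or
    the envelope has no m+1 abundance.
    """
    i0 = iset.value(0)
    if iset.n_iso < 2:
        return i0
    if len(envelope) < 2 or envelope[1] <= 0.0:
        warnings.warn(
            f"{iset.entry.label} {iset.entry.ion}: r1 = 0, hybrid m+0 falls back to measured m+0"
        )
        return i0
    i1 = iset.value(1)
    return 0.5 * (i0 + i1 / envelope[1])


def _theoretical_mzs(iset: IsotopologueSet, n: int = MAX_ISOTOPOLOGUES) -> np.ndarray:
    return np.array([iset.iso_mz(i) for i in range(n)])


def overlap_edges(sets: list[IsotopologueSet], tol_ppm: float) -> list[tuple[int, int]]:
    """Directed edges (a, b): any theoretical isotopologue of ``a`` (m+0..m+5)
    falls within tolerance of a *quantified* isotopologue m/z of ``b``."""
    edges = []
    theo = [_theoretical_mzs(s) for s in sets]
    quant = [np.array([s.iso_mz(i) for i in range(s.n_iso)]) for s in sets]
    for a in range(len(sets)):
        for b in range(len(sets)):
            if a == b:
                continue
            diff = np.abs(theo[a][:, None] - quant[b][None, :])
            lim = quant[b][None, :] * tol_ppm * 1e-6
            if np.any(diff <= lim):
                edges.append((a, b))
    return edges


def correct(
    sets: list[IsotopologueSet],
    tol_ppm: float = 5.0,
    envelopes: dict[int, IsotopeEnvelope] | None = None,
) -> list[IsotopologueSet]:
    """Apply the iterative overlap correction in place; returns ``sets``.

    ``envelopes`` may pre-supply theoretical envelopes keyed by list index;
    otherwise they are computed from each entry's formula.  Results are
    independent of the input ordering: each wave corrects every currently
    unaffected species from its own (already settled) values before any
    subtraction of that wave is visible to the next.
    """
    n = len(sets)
    for s in sets:
        if s.corrected is None:
            s.corrected = s.surrogates.astype(float).copy()
    if n <= 1:
        return sets
    envs = {
        i: (envelopes[i] if envelopes and i in envelopes else isotope_envelope(s.entry.formula))
        for i, s in enumerate(sets)
    }
    edges = overlap_edges(sets, tol_ppm)
    incoming: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in edges:
        incoming[b].add(a)
    # overlap positions cached: (a, b) -> list of (iso index of a, iso index of b)
    hits: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in edges:
        pairs = []
        for ia in range(MAX_ISOTOPOLOGUES):
            mz_a = sets[a].iso_mz(ia)
            for ib in range(sets[b].n_iso):
                mz_b = sets[b].iso_mz(ib)
                if abs(mz_a - mz_b) <= mz_b * tol_ppm * 1e-6:
                    pairs.append((ia, ib))
        hits[(a, b)] = pairs

    pending = set(range(n))
    while pending:
        ready = [i for i in pending if not (incoming[i] & pending)]
        if not ready:
            # mutual-overlap cycle: settle the dominant member first
            ready = [max(pending, key=lambda i: (hybrid_m0(sets[i], envs[i]), -i))]
            sets[ready[0]].flags.append("cycle-break")
        # compute contributions of the whole wave before applying any of them
        contributions: list[tuple[int, int, float]] = []  # (target, iso index, amount)
        for a in ready:
            m0 = hybrid_m0(sets[a], envs[a])
            if m0 <= 0:
                continue
            theo_int = np.array(
                [m0 * envs[a][i] if i < len(envs[a]) else 0.0 for i in range(MAX_ISOTOPOLOGUES)]
            )
            for b in pending:
                if b in ready or (a, b) not in hits:
                    continue
                for ia, ib in hits[(a, b)]:
                    contributions.append((b, ib, theo_int[ia]))
        for b, ib, amount in contributions:
            new = sets[b].corrected[ib] - amount
            if new < 0:
                new = 0.0
                if "floored" not in sets[b].flags:
                    sets[b].flags.append("floored")
            sets[b].corrected[ib] = new
        pending -= set(ready)
    return sets
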