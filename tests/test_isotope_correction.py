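"""Iterative isotope-overlap correction vs a hand-coded subtraction oracle."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from gangliofaims.chem_core import C13_SPACING, IsotopeEnvelope
from gangliofaims.isotope_correction import correct, hybrid_m0, overlap_edges
from gangliofaims.masslist import MassListEntry
from gangliofaims.ms1_quant import IsotopologueSet

from gangliofaims.chem_core import ElementalFormula

TOL = 5.0
PLACEHOLDER = ElementalFormula(C=1)  # envelopes are always passed explicitly


def make_set(mz: float, z: int, measured, name="X") -> IsotopologueSet:
    measured = np.asarray(measured, dtype=float)
    entry = MassListEntry(
        class_name=name,
        species="0:0;O2",
        formula=PLACEHOLDER,
        neutral_mass=mz * z,  # not used by the correction
        z=z,
        mz=mz,
    )
    return IsotopologueSet(
        entry=entry,
        per_scan=measured[None, :],
        surrogates=measured.copy(),
        mode="sum",
        tol_ppm=TOL,
    )


# ---------------------------------------------------------------------------
# independent oracle: plain-python sequential subtraction


def oracle_correct(sets_data, tol_ppm=TOL, n_theo=6):
    """sets_data: list of dicts {mz, z, measured(list), env(list, r0=1)}.

    Returns corrected lists.  Brute-force re-scan of 'who is unaffected'
    each round; cycles broken at the largest hybrid m+0.
    """
    data = copy.deepcopy(sets_data)
    for d in data:
        d["corr"] = list(d["measured"])

    def iso_mz(d, i):
        return d["mz"] + i * C13_SPACING / d["z"]

    def overlaps(a, b):  # a's theoretical isotopologues onto b's quantified
        out = []
        for ia in range(n_theo):
            for ib in range(len(b["measured"])):
                if abs(iso_mz(a, ia) - iso_mz(b, ib)) <= iso_mz(b, ib) * tol_ppm * 1e-6:
                    out.append((ia, ib))
        return out

    def hyb(d):
        if len(d["corr"]) >= 2 and len(d["env"]) >= 2 and d["env"][1] > 0:
            return 0.5 * (d["corr"][0] + d["corr"][1] / d["env"][1])
        return d["corr"][0]

    pending = list(range(len(data)))
    while pending:
        ready = []
        for i in pending:
            affected = False
            for j in pending:
                if j != i and overlaps(data[j], data[i]):
                    affected = True
            if not affected:
                ready.append(i)
        if not ready:
            ready = [max(pending, key=lambda i: (hyb(data[i]), -i))]
        for i in ready:
            m0 = hyb(data[i])
            if m0 <= 0:
                continue
            for j in pending:
                if j == i or j in ready:
                    continue
                for ia, ib in overlaps(data[i], data[j]):
                    contrib = m0 * (data[i]["env"][ia] if ia < len(data[i]["env"]) else 0.0)
                    data[j]["corr"][ib] = max(0.0, data[j]["corr"][ib] - contrib)
        pending = [i for i in pending if i not in ready]
    return [d["corr"] for d in data]


def env(ratios) -> IsotopeEnvelope:
    return IsotopeEnvelope(tuple(ratios))


# ---------------------------------------------------------------------------
# hybrid m+0


def test_hybrid_consistent_envelope():
    s = make_set(1000.0, 1, [100.0, 50.0])
    assert hybrid_m0(s, env([1.0, 0.5])) == pytest.approx(100.0)


def test_hybrid_m1_not_quantified_falls_back():
    s = make_set(1000.0, 1, [100.0])
    assert hybrid_m0(s, env([1.0, 0.5])) == pytest.approx(100.0)


def test_hybrid_recovers_suppressed_m0():
    s = make_set(1000.0, 1, [80.0, 60.0])
    assert hybrid_m0(s, env([1.0, 0.5])) == pytest.approx(100.0)


def test_hybrid_zero_r1_warns_and_falls_back():
    s = make_set(1000.0, 1, [80.0, 60.0])
    with pytest.warns(UserWarning, match="r1"):
        assert hybrid_m0(s, env([1.0, 0.0])) == pytest.approx(80.0)


# ---------------------------------------------------------------------------
# correction behaviour


def test_no_overlap_is_identity():
    a = make_set(1000.0, 1, [100.0, 10.0], "A")
    b = make_set(1200.0, 1, [200.0, 20.0], "B")
    correct([a, b], TOL, envelopes={0: env([1.0, 0.1]), 1: env([1.0, 0.1])})
    assert np.array_equal(a.corrected, a.surrogates)
    assert np.array_equal(b.corrected, b.surrogates)
    assert overlap_edges([a, b], TOL) == []


def test_hand_worked_two_species_subtraction():
    """A's m+2 lands on B's m+0: B corrected = 500 - 1000 x 0.2 = 300."""
    a = make_set(1000.0, 1, [1000.0], "A")
    b = make_set(a.iso_mz(2), 1, [500.0], "B")
    correct([a, b], TOL, envelopes={0: env([1.0, 0.3, 0.2]), 1: env([1.0, 0.3])})
    assert a.corrected[0] == pytest.approx(1000.0)
    assert b.corrected[0] == pytest.approx(300.0)


def test_subtraction_floors_at_zero_and_flags():
    a = make_set(1000.0, 1, [1000.0], "A")
    b = make_set(a.iso_mz(2), 1, [150.0], "B")
    correct([a, b], TOL, envelopes={0: env([1.0, 0.3, 0.2]), 1: env([1.0, 0.3])})
    assert b.corrected[0] == 0.0
    assert "floored" in b.flags


def test_correction_never_increases_intensity(demo_series, demo_masslist):
    from gangliofaims.ms1_quant import quantify_all

    series, _ = demo_series
    sets = quantify_all(series, demo_masslist, n_iso=2)
    before = [s.surrogates.copy() for s in sets]
    correct(sets, TOL)
    for s, b in zip(sets, before):
        assert np.all(s.corrected <= b + 1e-9)


def test_noiseless_two_species_parameter_recovery():
    """Known ground-truth abundances recovered within 1e-3 relative."""
    ra = [1.0, 0.8, 0.4, 0.15, 0.05, 0.01]
    rb = [1.0, 0.7, 0.3]
    qa, qb = 5000.0, 800.0
    a_mz = 900.0
    a = make_set(a_mz, 2, [qa * r for r in ra[:2]], "A")
    b_mz = a.iso_mz(3)  # B's m+0 sits on A's m+3
    # B measured values carry A's envelope contribution on both isotopologues
    b_meas = [qb * rb[0] + qa * ra[3], qb * rb[1] + qa * ra[4]]
    b = make_set(b_mz, 2, b_meas, "B")
    correct([a, b], TOL, envelopes={0: env(ra), 1: env(rb)})
    assert a.corrected[0] == pytest.approx(qa, rel=1e-9)
    assert b.corrected[0] == pytest.approx(qb, rel=1e-3)
    assert b.corrected[1] == pytest.approx(qb * rb[1], rel=1e-3)


def _random_scenario(rng):
    """Two or three species with engineered isotopologue collisions."""
    n_species = int(rng.integers(2, 4))
    z = int(rng.integers(1, 4))
    base = float(rng.uniform(400, 1500))
    specs = []
    mz = base
    for k in range(n_species):
        if k > 0:
            # place this species on an isotopologue of the previous one, or apart
            if rng.random() < 0.7:
                shift = int(rng.integers(1, 5))
                mz = specs[-1]["mz"] + shift * C13_SPACING / z
            else:
                mz = specs[-1]["mz"] + float(rng.uniform(5, 20))
        envr = [1.0] + sorted(rng.uniform(0.01, 1.2, 5).tolist(), reverse=True)
        n_iso = int(rng.integers(1, 3))
        measured = rng.uniform(10, 5000, n_iso).tolist()
        specs.append({"mz": mz, "z": z, "measured": measured, "env": envr})
    return specs


def test_matches_oracle_on_randomized_scenarios():
    """50 seeded two/three-species overlap scenarios agree to 1e-9."""
    rng = np.random.default_rng(123)
    for _ in range(50):
        specs = _random_scenario(rng)
        sets = [
            make_set(d["mz"], d["z"], d["measured"], f"S{i}") for i, d in enumerate(specs)
        ]
        correct(sets, TOL, envelopes={i: env(d["env"]) for i, d in enumerate(specs)})
        expected = oracle_correct(specs)
        for s, exp in zip(sets, expected):
            assert np.allclose(s.corrected, exp, rtol=0, atol=1e-9), specs


def test_order_independence():
    rng = np.random.default_rng(321)
    for _ in range(10):
        specs = _random_scenario(rng)
        sets1 = [make_set(d["mz"], d["z"], d["measured"], f"S{i}") for i, d in enumerate(specs)]
        correct(sets1, TOL, envelopes={i: env(d["env"]) for i, d in enumerate(specs)})
        perm = list(rng.permutation(len(specs)))
        sets2 = [make_set(specs[p]["mz"], specs[p]["z"], specs[p]["measured"], f"S{p}") for p in perm]
        correct(sets2, TOL, envelopes={i: env(specs[p]["env"]) for i, p in enumerate(perm)})
        for i, p in enumerate(perm):
            assert np.allclose(sets2[i].corrected, sets1[p].corrected, atol=1e-9)


def test_mutual_cycle_breaks_at_dominant_species():
    """Same m/z, same z: a genuine cycle; the larger hybrid m+0 wins."""
    a = make_set(1000.0, 1, [1000.0, 300.0], "A")
    b = make_set(1000.0, 1, [100.0, 30.0], "B")
    correct([a, b], TOL, envelopes={0: env([1.0, 0.3]), 1: env([1.0, 0.3])})
    assert "cycle-break" in a.flags
    assert np.array_equal(a.corrected, a.surrogates)  # dominant one untouched
    assert b.corrected[0] == 0.0  # fully explained by A's envelope
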