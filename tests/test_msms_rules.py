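"""Spectrum combination, fragment matching, decision rules and quantity splits."""

from __future__ import annotations

import numpy as np
import pytest

from gangliofaims.chem_core import HYDROGEN_MASS, monoisotopic_mass
from gangliofaims.masslist import RESIDUES, GangliosideClass, MassListEntry
from gangliofaims.msms_rules import (
    Annotation,
    DecisionRuleSet,
    Rejection,
    assign_molecular_species,
    combine_spectra,
    evaluate,
    fa_candidates,
    match_fragment,
    split_quantity,
)
from gangliofaims.spectra_io import Spectrum

GD1 = GangliosideClass.from_name("GD1")
GM3 = GangliosideClass.from_name("GM3")
ENTRY = MassListEntry.build(GD1, "38:1;O2", 2)
NEUAC_FRAG = monoisotopic_mass(RESIDUES["NeuAc"]) - HYDROGEN_MASS  # 290.0876
NEUAC2_FRAG = monoisotopic_mass(2 * RESIDUES["NeuAc"]) - HYDROGEN_MASS
RULES = DecisionRuleSet.default()


def ms2(peaks, activation="CID", precursor=None, prov=None):
    mzs, ints = zip(*peaks) if peaks else ((), ())
    return Spectrum(
        "t",
        2,
        mz=np.array(mzs),
        intensity=np.array(ints),
        activation=activation,
        precursor_mz=ENTRY.mz if precursor is None else precursor,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# combine_spectra


def test_combine_single_spectrum_identity():
    s = ms2([(290.0876, 100.0), (581.18, 50.0)])
    c = combine_spectra([s], method="sum")
    assert np.allclose(c.mz, s.mz)
    assert np.allclose(c.intensity, s.intensity)


def test_combine_sum_and_average_coalesce_within_tolerance():
    s1 = ms2([(290.0876, 100.0)], "CID")
    s2 = ms2([(290.0877, 300.0)], "UVPD")
    total = combine_spectra([s1, s2], method="sum")
    assert total.mz.size == 1
    assert total.intensity[0] == pytest.approx(400.0)
    avg = combine_spectra([s1, s2], method="average")
    assert avg.intensity[0] == pytest.approx(200.0)
    # intensity-weighted merged m/z
    assert total.mz[0] == pytest.approx((290.0876 * 100 + 290.0877 * 300) / 400, abs=1e-9)


def test_combine_keeps_activation_provenance():
    s1 = ms2([(290.0876, 100.0)], "CID")
    s2 = ms2([(581.1830, 40.0)], "UVPD")
    c = combine_spectra([s1, s2], method="sum")
    by_mz = dict(zip(np.round(c.mz, 2), c.provenance))
    assert by_mz[290.09] == frozenset({"CID"})
    assert by_mz[581.18] == frozenset({"UVPD"})


def test_combine_conserves_tic_exactly():
    rng = np.random.default_rng(11)
    spectra = [
        ms2([(float(m), float(i)) for m, i in zip(rng.uniform(200, 2000, 60), rng.uniform(1, 100, 60))], act)
        for act in ("CID", "HCD", "UVPD")
    ]
    c = combine_spectra(spectra, method="sum")
    assert c.tic == pytest.approx(sum(s.tic for s in spectra), rel=1e-12)


def test_combine_rejects_empty_and_mixed_precursors():
    with pytest.raises(ValueError):
        combine_spectra([])
    s1 = ms2([(290.0876, 1.0)])
    s2 = ms2([(290.0876, 1.0)], precursor=ENTRY.mz + 5.0)
    with pytest.raises(ValueError, match="mixed precursors"):
        combine_spectra([s1, s2])


# ---------------------------------------------------------------------------
# fragment matching


def test_neuac_anion_matched_with_signed_ppm():
    spec = next(f for f in RULES.fragments if f.name == "NeuAc")
    peak = 290.0877
    m = match_fragment(ms2([(peak, 55.0)]), spec, ENTRY, tol_ppm=10.0)
    assert m is not None
    assert m.mz_theoretical == pytest.approx(290.0876, abs=5e-4)
    assert m.ppm == pytest.approx((peak - m.mz_theoretical) / m.mz_theoretical * 1e6)
    assert 0 < m.ppm < 1.0


def test_no_peak_within_tolerance_is_absent():
    spec = next(f for f in RULES.fragments if f.name == "NeuAc")
    m = match_fragment(ms2([(290.095, 55.0)]), spec, ENTRY, tol_ppm=10.0)
    assert m is None


def test_neutral_loss_searched_over_product_charges():
    spec = next(f for f in RULES.fragments if f.name == "loss-NeuAc")
    loss = monoisotopic_mass(RESIDUES["NeuAc"])
    for zp in (1, 2):
        target = (ENTRY.neutral_mass - loss - zp * HYDROGEN_MASS) / zp
        m = match_fragment(ms2([(target, 10.0)]), spec, ENTRY, tol_ppm=10.0)
        assert m is not None and m.product_charge == zp


def test_uvpd_only_rule_ignores_cid_peaks():
    g_spec = next(f for f in RULES.fragments if f.name == "G")
    fa = dict(fa_candidates("38:1;O2"))["18:1;O2/20:0"]
    target = (ENTRY.neutral_mass - monoisotopic_mass(fa) - 2 * HYDROGEN_MASS) / 2
    cid_only = ms2([(target, 99.0)], "CID")
    assert match_fragment(cid_only, g_spec, ENTRY, 10.0, fa_formula=fa) is None
    uvpd = ms2([(target, 99.0)], "UVPD")
    assert match_fragment(uvpd, g_spec, ENTRY, 10.0, fa_formula=fa) is not None


# ---------------------------------------------------------------------------
# evaluation


def test_gd1_with_both_sialo_fragments_passes():
    s = ms2([(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0)])
    out = evaluate(ENTRY, GD1, s, RULES)
    assert isinstance(out, Annotation)
    assert out.level == "species"
    assert {m.name for m in out.fragments} >= {"NeuAc", "NeuAc-NeuAc"}


def test_gm3_missing_neuac_rejected_with_reason():
    gm3_entry = MassListEntry.build(GM3, "34:1;O2", 1)
    s = ms2([(500.0, 10.0)], precursor=gm3_entry.mz)
    out = evaluate(gm3_entry, GM3, s, RULES)
    assert isinstance(out, Rejection)
    assert out.missing == ["NeuAc"]


def test_combined_spectrum_matches_at_least_cid_only():
    """Adding UVPD peaks can only add matches, never remove them."""
    cid = ms2([(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0)], "CID")
    uvpd_extra = ms2(
        [(NEUAC_FRAG, 20.0), ((ENTRY.neutral_mass - monoisotopic_mass(RESIDUES["NeuAc"]) - 2 * HYDROGEN_MASS) / 2, 30.0)],
        "UVPD",
    )
    cid_only = evaluate(ENTRY, GD1, combine_spectra([cid]), RULES)
    combined = evaluate(ENTRY, GD1, combine_spectra([cid, uvpd_extra]), RULES)
    assert isinstance(cid_only, Annotation) and isinstance(combined, Annotation)
    assert len(combined.fragments) >= len(cid_only.fragments)


# ---------------------------------------------------------------------------
# molecular species assignment and quantity splitting


def uvpd_with_g_fragments(splits: dict[str, float]):
    cand = dict(fa_candidates("38:1;O2"))
    peaks = [(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0)]
    for label, inten in splits.items():
        fa_mass = monoisotopic_mass(cand[label])
        peaks.append(((ENTRY.neutral_mass - fa_mass - 2 * HYDROGEN_MASS) / 2, inten))
    return combine_spectra([ms2(peaks, "UVPD")])


def test_single_split_assigns_molecular_level():
    ann = evaluate(ENTRY, GD1, uvpd_with_g_fragments({"18:1;O2/20:0": 40.0}), RULES)
    ann = assign_molecular_species(ann, uvpd_with_g_fragments({"18:1;O2/20:0": 40.0}), RULES)
    assert ann.level == "molecular species"
    assert ann.partition == {"18:1;O2/20:0": 1.0}


def test_two_splits_partition_by_intensity():
    spectrum = uvpd_with_g_fragments({"18:1;O2/20:0": 300.0, "20:1;O2/18:0": 100.0})
    ann = evaluate(ENTRY, GD1, spectrum, RULES)
    ann = assign_molecular_species(ann, spectrum, RULES)
    assert ann.partition["18:1;O2/20:0"] == pytest.approx(0.75)
    assert ann.partition["20:1;O2/18:0"] == pytest.approx(0.25)


def test_no_g_fragments_stays_species_level():
    spectrum = combine_spectra([ms2([(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0)], "UVPD")])
    ann = evaluate(ENTRY, GD1, spectrum, RULES)
    ann = assign_molecular_species(ann, spectrum, RULES)
    assert ann.level == "species"
    assert ann.partition == {}


def test_cid_fa_evidence_does_not_promote_level():
    """G-type peaks present only in CID do not resolve the ceramide."""
    cand = dict(fa_candidates("38:1;O2"))
    fa_mass = monoisotopic_mass(cand["18:1;O2/20:0"])
    g_mz = (ENTRY.neutral_mass - fa_mass - 2 * HYDROGEN_MASS) / 2
    spectrum = combine_spectra(
        [ms2([(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0), (g_mz, 50.0)], "CID")]
    )
    ann = evaluate(ENTRY, GD1, spectrum, RULES)
    ann = assign_molecular_species(ann, spectrum, RULES)
    assert ann.level == "species"


def test_split_quantity_conserves_total():
    out = split_quantity(1000.0, {"a": 0.75, "b": 0.25})
    assert out == {"a": 750.0, "b": 250.0}
    assert sum(out.values()) == pytest.approx(1000.0, rel=1e-12)
    assert split_quantity(42.0, {"only": 1.0}) == {"only": 42.0}
    with pytest.raises(ValueError, match="sum"):
        split_quantity(10.0, {"a": 0.5, "b": 0.4})


def test_fa_candidates_enumeration():
    labels = {lab for lab, _ in fa_candidates("38:1;O2")}
    assert "18:1;O2/20:0" in labels
    assert "20:1;O2/18:0" in labels
    assert "18:0;O2/20:1" in labels
    # all complements stay within the physical fatty-acid range
    for lab, fa in fa_candidates("38:1;O2"):
        assert fa["C"] >= 10 and fa["H"] > 0


def test_relative_intensity_constraint_enforced():
    """A (greater, lesser) intensity relation rejects violating spectra."""
    import dataclasses

    rules = dataclasses.replace(
        DecisionRuleSet.default(), intensity_rules=[("NeuAc", "NeuAc-NeuAc")]
    )
    ok = evaluate(ENTRY, GD1, ms2([(NEUAC_FRAG, 100.0), (NEUAC2_FRAG, 60.0)]), rules)
    assert isinstance(ok, Annotation)
    bad = evaluate(ENTRY, GD1, ms2([(NEUAC_FRAG, 10.0), (NEUAC2_FRAG, 60.0)]), rules)
    assert isinstance(bad, Rejection)
    assert "intensity" in bad.missing[0]


def test_rule_file_roundtrip(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "tolerance_ppm: 7.5\n"
        "fragments:\n"
        "  - {name: NeuAc, kind: anion, formula: C11H17NO8, mandatory: true, min_neuac: 1}\n"
    )
    rules = DecisionRuleSet.from_yaml(path)
    assert rules.tolerance_ppm == 7.5
    assert rules.fragments[0].mandatory
    assert rules.fragments[0].applies_to(GM3)
    s = ms2([(NEUAC_FRAG, 5.0)])
    gm3_entry = MassListEntry.build(GM3, "34:1;O2", 1)
    out = evaluate(gm3_entry, GM3, ms2([(NEUAC_FRAG, 5.0)], precursor=gm3_entry.mz), rules)
    assert isinstance(out, Annotation)
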