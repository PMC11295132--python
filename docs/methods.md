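# Methods

This note documents the models, conventions and default parameters behind
`gangliofaims`, the assumptions baked into the synthetic validation data,
and the boundaries of what the shipped tests demonstrate.

## Mass conventions

Monoisotopic atomic masses and isotope abundances are fixed constants in
`chem_core` (IUPAC/CODATA values for H, C, N, O, P, S, Na, K), so outputs
are bit-stable across environments.

Deprotonated ions are placed at `(M − z·1.0078250319)/z`: the hydrogen
*atom* mass is subtracted per charge and the electron mass is not re-added.
This is the convention established lipidomics annotation software uses,
and it reproduces the canonical sialic-acid B-type fragment anion
(C₁₁H₁₆NO₈⁻) at m/z 290.0876. The physically exact anion m/z would
subtract the proton mass instead (1.00727646 Da), shifting every value by
+0.00055/z — about 0.6 ppm at m/z 900, inside any realistic matching
tolerance but visible at the fourth decimal of small fragments. The proton
mass is exported as `chem_core.PROTON_MASS` for users who need the exact
placement.

Isotope envelopes are *aggregated* (nominal) isotopologue distributions:
all +1 Da substitutions share a bin, which matches how Orbitrap
isotopologue quantitation treats peaks. Envelopes are computed by
truncated polynomial convolution of per-element distributions (binary
exponentiation over atom counts), normalized to the monoisotopic bin, and
capped at m+5. Fine isotopic structure (¹³C vs ¹⁵N splitting) is out of
scope. Formula syntax is Hill-like (`C11H19NO9`); isotope-labeled formulas
are not currently modeled — the parser and arithmetic are structured so a
label extension can be added without changing call sites.

## Ganglioside target space

A class is a glycan composition: the Svennerholm series letter sets the
NeuAc count (M=1 … O=8), the trailing digit the neutral core (1: 3 Hex +
HexNAc, 2: 2 Hex + HexNAc, 3: 2 Hex, 4: 1 Hex), and `-Ac`/`-Fuc` suffixes
add C₂H₂O / C₆H₁₀O₄. The default table holds 29 classes covering the
GM/GD/GT/GQ/GP/GH/GS/GO series with their acetylated and fucosylated
variants; the inventory (in particular the inclusion of GT1-Fuc-Ac,
completing the same Ac/Fuc/Fuc-Ac pattern GD1 carries) is this package's
reconstruction of the commonly analyzed class set and is user-overridable.

Ceramide sum compositions `C:DB;On` map to the formula
`C(c) H(2c+1−2·DB) N O(n+1)` (sphingoid base + N-acyl fatty acid, one
water condensed out, amide oxygen included); Cer 36:1;O2 = C₃₆H₇₁NO₃ =
565.5434 Da. The neutral species formula is ceramide + dehydrated residue
formulas (Hex 162.05282, HexNAc 203.07937, NeuAc 291.09542, dHex
146.05791, Ac 42.01057): residue masses already carry the per-bond water
loss, and the water freed by writing the glycan as residues is exactly the
one consumed by the ceramide–glycan bond.

Default enumeration bounds — C 28–48 (odd chains allowed; parity
configurable), 0–5 double bonds, O2 and O3 backbones — give 252
compositions per class, 7308 species over 29 classes, i.e. the ≈8500-target
regime the method is designed for. Charge states default to
1…min(#NeuAc, 8), reflecting the observed coupling between sialylation and
preferred charge. Glycan isomer topology (e.g. the GD1a/GD1b/GD1c
arrangements) is indistinguishable by this method and is not modeled.

## MS1 quantitation

For each target, every MS1 scan contributes the summed intensity of all
peaks within ±tol (default 5 ppm) of `mz + i·1.0033548/z` for isotopologues
i = 0…n−1 (default n = 2). Summing in-window peaks (rather than taking the
apex) is robust to split centroids; it can over-count when two analytes
fall in one window, which the isotope correction then handles. Surrogates
aggregate across scans as `median`, `mean` or `sum` (default `sum`). In
FAIMS mode, extraction is restricted to the CV window expected for the
target's (class, charge) when the CV table has one; scans without CV
metadata always participate, so noFAIMS files run unchanged.

## Isotope-overlap correction

Directed overlap: species A affects species B when any theoretical
isotopologue m/z of A (m+0…m+5 at A's charge) falls within the MS1
tolerance of a *quantified* isotopologue m/z of B. The correction loops:

1. find all species with no incoming overlap from not-yet-corrected
   species ("unaffected" — the processing order is derived from the graph,
   not from m/z order);
2. for each, project its theoretical envelope scaled by the hybrid
   monoisotopic estimate `½(I₀ + I₁/r₁)` (falling back to I₀ when m+1 was
   not quantified or r₁ = 0, with a warning);
3. subtract the projections from every overlapped isotopologue of the
   remaining species, flooring at zero (`floored` flag);
4. mark the wave corrected and repeat.

All members of a wave are settled from their own values before any of the
wave's subtractions become visible, which makes the result independent of
input ordering. Mutual-overlap cycles — not covered by the unaffected-first
rule — are broken by correcting the member with the largest hybrid m+0
first (`cycle-break` flag): the dominant species' envelope is the best
determined. Whether to floor negatives and how to break cycles are genuine
design choices of this implementation; both events are flagged in the
output so affected values can be audited. Full least-squares spectral
deconvolution is deliberately out of scope — sequential subtraction is the
specified behavior.

## MS/MS decision rules

MS2 scans sharing a precursor (within half the isolation width, default
1.5 m/z) are merged on a 10 ppm grid: peaks coalesce to their
intensity-weighted m/z, intensities are summed (`sum`) or divided by the
spectrum count (`average`), and each merged peak remembers which
activation types contributed.

The shipped rule file (`gangliofaims/data/rules.yaml`) is a reconstruction
seeded from the universally diagnostic fragments, and is user-overridable:

- NeuAc B-type anion (m/z 290.0876) — mandatory for every class;
- NeuAc–NeuAc anion (m/z 581.1830) — mandatory for ≥2 NeuAc classes;
- neutral losses of NeuAc, and of Ac/Fuc for modified classes — optional,
  searched at all product charges 1…z (multiply charged precursors yield
  charge-reduced products);
- G (neutral loss of the fatty acid) and G−NeuAc — UVPD-only,
  molecular-species evidence.

A species-level annotation requires every mandatory class-applicable
fragment to match; otherwise the candidate is rejected with the missing
list. Optional pairwise intensity relations (``intensity_rules``: fragment
A must be at least as intense as fragment B when both match) can be added
to a rule file; the default set ships none. Molecular-species assignment enumerates chain splits (default
sphingoid bases: 18 or 20 carbons, 0–1 double bonds, carrying the
composition's hydroxyls; fatty acid = complement, matched as the free acid
CₙH₂ₙ₋₂dbO₂ — the acid-vs-ketene choice is configurable by editing the
rule kinds) and admits splits with at least one G-type match among
UVPD-tagged peaks. Fatty-acid signals seen only in CID/HCD never promote
the level: negative-mode CID/HCD is not reliable for ceramide
characterization. Split fractions are proportional to summed
distinct-fragment intensities, and quantity splitting conserves the
species total exactly. Cross-ring (A/X) glycan fragments and double-bond
localization are not modeled.

## FAIMS dimension

A CV schedule is a stepped program (default reference ramp: 25→77 V in 2 V
steps, 6 s dwell → 27 steps, 2.7 min; arbitrary step lists supported). A
CV profile aggregates a target's m+0 intensity per distinct CV; CVmax is
the argmax. Two estimator conventions are package choices, exposed as
parameters:

- **CV range** = the maximal contiguous span around the apex with
  intensity ≥ 10 % of the profile maximum (`threshold_fraction`);
- **indeterminate CVmax** when max/median intensity < 2 — this captures
  the flat response of monosialylated species, which transmit over a broad
  CV range and have no meaningful apex.

The default expected-range table ships only the two established windows —
GD1²⁻ 37–51 V and GT1³⁻ 57–73 V — plus nothing invented; users extend it
from their own instrument (TSV: class, z, lo_V, hi_V). The CV filter
passes an annotation when the intensity-weighted CV of its supporting
evidence lies inside the expected window; (class, charge) pairs absent
from the table pass with an `unvalidated` note rather than failing, since
an absent calibration is not negative evidence. FAIMS does not provide
collision cross sections; none are computed.

## Synthetic data

The generator emits what the analysis consumes: per CV step, MS1 scans
containing each plant's isotope envelope (computed by the same
`chem_core` routine, which is additionally verified against a brute-force
multinomial oracle in the tests) scaled by a Gaussian CV transmission
curve, plus DDA-style CID/HCD/UVPD MS2 scans holding exactly the
rule-compliant fragments. Defaults emulate the study conditions the
package targets:

- CV transmission: Gaussian, σ = 6 V; real profiles are smooth and
  unimodal but their exact shape is unknown — the Gaussian is a documented
  assumption. Default apexes couple charge to CV (higher charge → higher
  CV), with GD1²⁻ at 45 V and GT1³⁻ at 65 V inside their reference
  windows.
- Intensities: plant base 10⁶ over an exponential noise floor of mean 10³
  (S/N ≈ 10³), 200 uniform-m/z background peaks per MS1 scan emulating
  singly charged bulk lipids, 50 per MS2 scan.
- Decoy plants receive MS1 envelopes and optional-only MS/MS content, no
  mandatory diagnostics — a correct pipeline must reject them.
- Everything is driven by one `numpy` Generator seed; identical seeds give
  bit-identical scan sets and manifests.

What the generator does **not** emulate: electrospray physics and
charge-state chemistry (solvent-additive effects are representable only as
abundance re-weighting across charges), profile-mode peak shapes, detector
saturation, isobaric non-ganglioside interferences with ganglioside-like
fragmentation, and retention-time structure. Passing the end-to-end tests
therefore demonstrates the correctness of the bookkeeping — extraction,
correction, rule logic, CV estimation — under controlled conditions, not
annotation accuracy on real brain extracts, where isomeric overlap and
matrix effects dominate.

The mzML written by the generator is produced by a minimal writer
(centroid spectra, 64-bit float arrays, per-scan FAIMS CV as cvParam
MS:1001581); the reader accepts general standard mzML including
zlib-compressed and 32-bit float arrays and resolves terms by accession
with name fallback.

## Pipeline defaults and determinism

MS1 5 ppm, MS/MS 10 ppm, m+0/m+1 in `sum` mode, combined-`sum` MS/MS
evaluation, FAIMS mode auto-detected from CV metadata. Each MS2 scan is
assigned to the nearest detected precursor within half its isolation
window. Reports count species as distinct (class, sum composition) at
species level or better, with molecular-species identifications counted
on top, and summarize per class and per sialylation tier (GM/GD/GT/GQup).
Runs are deterministic given config and input; the only randomness in the
package lives in the synthetic generator, behind an explicit seed.

Test problem sizes were chosen for tightness of the oracle comparisons at
desk scale: 50 randomized overlap scenarios for the correction oracle, 20
random formulas (≤200 atoms) for the envelope oracle, and a 12-plant
(10 genuine + 2 decoy) CV-ramp acquisition across charges 1–5 for the
end-to-end recovery check.

## Known limitations

- The shipped decision rules are a minimal reconstruction; real
  deployments should extend them per class from measured spectra.
- Sum-composition parsing restricts hydroxylation to O2/O3, the states
  relevant for ganglioside ceramides.
- The CV-range and indeterminacy thresholds are heuristics standing in for
  an unpublished operationalization; both are parameters.
- In-window peak summation can inflate surrogates in very dense spectra;
  the isotope correction mitigates but does not replace resolution.
- No absolute quantitation: intensities are relative surrogates, not
  response-factor-calibrated amounts.
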