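# gangliofaims

Automated annotation of **gangliosides** — sialylated glycosphingolipids —
from direct-infusion ("shotgun") high-resolution mass spectrometry, with or
without a FAIMS (high-field asymmetric waveform ion mobility) front end.

Gangliosides are hard targets for shotgun lipidomics: reference standards
and spectral libraries are scarce, the species of interest form multiply
charged anions (`[M−H]⁻` … `[M−8H]⁸⁻`) that drown in singly charged bulk
lipids, and annotations have traditionally been assigned by hand. This
package is for analytical chemists and lipidomics bioinformaticians who
want that annotation chain to be reproducible code:

- **masslist** — combinatorial target generation: 29 ganglioside classes
  (GM/GD/GT/GQ/GP/GH/GS/GO series with acetyl and fucosyl variants) ×
  ceramide sum compositions × charge states, ≈8500 species, written as a
  plain TSV.
- **spectra_io** — mzML (and plain-text peak list) reading with per-scan
  FAIMS compensation voltage (CV), activation type (CID/HCD/UVPD) and
  precursor metadata.
- **ms1_quant** — per-isotopologue intensity surrogates (m+0, m+1, …;
  median/mean/sum aggregation) from repeated MS1 scans at 5 ppm.
- **isotope_correction** — iterative subtraction of foreign isotope
  envelopes, starting from species unaffected by others' isotopes.
- **msms_rules** — decision-rule MS/MS verification on combined CID + HCD +
  UVPD spectra, molecular-species assignment from UVPD fatty-acyl neutral
  losses, and quantity splitting among fatty-acid isomers.
- **faims** — CV schedules, per-analyte CV transmission profiles
  (CVmax/CV range), and CV-consistency filtering of annotations.
- **synthetic** — a ground-truth generator that writes mzML-compatible
  scan sets with planted gangliosides, noise and decoys for validation.

## The core calculations

Negative-ion placement of a neutral of monoisotopic mass *M* at charge *z*:

    m/z = (M − z·1.0078250) / z

(hydrogen-atom convention used throughout shotgun lipidomics software;
the universal sialic-acid diagnostic, dehydrated deprotonated NeuAc
C₁₁H₁₆NO₈⁻, lands at m/z 290.0876).

Isotopologue surrogates are extracted at `mz + i·1.0033548/z` (¹³C spacing
over charge) and corrected iteratively: a species whose quantified
isotopologues receive no contribution from any uncorrected species projects
its theoretical envelope from the hybrid monoisotopic estimate

    m₀* = ½ (I₀ + I₁ / r₁)

(r₁ = theoretical m+1/m+0 ratio) and that projection is subtracted from
every overlapped isotopologue of the remaining species, floored at zero,
until no species is left. Verified species quantities are finally split
among molecular species (e.g. `GD1 18:1;O2/20:0`) in proportion to their
distinct UVPD G-fragment intensities.

## Worked example

Generate targets, synthesize a CV-ramp acquisition with four planted
gangliosides, and run the full annotation chain:

```
$ gangliofaims masslist --out targets.tsv --classes GD1,GT1,GM3 \
      --cmin 34 --cmax 40 --db-max 2 --o-states 2
wrote 126 entries to targets.tsv

$ gangliofaims synth --out synth.mzML --manifest manifest.tsv --seed 1
wrote 39 scans to synth.mzML; manifest -> manifest.tsv

$ gangliofaims run --mzml synth.mzML --masslist targets.tsv --report report.tsv
FAIMS mode auto-detected: on
MS1: 10/126 targets with nonzero m+0 surrogate
annotated 4 targets (4 species, 5 IDs incl. molecular)
wrote 4 annotation rows to report.tsv
```

`report.tsv` then contains:

```
class species   molecular_species      ion             level     quantity  cv_weighted  cv_pass
  GT1 38:1;O2                       [M-3H]3-           species 6.528680e+06    64.771642     True
  GD1 36:1;O2                       [M-2H]2-           species 6.117567e+06    45.004970     True
  GD1 38:1;O2 18:1;O2/20:0:1.0000   [M-2H]2- molecular species 6.117567e+06    45.004970     True
  GM3 34:1;O2                         [M-H]-           species 6.841630e+06    33.077648     True
```

Reading the rows: each planted species was verified by its mandatory
diagnostic fragments (NeuAc at m/z 290.0876; NeuAc–NeuAc for the di- and
trisialylated classes). `quantity` is the isotope-corrected m+0 intensity
surrogate summed over the scans in the class's CV window. `cv_weighted` is
the intensity-weighted compensation voltage of the supporting evidence —
GD1²⁻ transmits near 45 V (inside its expected 37–51 V window, hence
`cv_pass`), GT1³⁻ near 65 V (inside 57–73 V). For GD1 38:1;O2 the UVPD
G fragment (neutral loss of the 20:0 fatty acid) resolves the ceramide,
promoting the annotation to the molecular species `GD1 18:1;O2/20:0` with
the full species quantity allocated to that single chain split. A decoy
planted without diagnostic fragments would be listed in the audit log as
rejected, not in this table.

The same workflow is available programmatically via
`gangliofaims.run(RunConfig(...))`; see `docs/methods.md` for the model
details and parameter semantics.

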