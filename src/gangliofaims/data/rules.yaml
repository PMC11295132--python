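# Default ganglioside decision rules.
#
# This shipped rule set is a reconstruction seeded from the universally
# diagnostic sialic-acid fragments and the UVPD fatty-acyl neutral losses;
# it is user-overridable (pass your own file to DecisionRuleSet.from_yaml).
#
# kinds:
#   anion         — absolute fragment, matched at [F-H]- of `formula`
#   neutral_loss  — `formula` subtracted from the precursor neutral,
#                   matched at all product charges 1..z
#   fa_loss       — neutral loss of a candidate free fatty acid (the
#                   UVPD "G" fragment); licenses molecular-species level
#   fa_neuac_loss — loss of fatty acid + one NeuAc residue ("G-NeuAc")
#
# applicability: min_neuac (sialic-acid count), requires (Ac / Fuc
# modification present), activations (which ion-activation spectra count
# as evidence).

tolerance_ppm: 10.0
fragments:
  - name: NeuAc
    kind: anion
    formula: C11H17NO8          # dehydrated sialic acid B-type fragment
    mandatory: true
    min_neuac: 1
    activations: [CID, HCD, UVPD]
  - name: NeuAc-NeuAc
    kind: anion
    formula: C22H34N2O16        # disialyl B-type fragment
    mandatory: true
    min_neuac: 2
    activations: [CID, HCD, UVPD]
  - name: loss-NeuAc
    kind: neutral_loss
    formula: C11H17NO8
    mandatory: false
    min_neuac: 1
    activations: [CID, HCD, UVPD]
  - name: loss-Ac
    kind: neutral_loss
    formula: C2H2O
    mandatory: false
    requires: Ac
    activations: [CID, HCD, UVPD]
  - name: loss-Fuc
    kind: neutral_loss
    formula: C6H10O4
    mandatory: false
    requires: Fuc
    activations: [CID, HCD, UVPD]
  - name: G
    kind: fa_loss
    mandatory: false
    level: molecular
    activations: [UVPD]
  - name: G-NeuAc
    kind: fa_neuac_loss
    mandatory: false
    level: molecular
    activations: [UVPD]
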