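# Enzyme cleavage-rule catalog (PeptideCutter-style dialects), version 1.
#
# Sites are peptide bonds i|i+1 (1-based residues).  Simple rules give a
# matched-residue specificity with context vetoes; motif rules give
# position-specific subsite constraints with offsets relative to P1
# (P4..P1 = -3..0, P1'/P2' = +1/+2).  The dialects below are calibrated for
# the FFPE-dissociation enzyme screen; edit and version a copy of this file
# to change them (`cleave ... --rules my_rules.yaml`).
version: 1
enzymes:
  - enzyme_name: trypsin
    side: C
    residue_set: [K, R]
    context_exceptions:
      - {offset: 1, residues: [P]}   # no cleavage before proline
    notes: "Simple K/R dialect; PeptideCutter's rarer higher-order exceptions omitted."

  - enzyme_name: dispase
    side: N
    residue_set: [A, V, L, I, M, F, W, G, P]
    notes: "N-side of neutral/nonpolar residues; the residue set is the editable part of this dialect."

  - enzyme_name: clostripain
    side: C
    residue_set: [R]
    notes: "Major Arg-specific activity only; minor Lys activity reported in the literature is deliberately not modelled."

  - enzyme_name: proline_endopeptidase
    side: C
    motif_rules:
      - - {offset: -1, in: [H, K, R]}   # P2 basic
        - {offset: 0, in: [P]}          # P1 proline
        - {offset: 1, not_in: [P]}      # no Pro-Pro cleavage
    notes: "Restricted prolyl-endopeptidase dialect (basic P2 required)."

  - enzyme_name: thrombin
    side: C
    motif_rules:
      # Gly-Arg-|-Gly
      - - {offset: -1, in: [G]}
        - {offset: 0, in: [R]}
        - {offset: 1, in: [G]}
      # hydrophobic P4/P3, Pro at P2, Arg at P1, non-acidic P1'/P2'
      - - {offset: -3, in: [A, F, G, I, L, T, V, W, M]}
        - {offset: -2, in: [A, F, G, I, L, T, V, W, M]}
        - {offset: -1, in: [P]}
        - {offset: 0, in: [R]}
        - {offset: 1, not_in: [D, E]}
        - {offset: 2, not_in: [D, E]}
    notes: "Two-motif thrombin dialect."
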