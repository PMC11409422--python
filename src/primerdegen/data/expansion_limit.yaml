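# Degeneracy-budget scenario: the starting reverse primer (the improved
# M1, expansion 48) faces sequences whose only repair is one further
# 2-fold union (T/C at position 20), which would lift the expansion to
# 96 > 60 — every candidate step must be rejected and the primer must
# stay unchanged.
seed: 20240806
forward_primer: GTGYCAGCMGCCGCGGTAA
reverse_primer: GGACTACNVGRGTWTCTAAT
background_length: 800
f_r_spacing: 150
taxa:
  - taxonomy: Bacteria;Chloroflexi;Dehalococcoidia;Dehalococcoidales;Dehalococcoidaceae;Dehalococcoides
    n_sequences: 5
    mismatches:
      - count: 5
        sites:
          - orientation: reverse
            position: 20
            base: C
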