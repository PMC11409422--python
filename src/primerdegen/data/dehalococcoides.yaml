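# Dehalococcoides improvement scenario for the BA-515F-806R pair.
#
# 38 synthetic 16S-like sequences of the target genus: 2 carry exact sites
# for both primers, 36 carry a single planted template A under position 11
# (a G) of the reverse primer, so the original pair covers 2/38 and one
# G->R replacement recovers the rest.  A small off-target archaeal and
# bacterial backdrop with exact sites rides along for per-domain reporting.
seed: 20240515
forward_primer: GTGYCAGCMGCCGCGGTAA
reverse_primer: GGACTACNVGGGTWTCTAAT
background_length: 800
f_r_spacing: 150
taxa:
  - taxonomy: Bacteria;Chloroflexi;Dehalococcoidia;Dehalococcoidales;Dehalococcoidaceae;Dehalococcoides
    n_sequences: 38
    mismatches:
      - count: 36
        sites:
          - orientation: reverse
            position: 11
            base: A
  - taxonomy: Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia-Shigella
    n_sequences: 6
  - taxonomy: Archaea;Halobacterota;Methanosarcinia;Methanosarciniales;Methanosarcinaceae;Methanosarcina
    n_sequences: 6
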