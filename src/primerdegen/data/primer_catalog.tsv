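name	target_taxon	forward	reverse
BA-515F-806R	-	GTGYCAGCMGCCGCGGTAA	GGACTACNVGGGTWTCTAAT
BA-515F-806R-M1	Dehalococcoides	GTGYCAGCMGCCGCGGTAA	GGACTACNVGRGTWTCTAAT
BA-515F-806R-M2	Calescamantes	GTGYCAGCMGCCGCGGTAA	GGACTACNVGGGTHTCTAAT
BA-515F-806R-M3	Caldisericaceae	GTGYCAGCMGCYGCGGTAA	GGACTACNVGGGTWTCTAAT
BA-515F-806R-M4	Iainarchaeota	GTGYCAGCMGCCGCGGTAA	GGACTAMNVGGGTWTCTAAT
BA-515F-806R-M5	Nanohaloarchaeota	STGYCAGCMGCCGCGGTAA	GGACTACNVGGGTWTCTAAT
A-341F-1059R	-	CCTAYGGGRBGCASCAG	GGCCATGCACCWCCTCTC
A-341F-1059R-M1	Nanohaloarchaeota	CCTAYGGGRBGCASCAG	GGCCAYGCAVCWCCTCTC
A-341F-1059R-M2	Korarchaeota	CCTAHGGGRBGCASCAG	GGCCAYGCACCWCCYCTC
A-341F-1059R-M3	Micrarchaeota	CCTAYGGGRBGCASCAG	SGCCATGCAVYWCYTCTC
A-341F-1059R-M4	Altiarchaeota	CCTAYGGGRBGCABCAG	GGCCATGCACYWCCYCTC
B-341F-806R	-	CCTACGGGNGGCWGCAG	GACTACHVGGGTATCTAATCC
B-341F-806R-M1	Aerophobota,Deferrisomatota,Calescamantes	CCTAYGGGNGGCWGCAG	GACTACHVGGGTMTCTAATCC
B-341F-806R-M2	PAUC34f	CCTACGGGNGSCWGCAG	GACYACHVGGGTATCTAATCC
B-341F-806R-M3	Fermentibacterota	CCTHCGGGNGGCWGCAG	GACTACHVGGGTATCTAATCC
B-27F-1492R	-	AGRGTTYGATYMTGGCTCAG	RGYTACCTTGTTACGACTT
B-27F-1492R-M1	Fusobacteriota	AGRGTTYGATYMTGGCTCAG	DRYKRCCTTGTTACGACTT
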