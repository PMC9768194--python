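#name	chrom	strand	mature_start	mature_end	mature_rna	pos	ref	alt	ref_seed	alt_seed
miR-214	1	-	172107956	172107977	ACAGCAGGCACAGACAGGCAGU	172107971	C	T	CAGCAGG	CAGCAAG
miR-4423	1	+	85599525	85599545	AUAGGCACCAAAAAGCAACAA	85599526	T	C	UAGGCAC	CAGGCAC
miR-509-1	X	-	146342068	146342089	UGAUUGGUACGUCUGUGGGUAG	146342085	A	AATC	GAUUGGU	GAUGAUU
miR-518a-1	19	+	54234310	54234331	GAAAGCGCUUCCCUUUGCUGGA	54234315	C	G	AAAGCGC	AAAGGGC
miR-5586	14	-	60113680	60113701	CAGAGUGACAGGUAUUGCUGGU	60113697	C	T	AGAGUGA	AGAAUGA
miR-941-3	20	+	62550960	62550981	CACCCGGCUGUGUGCACAUGUG	62550965	G	A	ACCCGGC	ACCCAGC
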