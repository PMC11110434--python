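# hg38 chromosome-arm intervals (0-based half-open), centromere midpoints rounded
chr1	0	123400000	p
chr1	123400000	248956422	q
chr2	0	93900000	p
chr2	93900000	242193529	q
chr3	0	90900000	p
chr3	90900000	198295559	q
chr4	0	50000000	p
chr4	50000000	190214555	q
chr5	0	48800000	p
chr5	48800000	181538259	q
chr6	0	59800000	p
chr6	59800000	170805979	q
chr7	0	60100000	p
chr7	60100000	159345973	q
chr8	0	45200000	p
chr8	45200000	145138636	q
chr9	0	43000000	p
chr9	43000000	138394717	q
chr10	0	39800000	p
chr10	39800000	133797422	q
chr11	0	53400000	p
chr11	53400000	135086622	q
chr12	0	35500000	p
chr12	35500000	133275309	q
chr13	0	17700000	p
chr13	17700000	114364328	q
chr14	0	17200000	p
chr14	17200000	107043718	q
chr15	0	19000000	p
chr15	19000000	101991189	q
chr16	0	36800000	p
chr16	36800000	90338345	q
chr17	0	25100000	p
chr17	25100000	83257441	q
chr18	0	18500000	p
chr18	18500000	80373285	q
chr19	0	26200000	p
chr19	26200000	58617616	q
chr20	0	28100000	p
chr20	28100000	64444167	q
chr21	0	12000000	p
chr21	12000000	46709983	q
chr22	0	15000000	p
chr22	15000000	50818468	q
chrX	0	61000000	p
chrX	61000000	156040895	q
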