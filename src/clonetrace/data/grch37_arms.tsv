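#chrom	arm	start	end
chr1	1p	0	125000000
chr1	1q	125000000	249250621
chr2	2p	0	93300000
chr2	2q	93300000	243199373
chr3	3p	0	91000000
chr3	3q	91000000	198022430
chr4	4p	0	50400000
chr4	4q	50400000	191154276
chr5	5p	0	48400000
chr5	5q	48400000	180915260
chr6	6p	0	61000000
chr6	6q	61000000	171115067
chr7	7p	0	59900000
chr7	7q	59900000	159138663
chr8	8p	0	45600000
chr8	8q	45600000	146364022
chr9	9p	0	49000000
chr9	9q	49000000	141213431
chr10	10p	0	40200000
chr10	10q	40200000	135534747
chr11	11p	0	53700000
chr11	11q	53700000	135006516
chr12	12p	0	35800000
chr12	12q	35800000	133851895
chr13	13p	0	17900000
chr13	13q	17900000	115169878
chr14	14p	0	17600000
chr14	14q	17600000	107349540
chr15	15p	0	19000000
chr15	15q	19000000	102531392
chr16	16p	0	36600000
chr16	16q	36600000	90354753
chr17	17p	0	24000000
chr17	17q	24000000	81195210
chr18	18p	0	17200000
chr18	18q	17200000	78077248
chr19	19p	0	26500000
chr19	19q	26500000	59128983
chr20	20p	0	27500000
chr20	20q	27500000	63025520
chr21	21p	0	13200000
chr21	21q	13200000	48129895
chr22	22p	0	14700000
chr22	22q	14700000	51304566
chrX	Xp	0	60600000
chrX	Xq	60600000	155270560
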