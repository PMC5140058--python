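chrom	arm	start	end
chr1	1p	1	121535434
chr1	1q	124535435	249250621
chr2	2p	1	92326171
chr2	2q	95326172	243199373
chr3	3p	1	90504854
chr3	3q	93504855	198022430
chr4	4p	1	49660117
chr4	4q	52660118	191154276
chr5	5p	1	46405641
chr5	5q	49405642	180915260
chr6	6p	1	58830166
chr6	6q	61830167	171115067
chr7	7p	1	58054331
chr7	7q	61054332	159138663
chr8	8p	1	43838887
chr8	8q	46838888	146364022
chr9	9p	1	47367679
chr9	9q	50367680	141213431
chr10	10p	1	39254935
chr10	10q	42254936	135534747
chr11	11p	1	51644205
chr11	11q	54644206	135006516
chr12	12p	1	34856694
chr12	12q	37856695	133851895
chr13	13q	19000001	115169878
chr14	14q	19000001	107349540
chr15	15q	20000001	102531392
chr16	16p	1	35335801
chr16	16q	38335802	90354753
chr17	17p	1	22263006
chr17	17q	25263007	81195210
chr18	18p	1	15460898
chr18	18q	18460899	78077248
chr19	19p	1	24681782
chr19	19q	27681783	59128983
chr20	20p	1	26369569
chr20	20q	29369570	63025520
chr21	21q	14288130	48129895
chr22	22q	16000001	51304566
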