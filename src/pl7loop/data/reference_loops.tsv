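name	pdb_id	loop1_seq	loop1_start	loop1_end	loop2_seq	loop2_start	loop2_end	product_group	split_verified
AlyV	7W16	PINPRASVANTDKAKNDA	117	134	VIKNNAVNCGSKSGNKGTEECKNAYLKL	183	210	TRI_DI_PREDOMINANT	yes
AlyA	4OZX	HVTTTGVNWQVGRH	.	.	EPRKGFGDEQ	.	.	TRI_DI_PREDOMINANT	no
PyAly	7W13/7W18	TLPTPLRGMK	108	117	RLNNKSGDAGRF	159	170	LARGER_OLIGO_PREDOMINANT	yes
A1-II'	2ZAA	QLPSSGKIK	.	.	QNSDGTGSD	.	.	LARGER_OLIGO_PREDOMINANT	no
AlgAT5	5ZQI	HLPEVK	.	.	DHGDGE	.	.	LARGER_OLIGO_PREDOMINANT	no
ALY-1	1UAI	HLPEVK	.	.	PHKGDD	.	.	LARGER_OLIGO_PREDOMINANT	no
FlAlyA	5Y33	ISKEPDGKY	.	.	SRVLKDLNAPYKEMLSEHAW	.	.	LARGER_OLIGO_PREDOMINANT	no
PA1167	1VAV	AVPSTRR	.	.	VRERPDDGGTR	.	.	LARGER_OLIGO_PREDOMINANT	no
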