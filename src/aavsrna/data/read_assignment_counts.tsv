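sample	n_total	n_ge16	n_human	n_human_mirna	aav2	ad2	hsv1	n_unknown
cells_27hpi	19395459	17429392	14653485	4793871	17	348	6	809469
aav2_27hpi	18085432	16228519	13331538	5840779	1193	1209	9	1037657
aav2_ad2_27hpi	21333021	18814505	11238151	3307157	270577	2644519	12	2142730
ad2_27hpi	24841074	24202341	12151399	5129522	24	5332713	14	6079458
cells_8hpi	21851591	20985998	17475849	6899774	15	286	13	2644242
aav2_8hpi	20375107	20022269	16464292	7551710	160	449	10	3204520
aav2_hsv1_8hpi	23031470	20904023	16445457	7202911	146807	3933	108860	2071519
hsv1_8hpi	22391766	20895686	16671702	9745884	14	326	124055	2603509
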