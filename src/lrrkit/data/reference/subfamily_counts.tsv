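# Published LRR-RLK subfamily membership counts for Arabidopsis thaliana and
# the four Gossypium species (genome-wide family surveys).
subfamily	A_thaliana	G_arboreum	G_barbadense	G_hirsutum	G_raimondii
I	41	4	6	7	3
II	14	17	23	29	18
III	41	45	68	83	46
IV	3	5	10	10	5
V	9	10	15	19	9
VI-1	5	7	11	14	7
VI-2	4	2	2	6	3
VII-1	2	4	11	7	4
VII-2	5	6	6	12	6
VIII-1	8	4	7	7	4
VIII-2	12	17	26	30	17
IX	4	12	18	19	11
X	15	18	32	35	18
XI-1	28	75	135	132	81
XI-2	2	3	3	7	3
XI-3	2	1	1	2	1
XII	7	49	102	61	63
XIII-1	3	3	6	5	2
XIII-2	3	3	6	6	3
XIV	2	5	10	9	5
XV	3	8	13	15	8
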