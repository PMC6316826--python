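# Published tandem-duplication counts per subfamily (genes and sets) for the
# four Gossypium species.
subfamily	species	n_genes	n_sets
II	G_arboreum	5	2
II	G_barbadense	2	1
II	G_hirsutum	5	2
II	G_raimondii	5	2
III	G_arboreum	2	1
III	G_barbadense	4	2
III	G_hirsutum	4	2
III	G_raimondii	2	1
IX	G_barbadense	2	1
VII-1	G_barbadense	4	2
VIII-2	G_arboreum	10	4
VIII-2	G_barbadense	11	4
VIII-2	G_hirsutum	14	6
VIII-2	G_raimondii	11	4
XI-1	G_arboreum	31	11
XI-1	G_barbadense	59	19
XI-1	G_hirsutum	42	16
XI-1	G_raimondii	35	9
XI-2	G_hirsutum	2	1
XII	G_arboreum	31	8
XII	G_barbadense	64	18
XII	G_hirsutum	25	6
XII	G_raimondii	43	9
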