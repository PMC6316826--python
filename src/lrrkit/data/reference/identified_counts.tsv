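# Published genome-wide LRR-RLK identification counts per Gossypium species,
# with the number of family genes located on unplaced scaffolds.
species	n_identified	n_on_scaffold
G_arboreum	298	11
G_barbadense	511	19
G_hirsutum	515	40
G_raimondii	317	4
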