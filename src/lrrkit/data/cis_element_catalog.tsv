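# Default cis-regulatory element catalog: element ids follow the common
# promoter-element nomenclature (ABRE, W box, LTR, ...); the IUPAC motifs are
# synthetic placeholder definitions curated for offline scanning and testing,
# not database-derived consensus sequences.
element_id	motif	category
ABRE	YACGTGGCAC	ABA response
ABRE3a	TACGTGTCGA	ABA response
TATA-box	TATATAAGGC	core promoter/enhancer element
CAAT-box	CCAATTAGCC	core promoter/enhancer element
circadian	CAAAGATATC	circadian response
LTR	CCGAAATTGC	cold response
STRE	AGGGGCGGAA	heat and osmotic stress response
ARE	AAACCAGTTG	anoxic response
GC-motif	CCCCGGCGTA	anoxic response
AP-1	TGAGTCAGCT	Cd response
TC-rich repeats	ATTCTCTAAC	defense and stress response
W box	TTGACYTTGG	wounding and pathogen response
WUN-motif	AAATTTCCTG	wounding and pathogen response
G-Box	GCCACGTGGA	light response
GATA-motif	AGATAAGGCT	light response
GT1-motif	GGTTAATTCG	light response
ERE	ATTTCAAATC	ETH response
GARE-motif	TAACAGAGCC	GA response
P-box	CCTTTTGTCA	GA response
CGTCA-motif	CGTCATGGCA	JA response
TGACG-motif	TGACGTGCAT	JA response
TCA-element	TCATCTTCAT	SA response
TGA-element	AACGACGTCA	auxin response
MBS	CAACWGGCTA	drought response
MSA-like	CCAACGGTAG	cell cycle response
RY-element	CATGCATGGC	tissue specific expression
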