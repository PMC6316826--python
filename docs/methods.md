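# Methods

This note documents the models, rules and numerical choices behind
`lrrkit`, in the order the pipeline runs them, followed by what the
synthetic-data generator does and does not emulate.

## Evidence model and identification

Three evidence streams are consumed as tabular files, never produced by
the package itself: profile-HMM domain hits (HMMER per-domain table or a
generic TSV), protein similarity hits (12-column blast tabular), and two
per-protein transmembrane-segment tables from independent predictors.

A protein enters the candidate set by either route:

* **HMM route** — at least one kinase-domain hit (Pkinase PF00069 or
  Pkinase_Tyr PF07714) *and* at least one LRR-family hit (PF00560,
  PF07723, PF07725, PF12799, PF13306, PF13516, PF13855, PF14580,
  PF01816), both with E ≤ 1e-10;
* **similarity route** — a hit against reference LRR-RLK sequences with
  E ≤ 1e-5 and identity > 50 %.

E-value cutoffs are applied as ≤ rather than < : boundary hits are
vanishingly rare in practice and ≤ is safe under floating-point
round-trips of printed E-values.  The identity cutoff is strictly >, as
conventionally printed.  For the HMMER per-domain table the per-domain
independent E-value is used as the row's statistic, since each parsed hit
is one domain row.

The final call requires LRR, KD and TM evidence simultaneously plus the
canonical N→C order.  TM presence uses an either-predictor consensus (a
single predictor reporting ≥ 1 segment suffices); the union of both
predictors' segments is retained.  Domain order is tested on span
midpoints after merging overlapping same-class spans: the rightmost LRR
midpoint must precede the leftmost TM midpoint, which must precede the
leftmost KD midpoint.  Midpoints were chosen because the source
convention for comparing partially overlapping domains is not stated;
merging first makes the test insensitive to how a repeat region is split
into multiple hits.  When a curated ("confirmed") domain-span table is
not supplied, threshold-passing HMM alignment coordinates stand in as the
spans — this keeps the confirmation step testable offline.  Rejected
proteins record the first failing check in a fixed order
(not-candidate, no-LRR, no-KD, no-TM, bad-order), which makes decoy
classes in the synthetic data exactly recoverable.

## Subfamily classification

Trees are consumed as Newick (construction is out of scope).  Reference
leaves carry one of 21 subfamily labels (I–XV with the VI-1/VI-2,
VII-1/VII-2, VIII-1/VIII-2 and XI-1/XI-2/XI-3 splits); the split
granularity lives in the anchors file, not in code.  Each unlabelled leaf
walks rootward to the smallest clade containing ≥ 1 anchor and takes the
majority anchor label; ties break by smallest patristic distance to a
tied-label anchor, residual ties are flagged ambiguous and take the
lexicographically first label.  Support is the majority share among
anchors in the deciding clade.

Rooting: a binary root in the input is treated as a genuine rooting and
preserved.  Only trees with a basal multifurcation (the usual shape of an
unrooted Newick string) are midpoint-rooted first, so the clade walk does
not depend on where the string was arbitrarily opened.  Midpoint rooting
of an already-binary tree can collapse the root into a trifurcation and
destroy a deciding clade, which is why it is applied conditionally.

## Gene structure

Domain intervals in protein coordinates are projected through the
spliced CDS: residue *r* occupies coding nucleotides 3r−2…3r after
skipping the initial phase offset, and the nucleotide run is split at CDS
segment boundaries (minus-strand genes are walked 3′→5′ in genome
coordinates).  Introns inside a domain are the number of disjoint genomic
pieces minus one, after merging genomically abutting pieces.  The KD exon
count defines the structure group: A = 1 exon, B = 2, C ≥ 3.  Group C
accepts counts above the historically observed 3–6 range, since synthetic
data may exceed it.  The ECD is defined as the region N-terminal of the
first TM residue and its introns are counted over the CDS projection of
that region; whether untranslated-region introns should count is
unknowable from annotation alone, so CDS projection was chosen as the
unambiguous convention.

Retrogene candidates are single-exon genes whose subfamily contains at
least one member with ≥ 2 introns (the "close homologue" witness for
intron loss by retrotransposition).

## Tandem duplication

All annotated genes — not only family members — are rank-indexed per
chromosome so intervening-gene counts mean genomic neighbours.  Two
family genes are tandem neighbours when they share subfamily and
chromosome, have ≤ 10 intervening genes, and their gene spans are ≤
200 kb apart.  Distance is measured between the closer ends of the two
spans (gap distance, 0 for overlap): the conservative reading of a
"200 kb distance", and configurable.  Connected components of size ≥ 2
form tandem sets, so chained arrays merge transitively even when end
members exceed the pairwise window — consistent with observed arrays of
up to 11 genes.

## Promoters and cis-elements

The promoter is the 1.5 kb upstream of the translation start (first CDS
base in transcription orientation); minus-strand promoters are
reverse-complemented so they read 5′→3′ toward the start codon, and
windows truncated at contig edges are flagged.  A catalog of IUPAC
motifs is scanned exactly on both strands with all overlapping
occurrences reported.  Gene-level category presence (≥ 1 match from any
element of a category) feeds the summary percentages and the
per-subfamily over-representation test: one-sided hypergeometric against
the whole-family background, Benjamini–Hochberg corrected across all
(subfamily, category) tests, significant at adjusted p < 0.05.

Transcription-factor binding-site analysis is the same scanner run with a
second catalog of TF-family motifs; "regulated by family X" is presence
of ≥ 1 such motif.  The packaged default catalog carries familiar element
identifiers (ABRE, W box, LTR, …) with *synthetic placeholder motifs*
(mostly concrete 10-mers, a few degenerate) — adequate for testing and
offline runs; a real study should substitute database-derived
definitions via `--catalog`.

## Enrichment and proportion statistics

GO/KEGG enrichment uses the upper-tail hypergeometric probability
p = Σ_{k≥x} C(K,k)·C(N−K,n−k)/C(N,n) with BH correction per analysis
family.  Between-species subfamily proportions are compared with Fisher's
exact test (two-sided, summing tables as or less probable than observed)
on the 2×2 table in-subfamily/rest × species, BH-corrected across
subfamilies — proportion rather than raw counts, since genome sizes
differ.  The test choice is this package's own; comparable surveys
typically leave it unnamed.

Reported percentages round half-up to one decimal (81.25 % → 81.3 %),
matching how survey tables print shares; plain banker's rounding would
differ on exact halves.

## Expression

FPKM matrices are transformed as log10(x+1); the +1 offset keeps zero
FPKM at zero and the map order-preserving.  K-means uses k = 2 (the
fiber/ovule grouping), 25 restarts, a fixed default seed of 17 and
spread ("k-means++"-style) initial centers; determinism given the seed is
contracted, the initializer is an implementation detail.  Hierarchical
clustering is Ward linkage on the log matrix cut into exactly 4 groups
(the abiotic-stress grouping).  Group numbers are canonicalized by
descending mean expression.  The DE filter reads "log2FC > 1" as
magnitude (|log2FC| > 1), because both up- and down-regulated genes are
reported downstream, and requires the thresholds in every required
contrast (both infection strains) under the intersection rule.

## Synthetic data: what it emulates, what it does not

`lrrkit.simulate` generates, deterministically per seed: a 2-chromosome +
1-scaffold genome with 300 genes, 60 of them family genes across 8
subfamilies; domain layouts honoring LRR–TM–KD order with per-subfamily
KD exon structure (groups A/B/C); four within-window tandem arrays plus
two deliberate near-misses (one pair 250 kb apart, one pair with 12
intervening genes); two intronless retrogenes in subfamilies with
multi-intron witnesses; ten decoys covering every rejection class;
evidence tables whose zero-noise identification is exactly the planted
family; a subfamily-clade tree with two anchors per subfamily and an
optional leaf-misplacement rate; promoters re-rolled until motif-free and
then planted with exact occurrence counts (verified by an independent
naive sliding-window scan, with one subfamily/category pair planted as
enriched); two-cluster development and four-level stress FPKM matrices
(log-normal, widely separated); and DE tables with genes passing both,
one, or neither contrast.

Non-retro family genes always carry ≥ 1 intron so that intronless
structure appears only where planted.  Scattered same-subfamily genes are
kept > 10 intervening genes apart by construction, and an internal
assertion verifies no accidental tandem adjacency survives.

Deliberately not emulated: realistic sequence evolution (proteins are
random strings; domains exist only in the evidence tables), UTRs and
alternative transcripts beyond the representative-mRNA rule, realistic
FPKM distributions beyond log-normal clusters, and GO/KEGG annotation
maps (enrichment is exercised on synthetic term maps in the tests).
Passing tests therefore demonstrate the correctness of the *rules and
arithmetic* on inputs of the declared shape — not robustness to noisy
real-world annotation or search output beyond the modelled noise rates
(evidence false negatives/positives, TM predictor disagreement, leaf
misplacement).

## Problem sizes and numerical conventions

The default desk-scale genome (300 genes, 60 family members) exercises
every rule in a few seconds; oracle-equivalence checks run the tandem
detector against an exhaustive pair graph on fifty 200-gene chromosomes,
the coordinate mapper against a per-base brute-force map on a hundred
random gene models (both strands), the enrichment tail against full
subset enumeration for backgrounds ≤ 12, and the motif scanner against a
naive sliding window on 10 kb sequences.  Representative transcripts are
the longest-CDS mRNA with lexicographic tie-break.  Chromosome-versus-
scaffold status is a configurable sequence-name regex (default accepts
`A1`-style and bare-number names).  Noise-rate recovery checks use 95 %
binomial intervals at n = 60.  All randomness flows from explicit seeds;
identical seeds give byte-identical fixtures and reports.
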