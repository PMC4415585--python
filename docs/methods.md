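# Methods

This note documents the models behind `mcminer`, the defaults that matter,
and what the synthetic experiments do and do not demonstrate.

## Synthetic community model

**Genomes.** Each genome is sampled from an order-3 Markov chain over
{A,C,G,T}. All genomes share one base logit matrix (a package constant); a
genome's `composition_divergence` (default 1.0) is the standard deviation of
Gaussian noise added to those logits, which directly controls how far apart
genomes sit in tetranucleotide space — the feature the binning stage relies
on. After perturbation the transition matrix is exponentially tilted toward
G/C and the tilt is found by bisection on the chain's stationary GC so the
realised genomic GC lands within ~0.02 of `gc_target`. Divergence 0 gives
genomes that are compositionally near-identical (binning should fail);
divergence ≥ 1 with GC targets ≥ 0.05 apart gives clean separation.

**Annotations.** 40 universal single-copy marker families (900 bp, evenly
spaced, non-overlapping), 20 tRNA-synthetase classes (300 bp), and
protein-coding genes every 1 kb whose function labels are drawn from a
shared pool (default 200 labels) plus genome-unique labels (default 40).
These stand in for an annotation engine: they are labels with coordinates,
not biological sequences, which is all the downstream tallies need.

**Communities and enrichment.** The untreated community is uniform or
lognormal over genomes (the field lacks a measured abundance distribution
for this setting; lognormal is the conventional assumption and sigma is a
parameter). An enrichment scenario multiplies 1–3 genomes' abundances by
10²–10⁵ (log-uniform) and renormalises, while the DNA yield is scaled by a
decline factor drawn from [0.03, 0.6] — emulating blooms against an overall
population crash (e.g. 25 µg/g of extractable DNA dropping to below 1 µg/g).
After renormalisation, a genome's realised relative enrichment equals its
multiplier divided by the abundance-weighted mean multiplier.

**Reads.** Read counts per genome are multinomial with weights
abundance × genome length; positions uniform; lengths Gaussian
(mean 350 nt, sd 30, clipped at 50); errors are i.i.d. substitutions at
`error_rate` (default 1% in the pipeline). Indels and homopolymer errors —
the signature artefact of pyrosequencing — are deliberately not modelled:
substitution-only reads keep identity = matches/length exact and make the
mapping stage analytically checkable. Reads are forward-strand by default
(so an error-free read is literally a substring of its genome); the mapper
checks both orientations regardless.

**Contigs.** Assembly is emulated, not performed. A genome whose implied
coverage (abundance × `coverage_per_abundance`, default 100) reaches the
assembly floor (default 5×) is emitted as contigs: random lengths around
`mean_contig_len` (40 kb), inter-contig gaps of at most 4% of a contig
length (so ≥ 80% of the genome is covered), per-contig coverage = implied
coverage with 5% multiplicative noise. Genomes below the floor yield
nothing — they remain "rare biosphere". Annotations fully contained in a
contig are carried over in contig coordinates; annotations straddling a
breakpoint are lost, which is also what fragmented assemblies do to real
genes. For subsampling experiments where retained length should translate
one-to-one into retained markers, `tile_genome` provides an exact gap-free,
marker-aligned partition instead.

## Composition and binning

Tetranucleotide profiles use 136 canonical classes (each 4-mer identified
with its reverse complement) rather than raw 256 counts, making profiles
independent of which strand an unoriented contig was assembled from.
Windows containing any non-ACGT symbol are skipped whole. Structures are
fragmented into 20 kb sections with a 10 kb floor; a terminal remainder
below the floor merges into the previous section when that stays ≤ 20 kb,
otherwise the tail re-splits into two near-equal sections ≥ 10 kb each, so
every emitted section respects the 10–20 kb contract and the tiling is
gap-free.

Clustering is agglomerative on Euclidean distances, average linkage by
default (complete and Ward available). The implementation re-scans all
cluster pairs each step and recomputes distances from the original matrix,
with a deterministic tie-break (the pair whose smallest leaf indices are
lexicographically least). This O(n³) strategy is deliberate: section counts
are a few hundred at most, the merge sequence becomes exactly reproducible,
and the algorithm is directly comparable to an independent oracle; the test
suite additionally cross-checks flat cuts against scipy's linkage on
tie-free inputs. Coverage and GC are *not* clustering features (an opt-in
concatenated feature space exists): they are post-hoc coherence checks — a
bin whose members' coverage CV exceeds 0.5 (default) is flagged as likely
mixing populations at different abundances. Supervised binning — a human
merging or splitting clusters on an interactive plot — is represented
faithfully as explicit leaf-id lists (`manual` mode), with an `unbinned`
remainder bin; no attempt is made to model human judgement.

## Read recruitment and enrichment arithmetic

A read is recruited to a structure iff an ungapped placement on either
strand covers every read base at identity ≥ the threshold, where identity is
matches/read length. Placements are found by exact 16-mer seeding (seeds
sampled along the read at stride 4, plus the terminal seed) and verified by
direct array comparison; at a 90% threshold and 350 nt reads, dozens of
seeds guarantee a clean 16-mer with overwhelming probability. This is a
simplification of gapped mappers, consistent with the substitution-only read
model; "over the full read length" is interpreted strictly (reads hanging
off a structure end are rejected). With `one_best_target` (default), each
read counts toward the highest-identity structure, ties to the smallest
structure id.

Detection requires ≥ 10 recruited reads; the corresponding detection limit
in percent is 10/total_reads × 100 and is a policy parameter, not a
constant, because it depends on each dataset's depth (a ~12M-read reference
dataset puts the floor near 0.0001%). The relative in-situ enrichment of a
structure is its microcosm read proportion over its natural proportion,
reported at 2 significant figures; when the structure is undetected in the
natural data the quotient against the detection limit is reported as a
lower bound. Cell estimates multiply the natural proportion (as a fraction)
by 10⁹ cells/g of surface soil.

16S-style screening keeps reads having a local ungapped alignment of at
least `min_alignment_length` (200 nt) at ≥ 90% identity to any labelled
reference, assigning the best reference's taxon; inclusion is decided by
scanning windows of exactly the floor length along seed diagonals (a longer
segment qualifying only as a whole could in principle be missed; under
uniform substitution noise this is immaterial). Consensus building is a
greedy overlap layout (suffix/prefix overlaps ≥ 100 nt at ≥ 99%) with
per-column majority vote, each read joining at most one contig, the longest
contig serving as the taxon consensus.

## GC skew and scaffold arrangement

Skew is (G−C)/(G+C) per fixed window (trailing partial window dropped;
G+C = 0 scores 0). Scaffold ordering/orientation maximises a two-part
objective: primarily the fraction of skew steps consistent with a single
unimodal cumulative curve (one origin, one terminus), secondarily — among
equally unimodal arrangements — the smallest total variation of the
windowed skew series, because skew drifts gradually along a replichore and
an out-of-place scaffold appears as a jump. The search is exhaustive up to
6 scaffolds (all orders × orientations) and greedy insertion beyond. The
mirror arrangement (reversed order, all orientations flipped) is the same
molecule read from the other strand and is returned interchangeably. With
sign-only skew and compositionally homogeneous scaffolds the within-arm
order is fundamentally unidentifiable; the total-variation term resolves it
exactly when a skew gradient exists.

## Statistics

Kruskal–Wallis is computed from the rank formula with tie correction and a
chi-square p-value on (groups − 1) df; the test suite verifies equality
with an independent rank computation and with scipy, and calibrates the
type-I error at 5% ± 2% over 1,000 null simulations. No multiple-testing
correction is applied by default — the conventional readout in this setting
is raw p < 0.05 — but Benjamini–Hochberg q-values are available and flagged
in the output header. Each sample is treated as one observation; how
replicate microcosms are grouped into conditions is the caller's input.
Sample classification uses scipy's Ward linkage on Euclidean distances
between per-sample profiles; with planted groups the dendrogram is cut at
k = number of groups and scored by adjusted Rand index.

## Problem sizes and defaults

The synthetic experiments are scaled to a desktop: genomes of 50–620 kb
(620 kb where ≥ 30 sections per genome are required), communities of 3–8
genomes, 10³–10⁵ reads per sample, three ESCs in the demo pipeline. At this
scale a "rare" genome in a uniform natural community still sits at
percent-level proportions, so pipeline enrichment factors compress to
10⁰–10¹ even though the arithmetic is identical to the rare-biosphere
regime (the worked-example values exercise the full 10²–10⁵ range). The
acceptance script's recovery experiments use exactly these sizes.

## What passing tests do and do not show

The generator produces communities whose compositional structure, coverage
structure and enrichment arithmetic match the analysis assumptions, by
construction. Perfect recovery on it demonstrates internal correctness —
the clustering separates what the composition model makes separable, the
mapper counts what the read model makes countable — not performance on real
soil data, where strain mixtures, chimeric contigs, indel-rich reads,
horizontal transfer and shared mobile elements violate these assumptions in
ways the generator deliberately does not model (see Non-goals: no indels,
no chimeras, no mate pairs, no real assembler). The bundled published
summary table is used as *input* to the arithmetic operations; rows whose
printed enrichment is inconsistent with the quotient of their own printed
proportions (two such rows exist, presumably input rounding or typos) are
excluded from the worked examples.

## Numerical conventions

Coordinates 0-based half-open everywhere; FASTA written uppercase at 60
chars/line; FASTQ with constant quality 'I'; TSV with `#` metadata headers
naming the config hash. Enrichment factors, cell counts and summary
percentages are reported at 2 significant figures. All randomness flows
through explicit integer seeds; identical configuration reproduces
byte-identical artifacts.
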