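# Methods

## Model

`phylokmer` treats read classification as placement on a rooted
reference tree. The database is a key-value store over canonical k-mers
of the reference collection; the value of k-mer *x* is the tree's
lowest common ancestor of all leaves whose genomes contain *x*. This is
the tree-space analogue of taxonomic-LCA databases: a k-mer unique to
one genome resolves to its leaf, a clade-conserved k-mer resolves to the
clade root, and a universally conserved k-mer resolves to the tree root.

The underlying assumption is that if a read truly derives from (a close
relative of) reference *S*, every database value its k-mers hit must lie
on the root-to-leaf path ending at *S*. Hits off that path — a read
whose k-mer distribution spans multiple root-to-leaf paths — signal
either noise or sequence from an organism without a close reference.
Reads are therefore classified as single-lineage (SL) when one lineage
survives filtering and split-lineage otherwise, and split counts
accumulated per clade serve as a database-gap diagnostic.

## Algorithms and data structures

**Tree.** Node IDs are assigned in preorder (root = 0), so every
subtree is the contiguous ID range `[id, id + subtree_size)`. Ancestor
tests are two comparisons; an LCA query walks up from the
smaller-preorder node until its range covers the other (O(depth), cheap
on the near-balanced trees produced by random leaf attachment and
typical phylogenies). The LCA of a *set* is the LCA of its minimum- and
maximum-preorder members, which the index build exploits to reduce
per-k-mer leaf sets to (min, max) pairs and memoize LCA over unique
pairs. Multifurcating trees are accepted as written; no rerooting is
performed, and correctness nowhere assumes bifurcation.

**Encoding.** Bases map to A=0, C=1, G=2, T=3, packed
most-significant-first, so integer order equals lexicographic order and
a sorted uint64 array supports `searchsorted` lookup. k is capped at 31
(one uint64) and must be odd under canonicalization so no k-mer is its
own reverse complement. Windows containing non-ACGT characters are
skipped during extraction and counted as misses during read mapping.

**Build.** Per-leaf distinct k-mer sets are partitioned by high bits of
the encoding, each partition sorted and reduced independently, and the
partitions concatenated — bounding peak memory while leaving the output
byte-identical to a single-shot sort (verified in tests). All records
of one FASTA belong to one leaf; record boundaries never produce
spanning k-mers.

**Classification.** Lineage support is the sum of hit counts over the
terminal's root path. A hit node ancestral to several terminals
contributes to each lineage's support: ancestral hits are evidence for
every lineage beneath them. This deliberately double-counts across
lineages; conserved totals in reports use raw per-read statuses, which
do conserve (SL + split + unclassified = reads). The support statistic
compared against α is this root-path sum divided into mapped k-mers —
one consistent choice among several possible support definitions, and
the one documented contract here.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 31 | k-mer length (odd, ≤ 31); long k-mers give near-genome-specific keys |
| α | 0.1 | minimum lineage support as a fraction of mapped k-mers; absorbs sequencing-error noise without hiding genuine chimeric signal |
| paired_mode | concatenate | mates merged into one hit distribution (one fragment, one organism); `separate` classifies each mate alone |

The α default is this package's choice, made for general short-read use;
it is prominently configurable (`--alpha`). When α would discard every
lineage, the best-supported lineage is retained (ties to the smaller
preorder ID) so a read with hits never becomes unclassified by
filtering. FASTQ quality scores are ignored.

## Taxonomy projection

Every tree node maps to the taxonomic LCA of the taxids of reference
genomes in its subtree, computed bottom-up in one pass (taxonomic LCA is
associative over the partition into child subtrees). The projection is
monotone: along any root path, mapped taxids only coarsen. Leaf taxids
arrive as a two-column TSV; `merged.dmp` aliases are applied when
supplied; taxids absent from the dump are an error rather than silently
reassigned.

## Output formats

Per-read lines follow the Kraken dialect: status (C/U), read id,
assigned node label or taxid (0 when unclassified), read length
(`len1|len2` for pairs), and a run-length encoding of per-k-mer
outcomes in read order (`id:count`, misses `-:count`, mate boundary
`|:|`). The exact per-k-mer column dialect is this package's contract.
Reports print percentage (two decimals, half-up), clade count, direct
count, rank code (Kraken letters in taxonomy space, `-` in tree space),
identifier, and a two-space-per-level indented name; zero-count rows are
omitted; an unclassified row comes first. The split table lists, per
node with any classified clade reads: depth, direct SL/split counts,
clade-cumulative split count and split fraction, sorted by descending
cumulative splits.

## Synthetic data

The generator emulates the study conditions at desk scale: random
bifurcating topologies by sequential random leaf attachment; a uniform
random root genome (default 5 kb) evolved by i.i.d. per-branch point
substitutions (default 2% per branch, substitution-only so truth k-mer
sets stay analyzable); reads drawn uniformly over genomes, positions and
strands with i.i.d. substitution errors. Everything is a pure function
of its seed, byte-for-byte. It does not model indels, rearrangements,
quality-correlated errors, abundance skews or host contamination —
passing tests demonstrate algorithmic correctness on
substitution-divergent genomes, not benchmark performance on real
communities.

## Validation experiments (scripts/acceptance.py)

Problem sizes are chosen so the whole battery runs in seconds on one
CPU: 100 random trees of 5–200 leaves for the LCA oracle; 21 fixtures
(5 leaves, 1.5 kb, k ∈ {7, 11, 15}) for exhaustive database
verification; one 16-leaf / 5 kb community with 10,000 error-free 150 bp
reads at k = 31 for placement soundness; ten 12-leaf / 3 kb communities
for the leave-one-out split experiment; ten 9-leaf fixtures over a
two-genus fixture taxonomy for projection; and triplicate builds at 1,
4 and 16 partitions for determinism.

In the leave-one-out experiment the removed genome is a leaf of the
*deepest* cherry. This is deliberate experimental design: the split
diagnostic targets organisms whose relatives are present but scattered
across database clades, which requires the removed leaf to share
sequence with references beyond its sister. A cherry attached at the
root can share no k-mers with any non-sister leaf (all other lineages
are maximally divergent), in which case reads simply go unclassified or
SL at the sister — there is no gap signal to detect, for any method.

## Known limitations

- k ≤ 31; longer k-mers would need a two-word encoding.
- LCA queries are O(depth); pathological caterpillar trees with millions
  of leaves would warrant an Euler-tour/sparse-table index instead.
- Builds hold each partition's k-mer set in memory; genuinely large
  reference collections would need on-disk spills.
- No low-complexity masking of references, no minimizer subsampling, no
  abundance re-estimation downstream of raw counts.
- The classifier is single-threaded; the determinism contract (outputs
  independent of batching/partitioning) is what a parallel
  implementation would have to preserve.
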