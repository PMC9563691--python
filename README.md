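# phylokmer

Taxonomy-agnostic classification of shotgun metagenomic reads against an
arbitrary rooted reference tree, using a k-mer → lowest-common-ancestor
database.

## The problem

Reference-based metagenomic profilers typically assign reads to NCBI
taxa, but taxonomic groups do not always reflect genomic relatedness:
clades that share a phenotype may cut across named ranks, and strains of
one species may be more divergent than the rank suggests. `phylokmer`
classifies reads directly onto a user-supplied reference tree — a
phylogenetic or distance tree over the reference genomes — so results
are expressed in terms of the actual hierarchical structure of the
references. A taxonomic summary can still be produced afterwards by
projecting tree nodes onto the NCBI taxonomy.

The same machinery doubles as a database-gap detector: reads whose k-mer
hits span several root-to-leaf paths ("split-lineage" reads) concentrate
in clades that lack a close reference genome, pointing at the isolates
whose addition would most improve the database.

## Method

**Database.** For k-mer length *k* (default 31), every canonical k-mer
*x* (the lexicographic minimum of a window and its reverse complement,
*k* odd) occurring in any reference genome is stored with the value

> LCA( { leaves ℓ : x occurs in genome(ℓ) } )

where LCA is taken in the reference tree. Keys are 2-bit encoded,
sorted, and looked up by binary search.

**Classification.** For a read *r* with k-mer distribution
*c : node → count* (the multiset of database values hit by the read's
k-mers):

1. *Lineage decomposition* — the terminals are the hit nodes with no hit
   strictly below them; each terminal *t* defines a lineage with support
   *s(t) = Σ c(v)* over hit nodes *v* on the root path of *t*.
2. *α filter* — lineages with *s(t) < α · m* are discarded, where *m* is
   the number of mapped k-mers (default α = 0.1); if nothing survives
   the single best-supported lineage is kept.
3. *Assignment* — the read is assigned to the lowest common node of the
   surviving terminals: the deepest hit itself for a single-lineage (SL)
   read, an ancestral node for a split-lineage read.

Per-read results, hierarchical clade-count reports, and taxonomy-space
projections are written in the Kraken formats, plus a split-count table
ranking clades by split-lineage read load.

## Worked example

```sh
phylokmer simulate --n-leaves 6 --genome-length 1200 --substitution-prob 0.05 \
    --n-reads 60 --seed 7 --out-dir fixture
phylokmer build --tree fixture/tree.nwk --genomes fixture/genomes \
    --k 21 --out db.pki
phylokmer classify --db db.pki --tree fixture/tree.nwk \
    --out-dir results fixture/reads.fastq
head -4 results/report.tsv
```

prints (percentage of reads, clade count, direct count, rank, node,
indented name):

```
0.00	0	0	U	0	unclassified
100.00	60	0	-	n0	n0
26.67	16	16	-	G1	  G1
73.33	44	0	-	n2	  n2
```

All 60 reads were classified (unclassified row at 0.00%); 16 reads
(26.67%) were assigned directly to leaf genome `G1`, and the remaining
44 fall inside the clade rooted at internal node `n2`, none directly at
the root — with error-free reads and all genomes indexed, every read
resolves to a node on its source genome's root-to-leaf path. Deeper
rows (not shown) attribute the rest to the other leaf genomes. `results/splits.tsv` ranks nodes by
split-lineage load, and `results/per_read.tsv` holds one Kraken-style
line per read.

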