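# kmersnp

Alignment-free, reference-free SNP discovery from microbial genome
sequences, with phylogeny estimation from the discovered SNP matrix.

## The problem

Phylogenetic analysis needs homologous sites. For whole microbial genomes,
multiple alignment is impractical beyond a handful of taxa, and
reference-based SNP calling only sees variation present in the chosen
reference. `kmersnp` sidesteps both: two odd-length k-mers from different
genomes that are **identical at every position except the central base**
are taken as homologous, and that variable central base is a SNP. Each SNP
locus is thus a conserved (k−1)-base context with a per-genome central
allele. The method needs no alignment and no reference, works on complete
genomes, assemblies, or raw reads, and scales to hundreds of bacterial or
viral genomes. It is aimed at microbial phylogenomics, outbreak tracking,
and strain typing.

Key quantities:

- **FUK** (fraction of unique k-mers): among the distinct canonical k-mers
  of the median-sized genome, the fraction occurring exactly once. The
  optimal k is the smallest odd k at which FUK stops improving
  (ΔFUK < 0.001) — short enough to keep SNP contexts conserved, long
  enough that k-mers match by descent rather than chance.
- **FCK** (fraction of core k-mers): the fraction of k-mers sampled from
  the shortest genome that occur in *every* genome. When FCK ≥ 0.1, the
  topological accuracy of parsimony trees is ≥ 90%.
- **Trees**: maximum parsimony (Fitch score, exhaustive search for ≤ 8
  taxa, seeded random-addition + NNI otherwise) with a majority-rule
  consensus of up to 100 equally parsimonious trees, internal nodes
  labelled with the integer number of retained trees containing the
  clade; and Saitou–Nei neighbor joining on SNP p-distances. All trees
  are unrooted Newick.

## Worked example

Simulate a 10-genome data set evolved along a known tree, then run the
pipeline exactly as you would on real FASTA files:

```bash
kmersnp simulate -outdir demo --n-taxa 10 --genome-length 20000 --seed 1
kmersnp kchooser -in demo/genomes.in
kmersnp run -in demo/genomes.in -outdir demo/run1 -k 15 -core -NJ --seed 1
```

The k-chooser report (`Kchooser_genomes.in.report`) ends with:

```
median-sized genome: g05
optimum k-mer length: 15
FCK (fraction of core k-mers, 1000 k-mers sampled from shortest genome g01, seed 42): 0.3790
FCK >= 0.1: expected parsimony topological accuracy is at least 90%.
```

FUK converged at k = 15 (a random 20 kb sequence has essentially no
repeated 15-mers), and 37.9% of the shortest genome's 15-mers are present
in all ten genomes — comfortably above the 0.1 accuracy threshold. The
run itself prints:

```
INFO read 10 genomes
INFO found 1106 SNPs at k=15
INFO all-SNP parsimony: best score 1106 over 3 retained tree(s)
INFO 510 core SNPs
INFO core_SNPs parsimony: best score 510 over 3 retained tree(s)
INFO run complete: demo/run1
```

1,106 conserved contexts vary at their central base; the best parsimony
score equals the SNP count because almost every site is a clean single
substitution on one branch (one change per site is the theoretical
minimum for a bi-allelic site). 510 of those loci have a called allele in
all ten genomes (core SNPs). `demo/run1/` contains `COUNT_SNPs`, the
alignment-like `SNPs_all_matrix.fasta` (`-` marks missing), per-locus
positions and strands in `SNPs_all`, pairwise SNP differences, and the
Newick trees `tree.parsimony.tre`, `tree.core_SNPs.parsimony.tre`,
`tree.SNPs_all.NJ.tre` — internal labels on the parsimony consensus are
clade-support counts (here 3 of 3 retained trees). Comparing
`tree.parsimony.tre` with `demo/true_tree.nwk` shows every branch of the
generating topology recovered except one very short internal branch that
received no substitutions, which the consensus correctly leaves as a
polytomy (topological accuracy 0.93).

With GenBank files available, add `-annotate LISTFILE --genbank-dir DIR`
to classify each SNP as synonymous / nonsynonymous / intergenic with
codon, amino acid, peptide context and gene product
(`annotation_summary.tsv`, `SNPs_all_annotated.tsv`).

## Library use

```python
from kmersnp import find_snps, parsimony_search, read_genomes, InputManifest

genomes = read_genomes(InputManifest.read("run.in"))
matrix = find_snps(genomes, k=15)
result = parsimony_search(matrix, seed=1)
print(matrix.n_loci, result.best_score)
```
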