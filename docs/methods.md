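# Methods

## The SNP model

A SNP locus is an operational, alignment-free notion of homology: an
odd-length k-mer splits into a central base and a (k−1)-base context (the
two flanks concatenated). If the same context occurs in two genomes with
different central bases, the central site is called a SNP, on the
assumption that a sufficiently long exact flank match is identical by
descent rather than by chance. The assumptions this rests on:

- k is large enough that a (k−1)-context match is almost never chance
  identity (genome-length dependent — hence data-driven k selection);
- k is small enough that the flanks of a true SNP are themselves free of
  variation across the sampled genomes (divergence dependent);
- repeats that would make a context ambiguous within a genome are rare,
  and when they occur with two different central bases the honest answer
  is "unknown" for that genome.

Because genomes are double-stranded, every window is canonicalized to the
lexicographically smaller of the k-mer and its reverse complement before
comparison. The reverse complement of `L + c + R` is
`rc(R) + comp(c) + rc(L)`, so the canonical context is well defined and
results are exactly invariant under reverse-complementing any input
(verified by property tests). One inherent blind spot of this convention:
for the 4^((k−1)/2)-th fraction of contexts that are their own reverse
complement, the two strands report complementary central bases, so an
A↔T or C↔G polymorphism at a palindromic context collapses and is
invisible. At k = 11 this affects fewer than 1 in 1,000 contexts; the
naive oracle used in tests shares the convention, so comparisons are
exact.

### Calling rules

Per genome, a map context → {allele: positions} is built from all
canonical windows (windows containing any non-ACGT letter are skipped
entirely rather than expanded over IUPAC possibilities — conservative,
and avoids combinatorial allele inflation). Then:

1. a genome holding more than one distinct allele for a context is set to
   MISSING (`-`) at that locus — the repeat/paralog guard. The locus is
   kept for the unambiguous genomes rather than discarded globally;
2. a context with at least two distinct non-missing alleles across
   genomes becomes a locus;
3. multiple occurrences of a context with a single allele in one genome
   are allowed (the allele counted once, all positions reported);
4. loci are ordered lexicographically by context, which fixes locus ids,
   matrix columns, and all downstream output deterministically.

Core loci are those with a called allele in every genome. Pairwise
distances come in two forms: raw counts of differing, mutually called
loci, and p-distances (count / number of mutually called loci), the
latter feeding neighbor joining. An optional `--min-kmer-count` filter
(default 1) drops low-multiplicity k-mers before calling, intended for
raw-read input where singleton k-mers are dominated by sequencing error;
assemblies should keep the default.

## Choosing k

FUK — the fraction of the median-sized genome's distinct canonical
k-mers that occur exactly once — is evaluated at k = 7, 9, 11, … and the
scan stops at the first k whose improvement over k−2 falls below 0.001;
that k is reported as the optimum (the converged value is at least as
unique as its predecessor). A small tolerance rather than FUK = 1 is used
because genuinely duplicated regions keep FUK below 1 at any k. Bounds
k_start = 7 and k_max = 31 cover genomes from short viruses to bacteria;
if FUK has not converged by k_max the scan reports k_max with a warning.
The median of an even count is the lower median, ties broken by genome
id, so the choice is deterministic.

FCK samples 1,000 distinct canonical k-mers (without replacement, seeded,
default seed 42, recorded in the report) from the shortest genome and
reports the fraction present — on either strand — in every genome. If the
shortest genome has fewer distinct k-mers than requested, all are tested
with a warning. FCK ≥ 0.1 is the guidance threshold above which parsimony
trees are expected to reach ≥ 90% topological accuracy; the acceptance
script re-derives that number by simulation.

## Trees

**Parsimony.** Site patterns are collapsed with weights; each allele is a
4-bit state set (MISSING = all four bases, i.e. fully ambiguous) and the
Fitch small-parsimony score is computed bottom-up with vectorized bitwise
operations across patterns. For ≤ 8 genomes the search enumerates all
(2n−5)!! unrooted topologies, so the reported best score is provably
optimal; above 8 it uses random-addition-order stepwise insertion
followed by NNI hill climbing with seeded restarts (default 8), keeping
ties encountered on the final plateau. Up to 100 distinct best-score
topologies (identity = split set) are retained; their majority-rule
consensus is reported with each internal node labelled by the integer
count of retained trees containing that clade. Retained trees carry
branch lengths equal to mean Fitch state changes per SNP site on each
branch (one standard traceback); the consensus carries supports only. A
matrix with zero loci is an error ("no SNPs to analyze"), and fewer than
four genomes admit a single topology, which is returned directly.

**Neighbor joining.** Canonical Saitou–Nei on p-distances, with numpy Q
matrices and first-minimum tie-breaking. Negative branch-length estimates
are clamped to zero with the deficit moved to the sibling branch of the
join, preserving the joined pair's distance. On additive inputs NJ
reproduces topology and branch lengths exactly (tested to 1e-9). A genome
pair sharing no called loci has an undefined p-distance; NJ refuses with
advice to use core SNPs or a different k.

Maximum likelihood is deliberately not implemented: the `-ML` flag is
accepted and answers with a pointer to running an external ML program on
`SNPs_all_matrix.fasta`.

**Robinson–Foulds.** Topological accuracy used throughout is
1 − RF/(2(n−3)), where RF is the symmetric split difference. Consensus
polytomies count their absent splits against accuracy, so an unresolved
consensus is penalized, not excused.

## The synthetic-data generator

The generator is first-class, tested code and defines the conditions
under which the accuracy claims are computed:

- **Tree**: Yule topology by uniform random tip splitting; i.i.d.
  exponential branch lengths rescaled so the maximum root-to-tip path is
  `height` expected substitutions per site (default 0.03). With 10 taxa
  and 20 kb this yields total tree lengths near 0.1 subs/site, i.e.
  roughly 1,000–2,500 SNPs and measured FCK between about 0.15 and 0.5 at
  the selected k — safely above the 0.1 guidance threshold while
  realistically leaving occasional internal branches with no
  substitutions (such branches are unknowable by any method and appear as
  consensus polytomies).
- **Ancestor**: i.i.d. uniform ACGT, repaired until every canonical
  window at the uniqueness k (default 15) is distinct, so no fixture
  contains conflicted contexts by construction.
- **Substitutions**: per-branch Poisson counts with Jukes–Cantor base
  choice. Infinite-sites mode (default) draws all mutated sites without
  replacement across the whole tree, so each planted SNP is bi-allelic
  and its carriers form a clade — the emitted truth is exact. An optional
  minimum site spacing ≥ k keeps every SNP's context unmutated, making
  SNP discovery provably recover the truth set one for one.
- **Reads**: uniformly placed, error-free, both strands, at a requested
  coverage. Sequencing error is intentionally not modelled — it
  interacts with the min-count filter whose real-world default is a
  tuning question, not a correctness one.
- **GenBank fixtures**: `synth_genbank` writes valid flat files (plus- or
  minus-strand CDSs, `codon_start`, products) whose sequence matches the
  FASTA record, for exercising the annotation stage offline.

What passing these simulations does *not* show about real data:
no indels, no recombination, no rate heterogeneity, no contamination,
and no sequencing error, so real assemblies will show more MISSING calls
and somewhat lower FCK at the same divergence.

## Annotation

Only local GenBank files are read (`--genbank-dir`); nothing is fetched
from the network. The GenBank sequence must equal the FASTA sequence used
for calling (case-insensitive; contigs matched by name, else by order).
SNP positions come from the discovery pass — nothing is re-searched. For
each position, every overlapping CDS yields a row: the frame-aware codon
(strand and `codon_start` respected), its translation (table 11,
bacterial/archaeal, configurable per run), a peptide window of 5 residues
each side, and the product. Alleles are mapped from the locus's canonical
strand to the genome's forward strand via the recorded strand flag, then
onto the CDS strand. Synonymy substitutes each alternative allele
observed at the locus into the codon: all identical translations →
synonymous, any difference → nonsynonymous; no overlapping CDS →
intergenic; overlapping CDSs with differing verdicts → mixed (summary
level). Codons truncated by a CDS end are flagged partial rather than
raised. Synonymy is symmetric in the allele pair — there is no reference
genome to privilege.

## Numerical and interface choices

- Positions are 1-based on the forward strand of the named contig; the
  strand flag records whether canonicalization flipped the window.
- Manifest entries are sorted by genome id; all outputs are
  byte-deterministic given (inputs, k, seed), and no output embeds a
  timestamp, so reruns are bit-identical and diffable.
- Newick serialization places integer supports as internal node labels
  (MEGA-compatible); trees are emitted unrooted (basal trifurcation) and
  rooting is left to the viewer.
- Problem sizes in the test suite and acceptance script (10 taxa, 20 kb,
  50 replicates for the headline number; 10 replicates for the suite's
  in-line check) were chosen as the smallest sets at which per-branch
  substitution counts and FCK behave like the regime the guidance
  threshold describes.

## Known limitations

- Indels and rearrangements are invisible by design; only substitutions
  in conserved contexts are called.
- Palindromic-context A↔T / C↔G polymorphisms are undetectable (see
  above).
- The repeat guard is per-genome; a repeat fixed for the same allele in
  every genome silently behaves as a single locus with multiple
  positions.
- The parsimony search above 8 taxa is heuristic; seeded restarts make it
  reproducible but not provably optimal.
- Raw-read input assumes the min-count filter is set sensibly by the
  user; no base-quality model exists.
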