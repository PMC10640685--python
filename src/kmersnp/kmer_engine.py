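"""Odd-length k-mer enumeration, canonicalization and counting.

Every downstream stage (optimal-k selection, SNP discovery) works on
*canonical* k-mers so that results are independent of which strand of a
double-stranded genome happened to be sequenced.  A k-mer of odd length k
splits into a central base (the potential SNP allele) and a (k-1)-base
context (the two flanks); homology between genomes is asserted when the
context is identical and only the central base varies.

Canonical form: the lexicographically smaller of a k-mer and its reverse
complement.  Because the reverse complement of ``left + center + right`` is
``revcomp(right) + complement(center) + revcomp(left)``, the context of the
reverse complement is exactly the reverse complement of the context, so a
k-mer and its mirror image always collapse onto one context/allele pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from .genome_io import GenomeRecord

__all__ = [
    "ContextAllele",
    "revcomp",
    "complement_base",
    "canonicalize",
    "enumerate_kmers",
    "count_kmers",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class ContextAllele:
    """A canonical (k-1)-base context plus the central-base allele.

    ``flipped`` records whether canonicalization reverse-complemented the
    originating window; the allele is already expressed on the canonical
    strand.  Equality and hashing use (context, allele) only: a window and
    its reverse complement are the *same* canonical observation, differing
    only in provenance.
    """

    context: str
    allele: str
    flipped: bool = field(compare=False)

    @property
    def k(self) -> int:
        return len(self.context) + 1


def check_k(k: int) -> None:
    if not isinstance(k, int) or k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")


def canonicalize(kmer: str) -> ContextAllele:
    """Map a k-mer to its canonical context/allele representation.

    The canonical form is the lexicographically smaller of the k-mer and
    its reverse complement; the context is that form minus its central
    base and the allele is the central base of that form.  A k-mer and its
    reverse complement map to the identical :class:`ContextAllele`.
    """
    check_k(len(kmer))
    rc = revcomp(kmer)
    h = len(kmer) // 2
    if rc < kmer:
        return ContextAllele(rc[:h] + rc[h + 1 :], rc[h], True)
    return ContextAllele(kmer[:h] + kmer[h + 1 :], kmer[h], False)


def enumerate_kmers(
    record: GenomeRecord, k: int
) -> Iterator[Tuple[ContextAllele, str, int, str]]:
    """Yield every valid k-window of a genome as a canonical context/allele.

    Yields ``(context_allele, contig_name, position, strand)`` where
    ``position`` is the 1-based coordinate of the central base on the
    forward strand of the named contig and ``strand`` is ``'-'`` when
    canonicalization flipped the window.  Windows containing any letter
    outside A/C/G/T (ambiguity codes, N) are skipped entirely; contigs
    shorter than k contribute nothing.
    """
    check_k(k)
    h = k // 2
    for contig_name, seq in record.sequences:
        n = len(seq)
        if n < k:
            continue
        rcseq = seq.translate(_COMPLEMENT)[::-1]
        # index of the most recent non-ACGT letter; a window starting at s
        # is clean iff last_bad < s
        last_bad = -1
        for s in range(n - k + 1):
            end = s + k
            if s == 0:
                for j in range(k):
                    if seq[j] not in _ACGT:
                        last_bad = j
            else:
                if seq[end - 1] not in _ACGT:
                    last_bad = end - 1
            if last_bad >= s:
                continue
            fwd = seq[s:end]
            rc = rcseq[n - end : n - s]
            if rc < fwd:
                yield (
                    ContextAllele(rc[:h] + rc[h + 1 :], rc[h], True),
                    contig_name,
                    s + h + 1,
                    "-",
                )
            else:
                yield (
                    ContextAllele(fwd[:h] + fwd[h + 1 :], fwd[h], False),
                    contig_name,
                    s + h + 1,
                    "+",
                )


def canonical_kmer_counts(record: GenomeRecord, k: int) -> Dict[str, int]:
    """Count canonical full-length k-mers across all contigs of one genome."""
    check_k(k)
    counts: Dict[str, int] = {}
    for _, seq in record.sequences:
        n = len(seq)
        if n < k:
            continue
        rcseq = seq.translate(_COMPLEMENT)[::-1]
        last_bad = -1
        for s in range(n - k + 1):
            end = s + k
            if s == 0:
                for j in range(k):
                    if seq[j] not in _ACGT:
                        last_bad = j
            elif seq[end - 1] not in _ACGT:
                last_bad = end - 1
            if last_bad >= s:
                continue
            fwd = seq[s:end]
            rc = rcseq[n - end : n - s]
            key = rc if rc < fwd else fwd
            counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class KmerCountTable:
    """Canonical k-mer occurrence counts within a single genome."""

    k: int
    counts: Dict[str, int]

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_unique(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")


def count_kmers(record: GenomeRecord, k: int) -> KmerCountTable:
    """Build the per-genome canonical k-mer count table (contigs pooled)."""
    return KmerCountTable(k=k, counts=canonical_kmer_counts(record, k))
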