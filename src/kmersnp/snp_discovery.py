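"""Alignment-free SNP calling from conserved k-mer contexts.

A SNP locus is a (k-1)-base context — the flanks of an odd-length k-mer —
that recurs across genomes with different central bases.  No reference
genome and no alignment is involved: each genome is reduced to a map from
canonical context to the central-base allele(s) observed there, and any
context exhibiting at least two distinct alleles across the data set
becomes a locus.

Repeats are handled conservatively.  If one genome carries a context with
more than one central base (a repeat family or paralog differing at the
center), that genome's state at the locus is unknowable without alignment,
so it is set to MISSING there; unambiguous genomes keep their calls.  A
genome in which the context does not occur at all is likewise MISSING.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genome_io import GenomeRecord
from .kmer_engine import canonical_kmer_counts, check_k, enumerate_kmers

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "SnpLocus",
    "SnpMatrix",
    "DistanceMatrix",
    "find_snps",
    "core_loci",
    "count_snps",
    "snp_distance",
    "write_matrix_fasta",
    "read_matrix_fasta",
    "write_count",
    "write_snps_all_tsv",
    "write_distance_tsv",
]

MISSING = "-"

Position = Tuple[str, int, str]  # (contig_name, 1-based central base, strand)


@dataclass
class SnpLocus:
    """One SNP locus: a conserved context with per-genome central alleles."""

    locus_id: int
    context: str
    alleles: Dict[str, str]
    positions: Dict[str, List[Position]]

    @property
    def is_core(self) -> bool:
        return all(a != MISSING for a in self.alleles.values())

    def distinct_alleles(self) -> List[str]:
        return sorted({a for a in self.alleles.values() if a != MISSING})


@dataclass
class SnpMatrix:
    """Genomes x loci allele table with an explicit missing symbol."""

    genome_ids: List[str]
    loci: List[SnpLocus] = field(default_factory=list)
    missing_symbol: str = MISSING

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, genome_id: str) -> str:
        """Concatenated alleles for one genome, in locus order."""
        return "".join(
            locus.alleles.get(genome_id, MISSING) for locus in self.loci
        )


@dataclass
class DistanceMatrix:
    """Pairwise SNP differences: raw counts and p-distances."""

    genome_ids: List[str]
    counts: np.ndarray  # integer pairwise differing loci
    comparable: np.ndarray  # loci where both genomes are non-missing
    p: np.ndarray  # counts / comparable; NaN where comparable == 0

    def has_undefined_pairs(self) -> bool:
        off = ~np.eye(len(self.genome_ids), dtype=bool)
        return bool(np.isnan(self.p[off]).any())


def find_snps(
    genomes: Sequence[GenomeRecord],
    k: int,
    min_kmer_count: int = 1,
) -> SnpMatrix:
    """Call SNP loci across a genome set at k-mer length ``k``.

    For each genome a map from canonical (k-1)-context to observed central
    allele(s) and positions is built.  A genome holding more than one
    distinct allele for a context is MISSING at that locus (repeat guard);
    a context becomes a locus iff at least two distinct non-missing
    alleles remain across genomes.  Loci are ordered lexicographically by
    context and numbered in that order, making output deterministic.

    ``min_kmer_count`` drops k-mers seen fewer than that many times in a
    genome before context mapping — useful for raw-read input where
    singleton k-mers are usually sequencing artifacts (default 1: keep
    everything, appropriate for assemblies).
    """
    if len(genomes) < 2:
        raise ValueError("find_snps requires at least two genomes")
    check_k(k)
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("genome IDs must be unique")

    # per genome: context -> {allele: [positions]}
    genome_maps: List[Dict[str, Dict[str, List[Position]]]] = []
    for genome in genomes:
        keep = None
        if min_kmer_count > 1:
            counts = canonical_kmer_counts(genome, k)
            keep = {km for km, c in counts.items() if c >= min_kmer_count}
        ctx_map: Dict[str, Dict[str, List[Position]]] = {}
        h = k // 2
        for ca, contig, pos, strand in enumerate_kmers(genome, k):
            if keep is not None:
                kmer = ca.context[:h] + ca.allele + ca.context[h:]
                if kmer not in keep:
                    continue
            ctx_map.setdefault(ca.context, {}).setdefault(
                ca.allele, []
            ).append((contig, pos, strand))
        genome_maps.append(ctx_map)

    candidate_contexts = set()
    for ctx_map in genome_maps:
        candidate_contexts.update(ctx_map)

    loci: List[SnpLocus] = []
    for context in sorted(candidate_contexts):
        alleles: Dict[str, str] = {}
        positions: Dict[str, List[Position]] = {}
        for gid, ctx_map in zip(ids, genome_maps):
            entry = ctx_map.get(context)
            if entry is None:
                alleles[gid] = MISSING
            elif len(entry) > 1:
                # conflicted context within one genome: repeat/paralog guard
                alleles[gid] = MISSING
            else:
                (allele, poslist), = entry.items()
                alleles[gid] = allele
                positions[gid] = sorted(poslist)
        distinct = {a for a in alleles.values() if a != MISSING}
        if len(distinct) >= 2:
            loci.append(
                SnpLocus(
                    locus_id=len(loci),
                    context=context,
                    alleles=alleles,
                    positions=positions,
                )
            )
    return SnpMatrix(genome_ids=list(ids), loci=loci)


def core_loci(matrix: SnpMatrix) -> SnpMatrix:
    """Sub-matrix of loci with a called allele in every genome."""
    kept = [
        SnpLocus(
            locus_id=i,
            context=locus.context,
            alleles=dict(locus.alleles),
            positions={g: list(p) for g, p in locus.positions.items()},
        )
        for i, locus in enumerate(l for l in matrix.loci if l.is_core)
    ]
    return SnpMatrix(genome_ids=list(matrix.genome_ids), loci=kept)


def count_snps(matrix: SnpMatrix) -> int:
    """Number of SNP loci in the matrix."""
    return matrix.n_loci


def snp_distance(matrix: SnpMatrix) -> DistanceMatrix:
    """Pairwise SNP differences and p-distances between genomes.

    A locus contributes to a pair iff both genomes have a non-missing
    allele there; the count is the number of such loci where the alleles
    differ, and the p-distance divides by the number of comparable loci.
    A pair with zero comparable loci gets p = NaN with a warning.
    """
    if len(matrix.genome_ids) < 2:
        raise ValueError("snp_distance requires at least two genomes")
    n = len(matrix.genome_ids)
    rows = [matrix.row(g) for g in matrix.genome_ids]
    counts = np.zeros((n, n), dtype=int)
    comparable = np.zeros((n, n), dtype=int)
    for i in range(n):
        comparable[i, i] = matrix.n_loci
        for j in range(i + 1, n):
            comp = 0
            diff = 0
            for a, b in zip(rows[i], rows[j]):
                if a != MISSING and b != MISSING:
                    comp += 1
                    if a != b:
                        diff += 1
            counts[i, j] = counts[j, i] = diff
            comparable[i, j] = comparable[j, i] = comp
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(comparable > 0, counts / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    dm = DistanceMatrix(
        genome_ids=list(matrix.genome_ids),
        counts=counts,
        comparable=comparable,
        p=p,
    )
    if dm.has_undefined_pairs():
        logger.warning(
            "some genome pairs share no comparable SNP loci; their "
            "p-distance is undefined"
        )
    return dm


def write_matrix_fasta(matrix: SnpMatrix, path) -> None:
    """Write the SNP matrix as an alignment-like FASTA (one row per genome)."""
    if matrix.n_loci == 0:
        raise ValueError("cannot write an empty SNP matrix")
    with open(path, "w") as fh:
        for gid in matrix.genome_ids:
            fh.write(f">{gid}\n{matrix.row(gid)}\n")


def read_matrix_fasta(path) -> SnpMatrix:
    """Re-read a matrix FASTA into a positionless :class:`SnpMatrix`.

    Contexts and positions are not stored in the FASTA, so loci come back
    with empty contexts; allele columns and genome order round-trip
    exactly.
    """
    from Bio import SeqIO

    ids: List[str] = []
    rows: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("matrix FASTA rows have unequal lengths")
    n_loci = lengths.pop()
    loci = []
    for col in range(n_loci):
        alleles = {gid: rows[i][col] for i, gid in enumerate(ids)}
        loci.append(
            SnpLocus(locus_id=col, context="", alleles=alleles, positions={})
        )
    return SnpMatrix(genome_ids=ids, loci=loci)


def write_count(n: int, path, label: str = "SNPs") -> None:
    with open(path, "w") as fh:
        fh.write(f"Number of {label}: {n}\n")


def write_snps_all_tsv(matrix: SnpMatrix, path) -> None:
    """Per-locus, per-genome detail: allele, contig, position, strand."""
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tcontext\tgenome_id\tallele\tcontig\tposition\tstrand\n"
        )
        for locus in matrix.loci:
            for gid in matrix.genome_ids:
                allele = locus.alleles.get(gid, MISSING)
                if allele == MISSING:
                    continue
                for contig, pos, strand in locus.positions.get(gid, []):
                    fh.write(
                        f"{locus.locus_id}\t{locus.context}\t{gid}\t"
                        f"{allele}\t{contig}\t{pos}\t{strand}\n"
                    )


def write_distance_tsv(dm: DistanceMatrix, path, kind: str = "counts") -> None:
    """Write a square pairwise distance table (raw counts or p-distance)."""
    mat = dm.counts if kind == "counts" else dm.p
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(dm.genome_ids) + "\n")
        for i, gid in enumerate(dm.genome_ids):
            if kind == "counts":
                vals = "\t".join(str(int(v)) for v in mat[i])
            else:
                vals = "\t".join(
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in mat[i]
                )
            fh.write(f"{gid}\t{vals}\n")
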