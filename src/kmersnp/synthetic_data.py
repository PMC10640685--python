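"""Genome sets evolved along a known tree, with exact planted truth.

The generator produces everything needed to test the whole pipeline
offline: a random Yule tree, an ancestral sequence whose k-windows are
unique (so no context is repeated and oracle comparisons are exact),
Jukes-Cantor substitutions placed along branches, optional error-free
read shredding, and synthetic GenBank feature tables for the annotation
stage.  Under the infinite-sites regime (the default) every site mutates
at most once in the whole history, so each planted SNP is bi-allelic and
its carriers form a clade of the true tree — the emitted truth is exact.

Every function is a pure function of its seed and parameters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genome_io import GenomeRecord
from .kmer_engine import canonical_kmer_counts, check_k, revcomp

__all__ = [
    "SimulationTruth",
    "PlantedSnp",
    "simulate_tree",
    "evolve_genomes",
    "plant_mutations",
    "shred_reads",
    "synth_genbank",
    "write_genome_fastas",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSnp:
    """One substitution: where it happened and who inherited it."""

    position: int  # 1-based coordinate in the (single-contig) ancestor
    ancestral: str
    derived: str
    carriers: FrozenSet[str]  # genome_ids descending from the mutated branch


@dataclass
class SimulationTruth:
    """The generating tree, ancestor, and exact list of planted SNPs."""

    true_tree: Tree
    ancestor: str
    planted_snps: List[PlantedSnp] = field(default_factory=list)
    seed: int = 0

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tancestral\tderived\tcarriers\n")
            for snp in sorted(self.planted_snps, key=lambda s: s.position):
                fh.write(
                    f"{snp.position}\t{snp.ancestral}\t{snp.derived}\t"
                    f"{','.join(sorted(snp.carriers))}\n"
                )


def simulate_tree(
    n_taxa: int,
    model: str = "yule",
    seed: int = 0,
    height: float = 0.03,
) -> Tree:
    """Random Yule topology with exponential branch lengths.

    Topology grows by uniform random tip splitting (the Yule / equal-rates
    Markov process); branch lengths are i.i.d. exponential, then rescaled
    so the maximum root-to-tip path equals ``height`` (expected
    substitutions per site).  Leaves are named g01, g02, ...
    """
    if n_taxa < 3:
        raise ValueError("simulate_tree requires n_taxa >= 3")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = random.Random(seed)
    root = Clade()
    root.clades = [Clade(), Clade()]
    tips = list(root.clades)
    while len(tips) < n_taxa:
        tip = tips.pop(rng.randrange(len(tips)))
        tip.clades = [Clade(), Clade()]
        tips.extend(tip.clades)
    names = [f"g{i + 1:02d}" for i in range(n_taxa)]
    for name, tip in zip(names, tips):
        tip.name = name
    tree = Tree(root=root, rooted=True)
    for clade in tree.find_clades():
        if clade is not root:
            clade.branch_length = rng.expovariate(1.0)
    depths = tree.depths()
    max_depth = max(d for c, d in depths.items() if c.is_terminal())
    scale = height / max_depth
    for clade in tree.find_clades():
        if clade.branch_length is not None:
            clade.branch_length *= scale
    return tree


def _random_sequence(length: int, rng: random.Random) -> List[str]:
    return rng.choices(_BASES, k=length)


def _make_unique_ancestor(
    length: int, unique_k: int, rng: random.Random, max_rounds: int = 200
) -> List[str]:
    """Ancestor whose canonical ``unique_k``-mers are all distinct.

    Draws an i.i.d. sequence and then repairs duplicated windows by
    re-randomizing their central bases until every canonical window is
    unique (rejection/repair sampling).
    """
    check_k(unique_k)
    if length < unique_k:
        raise ValueError("genome_length must exceed the uniqueness k")
    seq = _random_sequence(length, rng)
    h = unique_k // 2
    for _ in range(max_rounds):
        record = GenomeRecord(
            genome_id="anc", sequences=[("anc", "".join(seq))]
        )
        counts = canonical_kmer_counts(record, unique_k)
        dupes = {km for km, c in counts.items() if c > 1}
        if not dupes:
            return seq
        text = "".join(seq)
        hit_centers = set()
        for s in range(length - unique_k + 1):
            w = text[s : s + unique_k]
            if w in dupes or revcomp(w) in dupes:
                hit_centers.add(s + h)
        for center in hit_centers:
            seq[center] = rng.choice(_BASES)
    raise RuntimeError(
        f"could not make all {unique_k}-mers unique in a {length} bp "
        "ancestor; increase the length or the uniqueness k"
    )


def evolve_genomes(
    tree: Tree,
    genome_length: int = 20000,
    subst_rate: float = 1.0,
    seed: int = 0,
    infinite_sites: bool = True,
    unique_k: int = 15,
    min_site_spacing: Optional[int] = None,
) -> Tuple[List[GenomeRecord], SimulationTruth]:
    """Evolve a genome down each branch of ``tree`` under Jukes-Cantor.

    The ancestor is i.i.d. uniform over ACGT, repaired so all canonical
    ``unique_k``-mers are distinct.  Each branch receives a Poisson number
    of substitutions with mean ``branch_length * subst_rate *
    genome_length``; the derived base is uniform over the three
    alternatives.  With ``infinite_sites`` (default) sites are drawn
    without replacement across the entire tree, so no site mutates twice
    and the returned truth is exact.  ``min_site_spacing`` additionally
    forces mutated sites at least that many bases apart (use >= k to keep
    every SNP's context unmutated, making SNP discovery recover the truth
    exactly).
    """
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    rng = random.Random(seed)
    ancestor = _make_unique_ancestor(genome_length, unique_k, rng)

    clades = [c for c in tree.find_clades() if c.branch_length is not None]
    n_muts = [
        _poisson(rng, c.branch_length * subst_rate * genome_length)
        for c in clades
    ]
    total = sum(n_muts)
    if infinite_sites:
        if total > genome_length:
            raise ValueError(
                "substitution rate too high for infinite-sites placement; "
                "lower the rate or enlarge the genome"
            )
        sites = _sample_sites(rng, genome_length, total, min_site_spacing)
    else:
        sites = [rng.randrange(genome_length) for _ in range(total)]

    # assign site batches to branches, then walk the tree root-to-tip
    site_iter = iter(sites)
    branch_sites: Dict[int, List[int]] = {
        id(c): [next(site_iter) for _ in range(nm)]
        for c, nm in zip(clades, n_muts)
    }

    records: List[GenomeRecord] = []
    planted: List[PlantedSnp] = []

    def leaf_names(clade: Clade) -> FrozenSet[str]:
        if clade.is_terminal():
            return frozenset([clade.name])
        return frozenset(t.name for t in clade.get_terminals())

    def walk(clade: Clade, seq: List[str]) -> None:
        if clade.branch_length is not None:
            seq = list(seq)
            carriers = leaf_names(clade)
            for pos in branch_sites[id(clade)]:
                old = seq[pos]
                new = rng.choice([b for b in _BASES if b != old])
                seq[pos] = new
                if infinite_sites:
                    planted.append(
                        PlantedSnp(
                            position=pos + 1,
                            ancestral=ancestor[pos],
                            derived=new,
                            carriers=carriers,
                        )
                    )
        if clade.is_terminal():
            records.append(
                GenomeRecord(
                    genome_id=clade.name,
                    sequences=[(clade.name, "".join(seq))],
                )
            )
        else:
            for child in clade.clades:
                walk(child, seq)

    walk(tree.root, ancestor)
    records.sort(key=lambda r: r.genome_id)
    truth = SimulationTruth(
        true_tree=tree,
        ancestor="".join(ancestor),
        planted_snps=planted,
        seed=seed,
    )
    return records, truth


def _poisson(rng: random.Random, lam: float) -> int:
    """Poisson draw by inversion (lam at desk scale is small per branch)."""
    if lam <= 0:
        return 0
    # Knuth's method is fine for lam up to a few hundred; use normal
    # approximation above that
    if lam > 500:
        return max(0, round(rng.gauss(lam, lam**0.5)))
    import math

    l_exp = math.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= l_exp:
            return k
        k += 1


def _sample_sites(
    rng: random.Random,
    length: int,
    n: int,
    min_spacing: Optional[int],
) -> List[int]:
    if min_spacing is None or min_spacing <= 1:
        return rng.sample(range(length), n)
    chosen: List[int] = []
    occupied: set = set()
    candidates = list(range(length))
    rng.shuffle(candidates)
    for pos in candidates:
        if len(chosen) == n:
            break
        if pos in occupied:
            continue
        chosen.append(pos)
        occupied.update(
            range(max(0, pos - min_spacing + 1), min(length, pos + min_spacing))
        )
    if len(chosen) < n:
        raise ValueError(
            f"cannot place {n} substitutions with spacing {min_spacing} "
            f"in {length} bp"
        )
    return chosen


def plant_mutations(
    n_genomes: int = 5,
    n_snps: int = 30,
    genome_length: int = 2000,
    k: int = 13,
    seed: int = 0,
) -> Tuple[List[GenomeRecord], List[PlantedSnp]]:
    """Plant ``n_snps`` substitutions in k-unique contexts, exact truth.

    All genomes start as one ancestor whose canonical k-windows are
    unique; each SNP site (sites at least k apart so contexts stay
    conserved) gets a derived base carried by a random nonempty proper
    subset of genomes.  Returns the genomes and the exact truth set.
    """
    check_k(k)
    rng = random.Random(seed)
    ancestor = _make_unique_ancestor(genome_length, k, rng)
    ids = [f"g{i + 1:02d}" for i in range(n_genomes)]
    # keep sites away from the edges so every SNP has full flanks
    h = k // 2
    interior = list(range(h, genome_length - h))
    rng.shuffle(interior)
    sites: List[int] = []
    occupied: set = set()
    for pos in interior:
        if len(sites) == n_snps:
            break
        if pos in occupied:
            continue
        sites.append(pos)
        occupied.update(range(pos - k + 1, pos + k))
    if len(sites) < n_snps:
        raise ValueError("genome too short to plant that many spaced SNPs")
    seqs = {gid: list(ancestor) for gid in ids}
    planted: List[PlantedSnp] = []
    for pos in sorted(sites):
        old = ancestor[pos]
        new = rng.choice([b for b in _BASES if b != old])
        n_carriers = rng.randrange(1, n_genomes)
        carriers = frozenset(rng.sample(ids, n_carriers))
        for gid in carriers:
            seqs[gid][pos] = new
        planted.append(
            PlantedSnp(
                position=pos + 1, ancestral=old, derived=new, carriers=carriers
            )
        )
    records = [
        GenomeRecord(genome_id=gid, sequences=[(gid, "".join(seqs[gid]))])
        for gid in ids
    ]
    return records, planted


def shred_reads(
    record: GenomeRecord,
    read_length: int = 150,
    coverage: float = 20.0,
    seed: int = 0,
) -> GenomeRecord:
    """Shred a genome into uniformly placed error-free reads.

    Reads come from both strands; the result is a multi-sequence
    :class:`GenomeRecord` standing in for a raw-read FASTA input.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = random.Random(seed)
    reads: List[Tuple[str, str]] = []
    read_no = 0
    for contig, seq in record.sequences:
        if read_length > len(seq):
            raise ValueError(
                f"read_length {read_length} exceeds contig {contig!r} "
                f"length {len(seq)}"
            )
        n_reads = max(1, round(coverage * len(seq) / read_length))
        for _ in range(n_reads):
            start = rng.randrange(len(seq) - read_length + 1)
            read = seq[start : start + read_length]
            if rng.random() < 0.5:
                read = revcomp(read)
            read_no += 1
            reads.append((f"read_{read_no:06d}", read))
    return GenomeRecord(
        genome_id=record.genome_id,
        sequences=reads,
        source_path=record.source_path,
    )


def synth_genbank(
    record: GenomeRecord,
    cds_spec: Sequence[dict],
    out_path,
) -> None:
    """Write a synthetic GenBank flat file matching a genome record.

    ``cds_spec`` is a list of dicts with keys ``start`` and ``end``
    (1-based inclusive), ``strand`` (+1/-1), ``product``, and optional
    ``protein_id`` and ``codon_start``.  One GenBank record is written per
    contig; features are placed on the contig named by the optional
    ``contig`` key (default: the first contig).
    """
    contig_names = [name for name, _ in record.sequences]
    seq_records = []
    for name, seq in record.sequences:
        sr = SeqRecord(
            Seq(seq),
            id=name,
            name=name[:16],
            description=f"synthetic genome {record.genome_id}",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        sr.features.append(
            SeqFeature(
                SimpleLocation(0, len(seq), strand=1), type="source"
            )
        )
        seq_records.append(sr)
    by_name = {sr.id: sr for sr in seq_records}
    for i, spec in enumerate(cds_spec):
        contig = spec.get("contig", contig_names[0])
        sr = by_name[contig]
        start, end = spec["start"], spec["end"]
        if not (1 <= start <= end <= len(sr.seq)):
            raise ValueError(
                f"CDS interval {start}..{end} out of bounds for contig "
                f"{contig!r} ({len(sr.seq)} bp)"
            )
        qualifiers = {
            "product": [spec.get("product", f"hypothetical protein {i + 1}")],
            "protein_id": [spec.get("protein_id", f"SYN_{i + 1:05d}.1")],
            "codon_start": [str(spec.get("codon_start", 1))],
        }
        sr.features.append(
            SeqFeature(
                SimpleLocation(start - 1, end, strand=spec.get("strand", 1)),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    with open(out_path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")


def write_genome_fastas(records: Sequence[GenomeRecord], directory) -> Path:
    """Write one FASTA per genome into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        path = directory / f"{rec.genome_id}.fasta"
        with open(path, "w") as fh:
            for name, seq in rec.sequences:
                fh.write(f">{name}\n")
                for s in range(0, len(seq), 80):
                    fh.write(seq[s : s + 80] + "\n")
        rec.source_path = str(path)
    return directory
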