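"""Data-driven choice of the odd k-mer length, and the core-k-mer fraction.

Two opposing failure modes bracket the choice of k.  Too short, and k-mers
match between genomes by chance rather than by descent, inflating the SNP
count with spurious homology.  Too long, and the conserved context around a
variable site is itself likely to contain further variation, so real SNPs
are missed.  The shortest k at which essentially every k-mer of the
median-sized genome is unique (fraction of unique k-mers, FUK, has
converged) balances the two.

The fraction of core k-mers (FCK) — k-mers of the shortest genome present
in every genome — predicts how much signal is shared by the whole data set:
data sets with FCK >= 0.1 yield parsimony trees of >= 90% topological
accuracy, so FCK below that is a warning that (for example) an overly
distant outgroup is eroding tree quality.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .genome_io import GenomeRecord
from .kmer_engine import canonical_kmer_counts, check_k, count_kmers

logger = logging.getLogger(__name__)

__all__ = [
    "KchooserReport",
    "fraction_unique_kmers",
    "choose_k",
    "fraction_core_kmers",
    "analyze",
]

DEFAULT_FCK_SAMPLE_SIZE = 1000
DEFAULT_FCK_SEED = 42


@dataclass
class KchooserReport:
    """FUK-by-k series, the chosen k, and the core-k-mer fraction."""

    fuk_series: List[Tuple[int, float]] = field(default_factory=list)
    optimum_k: int = 0
    fck: Optional[float] = None
    fck_sample_size: int = DEFAULT_FCK_SAMPLE_SIZE
    fck_seed: int = DEFAULT_FCK_SEED
    median_genome_id: str = ""
    shortest_genome_id: str = ""
    converged: bool = True

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tFUK\n")
            for k, fuk in self.fuk_series:
                fh.write(f"{k}\t{fuk:.6f}\n")
            fh.write("\n")
            fh.write(f"median-sized genome: {self.median_genome_id}\n")
            fh.write(f"optimum k-mer length: {self.optimum_k}\n")
            if not self.converged:
                fh.write(
                    "warning: FUK had not converged at the maximum k "
                    "examined; the optimum above is that maximum.\n"
                )
            if self.fck is not None:
                fh.write(
                    f"FCK (fraction of core k-mers, {self.fck_sample_size} "
                    f"k-mers sampled from shortest genome "
                    f"{self.shortest_genome_id}, seed {self.fck_seed}): "
                    f"{self.fck:.4f}\n"
                )
                if self.fck >= 0.1:
                    fh.write(
                        "FCK >= 0.1: expected parsimony topological "
                        "accuracy is at least 90%.\n"
                    )
                else:
                    fh.write(
                        "FCK < 0.1: tree accuracy may be poor; consider "
                        "removing highly divergent genomes.\n"
                    )


def fraction_unique_kmers(record: GenomeRecord, k: int) -> float:
    """Fraction of distinct canonical k-mers occurring exactly once.

    FUK = (# distinct canonical k-mers with count 1) / (# distinct
    canonical k-mers) within one genome.
    """
    table = count_kmers(record, k)
    if table.n_distinct == 0:
        raise ValueError(
            f"genome {record.genome_id!r} has no valid {k}-mer windows"
        )
    return table.n_unique / table.n_distinct


def _median_genome(genomes: Sequence[GenomeRecord]) -> GenomeRecord:
    # lower median for even counts; ties broken by genome_id
    ordered = sorted(genomes, key=lambda g: (g.total_length, g.genome_id))
    return ordered[(len(ordered) - 1) // 2]


def _shortest_genome(genomes: Sequence[GenomeRecord]) -> GenomeRecord:
    return min(genomes, key=lambda g: (g.total_length, g.genome_id))


def choose_k(
    genomes: Sequence[GenomeRecord],
    k_start: int = 7,
    delta: float = 0.001,
    k_max: int = 31,
) -> KchooserReport:
    """Scan odd k upward on the median-sized genome until FUK converges.

    FUK is evaluated at k_start, k_start+2, ...; the scan stops at the
    first k where FUK(k) - FUK(k-2) < ``delta`` and that k is reported as
    the optimum (the converged value is at least as unique as the previous
    one).  If convergence is not reached by ``k_max``, the optimum is
    ``k_max`` and a warning is logged.  Deterministic: FUK involves no
    randomness.
    """
    if not genomes:
        raise ValueError("choose_k requires at least one genome")
    check_k(k_start)
    check_k(k_max)
    median = _median_genome(genomes)
    report = KchooserReport(median_genome_id=median.genome_id)
    prev_fuk: Optional[float] = None
    k = k_start
    while k <= k_max:
        fuk = fraction_unique_kmers(median, k)
        report.fuk_series.append((k, fuk))
        if prev_fuk is not None and fuk - prev_fuk < delta:
            report.optimum_k = k
            return report
        prev_fuk = fuk
        k += 2
    report.optimum_k = k_max
    report.converged = False
    logger.warning(
        "FUK did not converge by k=%d; using optimum_k=%d", k_max, k_max
    )
    return report


def fraction_core_kmers(
    genomes: Sequence[GenomeRecord],
    k: int,
    sample_size: int = DEFAULT_FCK_SAMPLE_SIZE,
    seed: int = DEFAULT_FCK_SEED,
) -> float:
    """Fraction of sampled shortest-genome k-mers present in every genome.

    ``sample_size`` distinct canonical k-mers are drawn uniformly without
    replacement (seeded) from the shortest genome and tested for canonical
    (strand-agnostic) membership in all genomes.  ``sample_size`` of None
    or exceeding the available distinct k-mers means exhaustive testing.
    """
    if len(genomes) < 2:
        raise ValueError("fraction_core_kmers requires at least two genomes")
    check_k(k)
    if sample_size is not None and sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    shortest = _shortest_genome(genomes)
    pool = sorted(canonical_kmer_counts(shortest, k))
    if not pool:
        raise ValueError(
            f"shortest genome {shortest.genome_id!r} has no valid "
            f"{k}-mer windows"
        )
    if sample_size is None or sample_size >= len(pool):
        if sample_size is not None and sample_size > len(pool):
            logger.warning(
                "requested %d k-mers but shortest genome has only %d "
                "distinct; testing all of them",
                sample_size,
                len(pool),
            )
        sample = pool
    else:
        rng = random.Random(seed)
        sample = rng.sample(pool, sample_size)
    other_sets = [
        frozenset(canonical_kmer_counts(g, k))
        for g in genomes
        if g.genome_id != shortest.genome_id
    ]
    n_core = sum(
        1 for kmer in sample if all(kmer in s for s in other_sets)
    )
    return n_core / len(sample)


def analyze(
    genomes: Sequence[GenomeRecord],
    k_start: int = 7,
    delta: float = 0.001,
    k_max: int = 31,
    fck_sample_size: int = DEFAULT_FCK_SAMPLE_SIZE,
    seed: int = DEFAULT_FCK_SEED,
) -> KchooserReport:
    """Full k-selection analysis: FUK scan plus FCK at the chosen k."""
    report = choose_k(genomes, k_start=k_start, delta=delta, k_max=k_max)
    report.fck_sample_size = fck_sample_size
    report.fck_seed = seed
    shortest = _shortest_genome(genomes)
    report.shortest_genome_id = shortest.genome_id
    if len(genomes) >= 2:
        report.fck = fraction_core_kmers(
            genomes, report.optimum_k, sample_size=fck_sample_size, seed=seed
        )
    return report
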