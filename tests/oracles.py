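"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by the most naive route available —
explicit both-strand dictionaries, exhaustive enumeration of ancestral
state assignments — sharing conventions (canonical = lexicographic min of
k-mer and reverse complement) but no code with the package.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def naive_kmer_counts(sequences: Sequence[str], k: int) -> Dict[str, int]:
    """Dictionary recount of canonical k-mers over forward windows."""
    counts: Dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(b not in _COMP for b in w):
                continue
            key = min(w, rc(w))
            counts[key] = counts.get(key, 0) + 1
    return counts


def naive_find_snps(
    genomes: Sequence[Tuple[str, Sequence[str]]], k: int
) -> Dict[str, Dict[str, str]]:
    """Both-strand dictionary SNP caller.

    ``genomes`` is a list of (genome_id, [sequence, ...]).  Every window of
    every sequence AND of its reverse complement is hashed; windows are
    grouped by canonical flank string.  A genome holding >1 allele for a
    flank is missing ('-') there; flanks with >=2 distinct alleles across
    genomes are loci.  Returns {context: {genome_id: allele-or-'-'}}.
    """
    h = k // 2
    per_genome: List[Dict[str, set]] = []
    for _, seqs in genomes:
        table: Dict[str, set] = {}
        strands = list(seqs) + [rc(s) for s in seqs]
        for seq in strands:
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if any(b not in _COMP for b in w):
                    continue
                c = min(w, rc(w))
                table.setdefault(c[:h] + c[h + 1 :], set()).add(c[h])
        per_genome.append(table)
    contexts = set()
    for table in per_genome:
        contexts.update(table)
    loci: Dict[str, Dict[str, str]] = {}
    for ctx in contexts:
        calls: Dict[str, str] = {}
        for (gid, _), table in zip(genomes, per_genome):
            alleles = table.get(ctx, set())
            if len(alleles) == 1:
                calls[gid] = next(iter(alleles))
            else:
                calls[gid] = "-"
        if len({a for a in calls.values() if a != "-"}) >= 2:
            loci[ctx] = calls
    return loci


def brute_parsimony_score(
    adjacency: Dict[int, List[int]],
    n_leaves: int,
    leaf_states: Sequence[Sequence[str]],
) -> int:
    """Minimum state changes by exhaustive internal-assignment enumeration.

    ``leaf_states[i]`` is the set/list of bases permitted at leaf i
    (singleton for a called allele, all four for missing), one site at a
    time handled by the caller.  Internal nodes are ids >= n_leaves.
    """
    internals = sorted(x for x in adjacency if x >= n_leaves)
    edges = [
        (u, v) for u, vs in adjacency.items() for v in vs if u < v
    ]
    best = None
    for assign in itertools.product("ACGT", repeat=len(internals)):
        state = dict(zip(internals, assign))
        cost = 0
        feasible = True
        for u, v in edges:
            if u < n_leaves and v < n_leaves:
                # two-leaf tree edge
                cost += 0 if set(leaf_states[u]) & set(leaf_states[v]) else 1
            elif u < n_leaves:
                cost += 0 if state[v] in leaf_states[u] else 1
            elif v < n_leaves:
                cost += 0 if state[u] in leaf_states[v] else 1
            else:
                cost += 0 if state[u] == state[v] else 1
        if best is None or cost < best:
            best = cost
    return best


def count_clades(trees, clade: frozenset) -> int:
    """How many Bio.Phylo trees contain a given clade of terminal names."""
    n = 0
    for tree in trees:
        taxa = frozenset(t.name for t in tree.get_terminals())
        ref = min(taxa)
        sides = set()
        for c in tree.get_nonterminals():
            names = frozenset(t.name for t in c.get_terminals())
            sides.add(names if ref not in names else taxa - names)
        target = clade if ref not in clade else taxa - clade
        if target in sides:
            n += 1
    return n
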