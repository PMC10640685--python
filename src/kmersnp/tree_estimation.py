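"""Phylogeny estimation from the SNP matrix.

Maximum parsimony is the primary method: for SNP-only matrices, in which
every column is variable, parsimony is the most accurate of the classical
reconstruction methods.  The search retains up to ``max_trees`` equally
most-parsimonious topologies and reports their majority-rule consensus,
labelling each internal node with the integer number of retained trees
that contain the clade descended from it.  Neighbor joining (Saitou-Nei)
on p-distances is available as a fast distance-based alternative.  All
trees are unrooted and serialized as Newick.

Internally a tree is a plain adjacency dict over integer node ids (leaves
``0..n-1`` in genome order, internal nodes from ``n`` up); Fitch scoring
is vectorized with numpy over site patterns.  Public functions accept and
return ``Bio.Phylo`` trees.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .snp_discovery import MISSING, DistanceMatrix, SnpMatrix

__all__ = [
    "ParsimonyResult",
    "fitch_score",
    "parsimony_search",
    "consensus",
    "nj_tree",
    "rf_distance",
    "normalized_rf",
    "topological_accuracy",
    "write_newick",
    "read_newick",
]

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, MISSING: 15}

Adj = Dict[int, List[int]]
SplitKey = FrozenSet[FrozenSet[int]]


# ---------------------------------------------------------------------------
# pattern encoding


def _encode_matrix(matrix: SnpMatrix) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Collapse matrix columns into distinct site patterns with weights.

    Returns (taxa, states, weights) where states[i, p] is the bitmask of
    permitted bases for taxon i at pattern p (missing = all four).
    """
    taxa = list(matrix.genome_ids)
    rows = [matrix.row(g) for g in taxa]
    pattern_index: Dict[Tuple[str, ...], int] = {}
    weights: List[int] = []
    for col in range(matrix.n_loci):
        pat = tuple(row[col] for row in rows)
        idx = pattern_index.get(pat)
        if idx is None:
            pattern_index[pat] = len(weights)
            weights.append(1)
        else:
            weights[idx] += 1
    states = np.zeros((len(taxa), len(weights)), dtype=np.int16)
    for pat, p in pattern_index.items():
        for i, base in enumerate(pat):
            states[i, p] = _BASE_BITS[base]
    return taxa, states, np.asarray(weights, dtype=np.int64)


# ---------------------------------------------------------------------------
# adjacency-dict tree machinery (internal)


def _copy(adj: Adj) -> Adj:
    return {u: list(vs) for u, vs in adj.items()}


def _edges(adj: Adj) -> List[Tuple[int, int]]:
    return [(u, v) for u, vs in adj.items() for v in vs if u < v]


def _base_tree(leaves: Sequence[int], internal: int) -> Adj:
    a, b, c = leaves
    return {a: [internal], b: [internal], c: [internal], internal: [a, b, c]}


def _insert_leaf(adj: Adj, edge: Tuple[int, int], leaf: int, new_internal: int) -> Adj:
    u, v = edge
    out = _copy(adj)
    out[u][out[u].index(v)] = new_internal
    out[v][out[v].index(u)] = new_internal
    out[new_internal] = [u, v, leaf]
    out[leaf] = [new_internal]
    return out


def _all_topologies(n: int) -> Iterator[Adj]:
    """All unrooted binary topologies on leaves 0..n-1 ((2n-5)!! of them)."""
    if n < 3:
        raise ValueError("need at least 3 leaves")

    def rec(adj: Adj, next_leaf: int) -> Iterator[Adj]:
        if next_leaf == n:
            yield adj
            return
        new_internal = n + next_leaf - 2
        for edge in _edges(adj):
            yield from rec(
                _insert_leaf(adj, edge, next_leaf, new_internal), next_leaf + 1
            )

    yield from rec(_base_tree([0, 1, 2], n), 3)


def _postorder(adj: Adj) -> List[Tuple[int, List[int]]]:
    """Postorder (node, children) pairs rooted at the lowest leaf's neighbor.

    The lowest-numbered node present is always a leaf (internal ids start
    at n); it is excluded from the traversal and callers fold it in at
    the root edge.
    """
    r0 = min(adj)
    root = adj[r0][0]
    order: List[Tuple[int, List[int]]] = []
    stack = [(root, r0)]
    visit: List[Tuple[int, int]] = []
    while stack:
        node, parent = stack.pop()
        visit.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(visit):
        children = [nb for nb in adj[node] if nb != parent]
        order.append((node, children))
    return order


def _fitch_score_adj(adj: Adj, states: np.ndarray, weights: np.ndarray) -> int:
    """Fitch small parsimony score of one topology, summed over patterns."""
    sets: Dict[int, np.ndarray] = {}
    score = 0
    for node, children in _postorder(adj):
        if not children:
            sets[node] = states[node]
            continue
        acc = sets[children[0]]
        for ch in children[1:]:
            inter = acc & sets[ch]
            zero = inter == 0
            if zero.any():
                score += int(weights[zero].sum())
                inter = np.where(zero, acc | sets[ch], inter)
            acc = inter
        sets[node] = acc
    r0 = min(adj)
    root = adj[r0][0]
    inter = sets[root] & states[r0]
    zero = inter == 0
    if zero.any():
        score += int(weights[zero].sum())
    return score


def _lowbit(x: np.ndarray) -> np.ndarray:
    return x & (-x)


def _branch_changes(
    adj: Adj, states: np.ndarray, weights: np.ndarray
) -> Dict[Tuple[int, int], float]:
    """Mean state changes per site on each edge (one Fitch traceback)."""
    sets: Dict[int, np.ndarray] = {}
    order = _postorder(adj)
    for node, children in order:
        if not children:
            sets[node] = states[node].copy()
            continue
        acc = sets[children[0]]
        for ch in children[1:]:
            inter = acc & sets[ch]
            acc = np.where(inter == 0, acc | sets[ch], inter)
        sets[node] = acc
    r0 = min(adj)
    root = adj[r0][0]
    total_sites = float(weights.sum())
    changes: Dict[Tuple[int, int], float] = {}
    chosen: Dict[int, np.ndarray] = {}
    root_inter = sets[root] & states[r0]
    root_state = np.where(root_inter == 0, _lowbit(sets[root]), _lowbit(root_inter))
    chosen[root] = root_state
    # the root leaf's edge
    diff = (root_state & states[r0]) == 0
    changes[(min(r0, root), max(r0, root))] = float(weights[diff].sum()) / total_sites
    for node, children in reversed(order):
        for ch in children:
            keep = (chosen[node] & sets[ch]) != 0
            chosen[ch] = np.where(keep, chosen[node], _lowbit(sets[ch]))
            edge = (min(node, ch), max(node, ch))
            changes[edge] = float(weights[~keep].sum()) / total_sites
    return changes


def _splits_adj(adj: Adj, n: int) -> SplitKey:
    """Canonical nontrivial splits (leaf-index sets excluding leaf 0's side)."""
    splits = set()
    below: Dict[int, frozenset] = {}
    for node, children in _postorder(adj):
        if not children:
            below[node] = frozenset([node])
        else:
            acc: frozenset = frozenset()
            for ch in children:
                acc |= below[ch]
            below[node] = acc
        if 2 <= len(below[node]) <= n - 2:
            splits.add(below[node])
    return frozenset(splits)


def _nni_neighbors(adj: Adj, n: int) -> Iterator[Adj]:
    """The two nearest-neighbor interchanges around every internal edge."""
    for u, v in _edges(adj):
        if u < n or v < n:
            continue
        u_others = [x for x in adj[u] if x != v]
        v_others = [x for x in adj[v] if x != u]
        b = u_others[1]
        for c in v_others:
            out = _copy(adj)
            out[u][out[u].index(b)] = c
            out[v][out[v].index(c)] = b
            out[b][out[b].index(u)] = v
            out[c][out[c].index(v)] = u
            yield out


def _stepwise_addition(
    order: Sequence[int], n: int, states: np.ndarray, weights: np.ndarray
) -> Adj:
    """Greedy stepwise insertion following a given leaf-addition order."""
    internal0 = n
    adj = _base_tree(list(order[:3]), internal0)
    next_internal = n + 1
    for leaf in order[3:]:
        best: Optional[Adj] = None
        best_score = None
        for edge in _edges(adj):
            cand = _insert_leaf(adj, edge, leaf, next_internal)
            s = _fitch_score_adj(cand, states, weights)
            if best_score is None or s < best_score:
                best_score = s
                best = cand
        adj = best
        next_internal += 1
    return adj


def _adj_to_phylo(
    adj: Adj,
    taxa: Sequence[str],
    lengths: Optional[Dict[Tuple[int, int], float]] = None,
) -> Tree:
    """Convert an adjacency tree to an unrooted Bio.Phylo tree.

    The root is placed at the internal node adjacent to leaf 0, giving the
    conventional basal trifurcation of an unrooted Newick tree.
    """
    n = len(taxa)
    if n == 2:
        root = Clade()
        for leaf in (0, 1):
            bl = None
            if lengths is not None:
                bl = lengths.get((0, 1))
                bl = bl / 2 if bl is not None else None
            root.clades.append(Clade(name=taxa[leaf], branch_length=bl))
        return Tree(root=root, rooted=False)
    root_node = adj[0][0]

    def build(node: int, parent: int) -> Clade:
        edge = (min(node, parent), max(node, parent))
        bl = lengths.get(edge) if lengths is not None else None
        if node < n:
            return Clade(name=taxa[node], branch_length=bl)
        clade = Clade(branch_length=bl)
        for nb in adj[node]:
            if nb != parent:
                clade.clades.append(build(nb, node))
        return clade

    root = Clade()
    for nb in adj[root_node]:
        root.clades.append(build(nb, root_node))
    return Tree(root=root, rooted=False)


def _phylo_to_adj(tree: Tree, taxa: Sequence[str]) -> Adj:
    """Convert a Bio.Phylo tree to adjacency form over the given taxa order."""
    index = {name: i for i, name in enumerate(taxa)}
    terminals = [t.name for t in tree.get_terminals()]
    if sorted(terminals) != sorted(taxa):
        raise ValueError(
            "tree leaf set does not match the genome IDs of the matrix"
        )
    n = len(taxa)
    adj: Adj = {}
    counter = itertools.count(n)

    def add_edge(u: int, v: int) -> None:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def walk(clade: Clade) -> int:
        if clade.is_terminal():
            return index[clade.name]
        me = next(counter)
        for ch in clade.clades:
            add_edge(me, walk(ch))
        return me

    root = tree.root
    kids = [walk(ch) for ch in root.clades]
    if len(kids) == 2:
        # rooted binary representation of an unrooted tree: suppress root
        add_edge(kids[0], kids[1])
    else:
        me = next(counter)
        for kid in kids:
            add_edge(me, kid)
    # degree check: internal nodes must be binary (degree 3) for Fitch
    for node, nbs in adj.items():
        if node >= n and len(nbs) != 3:
            raise ValueError(
                "Fitch scoring requires a fully resolved (binary) tree"
            )
        if node < n and len(nbs) != 1:
            raise ValueError(f"leaf {taxa[node]!r} is not terminal")
    return adj


# ---------------------------------------------------------------------------
# public API


def fitch_score(tree: Tree, matrix: SnpMatrix) -> int:
    """Minimum total state changes of the SNP matrix on a fixed topology.

    Missing alleles are treated as fully ambiguous {A,C,G,T}.  The tree
    must be binary (a basal trifurcation, the unrooted convention, is
    accepted) with leaves exactly the matrix genome IDs.
    """
    taxa, states, weights = _encode_matrix(matrix)
    if len(taxa) < 3:
        raise ValueError("fitch_score requires at least 3 genomes")
    adj = _phylo_to_adj(tree, taxa)
    return _fitch_score_adj(adj, states, weights)


@dataclass
class ParsimonyResult:
    """Best score, the retained equally parsimonious trees, and consensus."""

    best_score: int
    trees: List[Tree] = field(default_factory=list)
    consensus: Optional[Tree] = None
    exhaustive: bool = False


def parsimony_search(
    matrix: SnpMatrix,
    max_trees: int = 100,
    seed: int = 0,
    n_starts: int = 8,
    method: str = "auto",
) -> ParsimonyResult:
    """Search for most-parsimonious topologies and build their consensus.

    For eight or fewer genomes (``method='auto'``) the search enumerates
    every unrooted topology, so the best score is provably optimal.  For
    larger sets it uses seeded random-addition-order stepwise insertion
    followed by NNI hill climbing, restarted ``n_starts`` times.  Up to
    ``max_trees`` distinct best-scoring topologies are retained (identity
    by split set); the consensus is majority-rule with integer
    tree-count supports.  Retained trees carry branch lengths equal to the
    mean number of state changes per SNP site on each branch.
    """
    if matrix.n_loci == 0:
        raise ValueError("no SNPs to analyze")
    taxa, states, weights = _encode_matrix(matrix)
    n = len(taxa)
    if n < 2:
        raise ValueError("parsimony_search requires at least 2 genomes")
    if method not in ("auto", "exhaustive", "heuristic"):
        raise ValueError(f"unknown method {method!r}")
    if n < 4:
        # a single unrooted topology exists; report it directly
        if n == 2:
            diff = int(
                sum(
                    w
                    for w, s0, s1 in zip(weights, states[0], states[1])
                    if (s0 & s1) == 0
                )
            )
            tree = _adj_to_phylo({}, taxa)
            return ParsimonyResult(
                best_score=diff, trees=[tree], consensus=tree, exhaustive=True
            )
        adj = _base_tree([0, 1, 2], 3)
        score = _fitch_score_adj(adj, states, weights)
        lengths = _branch_changes(adj, states, weights)
        tree = _adj_to_phylo(adj, taxa, lengths)
        cons = consensus([tree])
        return ParsimonyResult(
            best_score=score, trees=[tree], consensus=cons, exhaustive=True
        )

    use_exhaustive = method == "exhaustive" or (method == "auto" and n <= 8)
    best_score: Optional[int] = None
    kept: Dict[SplitKey, Adj] = {}

    def offer(adj: Adj, score: int) -> None:
        nonlocal best_score, kept
        if best_score is None or score < best_score:
            best_score = score
            kept = {}
        if score == best_score and len(kept) < max_trees:
            kept.setdefault(_splits_adj(adj, n), adj)

    if use_exhaustive:
        for adj in _all_topologies(n):
            offer(adj, _fitch_score_adj(adj, states, weights))
    else:
        rng = random.Random(seed)
        for _ in range(n_starts):
            order = list(range(n))
            rng.shuffle(order)
            adj = _stepwise_addition(order, n, states, weights)
            score = _fitch_score_adj(adj, states, weights)
            improved = True
            while improved:
                improved = False
                ties: List[Adj] = []
                for cand in _nni_neighbors(adj, n):
                    s = _fitch_score_adj(cand, states, weights)
                    if s < score:
                        adj, score = cand, s
                        improved = True
                        break
                    if s == score:
                        ties.append(cand)
                if not improved:
                    offer(adj, score)
                    for cand in ties:
                        offer(cand, score)

    trees = []
    for adj in kept.values():
        lengths = _branch_changes(adj, states, weights)
        trees.append(_adj_to_phylo(adj, taxa, lengths))
    cons = consensus(trees)
    return ParsimonyResult(
        best_score=int(best_score),
        trees=trees,
        consensus=cons,
        exhaustive=use_exhaustive,
    )


# ---------------------------------------------------------------------------
# consensus


def _phylo_split_sets(tree: Tree) -> Tuple[List[str], set]:
    taxa = sorted(t.name for t in tree.get_terminals())
    full = frozenset(taxa)
    ref = taxa[0]
    n = len(taxa)
    splits = set()
    for clade in tree.get_nonterminals():
        names = frozenset(t.name for t in clade.get_terminals())
        if ref in names:
            names = full - names
        if 2 <= len(names) <= n - 2:
            splits.add(names)
    return taxa, splits


def consensus(trees: Sequence[Tree]) -> Tree:
    """Majority-rule consensus with integer clade-support labels.

    Each internal node of the consensus is labelled (``confidence``) with
    the number of input trees containing the clade of taxa descended from
    it.  Splits present in more than half of the trees are mutually
    compatible, so the construction cannot conflict; less frequent splits
    are collapsed into polytomies.
    """
    if not trees:
        raise ValueError("consensus requires at least one tree")
    leafsets = [frozenset(t.name for t in tr.get_terminals()) for tr in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("all trees must share the same leaf set")
    taxa = sorted(leafsets[0])
    counts: Dict[frozenset, int] = {}
    for tr in trees:
        _, splits = _phylo_split_sets(tr)
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    majority = {
        s: c for s, c in counts.items() if c * 2 > len(trees)
    }
    # build: attach each split-clade inside the smallest clade containing it
    root = Clade()
    placed: List[Tuple[frozenset, Clade]] = [(frozenset(taxa), root)]
    # splits are processed large-to-small, so the tightest enclosing clade
    # of each split (and finally of each leaf) is already in `placed`
    for s in sorted(majority, key=len, reverse=True):
        _, parent = min(
            ((ps, pc) for ps, pc in placed if s < ps),
            key=lambda item: len(item[0]),
        )
        clade = Clade(confidence=majority[s])
        parent.clades.append(clade)
        placed.append((s, clade))
    for name in taxa:
        singleton = frozenset([name])
        _, parent = min(
            ((ps, pc) for ps, pc in placed if singleton <= ps),
            key=lambda item: len(item[0]),
        )
        parent.clades.append(Clade(name=name))
    return Tree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on SNP p-distances.

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling branch of the join, preserving the pairwise
    distance between the joined nodes.
    """
    n = len(dist.genome_ids)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 genomes")
    if dist.has_undefined_pairs():
        raise ValueError(
            "some genome pairs share no comparable SNP loci; re-run on core "
            "SNPs or with a different k"
        )
    D = dist.p.astype(float).copy()
    nodes: List[Clade] = [Clade(name=g) for g in dist.genome_ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = li
        cj.branch_length = lj
        merged = Clade(clades=[ci, cj])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [merged]
        D = D2
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    root = Clade(clades=[a, b, c])
    return Tree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Robinson-Foulds distance and Newick IO


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds symmetric split difference between two trees."""
    taxa_a, splits_a = _phylo_split_sets(a)
    taxa_b, splits_b = _phylo_split_sets(b)
    if taxa_a != taxa_b:
        raise ValueError("trees have different leaf sets")
    return len(splits_a ^ splits_b)


def normalized_rf(a: Tree, b: Tree) -> float:
    """RF distance scaled to [0, 1] by the maximum 2(n-3) for n taxa."""
    n = len(a.get_terminals())
    if n <= 3:
        return 0.0
    return rf_distance(a, b) / (2 * (n - 3))


def topological_accuracy(estimate: Tree, truth: Tree) -> float:
    """1 minus the normalized RF distance to the true tree."""
    return 1.0 - normalized_rf(estimate, truth)


def write_newick(tree: Tree, path) -> None:
    """Serialize as Newick with integer supports as internal node labels."""
    with open(path, "w") as fh:
        Phylo.write([tree], fh, "newick", format_confidence="%d")


def read_newick(path) -> Tree:
    """Parse a Newick file into a Bio.Phylo tree."""
    return Phylo.read(str(path), "newick")
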