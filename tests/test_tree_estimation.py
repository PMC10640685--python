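import io
import random

import numpy as np
import pytest
from Bio import Phylo

from kmersnp.snp_discovery import DistanceMatrix, SnpLocus, SnpMatrix
from kmersnp.tree_estimation import (
    _all_topologies,
    _adj_to_phylo,
    _phylo_split_sets,
    consensus,
    fitch_score,
    nj_tree,
    normalized_rf,
    parsimony_search,
    read_newick,
    rf_distance,
    write_newick,
)
from oracles import brute_parsimony_score, count_clades


def _tree(newick):
    return Phylo.read(io.StringIO(newick), "newick")


def _matrix(columns, ids):
    """columns: list of strings, one character per genome (in ids order)."""
    loci = [
        SnpLocus(
            locus_id=i,
            context=f"C{i}",
            alleles=dict(zip(ids, col)),
            positions={},
        )
        for i, col in enumerate(columns)
    ]
    return SnpMatrix(genome_ids=list(ids), loci=loci)


def _random_matrix(rng, ids, n_cols, p_missing=0.1):
    cols = []
    for _ in range(n_cols):
        while True:
            col = "".join(
                "-" if rng.random() < p_missing else rng.choice("ACGT")
                for _ in ids
            )
            if len({c for c in col if c != "-"}) >= 2:
                break
        cols.append(col)
    return _matrix(cols, ids)


def _brute_score(tree, matrix):
    from kmersnp.tree_estimation import _phylo_to_adj

    ids = matrix.genome_ids
    adj = _phylo_to_adj(tree, ids)
    rows = [matrix.row(g) for g in ids]
    total = 0
    for col in range(matrix.n_loci):
        leaf_states = [
            "ACGT" if rows[i][col] == "-" else rows[i][col]
            for i in range(len(ids))
        ]
        total += brute_parsimony_score(adj, len(ids), leaf_states)
    return total


def test_fitch_perfect_character_and_homoplasy():
    m = _matrix(["AAGG"], ["t1", "t2", "t3", "t4"])
    assert fitch_score(_tree("((t1,t2),(t3,t4));"), m) == 1
    assert fitch_score(_tree("((t1,t3),(t2,t4));"), m) == 2


def test_fitch_matches_bruteforce_on_random_matrices(rng):
    ids = [f"t{i}" for i in range(6)]
    for rep in range(5):
        m = _random_matrix(rng, ids, 8)
        tree = _tree("((t0,t1),(t2,(t3,t4)),t5);")
        assert fitch_score(tree, m) == _brute_score(tree, m)


def test_fitch_leaf_mismatch_errors():
    m = _matrix(["AAGG"], ["t1", "t2", "t3", "t4"])
    with pytest.raises(ValueError):
        fitch_score(_tree("((t1,t2),(t3,tX));"), m)


def test_parsimony_recovers_known_tree_with_compatible_characters(rng):
    # 6-taxon tree ((a,b),(c,d),(e,f)) with 200 perfectly compatible sites
    ids = list("abcdef")
    splits = [
        "AAGGGG",  # {a,b}
        "GGAAGG",  # {c,d}
        "GGGGAA",  # {e,f}
        "AAAAGG",  # {a,b,c,d}
    ]
    cols = [splits[i % len(splits)] for i in range(200)]
    m = _matrix(cols, ids)
    res = parsimony_search(m, seed=1)
    assert res.exhaustive
    assert len(res.trees) == 1
    truth = _tree("(((a,b),(c,d)),(e,f));")
    assert rf_distance(res.trees[0], truth) == 0
    # every consensus node carries support equal to the retained tree count
    for clade in res.consensus.get_nonterminals():
        if clade.confidence is not None:
            assert clade.confidence == len(res.trees)


def test_parsimony_star_matrix_unresolved(rng):
    # columns where a single taxon differs carry no grouping information
    ids = list("abcde")
    cols = []
    for i in range(20):
        col = ["A"] * 5
        col[i % 5] = "G"
        cols.append("".join(col))
    m = _matrix(cols, ids)
    res = parsimony_search(m, seed=0)
    assert len(res.trees) > 1
    # majority-rule consensus of conflicting ties is fully unresolved
    nontrivial = [
        c for c in res.consensus.get_nonterminals() if c.confidence is not None
    ]
    assert nontrivial == []


def test_parsimony_majority_split_wins_4_taxa():
    ids = list("abcd")
    cols = ["AAGG"] * 3 + ["AGAG"]  # 3 sites favor {a,b}, one favors {a,c}
    m = _matrix(cols, ids)
    res = parsimony_search(m, seed=0)
    assert res.best_score == 5  # 3*1 + 2 on the winning topology
    best = res.trees[0]
    assert rf_distance(best, _tree("((a,b),(c,d));")) == 0
    # exhaustive confirmation against the brute-force oracle on all 3 topologies
    scores = {
        nwk: _brute_score(_tree(nwk), m)
        for nwk in ["((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));"]
    }
    assert min(scores.values()) == res.best_score


def test_exhaustive_matches_heuristic(rng):
    for n in (5, 6, 7):
        ids = [f"t{i}" for i in range(n)]
        m = _random_matrix(rng, ids, 15)
        ex = parsimony_search(m, method="exhaustive", seed=1)
        he = parsimony_search(m, method="heuristic", seed=3, n_starts=5)
        assert he.best_score == ex.best_score


def test_parsimony_empty_matrix_errors():
    with pytest.raises(ValueError, match="no SNPs"):
        parsimony_search(SnpMatrix(genome_ids=list("abcd"), loci=[]))


def test_consensus_identical_trees():
    t = "(((a,b),(c,d)),e);"
    cons = consensus([_tree(t) for _ in range(3)])
    for clade in cons.get_nonterminals():
        if clade.confidence is not None:
            assert clade.confidence == 3
    assert rf_distance(cons, _tree(t)) == 0


def test_consensus_conflicting_splits_collapse():
    t1 = _tree("(((a,b),c),(d,e));")
    t2 = _tree("(((a,b),d),(c,e));")
    cons = consensus([t1, t2])
    _, splits = _phylo_split_sets(cons)
    # {a,b} (normalized to its complement side {c,d,e}) is in both trees
    assert frozenset("cde") in splits
    supports = [
        c.confidence for c in cons.get_nonterminals() if c.confidence is not None
    ]
    assert supports == [2]


def test_consensus_supports_equal_bruteforce_clade_counts():
    # a deliberate mixture: 25 copies of one topology, 15 of another,
    # so shared splits count 40 and private majority splits count 25
    a = "(((a,b),(c,d)),((e,f),g));"
    b = "(((a,c),(b,d)),((e,f),g));"
    trees = [_tree(a) for _ in range(25)] + [_tree(b) for _ in range(15)]
    cons = consensus(trees)
    for clade in cons.get_nonterminals():
        if clade.confidence is None:
            continue
        names = frozenset(t.name for t in clade.get_terminals())
        assert clade.confidence == count_clades(trees, names)
        assert clade.confidence <= len(trees)
        assert clade.confidence * 2 > len(trees)


def _additive_distance_from_tree(tree):
    ids = sorted(t.name for t in tree.get_terminals())
    n = len(ids)
    D = np.zeros((n, n))
    terms = {t.name: t for t in tree.get_terminals()}
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.distance(terms[ids[i]], terms[ids[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(
        genome_ids=ids,
        counts=D.astype(int),
        comparable=np.ones((n, n), dtype=int),
        p=D,
    )


def test_nj_exact_on_additive_matrix():
    truth = _tree("((A:2,B:3):1,(C:4,D:5):2,E:6);")
    dm = _additive_distance_from_tree(truth)
    est = nj_tree(dm)
    assert rf_distance(est, truth) == 0
    # branch lengths are recovered exactly: compare all patristic distances
    terms = sorted(t.name for t in est.get_terminals())
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            d_est = est.distance(a, b)
            d_true = truth.distance(a, b)
            assert abs(d_est - d_true) < 1e-9


def test_nj_three_taxa():
    dm = DistanceMatrix(
        genome_ids=["a", "b", "c"],
        counts=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]]),
        comparable=np.ones((3, 3), dtype=int),
        p=np.array([[0.0, 2, 3], [2, 0, 3], [3, 3, 0]]),
    )
    tree = nj_tree(dm)
    assert len(tree.get_terminals()) == 3
    assert abs(tree.distance("a", "b") - 2) < 1e-9


def test_nj_taxon_order_invariance(rng):
    truth = _tree("(((A:1,B:2):1,(C:2,D:1):2):1,(E:3,F:1):2,G:4);")
    dm = _additive_distance_from_tree(truth)
    est1 = nj_tree(dm)
    perm = list(range(len(dm.genome_ids)))
    rng.shuffle(perm)
    dm2 = DistanceMatrix(
        genome_ids=[dm.genome_ids[i] for i in perm],
        counts=dm.counts[np.ix_(perm, perm)],
        comparable=dm.comparable[np.ix_(perm, perm)],
        p=dm.p[np.ix_(perm, perm)],
    )
    est2 = nj_tree(dm2)
    assert rf_distance(est1, est2) == 0


def test_nj_matches_dendropy(rng):
    """Dual-route check: our Saitou-Nei against dendropy's implementation."""
    dendropy = pytest.importorskip("dendropy")
    ids = [f"t{i}" for i in range(6)]
    # a noisy (non-additive) symmetric matrix
    n = len(ids)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = rng.uniform(0.05, 0.9)
    dm = DistanceMatrix(
        genome_ids=ids,
        counts=M.astype(int),
        comparable=np.ones((n, n), dtype=int),
        p=M,
    )
    ours = nj_tree(dm)
    csv = "," + ",".join(ids) + "\n"
    for i, a in enumerate(ids):
        csv += a + "," + ",".join(str(M[i, j]) for j in range(n)) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
    theirs_dp = pdm.nj_tree()
    ours_dp = dendropy.Tree.get(
        data=ours.format("newick"),
        schema="newick",
        taxon_namespace=theirs_dp.taxon_namespace,
    )
    from dendropy.calculate import treecompare

    theirs_dp.encode_bipartitions()
    ours_dp.encode_bipartitions()
    assert treecompare.symmetric_difference(ours_dp, theirs_dp) == 0


def test_nj_undefined_distance_errors():
    p = np.array([[0.0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
    dm = DistanceMatrix(
        genome_ids=["a", "b", "c"],
        counts=np.zeros((3, 3), dtype=int),
        comparable=np.ones((3, 3), dtype=int),
        p=p,
    )
    with pytest.raises(ValueError, match="comparable"):
        nj_tree(dm)


def test_newick_roundtrip_random_trees(tmp_path):
    from kmersnp.synthetic_data import simulate_tree

    for seed in range(50):
        tree = simulate_tree(8, seed=seed)
        path = tmp_path / f"t{seed}.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert rf_distance(tree, back) == 0


def test_newick_supports_written_as_internal_labels(tmp_path):
    t = "(((a,b),(c,d)),e);"
    cons = consensus([_tree(t) for _ in range(5)])
    path = tmp_path / "c.nwk"
    write_newick(cons, path)
    text = path.read_text()
    assert ")5" in text  # label directly after the internal closing paren


def test_rf_distances():
    a = _tree("(((a,b),c),((d,e),f));")
    assert rf_distance(a, a) == 0
    # maximally different caterpillars on 6 taxa
    cat1 = _tree("(a,(b,(c,(d,(e,f)))));")
    cat2 = _tree("(a,(d,(b,(f,(c,e)))));")
    assert normalized_rf(cat1, cat2) == 1.0
    # trees one NNI apart differ by exactly one split on each side
    t1 = _tree("(((a,b),c),(d,(e,f)));")
    t2 = _tree("(((a,c),b),(d,(e,f)));")
    assert rf_distance(t1, t2) == 2
    with pytest.raises(ValueError):
        rf_distance(a, _tree("((a,b),(c,x));"))


def test_parsimony_branch_lengths_nonnegative(rng):
    ids = [f"t{i}" for i in range(6)]
    m = _random_matrix(rng, ids, 30, p_missing=0.0)
    res = parsimony_search(m, seed=2)
    for tree in res.trees:
        for clade in tree.find_clades():
            if clade.branch_length is not None:
                assert clade.branch_length >= 0
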