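import numpy as np
import pytest

from ionbind.phylo import (
    AlignedSequenceSet,
    bootstrap_support,
    greedy_cluster,
    identity_cdf,
    nj_tree,
    pairwise_identity,
    parse_newick,
    position_patterns,
    tree_distance_matrix,
)
from ionbind.phylo.tree import Tree, TreeNode


def aln(*pairs, taxa=None):
    ids = tuple(p[0] for p in pairs)
    seqs = tuple(p[1] for p in pairs)
    return AlignedSequenceSet(ids=ids, sequences=seqs, taxa=taxa)


# ---------------------------------------------------------------- identity

def test_identical_sequences():
    m = pairwise_identity(aln(("a", "ACDE"), ("b", "ACDE")))
    assert m.identity("a", "b") == 1.0


def test_three_quarters():
    m = pairwise_identity(aln(("a", "ACDE"), ("b", "ACDF")))
    assert m.identity("a", "b") == 0.75


def test_gap_excluded_denominator():
    # "AC-E" vs "ACDE": 3 comparable columns, all matching -> 1.0
    m = pairwise_identity(aln(("a", "AC-E"), ("b", "ACDE")))
    assert m.identity("a", "b") == 1.0
    # brute-force column walk
    s1, s2 = "AC-E", "ACDE"
    num = den = 0
    for c1, c2 in zip(s1, s2):
        if c1 != "-" and c2 != "-":
            den += 1
            num += c1 == c2
    assert m.identity("a", "b") == num / den


def test_all_gap_pair_flagged():
    m = pairwise_identity(aln(("a", "AA--"), ("b", "--CC"), ("c", "AACC")))
    assert ("a", "b") in m.undefined_pairs
    assert np.isnan(m.identity("a", "b"))
    assert m.identity("a", "c") == 1.0


def test_matrix_symmetric_unit_diagonal():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACDEFG"), size=30)) for _ in range(5)]
    m = pairwise_identity(aln(*[(f"s{i}", s) for i, s in enumerate(seqs)]))
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 1.0)


def test_cdf_monotone_ends_at_one():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=40)) for _ in range(6)]
    m = pairwise_identity(aln(*[(f"s{i}", s) for i, s in enumerate(seqs)]))
    cdf = identity_cdf(m)
    assert (cdf["cdf"].diff().dropna() >= 0).all()
    assert cdf["cdf"].iloc[-1] == 1.0


# ---------------------------------------------------------------- clustering

def test_two_similar_one_cluster():
    a = aln(("x", "A" * 19 + "C"), ("y", "A" * 20))
    m = pairwise_identity(a)
    cs = greedy_cluster(a, m, threshold=0.90)
    assert cs.n_clusters == 1
    assert set(cs.clusters[0].members) == {"x", "y"}


def test_three_sequences_two_clusters():
    # A~B 95%, both ~C 40%
    base = "ACDEFGHIKLMNPQRSTVWY"
    s_a = base
    s_b = base[:-1] + "A"                      # 19/20 = 95%
    s_c = "Y" * 12 + base[12:]                 # 8/20 = 40% to A
    a = aln(("A", s_a), ("B", s_b), ("C", s_c))
    m = pairwise_identity(a)
    cs = greedy_cluster(a, m, threshold=0.90)
    assert cs.n_clusters == 2
    membership = cs.membership()
    assert membership["A"] == membership["B"]
    assert membership["C"] != membership["A"]
    # exhaustive check of the greedy rule
    for c in cs.clusters:
        for member in c.members:
            ident = m.identity(member, c.representative)
            assert member == c.representative or ident >= 0.90


def test_threshold_one_all_singletons():
    a = aln(("x", "AAAA"), ("y", "AAAC"), ("z", "AACC"))
    cs = greedy_cluster(a, pairwise_identity(a), threshold=1.0)
    assert cs.n_clusters == 3


def test_clusters_partition_input():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("AC"), size=30)) for _ in range(10)]
    a = aln(*[(f"s{i}", s) for i, s in enumerate(seqs)])
    cs = greedy_cluster(a, pairwise_identity(a), threshold=0.8)
    members = [m for c in cs.clusters for m in c.members]
    assert sorted(members) == sorted(a.ids)


def test_bad_threshold_rejected():
    a = aln(("x", "AA"), ("y", "AC"))
    with pytest.raises(ValueError):
        greedy_cluster(a, pairwise_identity(a), threshold=0.0)


def test_longest_sequence_is_representative():
    a = aln(("short", "AC-E"), ("long", "ACDE"))
    cs = greedy_cluster(a, pairwise_identity(a), threshold=0.9)
    assert cs.clusters[0].representative == "long"


# ---------------------------------------------------------------- NJ

def test_two_taxa_single_edge():
    with pytest.warns(UserWarning, match="two taxa"):
        tree = nj_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
    assert tree.total_length() == pytest.approx(3.0)
    assert sorted(tree.leaf_names()) == ["a", "b"]


def test_three_taxa_ultrametric_join():
    D = np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 1.0], [1.0, 1.0, 0.0]])
    tree = nj_tree(D, ["a", "b", "c"])
    got, names = tree_distance_matrix(tree)
    order = [names.index(x) for x in ["a", "b", "c"]]
    assert np.allclose(got[np.ix_(order, order)], D, atol=1e-12)


def test_four_taxon_additive_recovery():
    # ((a:2,b:3):1,(c:4,d:5)) -> additive matrix, exact recovery
    truth = parse_newick("((a:2,b:3):1,(c:4,d:5):0);")
    D, names = tree_distance_matrix(truth)
    tree = nj_tree(D, names)
    assert tree.bipartitions() == truth.bipartitions()
    got, got_names = tree_distance_matrix(tree)
    order = [got_names.index(x) for x in names]
    assert np.allclose(got[np.ix_(order, order)], D, atol=1e-12)


@pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
def test_random_additive_trees_recovered(n_taxa, seed):
    rng = np.random.default_rng(seed)

    def random_tree(names):
        nodes = [TreeNode(name=n, length=float(rng.uniform(0.5, 3.0))) for n in names]
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = TreeNode(length=float(rng.uniform(0.5, 3.0)),
                              children=[nodes[i], nodes[j]])
            nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
        return Tree(TreeNode(children=nodes))

    truth = random_tree([f"t{i}" for i in range(n_taxa)])
    D, names = tree_distance_matrix(truth)
    tree = nj_tree(D, names)
    assert tree.bipartitions() == truth.bipartitions()
    got, got_names = tree_distance_matrix(tree)
    order = [got_names.index(x) for x in names]
    assert np.allclose(got[np.ix_(order, order)], D, atol=1e-10)


def test_nj_matches_dendropy_oracle():
    import dendropy

    rng = np.random.default_rng(11)
    n = 6
    names = [f"t{i}" for i in range(n)]
    # random symmetric distances (not additive): compare topologies
    M = rng.uniform(0.2, 1.0, size=(n, n))
    D = (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    tree = nj_tree(D, names)

    csv = "," + ",".join(names) + "\n"
    for i, nm in enumerate(names):
        csv += nm + "," + ",".join(f"{D[i, j]:.10f}" for j in range(n)) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv), delimiter=","
    )
    dtree = pdm.nj_tree()
    oracle = parse_newick(dtree.as_string(schema="newick").replace("[&U] ", ""))
    assert tree.bipartitions() == oracle.bipartitions()


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])  # asymmetric
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])  # negative
    with pytest.raises(ValueError):
        nj_tree(np.zeros((1, 1)), ["a"])  # too few


# ---------------------------------------------------------------- bootstrap

def concordant_alignment():
    # every column supports the split {a,b} | {c,d}
    return aln(("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAA"),
               ("c", "CCCCCCCCCC"), ("d", "CCCCCCCCCC"))


def test_bootstrap_full_support_on_planted_split():
    tree, supports = bootstrap_support(concordant_alignment(), n_reps=50, seed=0)
    split = frozenset({"a", "b"})
    assert supports[split] == 100.0


def test_bootstrap_single_column_all_or_nothing():
    a = aln(("a", "A"), ("b", "A"), ("c", "C"), ("d", "C"))
    _, supports = bootstrap_support(a, n_reps=20, seed=1)
    assert all(v in (0.0, 100.0) for v in supports.values())


def test_bootstrap_deterministic():
    a = concordant_alignment()
    _, s1 = bootstrap_support(a, n_reps=25, seed=7)
    _, s2 = bootstrap_support(a, n_reps=25, seed=7)
    assert s1 == s2


def test_bootstrap_taxon_order_invariant():
    a1 = concordant_alignment()
    a2 = aln(("d", "CCCCCCCCCC"), ("b", "AAAAAAAAAA"),
             ("a", "AAAAAAAAAA"), ("c", "CCCCCCCCCC"))
    _, s1 = bootstrap_support(a1, n_reps=30, seed=3)
    _, s2 = bootstrap_support(a2, n_reps=30, seed=3)
    assert s1 == s2


def test_bootstrap_nreps_validated():
    with pytest.raises(ValueError):
        bootstrap_support(concordant_alignment(), n_reps=0, seed=0)


def test_newick_support_serialization():
    tree, _ = bootstrap_support(concordant_alignment(), n_reps=10, seed=0)
    text = tree.to_newick(support=True)
    assert "100" in text
    back = parse_newick(text)
    assert sorted(back.leaf_names()) == ["a", "b", "c", "d"]


# ---------------------------------------------------------------- patterns

def test_patterns_clade_split():
    a = aln(("r1", "MNSA"), ("r2", "MNSA"), ("q1", "MSSA"), ("q2", "MSSA"),
            taxa=("cladeA", "cladeA", "cladeB", "cladeB"))
    table = position_patterns(a, "r1", {"3.35": 1}, expected_residues={"3.35": "N"})
    assert table.residues.loc["r1", "3.35"] == "N"
    assert table.residues.loc["q1", "3.35"] == "S"
    assert table.clade_consensus.loc["cladeA", "3.35"] == "N"
    assert table.clade_consensus.loc["cladeB", "3.35"] == "S"


def test_patterns_anchor_mismatch_rejected():
    a = aln(("r1", "MNSA"), ("q1", "MSSA"))
    with pytest.raises(ValueError, match="does not match"):
        position_patterns(a, "r1", {"3.35": 1}, expected_residues={"3.35": "Q"})


def test_patterns_invariant_column_frequency_one():
    a = aln(("r1", "MNSA"), ("q1", "MSSA"))
    table = position_patterns(a, "r1", {"1.50": 0})
    assert table.frequencies["1.50"] == {"M": 1.0}


def test_patterns_gapped_reference_mapping():
    # reference has a gap: residue indices map through it
    a = aln(("ref", "M-NSA"), ("other", "MQNTA"))
    table = position_patterns(a, "ref", {"x": 1})  # residue 1 of ref = 'N' at column 2
    assert table.columns["x"] == 2
    assert table.residues.loc["other", "x"] == "N"


def test_patterns_out_of_range_anchor():
    a = aln(("ref", "MNSA"), ("other", "MQNT"))
    with pytest.raises(ValueError, match="outside"):
        position_patterns(a, "ref", {"x": 10})
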