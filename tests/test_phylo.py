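"""Alignment, NJ, newick IO, monophyletic clusters, phylogenetic diversity."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from rapphr._util import InputError, NewickParseError
from rapphr.phylo import (PeptideCluster, ProteinAlignment, align_proteins,
                          build_nj_tree, p_distance_matrix,
                          peptide_monophyletic_clusters,
                          phylo_diversity_fraction, read_newick, write_newick)
from rapphr.phylo import _nj_from_distance
from rapphr.simulate import simulate_strain_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seqs(n, length, seed):
    rng = np.random.default_rng(seed)
    return {f"s{i}": "".join(rng.choice(list(AA), size=length)) for i in range(n)}


# ---------------------------------------------------------------------------
# alignment


def test_identical_pair_aligns_gap_free():
    al = align_proteins({"a": "MKLVAT", "b": "MKLVAT"})
    assert al.rows == ["MKLVAT", "MKLVAT"]


def test_single_gap_alignment_example():
    al = align_proteins({"a": "MKLV", "b": "MKV"})
    assert sorted(r.count("-") for r in al.rows) == [0, 1]
    matched = sum(x == y for x, y in zip(*al.rows))
    assert matched == 3


def test_ungapping_recovers_inputs():
    for seed in range(10):
        seqs = _random_seqs(4, 40, seed)
        al = align_proteins(seqs)
        assert al.ids == list(seqs)
        for i, sid in enumerate(al.ids):
            assert al.ungapped(i) == seqs[sid]


def test_duplicate_ids_rejected():
    with pytest.raises(InputError):
        ProteinAlignment(["a", "a"], ["MK", "MK"])
    with pytest.raises(InputError):
        align_proteins({})


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) in distance form
    d = DistanceMatrix(np.array([[0, 3, 5, 6],
                                 [3, 0, 6, 7],
                                 [5, 6, 0, 7],
                                 [6, 7, 7, 0]], float), list("ABCD"))
    tree = _nj_from_distance(d)
    # AB must be siblings (additive-case consistency of NJ)
    names = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
    assert frozenset("AB") in names or frozenset("CD") in names
    td = tree.tip_tip_distances().filter(list("ABCD"))
    assert np.allclose(td.data, d.filter(list("ABCD")).data, atol=1e-9)


def test_identical_sequences_give_zero_internal_lengths():
    al = ProteinAlignment(["a", "b", "c", "d"], ["MKLV"] * 4)
    tree = build_nj_tree(al, n_bootstrap=0)
    for node in tree.traverse():
        if node.length is not None:
            assert node.length == pytest.approx(0.0)


def test_nj_deterministic_given_seed():
    seqs = _random_seqs(25, 60, seed=9)
    al = align_proteins(seqs)
    t1 = build_nj_tree(al, n_bootstrap=10, seed=4)
    t2 = build_nj_tree(al, n_bootstrap=10, seed=4)
    assert write_newick(t1) == write_newick(t2)


def test_fewer_than_three_sequences_rejected():
    with pytest.raises(InputError):
        build_nj_tree(ProteinAlignment(["a", "b"], ["MK", "MK"]), n_bootstrap=0)


def test_p_distance_pairwise_deletion():
    al = ProteinAlignment(["a", "b"], ["MK-V", "MKLV"])
    d = p_distance_matrix(al)
    assert d["a", "b"] == pytest.approx(0.0)  # gap column deleted pairwise


# ---------------------------------------------------------------------------
# newick IO


def test_simple_newick_example():
    tree = read_newick("(A:1,(B:1,C:1):2);")
    assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
    internal = [n for n in tree.non_tips(include_self=False)]
    assert len(internal) == 1 and internal[0].length == 2


def test_newick_round_trip_on_random_trees():
    for seed in range(20):
        tree = simulate_strain_tree(7, 2, seed=seed)
        text = write_newick(tree)
        again = write_newick(read_newick(text))
        assert again == text


def test_unbalanced_parentheses_reports_position():
    with pytest.raises(NewickParseError) as err:
        read_newick("((A,B);")
    assert err.value.position == 1
    with pytest.raises(NewickParseError) as err:
        read_newick("(A,B));")
    assert err.value.position == 5


def test_bootstrap_labels_survive_round_trip():
    tree = read_newick("((A:1,B:1)95:2,C:1);")
    assert "95" in write_newick(tree)


# ---------------------------------------------------------------------------
# monophyletic peptide clusters


def brute_force_clusters(tree, peptides):
    """Oracle: enumerate every clade; keep pure clades maximal under purity."""
    clades = []
    for node in tree.postorder():
        tips = frozenset(t.name for t in node.tips(include_self=True))
        labels = {peptides[t] if peptides[t] else f"none-{t}" for t in tips}
        clades.append((node, tips, len(labels) == 1))
    pure = {tips for _, tips, ok in clades if ok}
    maximal = set()
    for node, tips, ok in clades:
        if not ok:
            continue
        parent = node.parent
        if parent is None:
            maximal.add(tips)
            continue
        ptips = frozenset(t.name for t in parent.tips(include_self=True))
        if ptips not in pure:
            maximal.add(tips)
    return maximal


def test_cluster_example():
    tree = read_newick("(((A:1,B:1):1,C:1):1,D:1);")
    clusters = peptide_monophyletic_clusters(
        tree, {"A": "p1", "B": "p1", "C": "p2", "D": "p1"})
    got = {frozenset(c.members) for c in clusters}
    assert got == {frozenset("AB"), frozenset("C"), frozenset("D")}
    assert len({c.peptide for c in clusters}) == 2


def test_all_same_peptide_yields_single_cluster():
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    clusters = peptide_monophyletic_clusters(tree, {t: "p" for t in "ABCD"})
    assert len(clusters) == 1 and clusters[0].peptide == "p"


@pytest.mark.parametrize("seed", range(15))
def test_clusters_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    tree = simulate_strain_tree(n, 1, seed=seed)
    leaves = [t.name for t in tree.tips()]
    peptides = {l: (None if rng.random() < 0.2
                    else f"p{rng.integers(3)}") for l in leaves}
    clusters = peptide_monophyletic_clusters(tree, peptides)
    got = {frozenset(c.members) for c in clusters}
    assert got == brute_force_clusters(tree, peptides)
    # partition property
    assert sorted(m for c in clusters for m in c.members) == sorted(leaves)


def test_unmapped_leaf_rejected():
    tree = read_newick("(A:1,(B:1,C:1):1);")
    with pytest.raises(InputError):
        peptide_monophyletic_clusters(tree, {"A": "p", "B": "p"})


def test_orphan_merging_within_distance():
    tree = read_newick("(((A:0.01,B:0.01):1,C:0.02):1,D:1);")
    peptides = {"A": None, "B": None, "C": "p", "D": "p"}
    merged = peptide_monophyletic_clusters(tree, peptides,
                                           orphan_merge_distance=0.1)
    got = {frozenset(c.members) for c in merged}
    assert frozenset("AB") in got
    singles = peptide_monophyletic_clusters(tree, peptides,
                                            orphan_merge_distance=None)
    assert {frozenset(c.members) for c in singles} >= {frozenset("A"), frozenset("B")}


# ---------------------------------------------------------------------------
# phylogenetic diversity


def test_full_leaf_set_spans_everything():
    tree = simulate_strain_tree(9, 3, seed=2)
    leaves = [t.name for t in tree.tips()]
    assert phylo_diversity_fraction(tree, leaves) == pytest.approx(1.0)


def test_single_leaf_on_star_tree():
    star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
    assert phylo_diversity_fraction(star, ["A"]) == pytest.approx(1 / 5)


def _oracle_fraction(tree, subset):
    """Edge-enumeration oracle: an edge counts iff a subset leaf lies below."""
    def spanned(group):
        total = 0.0
        for node in tree.postorder():
            if node.parent is None:
                continue
            below = {t.name for t in node.tips(include_self=True)}
            if below & group:
                total += node.length or 0.0
        return total

    all_leaves = {t.name for t in tree.tips()}
    return spanned(set(subset)) / spanned(all_leaves)


@pytest.mark.parametrize("seed", range(10))
def test_fraction_matches_edge_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    tree = simulate_strain_tree(int(rng.integers(4, 12)), 2, seed=seed)
    leaves = [t.name for t in tree.tips()]
    k = int(rng.integers(1, len(leaves) + 1))
    subset = list(rng.choice(leaves, size=k, replace=False))
    assert phylo_diversity_fraction(tree, subset) == \
        pytest.approx(_oracle_fraction(tree, subset))


def test_diversity_monotone_under_inclusion():
    rng = np.random.default_rng(3)
    tree = simulate_strain_tree(10, 2, seed=5)
    leaves = [t.name for t in tree.tips()]
    for _ in range(20):
        a = set(rng.choice(leaves, size=int(rng.integers(1, 9)), replace=False))
        extra = set(rng.choice(leaves, size=int(rng.integers(1, 3)), replace=False))
        b = a | extra
        assert phylo_diversity_fraction(tree, a) <= \
            phylo_diversity_fraction(tree, b) + 1e-12


def test_empty_subset_rejected():
    tree = read_newick("(A:1,B:1,C:1);")
    with pytest.raises(InputError):
        phylo_diversity_fraction(tree, [])
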