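"""Binarization and gain/loss parsimony against exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rapphr._util import InputError
from rapphr.phylo import ProteinAlignment, read_newick
from rapphr.simulate import simulate_strain_tree, simulate_trait_history
from rapphr.traits import (BinarizationThresholds, GainLossResult,
                           assignment_cost, binarize_targets,
                           column_conservation, count_independent_gains,
                           interface_conservation, parsimony_gainloss,
                           parsimony_gainloss_matrix)

# ---------------------------------------------------------------------------
# binarization


def _measurements():
    return pd.DataFrame({
        "sporulation_efficiency": [1e-4, 0.5, 0.5, None],
        "reporter_expression": [900.0, 80.0, 200.0, 100.0],
    }, index=["rapSpo", "rapCom", "rapNone", "rapMissing"])


def test_binarization_directions_and_missing_cells():
    thr = BinarizationThresholds(spo0a_cutoff=0.1, coma_cutoff=200.0)
    tm = binarize_targets(_measurements(), thr)
    assert tm.loc["rapSpo", "represses_spo0a"] == 1     # far below cutoff
    assert tm.loc["rapSpo", "represses_coma"] == 0
    assert tm.loc["rapCom", "represses_coma"] == 1
    assert tm.loc["rapNone", "represses_coma"] == 0     # at cutoff: not repressing
    assert pd.isna(tm.loc["rapMissing", "represses_spo0a"])


def test_values_at_threshold_are_all_zero():
    df = pd.DataFrame({"sporulation_efficiency": [0.1], "reporter_expression": [200.0]},
                      index=["rapX"])
    thr = BinarizationThresholds(spo0a_cutoff=0.1, coma_cutoff=200.0)
    tm = binarize_targets(df, thr)
    assert tm.loc["rapX"].tolist() == [0, 0]


# ---------------------------------------------------------------------------
# tree enumeration and oracles


def all_rooted_trees(leaves: list[str]):
    """All rooted binary topologies by sequential leaf insertion on edges."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in all_rooted_trees(leaves[:-1]):
        for t in _insert_everywhere(sub, leaves[-1]):
            yield t


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for new_left in _insert_everywhere(left, leaf):
            yield (new_left, right)
        for new_right in _insert_everywhere(right, leaf):
            yield (left, new_right)


def to_treenode(shape) -> TreeNode:
    counter = itertools.count()

    def build(node):
        if isinstance(node, str):
            return TreeNode(name=node, length=1.0)
        t = TreeNode(name=f"i{next(counter)}", length=1.0)
        t.extend([build(node[0]), build(node[1])])
        return t

    root = build(shape)
    root.length = None
    return root


def exhaustive_min_events(tree: TreeNode, tip_states: dict[str, int],
                          root_state: int | None) -> int:
    """Oracle: enumerate every internal-state assignment."""
    internals = [n for n in tree.traverse() if not n.is_tip()]
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        states = {n.name: s for n, s in zip(internals, combo)}
        states.update(tip_states)
        if root_state is not None and states[tree.name] != root_state:
            continue
        cost = 0
        for node in tree.traverse():
            if node.parent is not None:
                cost += states[node.name] != states[node.parent.name]
        best = cost if best is None else min(best, cost)
    return best


def fitch_free_root_events(tree: TreeNode, tip_states: dict[str, int]) -> int:
    """Independent Fitch-set oracle for equal costs and a free root."""
    count = 0

    def post(node):
        nonlocal count
        if node.is_tip():
            return {tip_states[node.name]}
        sets = [post(c) for c in node.children]
        inter = set.intersection(*sets)
        if inter:
            return inter
        count += len(sets) - 1 if len(sets) > 2 else 1
        return set.union(*sets)

    post(tree)
    return count


# ---------------------------------------------------------------------------
# parsimony correctness


def test_uniform_tips_need_no_events():
    tree = to_treenode((("A", "B"), ("C", "D")))
    res = parsimony_gainloss(tree, {t: 1 for t in "ABCD"})
    assert res.total_events == 0 and res.root_state == 1


@pytest.mark.parametrize("n_leaves", [4, 5])
def test_parsimony_equals_exhaustive_enumeration_all_trees(n_leaves):
    leaves = [f"t{i}" for i in range(n_leaves)]
    for shape in all_rooted_trees(leaves):
        tree = to_treenode(shape)
        for states in itertools.product((0, 1), repeat=n_leaves):
            tip_states = dict(zip(leaves, states))
            for root_state in (None, 0, 1):
                res = parsimony_gainloss(tree, tip_states, root_state=root_state)
                oracle = exhaustive_min_events(tree, tip_states, root_state)
                assert res.total_events == oracle
                # the emitted assignment must realize the minimal cost
                assert assignment_cost(tree, res.ancestral_states) == oracle


def test_parsimony_equals_exhaustive_on_sampled_six_leaf_trees():
    rng = np.random.default_rng(0)
    leaves = [f"t{i}" for i in range(6)]
    shapes = list(all_rooted_trees(leaves))
    idx = rng.choice(len(shapes), size=40, replace=False)
    for i in idx:
        tree = to_treenode(shapes[i])
        for states in itertools.product((0, 1), repeat=6):
            tip_states = dict(zip(leaves, states))
            res = parsimony_gainloss(tree, tip_states, root_state=None)
            assert res.total_events == exhaustive_min_events(tree, tip_states, None)


def test_sankoff_equals_fitch_on_random_trees():
    rng = np.random.default_rng(1)
    for seed in range(200):
        n = int(rng.integers(4, 12))
        tree = simulate_strain_tree(n, 1, seed=seed)
        tips = [t.name for t in tree.tips()]
        tip_states = {t: int(rng.integers(2)) for t in tips}
        free = parsimony_gainloss(tree, tip_states, root_state=None)
        assert free.total_events == fitch_free_root_events(tree, tip_states)


def test_fixed_root_never_cheaper_than_free():
    rng = np.random.default_rng(2)
    for seed in range(50):
        tree = simulate_strain_tree(int(rng.integers(4, 10)), 1, seed=seed)
        tip_states = {t.name: int(rng.integers(2)) for t in tree.tips()}
        free = parsimony_gainloss(tree, tip_states).total_events
        for root_state in (0, 1):
            fixed = parsimony_gainloss(tree, tip_states,
                                       root_state=root_state).total_events
            assert fixed >= free


def test_no_single_flip_improves_the_assignment():
    rng = np.random.default_rng(3)
    for seed in range(30):
        tree = simulate_strain_tree(8, 2, seed=seed)
        tip_states = {t.name: int(rng.integers(2)) for t in tree.tips()}
        res = parsimony_gainloss(tree, tip_states)
        base = assignment_cost(tree, res.ancestral_states)
        for node in tree.traverse():
            if node.is_tip():
                continue
            name = node.name if node.name is not None else "<root>"
            flipped = dict(res.ancestral_states)
            flipped[name] = 1 - flipped[name]
            assert assignment_cost(tree, flipped) >= base


def test_unknown_tips_are_unconstrained():
    tree = to_treenode((("A", "B"), ("C", "D")))
    res = parsimony_gainloss(tree, {"A": 1, "B": 1, "C": None, "D": 1})
    assert res.total_events == 0


def test_taxon_absent_from_tree_rejected():
    tree = to_treenode(("A", "B"))
    with pytest.raises(InputError):
        parsimony_gainloss(tree, {"A": 1, "B": 0, "Z": 1})


# ---------------------------------------------------------------------------
# gains, events, simulated histories


def test_constructed_two_gain_scenario():
    tree = read_newick("(((a:1,b:1)x:1,(c:1,d:1)y:1)u:1,(e:1,f:1)v:1)r;")
    tip_states = {"a": 1, "b": 1, "c": 0, "d": 0, "e": 1, "f": 1}
    res = parsimony_gainloss(tree, tip_states, root_state=0)
    assert res.total_events == 2
    assert count_independent_gains(res) == 2
    assert set(res.gains()) == {"x", "v"}


def test_zero_event_result_has_zero_gains():
    tree = to_treenode(("A", "B"))
    res = parsimony_gainloss(tree, {"A": 0, "B": 0})
    assert count_independent_gains(res) == 0


def test_parsimony_events_bounded_by_simulated_history():
    tree = simulate_strain_tree(25, 1, seed=9)
    matrix, events = simulate_trait_history(
        tree, {"spo0a": 1, "coma": 0}, gain_rate=0.4, loss_rate=0.4, seed=9)
    results = parsimony_gainloss_matrix(tree, matrix,
                                        root_states={"spo0a": 1, "coma": 0})
    for trait, res in results.items():
        true_flips = (events["trait"] == trait).sum()
        assert res.total_events <= true_flips


# ---------------------------------------------------------------------------
# conservation


def test_identical_column_is_fully_conserved():
    assert column_conservation(["K"] * 10) == pytest.approx(1.0)


def test_uniform_column_has_zero_conservation():
    col = list("ACDEFGHIKLMNPQRSTVWY")
    assert column_conservation(col) == pytest.approx(0.0)


def test_all_gap_column_is_nan():
    assert np.isnan(column_conservation(["-", "-"]))


def test_planted_interface_columns_beat_background():
    rng = np.random.default_rng(4)
    AA = list("ACDEFGHIKLMNPQRSTVWY")
    n, L = 12, 40
    rows = ["".join(rng.choice(AA, size=L)) for _ in range(n)]
    planted = [5, 17, 30]
    for p in planted:
        rows = [r[:p] + "W" + r[p + 1:] for r in rows]
    ids = [f"r{i}" for i in range(n)]
    aln = ProteinAlignment(ids, rows)
    labels = {i: (k < 6) for k, i in enumerate(ids)}
    prof = interface_conservation(aln, planted, labels)
    background = interface_conservation(aln, [0, 1, 2, 3], labels)
    assert np.nanmean(prof.scores) > np.nanmean(background.scores)
    assert prof.target_consensus.split() == ["W", "W", "W"]


def test_positions_and_labels_validated():
    aln = ProteinAlignment(["a", "b"], ["MK", "MK"])
    with pytest.raises(InputError):
        interface_conservation(aln, [5], {"a": True, "b": False})
    with pytest.raises(InputError):
        interface_conservation(aln, [0], {"a": True})
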