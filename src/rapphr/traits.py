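"""Gain/loss evolution of Rap target regulation (Spo0A / ComA pathways).

Experimentally measured effects (sporulation efficiency for the Spo0A
pathway, srfA-reporter expression for the ComA pathway) are binarized by
configurable thresholds into a taxa x traits matrix; equal-cost maximum
parsimony (Sankoff dynamic programming, unit gain and loss costs) then
reconstructs ancestral states and per-branch gain/loss events on a given
receptor tree, optionally with the root constrained — the family's
ancestral state is Spo0A-pathway control. Interface-residue conservation
summaries use per-column Shannon entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import ConfigError, InputError
from .phylo import ProteinAlignment

# ---------------------------------------------------------------------------
# binarization


@dataclass
class BinarizationThresholds:
    """Cutoffs separating repressing from non-repressing phenotypes.

    ``direction`` per trait states on which side of the cutoff a measurement
    indicates repression ("below" for both defaults: a Rap that represses
    the Spo0A pathway lowers sporulation efficiency; one that represses the
    ComA pathway lowers srfA reporter expression). Values exactly at a
    cutoff are scored as not repressing.
    """

    spo0a_cutoff: float
    coma_cutoff: float
    spo0a_direction: str = "below"
    coma_direction: str = "below"

    def __post_init__(self):
        if self.spo0a_cutoff <= 0 or self.coma_cutoff <= 0:
            raise ConfigError("cutoffs must be positive")
        for d in (self.spo0a_direction, self.coma_direction):
            if d not in ("below", "above"):
                raise ConfigError("direction must be 'below' or 'above'")


def _binarize(value: float, cutoff: float, direction: str):
    if pd.isna(value):
        return pd.NA
    if direction == "below":
        return 1 if value < cutoff else 0
    return 1 if value > cutoff else 0


def binarize_targets(measurements: pd.DataFrame,
                     thresholds: BinarizationThresholds) -> pd.DataFrame:
    """Taxa x {represses_spo0a, represses_coma} binary matrix.

    ``measurements`` must carry columns ``sporulation_efficiency`` and
    ``reporter_expression`` indexed by taxon. Missing measurements yield
    missing trait cells, which the parsimony step treats as unconstrained.
    """
    need = {"sporulation_efficiency", "reporter_expression"}
    if need - set(measurements.columns):
        raise InputError(f"measurements need columns {sorted(need)}")
    out = pd.DataFrame(index=measurements.index)
    out["represses_spo0a"] = [
        _binarize(v, thresholds.spo0a_cutoff, thresholds.spo0a_direction)
        for v in measurements["sporulation_efficiency"]
    ]
    out["represses_coma"] = [
        _binarize(v, thresholds.coma_cutoff, thresholds.coma_direction)
        for v in measurements["reporter_expression"]
    ]
    return out


# ---------------------------------------------------------------------------
# Sankoff parsimony


@dataclass
class GainLossResult:
    trait: str
    ancestral_states: dict[str, int]      # node name -> state (tips included)
    events: list[tuple[str, str]]         # (child node name, "gain" | "loss")
    total_events: int
    root_state: int
    ambiguous_nodes: list[str] = field(default_factory=list)

    def gains(self) -> list[str]:
        return [n for n, e in self.events if e == "gain"]

    def losses(self) -> list[str]:
        return [n for n, e in self.events if e == "loss"]


def parsimony_gainloss(tree: TreeNode, tip_states: dict[str, int | None],
                       root_state: int | None = None,
                       resolve: str = "delayed") -> GainLossResult:
    """Equal-cost gain/loss parsimony for one binary trait.

    Sankoff dynamic programming with unit costs; ``root_state`` of 0/1
    constrains the root (None leaves it free). Tips mapped to None are
    unconstrained. Among equally parsimonious child states, ``delayed``
    resolution keeps the parent's state (transformations pushed tipward),
    ``accelerated`` prefers the change. Ties are recorded in
    ``ambiguous_nodes``.
    """
    if resolve not in ("delayed", "accelerated"):
        raise ConfigError("resolve must be 'delayed' or 'accelerated'")
    tips = {t.name for t in tree.tips()}
    missing = set(k for k, v in tip_states.items() if v is not None) - tips
    if missing:
        raise InputError(f"taxa absent from tree: {sorted(missing)[:5]}")
    constrained = [t for t in tips if tip_states.get(t) is not None]
    if len(constrained) < 2:
        raise InputError("need binary states for at least two taxa")

    INF = float("inf")
    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            s = tip_states.get(node.name)
            if s is None:
                cost[id(node)] = [0.0, 0.0]
            elif s in (0, 1):
                cost[id(node)] = [INF, INF]
                cost[id(node)][s] = 0.0
            else:
                raise InputError(f"state of {node.name!r} must be 0, 1 or None")
        else:
            c = [0.0, 0.0]
            for child in node.children:
                cc = cost[id(child)]
                for s in (0, 1):
                    c[s] += min(cc[0] + (s != 0), cc[1] + (s != 1))
            cost[id(node)] = c

    root_cost = cost[id(tree)]
    if root_state is None:
        chosen_root = int(root_cost[1] < root_cost[0])
        root_ambiguous = root_cost[0] == root_cost[1]
    else:
        if root_state not in (0, 1):
            raise ConfigError("root_state must be 0, 1 or None")
        chosen_root = root_state
        root_ambiguous = False
    total = root_cost[chosen_root]
    if not math.isfinite(total):
        raise InputError("root constraint incompatible with tip states")

    states: dict[str, int] = {}
    events: list[tuple[str, str]] = []
    ambiguous: list[str] = ["<root>"] if root_ambiguous else []
    assign: dict[int, int] = {id(tree): chosen_root}
    for node in tree.preorder():
        s = assign[id(node)]
        states[node.name if node.name is not None else "<root>"] = s
        for child in node.children:
            cc = cost[id(child)]
            opts = [cc[0] + (s != 0), cc[1] + (s != 1)]
            best = min(opts)
            optimal = [t for t in (0, 1) if opts[t] == best]
            if len(optimal) == 2:
                ambiguous.append(child.name or "<unnamed>")
                t = s if resolve == "delayed" else 1 - s
            else:
                t = optimal[0]
            assign[id(child)] = t
            if t != s:
                events.append((child.name or "<unnamed>", "gain" if t == 1 else "loss"))
    return GainLossResult(trait="", ancestral_states=states, events=events,
                          total_events=int(total), root_state=chosen_root,
                          ambiguous_nodes=ambiguous)


def parsimony_gainloss_matrix(tree: TreeNode, trait_matrix: pd.DataFrame,
                              root_states: dict[str, int | None] | None = None,
                              resolve: str = "delayed",
                              ) -> dict[str, GainLossResult]:
    """Run gain/loss parsimony for every trait column of a binary matrix."""
    results = {}
    for trait in trait_matrix.columns:
        col = trait_matrix[trait]
        tip_states = {taxon: (None if pd.isna(v) else int(v))
                      for taxon, v in col.items()}
        rs = (root_states or {}).get(trait)
        res = parsimony_gainloss(tree, tip_states, root_state=rs, resolve=resolve)
        res.trait = str(trait)
        results[str(trait)] = res
    return results


def count_independent_gains(result: GainLossResult) -> int:
    """Number of branches on which the trait was independently gained."""
    return len(result.gains())


def assignment_cost(tree: TreeNode, states: dict[str, int]) -> int:
    """Number of state changes implied by a full node-state assignment;
    oracle-style helper for verifying parsimony outputs."""
    changes = 0
    for node in tree.preorder(include_self=False):
        parent_name = node.parent.name if node.parent.name is not None else "<root>"
        name = node.name if node.name is not None else "<root>"
        changes += states[parent_name] != states[name]
    return changes


def annotate_tree_with_events(tree: TreeNode,
                              results: dict[str, GainLossResult]) -> TreeNode:
    """Copy of the tree with branch event tags appended to node names,
    e.g. ``n3[+represses_coma]`` for a gain along the branch above n3."""
    out = tree.copy()
    tags: dict[str, list[str]] = {}
    for trait, res in results.items():
        for node_name, event in res.events:
            sign = "+" if event == "gain" else "-"
            tags.setdefault(node_name, []).append(f"{sign}{trait}")
    for node in out.traverse():
        if node.name in tags:
            node.name = f"{node.name}[{','.join(tags[node.name])}]"
    return out


# ---------------------------------------------------------------------------
# interface conservation


@dataclass
class ConservationProfile:
    positions: list[int]                   # alignment columns (0-based)
    scores: list[float]                    # 1 - normalized Shannon entropy; NaN if all-gap
    target_consensus: str                  # '/' joins tied modal residues
    offtarget_consensus: str


def column_conservation(column: list[str]) -> float:
    """1 - H/ln(20) over the non-gap residues of one column (NaN if all-gap)."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return float("nan")
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(1.0 - h / np.log(20.0))


def _group_consensus(rows: list[str], pos: int) -> str:
    col = [r[pos] for r in rows if r[pos] != "-"]
    if not col:
        return "-"
    vals, counts = np.unique(col, return_counts=True)
    top = counts.max()
    return "/".join(sorted(v for v, c in zip(vals, counts) if c == top))


def interface_conservation(alignment: ProteinAlignment, positions: list[int],
                           target_labels: dict[str, bool],
                           ) -> ConservationProfile:
    """Conservation scores and Target / OFF-Target consensus at the residues
    inferred to contact a downstream target (e.g. Spo0F or ComA).

    ``target_labels`` maps every sequence id to True (affects the target)
    or False; the two groups get separate consensus strings at the given
    alignment columns.
    """
    missing = set(alignment.ids) - set(target_labels)
    if missing:
        raise InputError(f"unlabeled sequences: {sorted(missing)[:5]}")
    bad = [p for p in positions if not 0 <= p < alignment.n_columns]
    if bad:
        raise InputError(f"positions outside alignment: {bad[:5]}")
    target_rows = [r for i, r in zip(alignment.ids, alignment.rows) if target_labels[i]]
    off_rows = [r for i, r in zip(alignment.ids, alignment.rows) if not target_labels[i]]
    scores = [column_conservation([r[p] for r in alignment.rows]) for p in positions]
    t_cons = " ".join(_group_consensus(target_rows, p) for p in positions) \
        if target_rows else ""
    o_cons = " ".join(_group_consensus(off_rows, p) for p in positions) \
        if off_rows else ""
    return ConservationProfile(list(positions), scores, t_cons, o_cons)
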