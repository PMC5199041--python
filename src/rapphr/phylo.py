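"""Protein alignment, neighbor-joining trees, peptide clusters, diversity.

Maximum-likelihood tree inference is deliberately not reimplemented:
externally computed trees are imported as newick, and a self-contained
neighbor-joining tree (p-distance with pairwise deletion of gap sites,
nonparametric bootstrap supports) is the default. All downstream analyses
are tree-agnostic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._util import InputError, NewickParseError, substream


# ---------------------------------------------------------------------------
# alignment


@dataclass
class ProteinAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence ids in alignment")
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("alignment rows must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)


def align_proteins(sequences: dict[str, str]) -> ProteinAlignment:
    """Progressive multiple alignment (BLOSUM62, affine gaps) preserving
    input row order; externally computed alignments can be imported with
    :meth:`ProteinAlignment.from_fasta` instead."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    if len(sequences) < 2:
        raise InputError("need at least two sequences to align")
    ids = list(sequences)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids")
    seqs = [bseq.ProteinSequence(sequences[i]) for i in ids]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alignment, _, _, _ = balign.align_multiple(seqs, matrix, gap_penalty=(-10, -1))
    rows = alignment.get_gapped_sequences()  # already in input order
    return ProteinAlignment(ids, [str(r) for r in rows])


def p_distance_matrix(alignment: ProteinAlignment) -> DistanceMatrix:
    """Pairwise p-distance with gap sites deleted pairwise."""
    arr = np.array([list(r) for r in alignment.rows])
    n = len(alignment)
    d = np.zeros((n, n))
    gaps = arr == "-"
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(gaps[i] | gaps[j])
            m = int(mask.sum())
            d[i, j] = d[j, i] = float((arr[i, mask] != arr[j, mask]).mean()) if m else 1.0
    return DistanceMatrix(d, alignment.ids)


# ---------------------------------------------------------------------------
# neighbor joining with bootstrap


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(taxa) - 1:
            comp = taxa - clade
            out.add(min(clade, comp, key=lambda s: (len(s), sorted(s))))
    return out


def _nj_from_distance(dm: DistanceMatrix) -> TreeNode:
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_nj_tree(alignment: ProteinAlignment, n_bootstrap: int = 100,
                  seed: int = 0) -> TreeNode:
    """Neighbor-joining tree with bootstrap supports on internal nodes.

    Supports (0-100, stored as internal node names) count the replicate
    trees, built from column resamples of the alignment, that contain the
    same bipartition. Deterministic for a fixed seed.
    """
    if len(alignment) < 3:
        raise InputError("need at least three sequences for a tree")
    dm = p_distance_matrix(alignment)
    tree = _nj_from_distance(dm)
    if n_bootstrap > 0:
        taxa = frozenset(alignment.ids)
        rng = substream(seed, "nj-bootstrap")
        counts: dict[frozenset[str], int] = {}
        ncol = alignment.n_columns
        for _ in range(n_bootstrap):
            cols = rng.integers(0, ncol, size=ncol)
            rows = ["".join(r[c] for c in cols) for r in alignment.rows]
            rep = _nj_from_distance(p_distance_matrix(ProteinAlignment(alignment.ids, rows)))
            for bp in _bipartitions(rep, taxa):
                counts[bp] = counts.get(bp, 0) + 1
        for node in tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if 1 < len(clade) < len(taxa) - 1:
                comp = taxa - clade
                bp = min(clade, comp, key=lambda s: (len(s), sorted(s)))
                node.name = str(round(100 * counts.get(bp, 0) / n_bootstrap))
    return tree


# ---------------------------------------------------------------------------
# newick IO


def read_newick(text: str) -> TreeNode:
    """Parse newick text (node labels may carry bootstrap supports).

    Raises :class:`NewickParseError` with the character position of the
    first unbalanced parenthesis when the text is malformed.
    """
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}", pos)
    if depth != 0:
        pos = text.rfind("(")
        raise NewickParseError(f"unclosed '(' at position {pos}", pos)
    try:
        return TreeNode.read(io.StringIO(text))
    except Exception as exc:  # malformed in some other way
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# monophyletic peptide clusters


@dataclass
class PeptideCluster:
    cluster_id: str
    members: list[str]
    peptide: str | None               # None for orphan clusters
    mean_depth: float                 # mean distance from cluster base to members


def _clade_depths(node: TreeNode) -> list[float]:
    out = []
    for tip in node.tips(include_self=True):
        d = 0.0
        cur = tip
        while cur is not node:
            d += cur.length or 0.0
            cur = cur.parent
        out.append(d)
    return out


def peptide_monophyletic_clusters(tree: TreeNode,
                                  peptide_map: dict[str, str | None],
                                  orphan_merge_distance: float | None = None,
                                  ) -> list[PeptideCluster]:
    """Partition leaves into maximal monophyletic same-peptide groups.

    Every maximal clade whose leaves all encode the same peptide string is
    one cluster; every leaf belongs to exactly one cluster. Leaves with no
    peptide (orphans) form singleton clusters by default; when
    ``orphan_merge_distance`` is set, monophyletic groups of orphan leaves
    whose maximal within-clade tip depth sum is within the threshold are
    merged into one orphan cluster.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in peptide_map]
    if missing:
        raise InputError(f"unmapped leaves: {missing[:5]}")

    def label(leaf: str):
        pep = peptide_map[leaf]
        if pep:
            return ("pep", pep)
        if orphan_merge_distance is not None:
            return ("orphan",)
        return ("orphan", leaf)

    pure: dict[int, tuple | None] = {}
    for node in tree.postorder():
        if node.is_tip():
            pure[id(node)] = label(node.name)
        else:
            child_labels = {pure[id(c)] for c in node.children}
            lab = child_labels.pop() if len(child_labels) == 1 else None
            pure[id(node)] = lab

    clusters: list[PeptideCluster] = []

    def emit(node: TreeNode, lab: tuple) -> None:
        if lab[0] == "orphan" and orphan_merge_distance is not None and not node.is_tip():
            depths = _clade_depths(node)
            if max(depths) * 2 > orphan_merge_distance:
                for c in node.children:
                    emit(c, pure[id(c)])
                return
        members = sorted(t.name for t in node.tips(include_self=True))
        peptide = lab[1] if lab[0] == "pep" else None
        depth = float(np.mean(_clade_depths(node)))
        clusters.append(PeptideCluster(f"c{len(clusters) + 1}", members, peptide, depth))

    def walk(node: TreeNode) -> None:
        lab = pure[id(node)]
        if lab is not None:
            emit(node, lab)
            return
        for c in node.children:
            walk(c)

    walk(tree)
    clusters.sort(key=lambda c: c.members[0])
    for i, c in enumerate(clusters):
        c.cluster_id = f"c{i + 1}"
    return clusters


# ---------------------------------------------------------------------------
# phylogenetic diversity


def phylo_diversity_fraction(tree: TreeNode, leaf_subset) -> float:
    """Faith-style fraction of total branch length spanned by a leaf subset.

    Spanned length sums the branches on the union of root-to-leaf paths of
    the subset (each leaf's pendant branch always counts); the denominator
    is the same quantity for the full leaf set, so the full set maps to 1.0
    and the fraction is monotone under subset inclusion.
    """
    subset = set(leaf_subset)
    if not subset:
        raise InputError("leaf subset must be nonempty")
    leaves = {t.name for t in tree.tips()}
    extra = subset - leaves
    if extra:
        raise InputError(f"not leaves of the tree: {sorted(extra)[:5]}")

    spanned = 0.0
    total = 0.0
    below: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip():
            below[id(node)] = 1 if node.name in subset else 0
        else:
            below[id(node)] = sum(below[id(c)] for c in node.children)
        if node.parent is not None:
            length = node.length or 0.0
            total += length
            if below[id(node)] > 0:
                spanned += length
    return spanned / total if total > 0 else 1.0
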