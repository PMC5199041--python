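"""Synthetic Bacillus-like genomes with planted Rap-Phr cassettes.

The generator emulates the statistical structure the downstream analyses
assume, with full ground truth:

* strains on a rooted species tree, species monophyletic by construction;
* per-species *core* cassette clusters, present in (nearly) every strain of
  the species at the genomic background GC;
* a pool of *mobile* cassette clusters gained and lost along branches by a
  two-state jump process, embedded in AT-shifted islands (GC depressed by a
  configurable delta, flanks included) at low per-species frequency;
* each cassette: a rap coding sequence translating to a >=300 aa receptor
  diverged from a per-cluster ancestor, followed on the same strand by zero
  (orphan clusters), one, or two phr open reading frames of 35-120 aa whose
  N-terminus is drawn from the secretion-signal PWM and whose C-terminal
  region carries 1-3 exact-or-diverged copies of the cluster autoinducer;
* binary regulatory trait histories (e.g. Spo0A / ComA repression) simulated
  as gain/loss events on the same tree, with a per-branch event log.

Every quantity is a pure function of (config, seed); re-running with the same
seed reproduces files byte for byte.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from ._util import ConfigError, substream
from .sequences import gc_fraction, reverse_complement, translate
from .signalpep import AMINO_ACIDS, DEFAULT_PWM, SignalPeptidePWM

_STOPS = ("TAA", "TAG", "TGA")
# contains an in-frame stop codon in every forward reading frame
FRAME_GUARD = "TTAATTAATTAA"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a *B. subtilis*-group-like population: four species,
    a mean of 11 cassettes per strain of which roughly 60% are core, three
    orphan core clusters per species (raps without a phr), and mobile
    cassettes at GC depressed by ``mobile_gc_delta`` below background.
    """

    n_strains: int = 20
    n_species: int = 4
    core_clusters_per_species: int = 7
    mobile_cluster_pool: int = 40
    mean_raps_per_strain: float = 11.0
    background_gc: float = 0.435
    mobile_gc_delta: float = 0.05
    repeat_copy_range: tuple[int, int] = (1, 3)
    repeat_mismatch_max: int = 2
    receptor_length_aa: int = 360
    propeptide_length_range: tuple[int, int] = (40, 60)
    seed: int = 0

    # secondary knobs (fixed study-condition details)
    n_orphan_clusters: int = 3          # orphan core clusters per species
    core_dropout: float = 0.05          # per-strain chance a core cluster is missing
    mobile_loss_rate: float = 1.0       # loss rate of the mobile two-state process
    n_duplicate_cases: int = 5          # same-cluster-twice-in-one-genome, non-orphan
    n_orphan_duplicate_cases: int = 3   # ditto for orphan clusters
    phr_duplication_prob: float = 0.03  # whole-phr-gene duplication per cassette
    hexa_fraction: float = 0.7          # hexapeptide (vs pentapeptide) autoinducers
    peptide_reuse_prob: float = 0.2     # distinct clusters sharing one autoinducer
    cluster_divergence: tuple[float, float] = (0.15, 0.35)
    within_cluster_divergence: float = 0.04
    phr_filler_divergence: float = 0.25
    n_background_genes: int = 25
    background_gene_length_aa: tuple[int, int] = (150, 400)
    island_flank: int = 500

    def validate(self) -> None:
        if self.n_species < 1 or self.n_strains < self.n_species:
            raise ConfigError("need n_strains >= n_species >= 1")
        lo, hi = self.propeptide_length_range
        if not (35 <= lo <= hi <= 120):
            raise ConfigError("propeptide_length_range must lie within [35, 120]")
        if not 0.0 < self.background_gc < 1.0:
            raise ConfigError("background_gc must be in (0, 1)")
        if self.mobile_gc_delta < 0:
            raise ConfigError("mobile_gc_delta must be >= 0")
        if self.receptor_length_aa < 300:
            raise ConfigError("receptor_length_aa must be >= 300")
        c_lo, c_hi = self.repeat_copy_range
        if not 1 <= c_lo <= c_hi:
            raise ConfigError("repeat_copy_range must be a nonempty positive interval")
        if self.mean_raps_per_strain <= self.core_clusters_per_species:
            raise ConfigError(
                "mean_raps_per_strain must exceed core_clusters_per_species "
                "(mobile cassettes make up the difference)"
            )
        pi = self.mobile_stationary_freq()
        if not 0.0 < pi < 0.9:
            raise ConfigError("mobile pool too small for the requested mean cassette count")

    def mobile_stationary_freq(self) -> float:
        """Stationary presence probability of each mobile cluster."""
        mobile_mean = self.mean_raps_per_strain - self.core_clusters_per_species
        return mobile_mean / self.mobile_cluster_pool


def cereus_profile(seed: int = 0) -> SimulationConfig:
    """A *B. cereus*-group-like profile: fewer cassettes per strain and
    essentially no orphan raps (almost every rap keeps its phr)."""
    return SimulationConfig(
        n_strains=20,
        n_species=4,
        core_clusters_per_species=4,
        mobile_cluster_pool=30,
        mean_raps_per_strain=6.0,
        background_gc=0.35,
        n_orphan_clusters=0,
        n_duplicate_cases=0,
        n_orphan_duplicate_cases=0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# strain tree


def _random_binary(items: list[str], rng: np.random.Generator,
                   length_range: tuple[float, float]) -> TreeNode:
    lo, hi = length_range
    if len(items) == 1:
        return TreeNode(name=items[0], length=float(rng.uniform(lo, hi)))
    order = list(rng.permutation(len(items)))
    k = int(rng.integers(1, len(items)))
    left = [items[i] for i in order[:k]]
    right = [items[i] for i in order[k:]]
    node = TreeNode(length=float(rng.uniform(lo, hi)))
    node.extend([_random_binary(left, rng, length_range),
                 _random_binary(right, rng, length_range)])
    return node


def simulate_strain_tree(n_strains: int, n_species: int, seed: int) -> TreeNode:
    """Rooted binary strain tree with every species' tips monophyletic.

    Strains are split as evenly as possible across species; interspecies
    branches are long relative to the shallow within-species subtrees.
    Internal nodes are named ``n0, n1, ...`` in preorder so that branches can
    be addressed by their child node in event logs.
    """
    if n_species < 1 or n_strains < n_species:
        raise ConfigError("need n_strains >= n_species >= 1")
    rng = substream(seed, "strain-tree")
    sizes = [n_strains // n_species + (1 if i < n_strains % n_species else 0)
             for i in range(n_species)]
    species = [f"sp{i + 1}" for i in range(n_species)]
    subtrees = []
    for sp, size in zip(species, sizes):
        tips = [f"{sp}_s{i + 1}" for i in range(size)]
        sub = _random_binary(tips, rng, (0.01, 0.05))
        sub.length = float(rng.uniform(0.5, 1.5))
        subtrees.append(sub)
    while len(subtrees) > 1:
        b = subtrees.pop(int(rng.integers(len(subtrees))))
        a = subtrees.pop(int(rng.integers(len(subtrees))))
        node = TreeNode(length=float(rng.uniform(0.5, 1.5)))
        node.extend([a, b])
        subtrees = [node] + subtrees
    root = subtrees[0]
    if root.children:
        root.length = None
    else:  # single strain: hang the tip under an explicit root
        tip = root
        root = TreeNode()
        root.append(tip)
    i = 0
    for node in root.preorder():
        if not node.is_tip() and node.name is None:
            node.name = f"n{i}"
            i += 1
    return root


def species_of(strain: str) -> str:
    return strain.split("_")[0]


# ---------------------------------------------------------------------------
# protein / DNA synthesis helpers


def _random_protein(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ("M" + body[1:]) if start_met else body


def mutate_protein(protein: str, rate: float, rng: np.random.Generator,
                   protect_first: bool = True) -> str:
    """Substitute a ``rate`` fraction of positions with a different residue."""
    n = len(protein)
    k = int(round(rate * n))
    start = 1 if protect_first else 0
    if k == 0 or n <= start:
        return protein
    positions = rng.choice(np.arange(start, n), size=min(k, n - start), replace=False)
    chars = list(protein)
    for pos in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _codon_weights(gc: float) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon probabilities biased toward a GC target."""
    from .sequences import CODON_TABLE

    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    out = {}
    for aa, codons in by_aa.items():
        codons = sorted(codons)
        w = np.array([
            np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c]) for c in codons
        ])
        out[aa] = w / w.sum()
    # keep codon lists alongside
    out["_codons"] = {aa: sorted(c) for aa, c in by_aa.items()}  # type: ignore[assignment]
    return out


_WEIGHT_CACHE: dict[float, dict] = {}


def _codon_gc(c: str) -> int:
    return sum(1 for b in c if b in "GC")


def encode_protein(protein: str, gc: float, rng: np.random.Generator,
                   stop: bool = True, start_codon: bool = True,
                   tol: float = 0.01) -> str:
    """Reverse-translate with synonymous codons steered to a GC target.

    Codons are first sampled with a GC-biased weighting, then a randomized
    greedy repair pass swaps synonymous codons until the coding sequence GC
    is within ``tol`` of the target (or no swap can move it closer; amino
    acid composition bounds the reachable range). The first residue uses its
    canonical initiator codon (ATG/GTG/TTG for M/V/L) so planted ORFs always
    begin with an accepted start.
    """
    key = round(gc, 4)
    if key not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[key] = _codon_weights(key)
    weights = _WEIGHT_CACHE[key]
    codon_lists = weights["_codons"]
    parts = []
    for i, aa in enumerate(protein):
        if i == 0 and start_codon:
            parts.append({"M": "ATG", "V": "GTG", "L": "TTG"}.get(aa, codon_lists[aa][0]))
            continue
        codons = codon_lists[aa]
        parts.append(codons[int(rng.choice(len(codons), p=weights[aa]))])
    if stop:
        stops = np.array([0.6, 0.2, 0.2]) if gc < 0.5 else np.array([0.34, 0.33, 0.33])
        parts.append(_STOPS[int(rng.choice(3, p=stops))])
    # greedy repair toward the target, first codon kept fixed
    total = 3 * len(parts)
    gc_count = sum(_codon_gc(c) for c in parts)
    lo = max(1, 1 if start_codon else 0)
    order = list(rng.permutation(np.arange(lo, len(parts) - (1 if stop else 0))))
    for idx in order:
        frac = gc_count / total
        if abs(frac - gc) <= tol:
            break
        aa = protein[idx]
        codons = codon_lists[aa]
        cur = parts[idx]
        if frac > gc:
            alt = min(codons, key=_codon_gc)
        else:
            alt = max(codons, key=_codon_gc)
        if _codon_gc(alt) != _codon_gc(cur):
            gc_count += _codon_gc(alt) - _codon_gc(cur)
            parts[idx] = alt
    return "".join(parts)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def _gc_capped_cds(protein: str, target: float, cap: float | None,
                   rng: np.random.Generator) -> str:
    """Encode a protein, re-drawing at lower GC targets until under ``cap``."""
    gc = target
    for _ in range(12):
        cds = encode_protein(protein, gc, rng)
        if cap is None or gc_fraction(cds) <= cap:
            return cds
        gc = max(0.05, gc - 0.015)
    return cds


# ---------------------------------------------------------------------------
# cluster specifications and cassette synthesis


@dataclass
class ClusterSpec:
    """Everything needed to synthesize one cassette of a cluster."""

    cluster_id: str
    ancestor_protein: str
    autoinducer: str | None          # None => orphan cluster
    kind: str                        # "core" | "mobile"
    signal_template: str
    filler_template: str
    divergence: float = 0.04
    filler_divergence: float = 0.25


@dataclass
class CassettePlan:
    """Per-cassette realization choices on top of a :class:`ClusterSpec`."""

    repeat_copies: int = 1
    copy_mismatches: tuple[int, ...] = ()   # mismatches of copies 2..k vs the motif
    prepeptide_length: int = 45
    gc_target: float = 0.435
    gc_cap: float | None = None
    n_phr_genes: int = 1                    # 2 => whole-gene duplication
    strand: int = 1


@dataclass
class CassetteSeqs:
    rap_cds: str
    rap_protein: str
    phr: list[tuple[int, str, str]]         # (offset from rap stop end, cds, protein)
    autoinducer: str | None
    repeat_copies: int
    copy_mismatches: tuple[int, ...]


def _mutate_motif(motif: str, n_mismatch: int, rng: np.random.Generator) -> str:
    return mutate_protein(motif, n_mismatch / len(motif) if motif else 0.0, rng,
                          protect_first=False) if n_mismatch else motif


def _build_prepeptide(spec: ClusterSpec, plan: CassettePlan,
                      rng: np.random.Generator) -> str:
    """Signal region + diverged filler + C-terminal autoinducer repeats.

    The C-terminal-most copy is always the exact cluster motif; additional
    copies (leftward) carry the planned number of mismatches, separated by
    single filler residues so copies never overlap.
    """
    motif = spec.autoinducer or ""
    copies = plan.repeat_copies
    sig = mutate_protein(spec.signal_template, 0.05, rng, protect_first=True)
    repeat_block = motif
    for m in plan.copy_mismatches[: copies - 1]:
        filler_sep = AMINO_ACIDS[int(rng.integers(20))]
        repeat_block = _mutate_motif(motif, m, rng) + filler_sep + repeat_block
    need = len(sig) + len(repeat_block)
    if need > plan.prepeptide_length:
        raise ConfigError(
            f"repeat plan needs {need} aa but prepeptide length is {plan.prepeptide_length}"
        )
    n_fill = plan.prepeptide_length - need
    filler = spec.filler_template[:n_fill]
    if len(filler) < n_fill:
        filler = filler + _random_protein(n_fill - len(filler), rng, start_met=False)
    filler = mutate_protein(filler, spec.filler_divergence, rng, protect_first=False)
    return sig + filler + repeat_block


def synthesize_cassette(spec: ClusterSpec, plan: CassettePlan,
                        rng: np.random.Generator) -> CassetteSeqs:
    """Realize one rap (+ optional phr) locus as coding DNA plus truth entry."""
    if spec.autoinducer is not None:
        w = len(spec.autoinducer)
        min_need = len(spec.signal_template) + plan.repeat_copies * w + (plan.repeat_copies - 1)
        if min_need > 120:
            raise ConfigError("repeat plan cannot fit any valid propeptide length")
    rap_protein = mutate_protein(spec.ancestor_protein, spec.divergence, rng)
    rap_cds = _gc_capped_cds(rap_protein, plan.gc_target, plan.gc_cap, rng)
    phr: list[tuple[int, str, str]] = []
    if spec.autoinducer is not None:
        offset = 0
        for _ in range(plan.n_phr_genes):
            prot = _build_prepeptide(spec, plan, rng)
            cds = _gc_capped_cds(prot, plan.gc_target, plan.gc_cap, rng)
            spacer = int(rng.integers(20, 60))
            offset += spacer + len(FRAME_GUARD)
            phr.append((offset, cds, prot))
            offset += len(cds)
    return CassetteSeqs(rap_cds, rap_protein, phr, spec.autoinducer,
                        plan.repeat_copies, plan.copy_mismatches)


# ---------------------------------------------------------------------------
# repertoire simulation


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    config: SimulationConfig
    tree: TreeNode
    strains: pd.DataFrame                 # strain, species, background_gc
    cassettes: pd.DataFrame               # one row per planted cassette
    events: pd.DataFrame                  # cluster, node, event (gain|loss)
    root_states: dict[str, int]
    clusters: dict[str, ClusterSpec]
    contigs: dict[str, str] = field(default_factory=dict)  # filled by emit_genomes

    def presence_matrix(self) -> pd.DataFrame:
        """Binary strains x clusters matrix from the cassette table."""
        m = pd.crosstab(self.cassettes["strain"], self.cassettes["cluster"])
        m = (m > 0).astype(int)
        return m.reindex(index=list(self.strains["strain"]), fill_value=0)


def _jump_process(state: int, t: float, gain: float, loss: float,
                  rng: np.random.Generator) -> tuple[int, int]:
    """Two-state process over time ``t``; returns (final state, n jumps)."""
    jumps = 0
    remaining = t
    while True:
        rate = gain if state == 0 else loss
        if rate <= 0:
            break
        dt = rng.exponential(1.0 / rate)
        if dt >= remaining:
            break
        remaining -= dt
        state = 1 - state
        jumps += 1
    return state, jumps


def simulate_repertoires(tree: TreeNode, config: SimulationConfig) -> SyntheticTruth:
    """Assign cassette repertoires (and their event history) to every strain.

    Core clusters are gained once on their species' stem branch and lost only
    by rare per-strain dropout (capped so each core cluster stays in >=90% of
    its species' strains). Mobile clusters follow a reversible two-state jump
    process along branches with stationary presence frequency
    ``config.mobile_stationary_freq()``; every state flip is logged so the tip
    pattern can be replayed exactly from the root states and the event log.
    """
    config.validate()
    rng = substream(config.seed, "repertoires")
    tips = [t.name for t in tree.tips()]
    strains = pd.DataFrame({
        "strain": tips,
        "species": [species_of(t) for t in tips],
        "background_gc": config.background_gc,
    })
    species = sorted(strains["species"].unique())

    # --- cluster pool with ancestors and autoinducers
    seq_rng = substream(config.seed, "cluster-seqs")
    family_ancestor = _random_protein(config.receptor_length_aa, seq_rng)
    clusters: dict[str, ClusterSpec] = {}
    core_peps_by_species: dict[str, list[str]] = {}

    def _new_peptide(species: str | None) -> str:
        # Core clusters may share an autoinducer with another species' core
        # (variants fixed across related species); two same-peptide systems
        # never co-occur within a genome, preserving orthogonality.
        if species is not None:
            pool = [p for sp2, peps in core_peps_by_species.items()
                    if sp2 != species for p in peps
                    if p not in core_peps_by_species.get(species, [])]
            if pool and seq_rng.random() < config.peptide_reuse_prob:
                pep = pool[int(seq_rng.integers(len(pool)))]
                core_peps_by_species.setdefault(species, []).append(pep)
                return pep
        w = 6 if seq_rng.random() < config.hexa_fraction else 5
        pep = _random_protein(w, seq_rng, start_met=False)
        if species is not None:
            core_peps_by_species.setdefault(species, []).append(pep)
        return pep

    def _new_cluster(cid: str, kind: str, orphan: bool,
                     species: str | None = None) -> ClusterSpec:
        lo, hi = config.cluster_divergence
        anc = mutate_protein(family_ancestor, float(seq_rng.uniform(lo, hi)), seq_rng)
        spec = ClusterSpec(
            cluster_id=cid,
            ancestor_protein=anc,
            autoinducer=None if orphan else _new_peptide(species),
            kind=kind,
            signal_template=DEFAULT_PWM.sample(seq_rng),
            filler_template=_random_protein(120, seq_rng, start_met=False),
            divergence=config.within_cluster_divergence,
            filler_divergence=config.phr_filler_divergence,
        )
        clusters[cid] = spec
        return spec

    core_by_species: dict[str, list[str]] = {}
    for sp in species:
        ids = []
        for j in range(config.core_clusters_per_species):
            cid = f"{sp}_core{j + 1}"
            orphan = j < config.n_orphan_clusters
            _new_cluster(cid, "core", orphan, species=sp)
            ids.append(cid)
        core_by_species[sp] = ids
    mobile_ids = []
    for j in range(config.mobile_cluster_pool):
        cid = f"mob{j + 1}"
        _new_cluster(cid, "mobile", orphan=False)
        mobile_ids.append(cid)

    # --- presence + event log
    events: list[dict] = []
    root_states: dict[str, int] = {}
    presence: dict[str, set[str]] = {t: set() for t in tips}

    for sp in species:
        sp_tips = [t for t in tips if species_of(t) == sp]
        if len(sp_tips) == 1:
            stem = tree.find(sp_tips[0])
        else:
            stem = tree.lca(sp_tips)
        stem_name = stem.name
        cap = len(sp_tips) // 10  # keep core frequency >= 90% by construction
        for cid in core_by_species[sp]:
            root_states[cid] = 0
            events.append({"cluster": cid, "node": stem_name, "event": "gain"})
            n_drop = min(int(rng.binomial(len(sp_tips), config.core_dropout)), cap)
            dropped = set(rng.choice(sp_tips, size=n_drop, replace=False)) if n_drop else set()
            for t in sp_tips:
                if t in dropped:
                    events.append({"cluster": cid, "node": t, "event": "loss"})
                else:
                    presence[t].add(cid)

    pi = config.mobile_stationary_freq()
    loss = config.mobile_loss_rate
    gain = loss * pi / (1.0 - pi)
    for cid in mobile_ids:
        root_state = int(rng.random() < pi)
        root_states[cid] = root_state
        state_at: dict[int, int] = {id(tree): root_state}
        for node in tree.preorder(include_self=False):
            s = state_at[id(node.parent)]
            t = node.length or 0.0
            s2, jumps = _jump_process(s, t, gain, loss, rng)
            # log individual flips (parity equals s -> s2)
            cur = s
            for _ in range(jumps):
                cur = 1 - cur
                events.append({"cluster": cid, "node": node.name,
                               "event": "gain" if cur == 1 else "loss"})
            state_at[id(node)] = s2
            if node.is_tip() and s2 == 1:
                presence[node.name].add(cid)

    # --- duplicate-cluster-in-genome cases
    dup_counts: dict[tuple[str, str], int] = {}
    nonorph = [(t, c) for t in tips for c in sorted(presence[t])
               if clusters[c].autoinducer]
    orph = [(t, c) for t in tips for c in sorted(presence[t])
            if clusters[c].autoinducer is None]
    for pool, n_cases in ((nonorph, config.n_duplicate_cases),
                          (orph, config.n_orphan_duplicate_cases)):
        if pool and n_cases:
            idx = rng.choice(len(pool), size=min(n_cases, len(pool)), replace=False)
            for i in idx:
                dup_counts[pool[i]] = 2

    # --- per-cassette synthesis
    rows = []
    c_lo, c_hi = config.repeat_copy_range
    p_lo, p_hi = config.propeptide_length_range
    for t in tips:
        for cid in sorted(presence[t]):
            spec = clusters[cid]
            for copy_i in range(dup_counts.get((t, cid), 1)):
                if spec.autoinducer is None:
                    copies, mism, plen = 0, (), 0
                else:
                    w = len(spec.autoinducer)
                    feas_max = min(c_hi, max(1, (120 - len(spec.signal_template) + 1) // (w + 1)))
                    copies = int(rng.integers(c_lo, feas_max + 1))
                    mism = tuple(int(rng.integers(0, config.repeat_mismatch_max + 1))
                                 for _ in range(copies - 1))
                    min_len = max(p_lo, len(spec.signal_template) + copies * w + copies - 1)
                    plen = int(rng.integers(min_len, max(p_hi, min_len) + 1))
                if spec.kind == "mobile":
                    gc_target = config.background_gc - config.mobile_gc_delta - 0.02
                    gc_cap = config.background_gc - config.mobile_gc_delta
                else:
                    gc_target, gc_cap = config.background_gc, None
                n_phr = 2 if (spec.autoinducer is not None
                              and rng.random() < config.phr_duplication_prob) else 1
                plan = CassettePlan(
                    repeat_copies=copies, copy_mismatches=mism,
                    prepeptide_length=plen, gc_target=gc_target, gc_cap=gc_cap,
                    n_phr_genes=n_phr if spec.autoinducer else 0,
                    strand=1 if rng.random() < 0.5 else -1,
                )
                seqs = synthesize_cassette(spec, plan, rng)
                rows.append({
                    "strain": t, "species": species_of(t), "cluster": cid,
                    "kind": spec.kind, "orphan": spec.autoinducer is None,
                    "copy": copy_i + 1, "strand": plan.strand,
                    "rap_protein": seqs.rap_protein, "rap_cds": seqs.rap_cds,
                    "phr_offsets": ";".join(str(o) for o, _, _ in seqs.phr),
                    "phr_cds": ";".join(c for _, c, _ in seqs.phr),
                    "phr_proteins": ";".join(p for _, _, p in seqs.phr),
                    "autoinducer": spec.autoinducer or "",
                    "repeat_copies": seqs.repeat_copies,
                    "copy_mismatches": ";".join(str(m) for m in seqs.copy_mismatches),
                    "gc_target": gc_target,
                })
    cassettes = pd.DataFrame(rows)
    return SyntheticTruth(
        config=config, tree=tree, strains=strains, cassettes=cassettes,
        events=pd.DataFrame(events, columns=["cluster", "node", "event"]),
        root_states=root_states, clusters=clusters,
    )


def replay_events(truth: SyntheticTruth) -> pd.DataFrame:
    """Replay root states + event log down the tree; returns tip presence.

    Used as an internal consistency oracle: the replayed matrix must equal
    the presence matrix derived from the cassette table.
    """
    ev = truth.events
    by_branch: dict[str, list[tuple[str, str]]] = {}
    for _, r in ev.iterrows():
        by_branch.setdefault(r["node"], []).append((r["cluster"], r["event"]))
    tips = [t.name for t in truth.tree.tips()]
    all_clusters = sorted(truth.root_states)
    state: dict[int, dict[str, int]] = {id(truth.tree): dict(truth.root_states)}
    out = {}
    for node in truth.tree.preorder(include_self=False):
        s = dict(state[id(node.parent)])
        for cid, event in by_branch.get(node.name, []):
            s[cid] = 1 if event == "gain" else 0
        state[id(node)] = s
        if node.is_tip():
            out[node.name] = s
    mat = pd.DataFrame(
        {c: [out[t].get(c, 0) for t in tips] for c in all_clusters}, index=tips
    )
    mat.index.name = "strain"
    return mat


# ---------------------------------------------------------------------------
# genome emission


def _assemble_contig(strain: str, truth: SyntheticTruth,
                     rng: np.random.Generator) -> tuple[str, list[dict]]:
    cfg = truth.config
    g_lo, g_hi = cfg.background_gene_length_aa
    blocks: list[tuple[str, dict | None]] = []
    for b in range(cfg.n_background_genes):
        prot = _random_protein(int(rng.integers(g_lo, g_hi + 1)), rng)
        cds = encode_protein(prot, cfg.background_gc, rng)
        blocks.append((FRAME_GUARD + cds + FRAME_GUARD, None))
    cass = truth.cassettes
    sub = cass[cass["strain"] == strain]
    for idx, row in sub.iterrows():
        parts = [FRAME_GUARD, row["rap_cds"]]
        pos = len(FRAME_GUARD)
        rap_start, rap_end = pos, pos + len(row["rap_cds"])
        phr_intervals = []
        offsets = [int(x) for x in row["phr_offsets"].split(";")] if row["phr_offsets"] else []
        cds_list = row["phr_cds"].split(";") if row["phr_cds"] else []
        cursor = rap_end
        for off, cds in zip(offsets, cds_list):
            start = rap_end + off
            gap = start - cursor
            parts.append(random_dna(gap - len(FRAME_GUARD), row["gc_target"], rng)
                         + FRAME_GUARD)
            parts.append(cds)
            phr_intervals.append((start, start + len(cds)))
            cursor = start + len(cds)
        parts.append(FRAME_GUARD)
        cassette_seq = "".join(parts)
        meta = {
            "row_index": idx,
            "rap": (rap_start, rap_end),
            "phr": phr_intervals,
            "strand": int(row["strand"]),
            "mobile": row["kind"] == "mobile",
            "gc_target": float(row["gc_target"]),
        }
        if meta["strand"] == -1:
            L = len(cassette_seq)
            cassette_seq = reverse_complement(cassette_seq)
            meta["rap"] = (L - rap_end, L - rap_start)
            meta["phr"] = [(L - e, L - s) for s, e in phr_intervals]
        if meta["mobile"]:
            flank = cfg.island_flank
            pre = random_dna(flank, meta["gc_target"], rng)
            post = random_dna(flank, meta["gc_target"], rng)
            meta["rap"] = (meta["rap"][0] + flank, meta["rap"][1] + flank)
            meta["phr"] = [(s + flank, e + flank) for s, e in meta["phr"]]
            meta["island_len"] = len(cassette_seq) + 2 * flank
            cassette_seq = pre + cassette_seq + post
        blocks.append((cassette_seq, meta))
    order = rng.permutation(len(blocks))
    pieces = [random_dna(int(rng.integers(150, 400)), cfg.background_gc, rng)]
    pos = len(pieces[0])
    placed = []
    for i in order:
        seq, meta = blocks[i]
        if meta is not None:
            meta = dict(meta)
            meta["island"] = (pos, pos + meta.get("island_len", len(seq))) \
                if meta["mobile"] else None
            meta["rap"] = (meta["rap"][0] + pos, meta["rap"][1] + pos)
            meta["phr"] = [(s + pos, e + pos) for s, e in meta["phr"]]
            placed.append(meta)
        pieces.append(seq)
        pos += len(seq)
        spacer = random_dna(int(rng.integers(150, 400)), cfg.background_gc, rng)
        pieces.append(spacer)
        pos += len(spacer)
    return "".join(pieces), placed


def emit_genomes(truth: SyntheticTruth, out_dir: str | Path | None = None) -> SyntheticTruth:
    """Realize contigs for every strain and (optionally) write them to disk.

    Fills ``truth.contigs`` and adds genomic coordinates to the cassette
    table. With ``out_dir`` set, writes one FASTA per strain, the truth
    tables as TSV, the strain tree as newick, and a YAML echo of the config.
    """
    cfg = truth.config
    cass = truth.cassettes
    for col, default in (("contig", ""), ("rap_start", -1), ("rap_end", -1),
                         ("phr_starts", ""), ("phr_ends", ""),
                         ("island_start", -1), ("island_end", -1)):
        cass[col] = default
    for strain in truth.strains["strain"]:
        rng = substream(cfg.seed, f"genome:{strain}")
        contig, placed = _assemble_contig(strain, truth, rng)
        cname = f"{strain}_c1"
        truth.contigs[strain] = contig
        for meta in placed:
            i = meta["row_index"]
            cass.at[i, "contig"] = cname
            cass.at[i, "rap_start"], cass.at[i, "rap_end"] = meta["rap"]
            cass.at[i, "phr_starts"] = ";".join(str(s) for s, _ in meta["phr"])
            cass.at[i, "phr_ends"] = ";".join(str(e) for _, e in meta["phr"])
            if meta["island"]:
                cass.at[i, "island_start"], cass.at[i, "island_end"] = meta["island"]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gdir = out / "genomes"
        gdir.mkdir(exist_ok=True)
        for strain, contig in truth.contigs.items():
            with open(gdir / f"{strain}.fasta", "w") as fh:
                fh.write(f">{strain}_c1 species={species_of(strain)}\n")
                for i in range(0, len(contig), 70):
                    fh.write(contig[i : i + 70] + "\n")
        truth.strains.to_csv(out / "strains.tsv", sep="\t", index=False)
        cass.to_csv(out / "cassettes.tsv", sep="\t", index=False)
        truth.events.to_csv(out / "events.tsv", sep="\t", index=False)
        buf = io.StringIO()
        truth.tree.write(buf)
        (out / "strain_tree.nwk").write_text(buf.getvalue())
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return truth


def simulate_dataset(config: SimulationConfig,
                     out_dir: str | Path | None = None) -> SyntheticTruth:
    """Tree + repertoires + genomes in one call."""
    tree = simulate_strain_tree(config.n_strains, config.n_species, config.seed)
    truth = simulate_repertoires(tree, config)
    return emit_genomes(truth, out_dir)


# ---------------------------------------------------------------------------
# binary trait histories


def simulate_trait_history(tree: TreeNode, traits: dict[str, int],
                           gain_rate: float, loss_rate: float, seed: int,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve binary traits along a tree from fixed root states.

    ``traits`` maps trait name -> root state. Returns (tip state matrix,
    event log with one row per state flip, branch keyed by child node name).
    Default use mirrors ancestral Spo0A-pathway control: the first trait
    starts present, later-acquired regulation starts absent.
    """
    rng = substream(seed, "trait-history")
    tips = [t.name for t in tree.tips()]
    events = []
    states = {name: {} for name in traits}
    for name, root_state in traits.items():
        state_at = {id(tree): root_state}
        for node in tree.preorder(include_self=False):
            s = state_at[id(node.parent)]
            s2, jumps = _jump_process(s, node.length or 0.0, gain_rate, loss_rate, rng)
            cur = s
            for _ in range(jumps):
                cur = 1 - cur
                events.append({"trait": name, "node": node.name,
                               "event": "gain" if cur == 1 else "loss"})
            state_at[id(node)] = s2
            if node.is_tip():
                states[name][node.name] = s2
    matrix = pd.DataFrame({name: [states[name][t] for t in tips] for name in traits},
                          index=tips)
    matrix.index.name = "taxon"
    return matrix, pd.DataFrame(events, columns=["trait", "node", "event"])
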