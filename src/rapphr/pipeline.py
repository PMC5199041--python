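"""End-to-end analysis: mine -> call peptides -> tree/cluster -> mobility ->
population statistics, with an optional synthetic-data front end.

Every stage logs one line with input/output counts; a run writes all tables,
a fully resolved config echo, and a JSON summary whose bytes are a pure
function of the configuration (seed included).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import InputError
from .autoinducer import call_autoinducer
from .config import PipelineConfig
from .mining import (Cassette, GenomeRecord, PropeptideScanParams, SearchParams,
                     cassettes_to_table, mine_genome, write_gff3,
                     START_CODONS, STOP_CODONS)
from .mobility import (build_association_matrix, cluster_mobility_labels,
                       duplicate_cluster_cases, per_species_frequency,
                       rarefaction_curve, strain_gene_gc)
from .phylo import (ProteinAlignment, align_proteins, build_nj_tree,
                    peptide_monophyletic_clusters, write_newick)
from .sequences import gc_fraction, reverse_complement
from .simulate import SyntheticTruth, simulate_dataset, species_of

log = logging.getLogger("rapphr")


# ---------------------------------------------------------------------------
# helpers


def genome_orf_gcs(genome: GenomeRecord, min_len_nt: int = 300) -> list[float]:
    """GC of every complete ORF >= ``min_len_nt`` (both strands); the
    strain's gene-GC background when no annotation is available."""
    out = []
    for seq_fwd in genome.contigs.values():
        for seq in (seq_fwd, reverse_complement(seq_fwd)):
            L = len(seq)
            for frame in range(3):
                start = None
                pos = frame
                while pos + 3 <= L:
                    codon = seq[pos : pos + 3]
                    if codon in STOP_CODONS:
                        if start is not None and pos + 3 - start >= min_len_nt:
                            out.append(gc_fraction(seq[start : pos + 3]))
                        start = None
                    elif start is None and codon in START_CODONS:
                        start = pos
                    pos += 3
    return out


def seed_queries_from_truth(truth: SyntheticTruth, n: int = 4) -> dict[str, str]:
    """Pick ``n`` cluster ancestors spread over the pool as search seeds
    (the synthetic stand-in for a small panel of reference Rap proteins)."""
    ids = sorted(truth.clusters)
    picks = [ids[int(round(i * (len(ids) - 1) / max(1, n - 1)))] for i in range(n)]
    return {cid: truth.clusters[cid].ancestor_protein for cid in dict.fromkeys(picks)}


def cassette_id(c: Cassette) -> str:
    return f"{c.strain}|{c.receptor.contig}|{c.receptor.start}"


# ---------------------------------------------------------------------------
# result container


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: SyntheticTruth | None
    cassettes: list[Cassette]
    cassette_table: pd.DataFrame
    tree: TreeNode | None
    alignment: ProteinAlignment | None
    clusters: list
    peptide_map: dict[str, str | None]
    cluster_of: dict[str, str]
    mobility_table: pd.DataFrame
    cluster_labels: pd.DataFrame
    matrix: pd.DataFrame
    frequencies: pd.DataFrame
    rarefaction: object
    summary: dict = field(default_factory=dict)

    def summary_json(self) -> str:
        return json.dumps(self.summary, sort_keys=True, indent=2) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cassette_table.to_csv(out / "cassettes_mined.tsv", sep="\t", index=False)
        write_gff3(self.cassettes, out / "cassettes.gff3")
        if self.tree is not None:
            (out / "rap_tree.nwk").write_text(write_newick(self.tree) + "\n")
        if self.alignment is not None:
            self.alignment.to_fasta(out / "rap_alignment.fasta")
        pd.DataFrame(
            [{"cluster_id": c.cluster_id, "peptide": c.peptide or "",
              "n_members": len(c.members), "mean_depth": c.mean_depth,
              "members": ";".join(c.members)} for c in self.clusters]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        self.mobility_table.to_csv(out / "mobility.tsv", sep="\t", index=False)
        self.cluster_labels.to_csv(out / "cluster_mobility.tsv", sep="\t")
        self.matrix.to_csv(out / "association_matrix.tsv", sep="\t")
        self.frequencies.to_csv(out / "cluster_frequencies.tsv", sep="\t")
        if self.rarefaction is not None:
            self.rarefaction.to_frame().to_csv(out / "rarefaction.csv", index=False)
        self.config.to_yaml(out / "config_echo.yaml")
        (out / "summary.json").write_text(self.summary_json())


# ---------------------------------------------------------------------------
# pipeline


def load_genomes(genomes_dir: str | Path, species_map: str | Path | None,
                 ) -> list[GenomeRecord]:
    species = {}
    if species_map:
        df = pd.read_csv(species_map, sep="\t")
        species = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    genomes = []
    for path in sorted(Path(genomes_dir).glob("*.fasta")):
        strain = path.stem
        genomes.append(GenomeRecord.from_fasta(path, strain,
                                               species.get(strain, species_of(strain))))
    if not genomes:
        raise InputError(f"no FASTA genomes under {genomes_dir}")
    return genomes


def run_pipeline(config: PipelineConfig, write: bool = False) -> PipelineResult:
    truth = None
    if config.simulate:
        truth = simulate_dataset(config.simulation)
        genomes = [GenomeRecord(s, species_of(s), {f"{s}_c1": truth.contigs[s]})
                   for s in truth.strains["strain"]]
        queries = seed_queries_from_truth(truth)
    else:
        genomes = load_genomes(config.genomes_dir, config.species_map)
        if not config.queries_fasta:
            raise InputError("queries_fasta is required when not simulating")
        from Bio import SeqIO
        queries = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(config.queries_fasta, "fasta")}
    log.info("stage=input genomes=%d queries=%d", len(genomes), len(queries))

    search = SearchParams(evalue_max=config.search.evalue_max,
                          min_homology_len_aa=config.search.min_homology_len_aa,
                          seed_queries=queries, profile=config.profile)
    scan = None
    if config.scan is not None:
        scan = PropeptideScanParams(window=tuple(config.scan.window),
                                    orf_len_aa=tuple(config.scan.orf_len_aa),
                                    same_strand_required=config.scan.same_strand_required,
                                    signal_threshold=config.scan.signal_threshold)
    cassettes: list[Cassette] = []
    for g in genomes:
        cassettes.extend(mine_genome(g, search, scan,
                                     scan_propeptides=config.scan is not None))

    def _make_table() -> pd.DataFrame:
        t = cassettes_to_table(cassettes)
        t.insert(0, "cassette_id", [cassette_id(c) for c in cassettes])
        t.insert(2, "species", [next(g.species for g in genomes if g.strain == c.strain)
                                for c in cassettes])
        return t

    log.info("stage=mining cassettes=%d orphans=%d",
             len(cassettes), sum(c.orphan for c in cassettes))

    # --- receptor tree and peptide clusters
    tree = alignment = None
    clusters = []
    peptide_map: dict[str, str | None] = {}
    cluster_of: dict[str, str] = {}
    if len(cassettes) >= 3:
        seqs = {cassette_id(c): c.receptor.protein for c in cassettes}
        alignment = align_proteins(seqs)
        tree = build_nj_tree(alignment, n_bootstrap=config.tree.n_bootstrap,
                             seed=config.seed)
        # pass 1: provisional per-cassette peptide (C-terminal pentamer —
        # a suffix of the mature peptide whether penta or hexa)
        prepep = {cassette_id(c): c.propeptides[0].protein
                  for c in cassettes if not c.orphan}
        # conservation screen (automated stand-in for manual screening of
        # candidates by conservation pattern): reject a propeptide when the
        # receptor has close relatives on the tree and none of them carries
        # a propeptide ending in the same pentamer
        d_screen = config.tree.conservation_screen_distance
        if d_screen is not None and prepep:
            dists = tree.tip_tip_distances()
            rejected = []
            for cid in prepep:
                suffix = prepep[cid][-5:]
                close = [other for other in seqs
                         if other != cid and dists[cid, other] <= d_screen]
                if close and not any(other in prepep
                                     and prepep[other][-5:] == suffix
                                     for other in close):
                    rejected.append(cid)
            by_id = {cassette_id(c): c for c in cassettes}
            for cid in rejected:
                del prepep[cid]
                by_id[cid].propeptides = []  # screened out: cassette is orphan
            if rejected:
                log.info("stage=phr-screen rejected=%d", len(rejected))
        guess = {cid: (prepep[cid][-5:] if cid in prepep else None) for cid in seqs}
        provisional = peptide_monophyletic_clusters(
            tree, guess, config.tree.orphan_merge_distance)
        # pass 2: group-level call over aligned member propeptides
        for cl in provisional:
            members = [m for m in cl.members if m in prepep]
            if not members:
                for m in cl.members:
                    peptide_map[m] = None
                continue
            if len(members) == 1:
                rows = [prepep[members[0]]]
                call = call_autoinducer(rows, known_peptides=[rows[0][-6:], rows[0][-5:]])
            else:
                sub = align_proteins({m: prepep[m] for m in members})
                call = call_autoinducer(sub.rows)
            for m in cl.members:
                peptide_map[m] = call.peptide if m in prepep else None
        clusters = peptide_monophyletic_clusters(
            tree, peptide_map, config.tree.orphan_merge_distance)
        for cl in clusters:
            for m in cl.members:
                cluster_of[m] = cl.cluster_id
    log.info("stage=clustering clusters=%d unique_peptides=%d", len(clusters),
             len({c.peptide for c in clusters if c.peptide}))

    # --- mobility
    gc_background = {}
    for g in genomes:
        mob_block = config.mobility
        orf_gcs = genome_orf_gcs(g, mob_block.min_orf_len_nt)
        gc_background[g.strain] = strain_gene_gc(orf_gcs)
    mob_rows = []
    for c in cassettes:
        g = next(g for g in genomes if g.strain == c.strain)
        cds = g.contigs[c.receptor.contig][c.receptor.start : c.receptor.end]
        mean, sd = gc_background[c.strain]
        mob_rows.append({
            "cassette_id": cassette_id(c), "strain": c.strain,
            "cluster": cluster_of.get(cassette_id(c), "unclustered"),
            "gene_gc": gc_fraction(cds), "strain_mean": mean, "strain_sd": sd,
        })
    mobility_table = pd.DataFrame(
        mob_rows, columns=["cassette_id", "strain", "cluster", "gene_gc",
                           "strain_mean", "strain_sd"])
    cluster_labels = (cluster_mobility_labels(mobility_table, config.mobility.alpha)
                      if len(mobility_table) else pd.DataFrame())
    log.info("stage=mobility cassettes=%d mobile_clusters=%d", len(mobility_table),
             int((cluster_labels["label"] == "mobile").sum()) if len(cluster_labels) else 0)

    # --- association matrix and population statistics
    assoc_input = pd.DataFrame({
        "strain": [c.strain for c in cassettes],
        "cluster": [cluster_of.get(cassette_id(c), "unclustered") for c in cassettes],
        "orphan": [c.orphan for c in cassettes],
    })
    matrix = build_association_matrix(assoc_input, strains=[g.strain for g in genomes])
    species_series = pd.Series({g.strain: g.species for g in genomes},
                               name="species").reindex(matrix.index)
    frequencies = (per_species_frequency(matrix, species_series)
                   if matrix.shape[1] else pd.DataFrame())
    n_dup, n_dup_orphan, _ = duplicate_cluster_cases(assoc_input)
    rare = None
    if matrix.shape[0] >= 2 and matrix.shape[1]:
        tail = min(config.rarefaction.tail_window, matrix.shape[0] - 1)
        rare = rarefaction_curve(matrix, config.rarefaction.n_resamples,
                                 tail, config.seed)
    log.info("stage=population clusters=%d dup_cases=%d", matrix.shape[1], n_dup)

    # --- summary
    table = _make_table()
    per_strain = table.groupby("strain").size() if len(table) else pd.Series(dtype=int)
    orphans_per_strain = (table.groupby("strain")["orphan"].sum()
                          if len(table) else pd.Series(dtype=float))
    label_of = dict(cluster_labels["label"]) if len(cluster_labels) else {}
    core_fracs = []
    for strain, grp in assoc_input.groupby("strain"):
        labels = [label_of.get(cl) for cl in grp["cluster"]]
        labels = [l for l in labels if l]
        if labels:
            core_fracs.append(np.mean([l == "core" for l in labels]))
    summary = {
        "n_strains": len(genomes),
        "n_cassettes": len(cassettes),
        "mean_raps_per_strain": round(float(per_strain.mean()), 3) if len(per_strain) else 0.0,
        "sd_raps_per_strain": round(float(per_strain.std(ddof=1)), 3)
        if len(per_strain) > 1 else 0.0,
        "mean_orphans_per_strain": round(float(orphans_per_strain.mean()), 3)
        if len(orphans_per_strain) else 0.0,
        "fraction_raps_with_phr": round(float(1 - table["orphan"].mean()), 4)
        if len(table) else 0.0,
        "n_clusters": len(clusters),
        "n_unique_peptides": len({c.peptide for c in clusters if c.peptide}),
        "mobile_cluster_fraction": round(float((cluster_labels["label"] == "mobile").mean()), 4)
        if len(cluster_labels) else 0.0,
        "mean_core_fraction_per_strain": round(float(np.mean(core_fracs)), 4)
        if core_fracs else 0.0,
        "duplicate_cluster_cases": n_dup,
        "orphan_duplicate_cases": n_dup_orphan,
        "rarefaction_tail_slope": round(rare.tail_slope, 4) if rare else None,
        "seed": config.seed,
        "profile": config.profile,
    }
    result = PipelineResult(
        config=config, truth=truth, cassettes=cassettes, cassette_table=table,
        tree=tree, alignment=alignment, clusters=clusters, peptide_map=peptide_map,
        cluster_of=cluster_of, mobility_table=mobility_table,
        cluster_labels=cluster_labels, matrix=matrix, frequencies=frequencies,
        rarefaction=rare, summary=summary,
    )
    if write:
        result.write(config.out_dir)
        if truth is not None:
            from .simulate import emit_genomes
            emit_genomes(truth, Path(config.out_dir) / "synthetic")
    return result
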