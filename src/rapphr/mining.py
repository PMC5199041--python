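"""Mining of receptor-propeptide cassettes from genome assemblies.

The search is tblastn-style: protein seed queries against the six-frame
translation of each contig, with exact k-mer seeding, Smith-Waterman
extension (BLOSUM62, affine gaps) and Karlin-Altschul e-values. Default
filters follow the family profile used for Rap receptors: e-value <= 1e-20
against any query and homology length >= 300 aa; the NprR profile differs
only in e-value (1e-30) and propeptide window.

Each receptor hit is extended to a complete open reading frame
(ATG/GTG/TTG starts, table 11), and a downstream window (default -100..+600
nt from the receptor stop, in receptor orientation) is scanned for short
same-strand ORFs of 35-120 aa scoring >= 0.3 on the secretion-signal PWM.
A receptor with no passing propeptide is an *orphan* cassette; two or more
non-overlapping passing propeptides mark a phr gene duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from ._util import ConfigError, CoordinateError
from .sequences import reverse_complement, six_frame_translate, translate
from .signalpep import DEFAULT_PWM, SignalPeptidePWM

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
_LAMBDA = 0.267
_KAPPA = 0.041
# raw (pre-merge) significance floor keeping fragment hits but not seed noise
_RAW_EVALUE_MAX = 1e-3

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeRecord:
    """One strain's assembly plus metadata."""

    strain: str
    species: str
    contigs: dict[str, str]

    @classmethod
    def from_fasta(cls, path: str | Path, strain: str | None = None,
                   species: str = "") -> "GenomeRecord":
        path = Path(path)
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(strain=strain or path.stem, species=species, contigs=contigs)


@dataclass
class SearchParams:
    evalue_max: float = 1e-20
    min_homology_len_aa: int = 300
    seed_queries: dict[str, str] = field(default_factory=dict)
    profile: str = "rap"

    def validate(self) -> None:
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be positive")
        if self.min_homology_len_aa < 1:
            raise ConfigError("min_homology_len_aa must be >= 1")
        if not self.seed_queries:
            raise ConfigError("at least one seed query is required")


@dataclass
class HomologyHit:
    contig: str
    strand: int                       # +1 / -1
    frame: int                        # 0..2 on the hit strand
    start: int                        # nucleotide coords, 0-based half-open,
    end: int                          # always on the forward strand
    query: str
    score: float
    evalue: float
    aligned_len_aa: int
    # best single-member interval of a merged hit; ORF extension anchors here
    anchor_start: int = -1
    anchor_end: int = -1

    def __post_init__(self):
        if self.anchor_start < 0:
            self.anchor_start, self.anchor_end = self.start, self.end


@dataclass
class ReceptorORF:
    contig: str
    strand: int
    start: int
    end: int                          # includes the stop codon
    protein: str
    frameshift_flag: bool = False


@dataclass
class PropeptideScanParams:
    window: tuple[int, int] = (-100, 600)
    orf_len_aa: tuple[int, int] = (35, 120)
    same_strand_required: bool = True
    signal_threshold: float = 0.3
    max_x_fraction: float = 0.05
    pwm: SignalPeptidePWM = field(default_factory=lambda: DEFAULT_PWM)

    def validate(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ConfigError("propeptide window must be a nonempty interval")
        lo, hi = self.orf_len_aa
        if not (1 <= lo <= hi <= 1000):
            raise ConfigError("orf_len_aa must lie within [1, 1000]")


@dataclass
class PropeptideCandidate:
    contig: str
    strand: int
    start: int
    end: int
    protein: str
    score: float
    distance: int                     # ORF start - receptor stop, receptor orientation
    rank: int = 0


@dataclass
class Cassette:
    strain: str
    receptor: ReceptorORF
    propeptides: list[PropeptideCandidate]

    @property
    def orphan(self) -> bool:
        return len(self.propeptides) == 0

    @property
    def duplication(self) -> bool:
        return len(self.propeptides) >= 2


# ---------------------------------------------------------------------------
# translated homology search


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "local"
    return a


def _seed_regions(query: str, prot: str, k: int = 4, band: int = 16,
                  min_seeds: int = 2, max_gap: int = 250) -> list[tuple[int, int]]:
    """Diagonal-banded k-mer seeding; returns candidate [start, end) spans
    on the frame protein."""
    index: dict[str, list[int]] = {}
    for i in range(len(prot) - k + 1):
        index.setdefault(prot[i : i + k], []).append(i)
    seeds = []
    for q in range(len(query) - k + 1):
        for p in index.get(query[q : q + k], ()):
            seeds.append((p - q, p))
    if not seeds:
        return []
    seeds.sort()
    regions = []
    cur: list[tuple[int, int]] = []
    for d, p in seeds:
        if cur and (d - cur[-1][0] > band):
            regions.extend(_split_by_gap(cur, max_gap, min_seeds))
            cur = []
        cur.append((d, p))
    regions.extend(_split_by_gap(cur, max_gap, min_seeds))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(regions):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _split_by_gap(group: list[tuple[int, int]], max_gap: int,
                  min_seeds: int) -> list[tuple[int, int]]:
    if not group:
        return []
    pts = sorted(p for _, p in group)
    runs, run = [], [pts[0]]
    for p in pts[1:]:
        if p - run[-1] > max_gap:
            runs.append(run)
            run = []
        run.append(p)
    runs.append(run)
    return [(r[0], r[-1] + 1) for r in runs if len(r) >= min_seeds]


def _frame_to_forward(strand: int, frame: int, contig_len: int,
                      p_start: int, p_end: int) -> tuple[int, int]:
    """Map a frame-protein interval to forward-strand nucleotide coords."""
    s = frame + 3 * p_start
    e = frame + 3 * p_end
    if strand == 1:
        return s, e
    return contig_len - e, contig_len - s


def search_receptor_homologs(genome: GenomeRecord,
                             params: SearchParams) -> list[HomologyHit]:
    """All merged receptor-family hits passing the profile's filters.

    Hits from different queries or frames overlapping the same locus (same
    contig and strand, gap <= 100 nt) are merged; the best-scoring member
    supplies score/e-value and the members' aligned lengths are summed, so a
    frameshifted receptor split across two frames still reports its full
    homology length.
    """
    params.validate()
    aligner = _aligner()
    db_len_aa = 2 * sum(len(c) for c in genome.contigs.values())
    raw: list[HomologyHit] = []
    for cname, seq in genome.contigs.items():
        frames = six_frame_translate(seq)
        for fi, prot in enumerate(frames):
            strand = 1 if fi < 3 else -1
            frame = fi % 3
            for qname, query in params.seed_queries.items():
                for r_start, r_end in _seed_regions(query, prot):
                    pad = len(query) // 2 + 10
                    w_start = max(0, r_start - pad)
                    w_end = min(len(prot), r_end + pad)
                    window = prot[w_start:w_end]
                    alns = aligner.align(query, window)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    score = float(aln.score)
                    evalue = _KAPPA * len(query) * db_len_aa * math.exp(-_LAMBDA * score)
                    if evalue > _RAW_EVALUE_MAX:
                        continue  # spurious seed region; keep merge pool clean
                    tgt = aln.aligned[1]
                    p_start = int(tgt[0][0]) + w_start
                    p_end = int(tgt[-1][1]) + w_start
                    s, e = _frame_to_forward(strand, frame, len(seq), p_start, p_end)
                    raw.append(HomologyHit(cname, strand, frame, s, e, qname,
                                           score, evalue, p_end - p_start))
    merged = _merge_hits(raw)
    return [h for h in merged
            if h.evalue <= params.evalue_max
            and h.aligned_len_aa >= params.min_homology_len_aa]


def _merge_hits(hits: list[HomologyHit], max_gap: int = 100) -> list[HomologyHit]:
    out: list[HomologyHit] = []
    key = lambda h: (h.contig, h.strand, h.start, h.end)
    for h in sorted(hits, key=key):
        last = out[-1] if out else None
        if (last is not None and last.contig == h.contig and last.strand == h.strand
                and h.start <= last.end + max_gap):
            span = max(last.end, h.end) - last.start
            covered = min(last.aligned_len_aa + h.aligned_len_aa, span // 3)
            best = last if last.score >= h.score else h
            out[-1] = HomologyHit(last.contig, last.strand, best.frame,
                                  last.start, max(last.end, h.end), best.query,
                                  best.score, min(last.evalue, h.evalue), covered,
                                  best.anchor_start, best.anchor_end)
        else:
            out.append(h)
    return out


def read_blast_hits(path: str | Path) -> list[HomologyHit]:
    """Import tblastn tabular output (outfmt 6) as HomologyHit records,
    for exact parity with externally computed searches."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for _, r in df.iterrows():
        sstart, send = int(r.sstart), int(r.send)
        strand = 1 if send >= sstart else -1
        lo, hi = (sstart - 1, send) if strand == 1 else (send - 1, sstart)
        hits.append(HomologyHit(str(r.sseqid), strand, lo % 3, lo, hi,
                                str(r.qseqid), float(r.bitscore), float(r.evalue),
                                int(r.length)))
    return hits


# ---------------------------------------------------------------------------
# ORF extension


def _strand_coords(start: int, end: int, strand: int, contig_len: int) -> tuple[int, int]:
    """Forward-strand half-open interval -> interval on the given strand's
    own coordinate system (reverse complement for -1)."""
    if strand == 1:
        return start, end
    return contig_len - end, contig_len - start


def extend_to_orf(genome: GenomeRecord, hit: HomologyHit,
                  min_homology_len_aa: int = 300) -> ReceptorORF | None:
    """Extend a hit to a full open reading frame on its strand.

    Walks downstream to the nearest in-frame stop and upstream to the
    5'-most start codon not preceded by an in-frame stop (the complete ORF
    containing the hit). Returns None for hits running off the contig edge
    without a stop codon (partial genes). ``frameshift_flag`` is set when
    the recovered single-frame ORF is shorter than the homology evidence,
    the automated counterpart of manually browsing short high-homology hits.
    """
    seq_fwd = genome.contigs.get(hit.contig)
    if seq_fwd is None:
        raise CoordinateError(f"unknown contig {hit.contig!r}")
    L = len(seq_fwd)
    if not (0 <= hit.start < hit.end <= L):
        raise CoordinateError("hit interval outside contig")
    seq = seq_fwd if hit.strand == 1 else reverse_complement(seq_fwd)
    s0, _ = _strand_coords(hit.anchor_start, hit.anchor_end, hit.strand, L)
    # walk downstream to the nearest in-frame stop
    stop_end = None
    pos = s0
    while pos + 3 <= L:
        if seq[pos : pos + 3] in STOP_CODONS:
            stop_end = pos + 3
            break
        pos += 3
    if stop_end is None:
        return None  # contig edge, partial gene
    # walk upstream: 5'-most start after the previous in-frame stop
    best_start = None
    pos = s0
    while pos - 3 >= 0:
        pos -= 3
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        if codon in START_CODONS:
            best_start = pos
    if seq[s0 : s0 + 3] in START_CODONS and best_start is None:
        best_start = s0
    if best_start is None:
        best_start = s0  # no start between stop and hit; report in-frame span
    protein = translate(seq[best_start:stop_end])[:-1]
    fstart, fend = _strand_coords(best_start, stop_end, hit.strand, L)
    flag = len(protein) < min_homology_len_aa <= hit.aligned_len_aa
    return ReceptorORF(hit.contig, hit.strand, fstart, fend, protein, flag)


# ---------------------------------------------------------------------------
# propeptide scan


def scan_propeptide_orfs(genome: GenomeRecord, receptor: ReceptorORF,
                         params: PropeptideScanParams | None = None,
                         ) -> list[PropeptideCandidate]:
    """Short signal-peptide-bearing ORFs in the downstream window.

    The window is measured from the last base of the receptor stop codon in
    receptor orientation; an ORF qualifies if its start codon lies inside
    the window, it is on the receptor strand (default), its length is within
    bounds and its PWM signal score passes the threshold. Candidates are
    ranked by score (desc), then distance to the receptor (asc), then
    coordinate.
    """
    params = params or PropeptideScanParams()
    params.validate()
    seq_fwd = genome.contigs[receptor.contig]
    L = len(seq_fwd)
    seq = seq_fwd if receptor.strand == 1 else reverse_complement(seq_fwd)
    _, rap_end_s = _strand_coords(receptor.start, receptor.end, receptor.strand, L)
    w_lo = max(0, rap_end_s + params.window[0])
    w_hi = min(L, rap_end_s + params.window[1])
    lo_aa, hi_aa = params.orf_len_aa
    out: list[PropeptideCandidate] = []
    strands = [receptor.strand] if params.same_strand_required \
        else [receptor.strand, -receptor.strand]
    for cand_strand in strands:
        if cand_strand == receptor.strand:
            s_seq, s_lo, s_hi = seq, w_lo, w_hi
        else:
            s_seq = reverse_complement(seq)
            s_lo, s_hi = L - w_hi, L - w_lo
        seen_stops: set[tuple[int, int]] = set()
        for start in range(s_lo, s_hi):
            if s_seq[start : start + 3] not in START_CODONS:
                continue
            frame = start % 3
            stop = None
            pos = start
            limit = min(L, start + 3 * (hi_aa + 1) + 3)
            while pos + 3 <= limit:
                if s_seq[pos : pos + 3] in STOP_CODONS:
                    stop = pos + 3
                    break
                pos += 3
            if stop is None:
                continue
            n_aa = (stop - start) // 3 - 1
            if not (lo_aa <= n_aa <= hi_aa):
                continue
            if (frame, stop) in seen_stops:
                continue  # keep the 5'-most valid ORF per stop
            seen_stops.add((frame, stop))
            protein = translate(s_seq[start:stop])[:-1]
            if protein.count("X") > params.max_x_fraction * len(protein):
                continue
            score = params.pwm.score(protein)
            if score < params.signal_threshold:
                continue
            # map back to receptor-strand coords, then forward coords
            if cand_strand == receptor.strand:
                r_start, r_end = start, stop
            else:
                r_start, r_end = L - stop, L - start
            f_start, f_end = _strand_coords(r_start, r_end, receptor.strand, L)
            out.append(PropeptideCandidate(
                contig=receptor.contig, strand=cand_strand * receptor.strand
                if cand_strand != receptor.strand else receptor.strand,
                start=f_start, end=f_end, protein=protein, score=score,
                distance=r_start - rap_end_s,
            ))
    out.sort(key=lambda c: (-c.score, c.distance, c.start))
    for i, c in enumerate(out):
        c.rank = i + 1
    return out


# ---------------------------------------------------------------------------
# cassette assembly and per-genome driver


def assemble_cassettes(genome: GenomeRecord, receptors: list[ReceptorORF],
                       candidates: dict[int, list[PropeptideCandidate]],
                       ) -> list[Cassette]:
    """One cassette per receptor; accepted candidates are the passing ORFs
    pruned to a non-overlapping set (best rank first)."""
    cassettes = []
    for i, rec in enumerate(receptors):
        accepted: list[PropeptideCandidate] = []
        for cand in candidates.get(i, []):
            if all(cand.end <= a.start or cand.start >= a.end for a in accepted):
                accepted.append(cand)
        cassettes.append(Cassette(genome.strain, rec, accepted))
    return cassettes


def mine_genome(genome: GenomeRecord, search_params: SearchParams,
                scan_params: PropeptideScanParams | None = None,
                scan_propeptides: bool = True) -> list[Cassette]:
    """Full per-genome pipeline: search -> ORF extension -> propeptide scan.

    ``scan_propeptides=False`` skips the propeptide stage (marker-gene
    profiles such as the species-tree search have no cognate peptide)."""
    hits = search_receptor_homologs(genome, search_params)
    receptors: list[ReceptorORF] = []
    seen: set[tuple[str, int, int, int]] = set()
    for hit in hits:
        orf = extend_to_orf(genome, hit, search_params.min_homology_len_aa)
        if orf is None:
            continue
        key = (orf.contig, orf.strand, orf.start, orf.end)
        if key in seen:
            continue
        seen.add(key)
        receptors.append(orf)
    receptors.sort(key=lambda r: (r.contig, r.start))
    candidates = {i: (scan_propeptide_orfs(genome, rec, scan_params)
                      if scan_propeptides else [])
                  for i, rec in enumerate(receptors)}
    return assemble_cassettes(genome, receptors, candidates)


def cassettes_to_table(cassettes: list[Cassette]) -> pd.DataFrame:
    """Flat cassette table (1-based inclusive coordinates in reports)."""
    rows = []
    for c in cassettes:
        r = c.receptor
        rows.append({
            "strain": c.strain, "contig": r.contig,
            "strand": "+" if r.strand == 1 else "-",
            "rap_start": r.start + 1, "rap_end": r.end,
            "rap_protein": r.protein, "frameshift": r.frameshift_flag,
            "orphan": c.orphan, "duplication": c.duplication,
            "phr_starts": ";".join(str(p.start + 1) for p in c.propeptides),
            "phr_ends": ";".join(str(p.end) for p in c.propeptides),
            "phr_proteins": ";".join(p.protein for p in c.propeptides),
            "signal_scores": ";".join(f"{p.score:.3f}" for p in c.propeptides),
        })
    cols = ["strain", "contig", "strand", "rap_start", "rap_end", "rap_protein",
            "frameshift", "orphan", "duplication", "phr_starts", "phr_ends",
            "phr_proteins", "signal_scores"]
    return pd.DataFrame(rows, columns=cols)


def write_gff3(cassettes: list[Cassette], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(cassettes):
            r = c.receptor
            strand = "+" if r.strand == 1 else "-"
            fh.write("\t".join([r.contig, "rapphr", "gene", str(r.start + 1),
                                str(r.end), ".", strand, ".",
                                f"ID=rap{i + 1};product=Rap receptor"]) + "\n")
            for j, p in enumerate(c.propeptides):
                fh.write("\t".join([p.contig, "rapphr", "gene", str(p.start + 1),
                                    str(p.end), f"{p.score:.3f}", strand, ".",
                                    f"ID=phr{i + 1}.{j + 1};Parent=rap{i + 1};"
                                    f"product=Phr propeptide"]) + "\n")
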