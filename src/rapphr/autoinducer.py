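"""Autoinducer calling and repeat/duplication detection in Phr propeptides.

The mature Phr signal is a penta- or hexapeptide cut from the C-terminal
region of the propeptide. Calls are made by sliding a 5/6-residue window
over aligned propeptides of a group and scoring each window by a blend of
per-column conservation (majority fraction) and similarity to a library of
known autoinducers; ties prefer the most C-terminal, then the longer window
(mature peptides are typically C-terminal). A pentapeptide and its
hexapeptide extension are distinct peptides — equality is exact string
equality throughout the package.

Intragenic repeats — duplicated autoinducer coding regions, possibly
diverged (e.g. the [S/I][D/I/N/Y]RNT[T/I] family of motifs) — are reported
as maximal sets of >=2 non-overlapping windows within a mismatch budget of
a common consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import InputError
from .mining import Cassette

WINDOW_LENGTHS = (5, 6)


@dataclass
class AutoinducerCall:
    peptide: str
    position: int                  # start in the (first) ungapped prepeptide
    confidence: float
    method: str                    # "conservation" | "known-motif"

    @property
    def low_confidence(self) -> bool:
        return self.confidence < 0.5


@dataclass
class RepeatReport:
    motif: str                     # consensus of the copies
    copies: list[tuple[int, int]]  # (position, mismatches vs consensus)
    max_pairwise_mismatches: int
    pattern: str                   # degenerate bracket form, e.g. E[R/K]PVGT

    @property
    def copy_count(self) -> int:
        return len(self.copies)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _column_consensus(chars: list[str]) -> tuple[str, float]:
    """Modal non-gap residue and its fraction among non-gap symbols."""
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for i, ch in enumerate(chars):
        if ch == "-":
            continue
        counts[ch] = counts.get(ch, 0) + 1
        order.setdefault(ch, i)
    if not counts:
        return "-", 0.0
    best = max(counts, key=lambda ch: (counts[ch], -order[ch]))
    return best, counts[best] / sum(counts.values())


def call_autoinducer(prepeptides: list[str],
                     known_peptides: list[str] | None = None,
                     window_lengths: tuple[int, ...] = WINDOW_LENGTHS,
                     ) -> AutoinducerCall:
    """Call the putative autoinducer of a group of (aligned) propeptides.

    For groups of >=2 the rows must be aligned (equal length, '-' gaps); the
    score of a window is 0.5 * mean column conservation + 0.5 * best library
    identity (conservation alone when the library is empty; library identity
    alone for singletons, the "known-motif" method). The best-scoring window
    wins; ties prefer larger end position, then larger window length.
    Confidence below 0.5 marks a low-confidence call rather than an error.
    """
    if not prepeptides:
        raise InputError("empty propeptide group")
    library = [p for p in (known_peptides or [])]
    singleton = len(prepeptides) == 1
    if singleton and not library:
        raise InputError("a singleton group needs a known-peptide library")
    rows = prepeptides
    if len({len(r) for r in rows}) != 1:
        raise InputError("group propeptides must be aligned to equal length")
    ncol = len(rows[0])
    best: tuple[float, int, int] | None = None
    best_call: AutoinducerCall | None = None
    for w in window_lengths:
        for start in range(ncol - w + 1):
            cols = [[row[start + j] for row in rows] for j in range(w)]
            consensus_chars = []
            cons_sum = 0.0
            gapped = False
            for col in cols:
                ch, frac = _column_consensus(col)
                if ch == "-" or sum(c == "-" for c in col) * 2 > len(col):
                    gapped = True
                    break
                consensus_chars.append(ch)
                cons_sum += frac
            if gapped:
                continue
            consensus = "".join(consensus_chars)
            sim = max((1 - _hamming(consensus, p) / w
                       for p in library if len(p) == w), default=None)
            if singleton:
                if sim is None:
                    continue
                score, method = sim, "known-motif"
            elif sim is None:
                score, method = cons_sum / w, "conservation"
            else:
                score, method = 0.5 * cons_sum / w + 0.5 * sim, "conservation"
            rank = (score, start + w, w)
            if best is None or rank > best:
                best = rank
                ungapped_pos = len(rows[0][:start].replace("-", ""))
                best_call = AutoinducerCall(consensus, ungapped_pos, score, method)
    if best_call is None:
        raise InputError("no gap-free window available for calling")
    return best_call


def detect_intragenic_repeats(prepeptide: str, motif_len: int = 6,
                              max_mismatch: int = 1,
                              signal_trim: int = 0) -> list[RepeatReport]:
    """Maximal sets of >=2 non-overlapping windows within ``max_mismatch``
    of a common consensus, most copies first.

    Every window is tried as the provisional consensus; compatible windows
    are collected greedily left to right (earliest end first), the actual
    per-column consensus of the chosen copies is recomputed and per-copy
    mismatch counts are reported against it. Duplicate copy sets are
    deduplicated; sets are ordered by copy count (desc) then position.

    ``signal_trim`` drops that many N-terminal residues before scanning:
    autoinducer repeats live in the mature region, and the compositionally
    biased secretion signal (poly-hydrophobic h-region, small-residue
    c-region) otherwise produces trivial approximate matches. Reported
    positions refer to the full propeptide.
    """
    if motif_len not in (5, 6):
        raise InputError("motif_len must be 5 or 6")
    if signal_trim:
        trimmed = detect_intragenic_repeats(prepeptide[signal_trim:], motif_len,
                                            max_mismatch, 0)
        return [RepeatReport(r.motif,
                             [(p + signal_trim, m) for p, m in r.copies],
                             r.max_pairwise_mismatches, r.pattern)
                for r in trimmed]
    n = len(prepeptide)
    if n < 2 * motif_len:
        return []
    windows = [prepeptide[i : i + motif_len] for i in range(n - motif_len + 1)]
    seen: set[tuple[int, ...]] = set()
    reports: list[RepeatReport] = []
    for anchor in windows:
        chosen: list[int] = []
        for i, w in enumerate(windows):
            if _hamming(anchor, w) <= max_mismatch and (
                    not chosen or i >= chosen[-1] + motif_len):
                chosen.append(i)
        if len(chosen) < 2:
            continue
        key = tuple(chosen)
        if key in seen:
            continue
        seen.add(key)
        copies_seq = [windows[i] for i in chosen]
        consensus = "".join(
            _column_consensus([c[j] for c in copies_seq])[0] for j in range(motif_len)
        )
        copies = [(i, _hamming(windows[i], consensus)) for i in chosen]
        max_pair = max(_hamming(a, b) for a in copies_seq for b in copies_seq)
        pattern_parts = []
        for j in range(motif_len):
            residues = []
            for c in copies_seq:
                if c[j] not in residues:
                    residues.append(c[j])
            pattern_parts.append(residues[0] if len(residues) == 1
                                 else "[" + "/".join(residues) + "]")
        reports.append(RepeatReport(consensus, copies, max_pair, "".join(pattern_parts)))
    reports.sort(key=lambda r: (-r.copy_count, r.copies[0][0]))
    return reports


def best_repeat_report(prepeptide: str, motif_len: int = 6,
                       max_mismatch: int = 1,
                       signal_trim: int = 0) -> RepeatReport | None:
    reports = detect_intragenic_repeats(prepeptide, motif_len, max_mismatch,
                                        signal_trim)
    return reports[0] if reports else None


def detect_phr_gene_duplication(cassette: Cassette,
                                window: int = 6) -> tuple[bool, float | None]:
    """Whole-phr-gene duplication: >=2 accepted propeptides on one cassette.

    Divergence is the normalized Hamming distance between the C-terminal
    autoinducer windows of the two highest-ranked propeptides (mature
    peptides sit at the propeptide C-terminus by default).
    """
    if len(cassette.propeptides) < 2:
        return False, None
    a, b = cassette.propeptides[0].protein, cassette.propeptides[1].protein
    wa, wb = a[-window:], b[-window:]
    w = min(len(wa), len(wb))
    return True, _hamming(wa[-w:], wb[-w:]) / w
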