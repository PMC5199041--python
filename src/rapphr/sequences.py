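"""Nucleotide-level primitives: translation, six-frame scans, GC content.

Translation uses the bacterial/archaeal code (NCBI table 11). Alternative
start codons ATG/GTG/TTG are accepted for open reading frames, as is usual
for *Bacillus* genomes; internally an initiator codon is still translated by
the codon table (no forced methionine), which keeps translation a pure
per-codon lookup.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from ._util import AlphabetError, UndefinedScoreError

DNA_ALPHABET = frozenset("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TABLE: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TABLE.update({c: "*" for c in _TABLE11.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _check_alphabet(dna: str) -> None:
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal nucleotide characters: {sorted(bad)!r}")


def reverse_complement(dna: str) -> str:
    _check_alphabet(dna)
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0) -> str:
    """Translate one reading frame; codons containing N become 'X', stops '*'.

    A frame ``f`` of a sequence of length ``L`` yields ``(L - f) // 3``
    residues; trailing partial codons are dropped.
    """
    _check_alphabet(dna)
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(dna: str) -> tuple[str, str, str, str, str, str]:
    """Return the three forward and three reverse-complement frame proteins."""
    _check_alphabet(dna)
    rc = reverse_complement(dna)
    return (
        translate(dna, 0),
        translate(dna, 1),
        translate(dna, 2),
        translate(rc, 0),
        translate(rc, 1),
        translate(rc, 2),
    )


def gc_fraction(dna: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from the denominator."""
    _check_alphabet(dna)
    gc = dna.count("G") + dna.count("C")
    informative = len(dna) - dna.count("N")
    if informative == 0:
        raise UndefinedScoreError("no informative (non-N) bases")
    return gc / informative
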