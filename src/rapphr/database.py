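"""Loader/writer for Rap-database-shaped tables (TSV or Excel).

The canonical record layout is one row per
receptor with its strain, clade, cluster assignment, nucleotide and protein
sequences, the putative Phr autoinducer (empty for orphans), and the phr
sequences. Column naming in the wild varies, so a column-mapping override
is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from ._util import InputError
from .sequences import translate

COLUMNS = ["index", "strain", "clade", "cluster", "rap_dna", "rap_protein",
           "autoinducer", "phr_protein", "phr_dna"]
MANDATORY = ["index", "strain", "cluster", "rap_protein"]

# lowercase alias -> canonical column
_ALIASES = {
    "index number": "index", "idx": "index", "id": "index",
    "strain number": "strain", "associated strain number": "strain",
    "associated cluster number": "cluster", "cluster number": "cluster",
    "nucleotide sequence": "rap_dna", "rap nucleotide sequence": "rap_dna",
    "amino-acid sequence": "rap_protein", "amino acid sequence": "rap_protein",
    "putative phr autoinducer sequence": "autoinducer",
    "putative phr autoinducer": "autoinducer",
    "phr amino-acid sequence": "phr_protein", "phr aa sequence": "phr_protein",
    "phr dna sequence": "phr_dna", "phr nucleotide sequence": "phr_dna",
}


@dataclass
class RapDatabaseRecord:
    index: int
    strain: str
    clade: str
    cluster: str
    rap_dna: str
    rap_protein: str
    autoinducer: str          # empty string <=> orphan
    phr_protein: str
    phr_dna: str

    @property
    def orphan(self) -> bool:
        return self.autoinducer == ""

    def translation_consistent(self) -> bool | None:
        """Does the stored protein equal the translation of the stored CDS?
        None when either sequence is absent."""
        if not self.rap_dna or not self.rap_protein:
            return None
        prot = translate(self.rap_dna)
        return prot.rstrip("*") == self.rap_protein


def _normalize_columns(df: pd.DataFrame,
                       column_map: dict[str, str] | None) -> pd.DataFrame:
    ren = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if column_map and col in column_map:
            ren[col] = column_map[col]
        elif key in _ALIASES:
            ren[col] = _ALIASES[key]
        elif key in COLUMNS:
            ren[col] = key
    return df.rename(columns=ren)


def load_rap_database(path: str | Path,
                      column_map: dict[str, str] | None = None,
                      ) -> list[RapDatabaseRecord]:
    """Read a Rap database export (.tsv/.csv/.xlsx); empty files yield []."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, dtype=str)
        except pd.errors.EmptyDataError:
            return []
    if df.empty and len(df.columns) == 0:
        return []
    df = _normalize_columns(df, column_map)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise InputError(f"missing mandatory column(s): {missing}")
    records = []
    for _, r in df.iterrows():
        def get(col: str) -> str:
            v = r.get(col, "")
            return "" if pd.isna(v) else str(v)

        records.append(RapDatabaseRecord(
            index=int(float(r["index"])), strain=get("strain"), clade=get("clade"),
            cluster=get("cluster"), rap_dna=get("rap_dna").upper(),
            rap_protein=get("rap_protein").upper(), autoinducer=get("autoinducer"),
            phr_protein=get("phr_protein").upper(), phr_dna=get("phr_dna").upper(),
        ))
    return records


def write_rap_database(records: list[RapDatabaseRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def counts_by_clade(records: list[RapDatabaseRecord]) -> pd.Series:
    return pd.Series([r.clade for r in records]).value_counts()


def truth_to_records(truth) -> list[RapDatabaseRecord]:
    """Export a synthetic ground truth as database records (useful both as
    a loader fixture and to push simulated data through database-driven
    analyses)."""
    records = []
    for i, (_, r) in enumerate(truth.cassettes.iterrows(), start=1):
        phr_prot = r["phr_proteins"].split(";")[0] if r["phr_proteins"] else ""
        phr_dna = r["phr_cds"].split(";")[0] if r["phr_cds"] else ""
        records.append(RapDatabaseRecord(
            index=i, strain=str(r["strain"]), clade=str(r["species"]),
            cluster=str(r["cluster"]), rap_dna=str(r["rap_cds"]),
            rap_protein=str(r["rap_protein"]), autoinducer=str(r["autoinducer"]),
            phr_protein=phr_prot, phr_dna=phr_dna,
        ))
    return records
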