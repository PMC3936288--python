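"""Readers and writers for the interchange formats (TSV with header, UTF-8,
'.' decimal; FASTA for sequences)."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .config import FractionMeta, fractions_from_frame

EVIDENCE_COLUMNS = [
    "peptide_id", "sequence", "protease", "gene_id", "proteins",
    "modifications", "phospho_sites", "is_contaminant", "is_reverse",
    "sample", "intensity", "msms_count",
]


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"phospho_sites": str},
                     keep_default_na=False, na_values=[""])
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    df["phospho_sites"] = df["phospho_sites"].fillna("")
    for col in ("is_contaminant", "is_reverse"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(fasta: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in fasta.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample", "fpkm"}
    if not required <= set(df.columns):
        raise ValueError(f"FPKM table missing columns: {sorted(required - set(df.columns))}")
    if "is_histone" not in df.columns:
        df["is_histone"] = False
    return df


def read_fractions(path: str | Path) -> tuple[FractionMeta, ...]:
    return fractions_from_frame(pd.read_csv(path, sep="\t"))


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_type", "term_id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(required - set(df.columns))}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")
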