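"""File round-trips for the formats the pipeline consumes and emits."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_tissue_map",
    "read_ortholog_map",
    "read_gene_age_table",
    "write_gene_age_table",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence (uppercase) from a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples FPKM TSV: header row of sample ids, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_tissue_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, tissue) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"])
    return dict(zip(df["sample"].astype(str), df["tissue"].astype(str)))


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (focal gene, outgroup ortholog)."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["focal", "ortholog"])


def read_gene_age_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_gene_age_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
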