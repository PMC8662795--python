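"""Readers for tabular homology-hit files (BLAST outfmt-6 dialect).

The 12 columns are query, subject, percent identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, e-value, bitscore.
Subject identifiers are resolved to genomes either directly (subject ==
genome id, as the simulator emits) or through a user-supplied subject->genome
map for real BLAST databases with per-sequence subjects.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

OUTFMT6_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

#: minimal column set the downstream operations need
HIT_COLUMNS = ["query", "subject_genome", "evalue", "bitscore", "program"]


def read_hit_table(
    path: str | Path,
    subject_to_genome: Mapping[str, str] | None = None,
    program: str = "blastp",
) -> pd.DataFrame:
    """Read a 12-column tab-separated hit table into a hit frame.

    Parameters
    ----------
    path : str or Path
        Tab-separated file without header, BLAST ``-outfmt 6`` field order.
    subject_to_genome : mapping, optional
        Maps subject sequence ids to genome ids.  When omitted the subject
        column is taken to already hold genome ids.
    program : str
        Provenance tag (``blastp`` for protein-protein, ``tblastn`` for
        protein vs. translated nucleotide); retained but not interpreted.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                     comment="#")
    return as_hit_frame(df, subject_to_genome=subject_to_genome,
                        program=program)


def as_hit_frame(
    df: pd.DataFrame,
    subject_to_genome: Mapping[str, str] | None = None,
    program: str = "blastp",
) -> pd.DataFrame:
    """Normalise a raw table to the internal hit-frame layout.

    The hit frame has columns ``query, subject_genome, evalue, bitscore,
    program``.  Negative e-values are rejected.
    """
    out = pd.DataFrame(
        {
            "query": df["query"].astype(str),
            "subject_genome": df["subject"].astype(str),
            "evalue": pd.to_numeric(df["evalue"]),
            "bitscore": pd.to_numeric(df.get("bitscore", 0.0)),
        }
    )
    if subject_to_genome is not None:
        unknown = set(out["subject_genome"]) - set(subject_to_genome)
        if unknown:
            raise KeyError(
                f"subjects without genome mapping: {sorted(unknown)[:5]}"
            )
        out["subject_genome"] = out["subject_genome"].map(subject_to_genome)
    if (out["evalue"] < 0).any():
        bad = out.loc[out["evalue"] < 0, "query"].iloc[0]
        raise ValueError(f"negative e-value for query {bad!r}")
    out["program"] = program
    return out


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit frame back out as a 12-column outfmt-6 style table.

    Columns the frame does not carry are zero-filled; identity is set to
    100 for simulator-emitted hits.
    """
    n = len(hits)
    full = pd.DataFrame(
        {
            "query": hits["query"],
            "subject": hits["subject_genome"],
            "pident": hits.get("pident", pd.Series([100.0] * n)).values,
            "length": hits.get("length", pd.Series([0] * n)).values,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 0,
            "qend": 0,
            "sstart": 0,
            "send": 0,
            "evalue": hits["evalue"],
            "bitscore": hits["bitscore"],
        }
    )
    full.to_csv(path, sep="\t", header=False, index=False)
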