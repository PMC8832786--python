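"""Small FASTA/TSV I/O helpers used across the pipeline stages.

FASTA goes through Biopython; tables through pandas.  Sequences are kept
as plain Python strings in ordered dicts keyed by record id — the working
currency of the whole package.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike,
                descriptions: dict[str, str] | None = None) -> None:
    """Write an ``{id: sequence}`` dict as FASTA (60-column wrapping)."""
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
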