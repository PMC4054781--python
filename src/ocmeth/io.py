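"""Plain-text readers and writers for the pipeline's tabular inputs.

Everything is TSV, FASTA, or BED; no binary formats.  Beta and expression
matrices carry the feature id in the first column with sample ids as the
header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_matrix(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_matrix(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    # keep literal strings like "null" (a truth label) and empty gene fields
    # as strings; no table written by this package has missing numeric cells
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
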