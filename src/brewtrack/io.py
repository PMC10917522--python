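"""Reading and writing the package's plain-text table dialects.

Everything is TSV; abundance matrices carry a small ``#``-prefixed header
block recording the value kind and merge state so a written matrix can be
round-tripped. FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .matrix import AbundanceMatrix


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: AbundanceMatrix, path) -> None:
    """Abundance matrix as TSV with a header block and a metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# value_kind={matrix.value_kind}\n")
        fh.write(f"# merged={matrix.merged}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="protein_id")
    matrix.samples.to_csv(path.with_suffix(".samples.tsv"), sep="\t",
                          index_label="sample_id")


def read_matrix(path) -> AbundanceMatrix:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
        values = pd.read_csv(fh, sep="\t", index_col="protein_id")
    if "value_kind" not in header:
        raise InputError(f"{path} lacks a value_kind header")
    samples = pd.read_csv(path.with_suffix(".samples.tsv"), sep="\t",
                          index_col="sample_id")
    return AbundanceMatrix(values=values, samples=samples,
                           value_kind=header["value_kind"],
                           merged=header.get("merged", "False") == "True")
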