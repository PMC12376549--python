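"""Reading and writing of the pipeline's tabular and FASTA interchange files.

All tables are plain TSV with a header row; missing values are empty fields.
FASTA goes through Biopython. Writers are deterministic: same inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column order of the 12-column tabular homology-hit dialect
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_outfmt6(path: str | Path) -> pd.DataFrame:
    """Read headerless 12-column tabular hits, validating row shape."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(OUTFMT6_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(OUTFMT6_COLUMNS)} columns, found {df.shape[1]}"
        )
    df.columns = OUTFMT6_COLUMNS
    return df


def write_outfmt6(df: pd.DataFrame, path: str | Path) -> None:
    df[OUTFMT6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    if hasattr(x, "item"):
        return x.item()
    if hasattr(x, "tolist"):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
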