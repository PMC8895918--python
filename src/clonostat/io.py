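"""Reading and writing AIRR-style rearrangement tables and FASTQ reads.

Clone tables travel as pandas DataFrames with canonical column names
(``v_gene``, ``cdr3_nt``, ``count`` ...). On disk they are AIRR
rearrangement TSVs (``v_call``, ``junction``, ``duplicate_count`` ...);
the mapping between the two is configurable so tables exported by
different clone callers can be consumed without editing them.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: AIRR column -> canonical column. Metadata columns (sample_id, mouse_id,
#: strain, tissue, batch, isotype) keep their names on both sides.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "duplicate_count": "count",
}

METADATA_COLUMNS = ["sample_id", "mouse_id", "strain", "tissue", "batch", "isotype"]
SEQUENCE_COLUMNS = ["v_gene", "d_gene", "j_gene", "cdr3_nt", "cdr3_aa", "count"]
CANONICAL_COLUMNS = METADATA_COLUMNS + SEQUENCE_COLUMNS

#: canonical columns that must be present after mapping
REQUIRED_COLUMNS = ["v_gene", "j_gene", "cdr3_nt", "cdr3_aa", "count"]


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load an AIRR-column -> canonical-column mapping from a YAML file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"column map {path!s} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_airr(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV into a canonical clone table.

    Parameters
    ----------
    path:
        TSV file (optionally gzip-compressed).
    column_map:
        AIRR-column -> canonical-column mapping; defaults to
        :data:`DEFAULT_COLUMN_MAP`.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        wanted = {v: k for k, v in column_map.items()}
        hints = ", ".join(f"{c} (mapped from column {wanted.get(c, c)!r})" for c in missing)
        raise KeyError(f"{path!s}: missing required columns: {hints}")
    if len(df):
        df["count"] = pd.to_numeric(df["count"]).astype(int)
    else:
        df["count"] = df["count"].astype(int)
    if "d_gene" not in df.columns:
        df["d_gene"] = ""
    keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in keep]
    return df[keep + extra]


def write_airr(df: pd.DataFrame, path: str | Path, column_map: dict[str, str] | None = None) -> None:
    """Write a canonical clone table as an AIRR rearrangement TSV."""
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    inverse = {v: k for k, v in column_map.items()}
    out = df.rename(columns=inverse)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a FASTQ file (gzip tolerated)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(read_id, sequence)`` pairs as FASTQ with flat quality strings.

    Returns the number of reads written.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq in records:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
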