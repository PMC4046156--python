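"""Readers and writers for the delimited-text formats nucmir consumes.

CT tables are TSV/CSV with a header row ``assay<sep>sample1<sep>...``; sample
metadata lives in a side-car sample sheet (TSV with columns sample_id,
cell_type, fraction, replicate). The instrument's "Undetermined" token is
configurable. Sequences travel as FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ctmatrix import CtMatrix, ExpressionMatrix, SampleMeta
from .errors import SchemaError, ValidationError

DEFAULT_SENTINEL = "Undetermined"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_sample_sheet(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = {"sample_id", "cell_type", "fraction", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"sample sheet {path}: missing columns {sorted(missing)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        if row.isna().any():
            raise SchemaError(
                f"sample sheet {path}: incomplete metadata for sample "
                f"{row.get('sample_id')!r}"
            )
        meta = SampleMeta(
            sample_id=row["sample_id"],
            cell_type=row["cell_type"],
            fraction=row["fraction"],
            replicate=int(row["replicate"]),
        )
        if meta.sample_id in out:
            raise SchemaError(f"duplicate sample_id {meta.sample_id!r} in {path}")
        out[meta.sample_id] = meta
    return out


def write_sample_sheet(samples, path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cell_type": s.cell_type,
            "fraction": s.fraction,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_ct_table(
    path,
    sample_sheet,
    assay_class: Mapping[str, str] | None = None,
    sentinel: str = DEFAULT_SENTINEL,
) -> CtMatrix:
    """Parse a delimited CT table plus its sample sheet into a CtMatrix.

    ``sample_sheet`` may be a path or a pre-parsed ``{sample_id: SampleMeta}``
    mapping. Cells equal to ``sentinel`` map to UNDETERMINED; every other cell
    must parse as a CT in [0, 40] (a parse failure or out-of-range value raises
    ValidationError naming the offending row and column).
    """
    if not isinstance(sample_sheet, Mapping):
        sample_sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.columns[0].lower() not in ("assay", "assay_id", "mirna"):
        raise SchemaError(
            f"{path}: first column must be the assay name column, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    metas = []
    for sid in df.columns:
        if sid not in sample_sheet:
            raise SchemaError(f"{path}: no metadata for sample {sid!r}")
        metas.append(sample_sheet[sid])

    def parse(cell, assay, sid):
        if pd.isna(cell) or str(cell).strip() == sentinel:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise ValidationError(
                f"{path}: unparseable CT {cell!r} at assay {assay!r}, sample {sid!r}"
            ) from None

    values = pd.DataFrame(
        {sid: [parse(df.at[a, sid], a, sid) for a in df.index] for sid in df.columns},
        index=df.index,
    )
    return CtMatrix(values, metas, assay_class)


def write_ct_table(m: CtMatrix, path, sentinel: str = DEFAULT_SENTINEL) -> None:
    """Write a CtMatrix as delimited text; inverse of :func:`read_ct_table`.

    Uses repr-precision floats so a read/write round-trip is bit-exact.
    """
    out = m.values.map(lambda v: sentinel if pd.isna(v) else repr(float(v)))
    out.index.name = "assay"
    out.to_csv(path, sep=_sep_for(path))


def read_expression_matrix(path, sample_sheet=None) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if sample_sheet is not None:
        if not isinstance(sample_sheet, Mapping):
            sample_sheet = read_sample_sheet(sample_sheet)
        metas = []
        for sid in df.columns:
            if sid not in sample_sheet:
                raise SchemaError(f"{path}: no metadata for sample {sid!r}")
            metas.append(sample_sheet[sid])
    else:
        metas = [SampleMeta(sid, "other", "whole", 1) for sid in df.columns]
    return ExpressionMatrix(df, metas)


def write_expression_matrix(x: ExpressionMatrix, path) -> None:
    out = x.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path))


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: uppercase sequence} (order-preserving)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
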