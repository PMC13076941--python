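"""File I/O: AIRR Rearrangement TSV, FASTA, paratope label tables.

AIRR files use the community column names (sequence_id,
sequence_alignment_aa, junction_aa, v_call, d_call, j_call, c_call,
locus) plus two non-standard columns, ``cell_subtype`` and
``n_mutations``, that carry the simulation/supervision metadata.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import HEAVY, LIGHT, BCRRecord, ParatopeRecord

PathLike = Union[str, Path]

AIRR_REQUIRED_COLUMNS = ("sequence_id", "sequence_alignment_aa", "v_call", "j_call", "locus")
AIRR_COLUMNS = (
    "sequence_id",
    "sequence_alignment_aa",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "locus",
    "cell_subtype",
    "n_mutations",
)


class AirrFormatError(ValueError):
    """Raised when an AIRR TSV is missing mandatory columns."""


def _locus(record: BCRRecord) -> str:
    if record.chain == HEAVY:
        return "IGH"
    if record.isotype in ("IGK", "IGL"):
        return record.isotype
    return "IGL"


def write_airr(records: Sequence[BCRRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.id,
                "sequence_alignment_aa": r.sequence,
                "junction_aa": r.hcdr3 or "",
                "v_call": r.v_call or "",
                "d_call": r.d_call or "",
                "j_call": r.j_call or "",
                "c_call": r.isotype or "",
                "locus": _locus(r),
                "cell_subtype": r.subtype or "",
                "n_mutations": "" if r.n_mutations is None else int(r.n_mutations),
            }
        )
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_airr(path: PathLike) -> List[BCRRecord]:
    """Read an AIRR Rearrangement TSV into records.

    Missing optional fields become ``None``; a missing mandatory column
    raises :class:`AirrFormatError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty AIRR file, returning no records")
        return []
    for col in AIRR_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"{path}: missing mandatory AIRR column {col!r}")
    if df.empty:
        warnings.warn(f"{path}: AIRR file contains a header but no rows")
        return []

    def opt(row, col) -> Optional[str]:
        val = row.get(col, "") if col in df.columns else ""
        return val if val else None

    records: List[BCRRecord] = []
    for _, row in df.iterrows():
        seq = row["sequence_alignment_aa"]
        cdr3 = opt(row, "junction_aa")
        chain = HEAVY if row["locus"] == "IGH" else LIGHT
        span = None
        if cdr3:
            pos = seq.find(cdr3)
            if pos >= 0:
                span = (pos, pos + len(cdr3))
        n_mut = opt(row, "n_mutations")
        records.append(
            BCRRecord(
                id=row["sequence_id"],
                chain=chain,
                sequence=seq,
                hcdr3=cdr3,
                v_call=opt(row, "v_call"),
                d_call=opt(row, "d_call"),
                j_call=opt(row, "j_call"),
                isotype=opt(row, "c_call"),
                subtype=opt(row, "cell_subtype"),
                n_mutations=int(n_mut) if n_mut is not None else None,
                hcdr3_span=span,
            )
        )
    return records


def write_fasta(records: Sequence[BCRRecord], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: PathLike, chain: str = HEAVY) -> List[BCRRecord]:
    """Read bare sequences from FASTA (no metadata; QC will reject them
    unless CDR3/gene annotations are attached afterwards)."""
    return [
        BCRRecord(id=rec.id, chain=chain, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_paratope_tsv(records: Sequence[ParatopeRecord], path: PathLike) -> None:
    rows = [
        {
            "sequence_id": r.id,
            "chain": r.chain,
            "sequence": r.sequence,
            "labels": "".join(map(str, r.labels.tolist())),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_paratope_tsv(path: PathLike) -> List[ParatopeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence_id", "chain", "sequence", "labels"):
        if col not in df.columns:
            raise AirrFormatError(f"{path}: missing paratope column {col!r}")
    return [
        ParatopeRecord(
            id=row["sequence_id"],
            chain=row["chain"],
            sequence=row["sequence"],
            labels=np.array([int(c) for c in row["labels"]], dtype=np.int64),
        )
        for _, row in df.iterrows()
    ]


def write_cluster_map(cluster_rows: Sequence[dict], path: PathLike) -> None:
    """Cluster assignment table: sequence_id, cluster_id, representative_id,
    identity_to_rep."""
    pd.DataFrame(
        cluster_rows, columns=["sequence_id", "cluster_id", "representative_id", "identity_to_rep"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
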