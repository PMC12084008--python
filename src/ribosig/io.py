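"""Reading and writing the pipeline's file formats.

One tabular dialect everywhere: tab-separated, header row, UTF-8, '.'
decimal, empty cell = missing.  Sequences travel as FASTA (ids are the
first whitespace-delimited header token; U is normalized to T).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import DataError, QuantMatrix
from .simulate import GroundTruth
from .transcripts import TranscriptRecord, normalize_seq


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA -> {id: sequence}. Duplicate ids and empty files are data errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DataError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = normalize_seq(str(rec.seq))
    if not out:
        raise DataError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# Quant matrix + condition map


def write_quant_matrix(matrix: QuantMatrix, values_path, conditions_path) -> None:
    write_tsv(matrix.values, values_path, index=True)
    cond = matrix.conditions.rename("condition").rename_axis("sample_id").reset_index()
    write_tsv(cond, conditions_path)


def read_quant_matrix(
    values_path, conditions_path, log2_transformed: bool
) -> QuantMatrix:
    vals = read_tsv(values_path, index_col=0)
    cond = read_tsv(conditions_path)
    conditions = pd.Series(cond["condition"].values, index=cond["sample_id"].values)
    return QuantMatrix(vals, conditions, log2_transformed=log2_transformed)


# ---------------------------------------------------------------------------
# Transcript sets


def write_transcripts(
    records: list[TranscriptRecord],
    utr5_path,
    cds_path,
    map_path,
    groups: dict[str, str] | None = None,
) -> None:
    """Two FASTAs (5'UTR, CDS) keyed by transcript id plus a mapping TSV."""
    write_fasta({t.transcript_id: t.utr5 for t in records}, utr5_path)
    write_fasta({t.transcript_id: t.cds for t in records}, cds_path)
    rows = [
        {"gene_id": t.gene_id, "transcript_id": t.transcript_id,
         "group": (groups or {}).get(t.transcript_id, "")}
        for t in records
    ]
    write_tsv(pd.DataFrame(rows), map_path)


def read_transcripts(utr5_path, cds_path, map_path) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Load transcript records from the FASTA pair and the gene map TSV."""
    utr5 = read_fasta(utr5_path)
    cds = read_fasta(cds_path)
    mapping = read_tsv(map_path, dtype=str).fillna("")
    records = []
    for row in mapping.itertuples(index=False):
        tid = row.transcript_id
        if tid not in utr5 or tid not in cds:
            raise DataError(f"transcript {tid!r} missing from a FASTA file")
        records.append(TranscriptRecord(row.gene_id, tid, utr5[tid], cds[tid]))
    return records, mapping


def write_ground_truth(truth: GroundTruth, proteins_path=None, transcripts_path=None) -> None:
    if truth.proteins is not None and proteins_path is not None:
        write_tsv(truth.proteins, proteins_path)
    if truth.transcripts is not None and transcripts_path is not None:
        write_tsv(truth.transcripts, transcripts_path)
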