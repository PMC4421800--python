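"""File-format helpers: FASTA/FASTQ via biopython, GFF3 as a flat
feature table (0-based half-open in memory, 1-based inclusive on disk)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path, id_prefix: str = "read") -> None:
    """``reads`` is a list of (sequence, quality-string) pairs."""
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@{id_prefix}_{i + 1:06d}\n{seq}\n+\n{qual}\n")


GFF_COLUMNS = ("seqid", "ftype", "start", "end", "strand", "feature_id", "parent")


def write_gff3(features: pd.DataFrame, path, source: str = "mirgonad") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = f"ID={row.feature_id}"
            if getattr(row, "parent", ""):
                attrs += f";Parent={row.parent}"
            fh.write(
                f"{row.seqid}\t{source}\t{row.ftype}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        rows.append(
            {
                "seqid": seqid,
                "ftype": ftype,
                "start": int(start) - 1,
                "end": int(end),
                "strand": strand,
                "feature_id": fields.get("ID", ""),
                "parent": fields.get("Parent", ""),
            }
        )
    return pd.DataFrame(rows, columns=list(GFF_COLUMNS))


def write_tsv(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
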