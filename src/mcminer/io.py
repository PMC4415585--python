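"""Standard-format I/O: FASTA/FASTQ via Biopython, TSV via pandas, YAML config.

Dialect: FASTA is written uppercase at 60 characters per line; FASTQ carries
a constant quality of 'I'; TSVs have a header row and may start with
``#``-prefixed metadata lines. Sequences are uppercased on read.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .composition import SequenceRecord
from .synthetic import Read, ReadSet


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence.upper()), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")  # wraps at 60 characters


def read_fastq(path: str | Path, sample_id: str = "sample") -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                true_origin="",
                true_start=-1,
                true_substitutions=-1,
            )
        )
    lengths = [len(r.sequence) for r in reads]
    mean_len = sum(lengths) / len(lengths) if lengths else 0.0
    return ReadSet(
        reads=reads, mean_length=mean_len, length_sd=0.0, error_rate=float("nan"),
        sample_id=sample_id,
    )


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    bio = []
    for r in readset:
        rec = BioSeqRecord(Seq(r.sequence.upper()), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)  # 'I'
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash naming the configuration that produced an output."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
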