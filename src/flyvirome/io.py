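"""Shared readers and writers: TSV tables with metadata headers, FASTA, JSON.

All tabular interchange uses tab-delimited UTF-8 text.  Lines beginning
with ``#`` are metadata (tool version and parameters) and are skipped on
read; every writer emits one such line so outputs are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


def read_table(path, schema: list | None = None) -> pd.DataFrame:
    """Read a TSV table, skipping '#' metadata lines.

    ``schema`` lists required columns; a missing column raises with its
    name.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path, params: dict | None = None):
    """Write a TSV table with a '#' metadata header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"flyvirome {__version__}", **(params or {})}
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fasta(path) -> dict:
    """FASTA file -> {id: sequence} (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path):
    """{id: sequence} -> FASTA file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_reads(path) -> list:
    """Read small RNAs from FASTA or a 'sequence<TAB>count' collapsed file."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        reads = []
        for rec in SeqIO.parse(str(path), "fasta"):
            reads.append(str(rec.seq).upper())
        return reads
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq, count = line.split("\t")
            reads.extend([seq.upper()] * int(count))
    return reads


def write_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def placements_to_table(placements) -> pd.DataFrame:
    """Mapped-read placements -> TSV-ready DataFrame."""
    rows = [{
        "read_sequence": p.read_sequence, "contig_id": p.contig_id,
        "start": p.start, "strand": p.strand, "length": p.length,
        "weight": p.weight,
        "three_prime_mismatches": ";".join(
            f"{off}:{rb}>{tb}" for off, rb, tb in p.three_prime_mismatches),
    } for p in placements]
    return pd.DataFrame(rows, columns=[
        "read_sequence", "contig_id", "start", "strand", "length", "weight",
        "three_prime_mismatches"])


def table_to_placements(df: pd.DataFrame):
    """Inverse of :func:`placements_to_table`."""
    from .mapping import MappedSmallRead

    placements = []
    for row in df.itertuples(index=False):
        mm = []
        field = getattr(row, "three_prime_mismatches", "")
        if isinstance(field, str) and field:
            for item in field.split(";"):
                off, pair = item.split(":")
                rb, tb = pair.split(">")
                mm.append((int(off), rb, tb))
        placements.append(MappedSmallRead(
            read_sequence=row.read_sequence, contig_id=row.contig_id,
            start=int(row.start), strand=row.strand, length=int(row.length),
            three_prime_mismatches=tuple(mm),
            weight=float(getattr(row, "weight", 1.0))))
    return placements
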