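"""Sequence and table I/O plus the shared record contract.

Reads arrive as FASTA or FASTQ, optionally gzip-compressed (detected by
magic bytes, never by file extension). Sequences are uppercased on
ingest and every character outside {A, C, G, T} is normalised to N, so
downstream k-mer code only ever handles a five-letter alphabet. FASTQ
qualities are discarded: composition statistics do not use them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO

_NORMALISE = bytes.maketrans(
    bytes(range(256)),
    bytes(ord(chr(c).upper()) if chr(c).upper() in "ACGT" else ord("N") for c in range(256)),
)


def normalise_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    return seq.encode("ascii", errors="replace").translate(_NORMALISE).decode("ascii")


@dataclass(frozen=True)
class SeqRecord:
    """One read or contig: identifier plus nucleotide string.

    The id is the token before the first whitespace in the source
    header; the sequence is normalised per :func:`normalise_sequence`.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be nonempty")

    @property
    def length(self) -> int:
        return len(self.seq)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _sniff_format(handle: IO[str]) -> str | None:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == "":
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot determine sequence format from leading character {first!r}")


def read_seq_file(path: str | Path, format: str = "auto") -> Iterator[SeqRecord]:
    """Stream :class:`SeqRecord` objects from a FASTA/FASTQ file.

    Gzip compression is detected transparently. Records are yielded in
    file order with memory bounded by the longest single record (the
    underlying Biopython parser is streaming). An empty file yields an
    empty stream. FASTQ qualities are dropped. A malformed record
    raises a ``ValueError`` naming its zero-based index in the file.
    """
    with _open_maybe_gzip(path) as handle:
        fmt = format
        if fmt == "auto":
            sniffed = _sniff_format(handle)
            if sniffed is None:
                return
            fmt = sniffed
        parser = SeqIO.parse(handle, fmt)
        idx = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed record at index {idx} in {path}: {exc}") from exc
            yield SeqRecord(id=rec.id, seq=normalise_sequence(str(rec.seq)))
            idx += 1


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-read table as tab-delimited text with a header row.

    The index is expected to hold read ids; the matching reader
    :func:`read_table` round-trips the result losslessly.
    """
    df = table.copy()
    df.index.name = df.index.name or "read_id"
    df.to_csv(path, sep="\t", index=True)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_label_table(path: str | Path) -> pd.Series:
    """Read a two-column (read id, class label) TSV; labels are opaque strings."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label table needs two columns: read id, label")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class_label")


def read_id_set(path: str | Path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> int:
    """Write records as FASTA, wrapping sequence lines; returns count written."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                out.write(rec.seq[i : i + width] + "\n")
            if rec.length == 0:
                out.write("\n")
            n += 1
    return n


def export_fasta_subset(source: str | Path, ids: Iterable[str], out: str | Path) -> int:
    """Extract the requested read ids from a sequence file into a FASTA.

    Source order is preserved; ids absent from the source are silently
    reflected in the returned count. Intended for handing sampled reads
    to an external homology search.
    """
    wanted = set(ids)
    return write_fasta((rec for rec in read_seq_file(source) if rec.id in wanted), out)
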