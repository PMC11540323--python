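"""Canonical k-mer composition features.

The primary feature here is the per-read canonical tetranucleotide
count vector: every 4-mer and its reverse complement share one key,
which shrinks the feature space from 256 to 136 columns and makes a
read and its reverse complement indistinguishable — exactly what is
wanted when reads are sequenced from either strand at random. GC
content and the distinct-8-mer fraction (a repeat detector) live here
too because they share the same integer sequence encoding.

Counting is vectorised per record, so memory scales with the longest
read and the feature count, never with the number of reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .io_core import SeqRecord

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_bases(seq: str) -> np.ndarray:
    """Map a normalised sequence to integer codes A=0 C=1 G=2 T=3 N=4."""
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement integer codes for every k-window.

    Returns (forward codes, revcomp codes, validity mask); windows that
    contain an N are flagged invalid and must be ignored by callers.
    With A<C<G<T the base-4 integer order equals lexicographic order,
    so min(forward, revcomp) is the canonical code.
    """
    n = codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty, np.empty(0, dtype=bool)
    b = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd += b[j : j + n] << np.uint64(2 * (k - 1 - j))
        rc += (np.uint64(3) - np.minimum(b[j : j + n], np.uint64(3))) << np.uint64(2 * j)
    bad = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, rc, valid


def kmer_string(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def all_kmers(k: int) -> list[str]:
    """All 4^k noncanonical k-mer strings in lexicographic order."""
    return [kmer_string(c, k) for c in range(4**k)]


@dataclass(frozen=True)
class CanonicalIndex:
    """Fixed, lexicographically ordered canonical k-mer feature space.

    ``column_of`` maps every noncanonical k-mer code (0..4^k-1) to the
    column of its canonical representative, so counting is a single
    ``bincount`` after code extraction.
    """

    k: int
    keys: tuple[str, ...]
    column_of: np.ndarray = field(repr=False, compare=False)

    @property
    def n_keys(self) -> int:
        return len(self.keys)


def canonical_index(k: int) -> CanonicalIndex:
    """Build the canonical k-mer index (k=4 gives the 136-key space)."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in 1..8, got {k}")
    codes = np.arange(4**k, dtype=np.uint64)
    rc = np.zeros_like(codes)
    for j in range(k):
        rc |= (np.uint64(3) - ((codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3))) << np.uint64(2 * j)
    canon = np.minimum(codes, rc)
    canon_codes = np.unique(canon)
    keys = tuple(kmer_string(int(c), k) for c in canon_codes)
    column_of = np.searchsorted(canon_codes, canon).astype(np.uint32)
    return CanonicalIndex(k=k, keys=keys, column_of=column_of)


def count_canonical(record: SeqRecord, index: CanonicalIndex) -> tuple[np.ndarray, bool]:
    """Canonical k-mer count vector for one record.

    Returns (counts, too_short). Windows containing N are skipped; the
    vector sums to the number of valid windows.
    """
    codes = encode_bases(record.seq)
    fwd, _rc, valid = _window_codes(codes, index.k)
    if fwd.size == 0:
        return np.zeros(index.n_keys, dtype=np.int64), True
    cols = index.column_of[fwd[valid]]
    return np.bincount(cols, minlength=index.n_keys).astype(np.int64), False


@dataclass
class KmerFeatureMatrix:
    """Reads x canonical-k-mer counts with a fixed column ordering."""

    ids: list[str]
    counts: np.ndarray  # (n_reads, n_keys) int64
    index: CanonicalIndex
    too_short: np.ndarray  # bool per read

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.ids, columns=list(self.index.keys))
        df.index.name = "read_id"
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "KmerFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        k = len(df.columns[0])
        idx = canonical_index(k)
        if list(df.columns) != list(idx.keys):
            raise ValueError("count table columns do not match the canonical key ordering")
        counts = df.to_numpy(dtype=np.int64)
        return cls(
            ids=[str(i) for i in df.index],
            counts=counts,
            index=idx,
            too_short=counts.sum(axis=1) == 0,
        )


def count_matrix(
    records: Iterable[SeqRecord],
    index: CanonicalIndex,
    out: str | Path | None = None,
) -> KmerFeatureMatrix:
    """Count canonical k-mers for a stream of records.

    Rows appear in input order. Too-short records produce a zero row
    and a flag rather than aborting the stream. When ``out`` is given
    the rows are additionally streamed to a TSV as they are produced,
    keeping working memory bounded by one record plus the accumulating
    (reads x 136) integer matrix.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    flags: list[bool] = []
    writer = None
    if out is not None:
        writer = open(out, "w")
        writer.write("read_id\t" + "\t".join(index.keys) + "\n")
    try:
        for rec in records:
            vec, short = count_canonical(rec, index)
            ids.append(rec.id)
            rows.append(vec.astype(np.int32))
            flags.append(short)
            if writer is not None:
                writer.write(rec.id + "\t" + "\t".join(map(str, vec.tolist())) + "\n")
    finally:
        if writer is not None:
            writer.close()
    counts = np.vstack(rows) if rows else np.zeros((0, index.n_keys), dtype=np.int32)
    return KmerFeatureMatrix(ids=ids, counts=counts.astype(np.int64), index=index, too_short=np.array(flags, dtype=bool))


def gc_content(record: SeqRecord) -> float:
    """(G+C) / (A+C+G+T); N excluded from both sides; NaN if no ACGT bases."""
    codes = encode_bases(record.seq)
    tallies = np.bincount(codes, minlength=5)
    denom = int(tallies[:4].sum())
    if denom == 0:
        return float("nan")
    return float((tallies[1] + tallies[2]) / denom)


def unique_kmer_fraction(record: SeqRecord, k: int = 8) -> float:
    """Distinct noncanonical N-free k-mers over total N-free windows.

    The default k=8 keeps 4^k above typical HiFi read lengths, so a
    read with no internal repetition scores close to 1 while reads from
    tandem arrays score low. NaN when no valid window exists.
    """
    codes = encode_bases(record.seq)
    fwd, _rc, valid = _window_codes(codes, k)
    total = int(valid.sum())
    if total == 0:
        return float("nan")
    return float(np.unique(fwd[valid]).size / total)
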