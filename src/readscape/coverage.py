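"""Coverage estimation from whole-set k-mer multiplicities.

For accurate long reads, the median number of times a read's 31-mers
occur across the entire read set approximates its sequencing depth:
k=31 is long enough that a given substring is unlikely to recur within
one genome, yet short enough to tolerate HiFi-scale error rates. The
table is built in one pass, reads are annotated in a second pass, and
the per-coverage histogram of distinct k-mers supports the classic
"where is my target in the coverage distribution" question.

Not suitable for noisy (uncorrected CLR/ONT) reads, where most 31-mers
are unique to their read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io_core import SeqRecord
from .kmer_features import encode_bases, _window_codes

DEFAULT_K = 31
DEFAULT_CAP = 2**16 - 1


@dataclass
class MultiplicityTable:
    """Canonical k-mer -> occurrence count over a whole read set.

    Codes are 2-bit packed integers sorted ascending, so lookup is a
    binary search. Counts are capped (default 2^16-1) to bound memory
    on pathological repeats; cap events are tallied in ``n_capped``.
    """

    k: int
    codes: np.ndarray  # sorted uint64
    counts: np.ndarray  # int64, >= 1, capped
    total_windows: int  # all valid windows tallied (before capping)
    n_capped: int
    cap: int = DEFAULT_CAP

    @property
    def total_distinct(self) -> int:
        return int(self.codes.size)

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity for each query code; absent codes get 0."""
        pos = np.searchsorted(self.codes, codes)
        pos = np.clip(pos, 0, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=np.int64)
        hit = self.codes[pos] == codes
        out = np.where(hit, self.counts[pos], 0)
        return out.astype(np.int64)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tcap={self.cap}\ttotal_windows={self.total_windows}\tn_capped={self.n_capped}\n")
            for code, count in zip(self.codes.tolist(), self.counts.tolist()):
                fh.write(f"{code}\t{count}\n")

    @classmethod
    def read(cls, path: str | Path) -> "MultiplicityTable":
        with open(path) as fh:
            header = fh.readline().lstrip("#").strip()
            meta = dict(item.split("=") for item in header.split("\t"))
            data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
        codes = data[:, 0].astype(np.uint64) if data.size else np.empty(0, dtype=np.uint64)
        counts = data[:, 1] if data.size else np.empty(0, dtype=np.int64)
        return cls(
            k=int(meta["k"]),
            codes=codes,
            counts=counts,
            total_windows=int(meta["total_windows"]),
            n_capped=int(meta["n_capped"]),
            cap=int(meta["cap"]),
        )


def _canonical_window_codes(seq: str, k: int) -> np.ndarray:
    fwd, rc, valid = _window_codes(encode_bases(seq), k)
    return np.minimum(fwd[valid], rc[valid])


def build_multiplicity_table(
    records: Iterable[SeqRecord],
    k: int = DEFAULT_K,
    cap: int = DEFAULT_CAP,
    min_count: int = 1,
    chunk_windows: int = 4_000_000,
) -> MultiplicityTable:
    """Tally every N-free canonical k-mer window across a read set.

    k must be odd so no k-mer equals its own reverse complement.
    Per-chunk unique/count reduction keeps peak memory well below the
    raw window count. ``min_count`` optionally drops low-multiplicity
    k-mers (for example sequencing-error singletons) from the table.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd to avoid palindromic canonical k-mers")
    chunk_codes: list[np.ndarray] = []
    chunk_counts: list[np.ndarray] = []
    pending: list[np.ndarray] = []
    pending_size = 0
    total_windows = 0

    def _flush() -> None:
        nonlocal pending, pending_size
        if not pending:
            return
        u, c = np.unique(np.concatenate(pending), return_counts=True)
        chunk_codes.append(u)
        chunk_counts.append(c.astype(np.int64))
        pending = []
        pending_size = 0

    for rec in records:
        codes = _canonical_window_codes(rec.seq, k)
        total_windows += codes.size
        pending.append(codes)
        pending_size += codes.size
        if pending_size >= chunk_windows:
            _flush()
    _flush()

    if not chunk_codes:
        return MultiplicityTable(k=k, codes=np.empty(0, dtype=np.uint64), counts=np.empty(0, dtype=np.int64), total_windows=0, n_capped=0, cap=cap)

    merged = np.concatenate(chunk_codes)
    weights = np.concatenate(chunk_counts)
    codes, inverse = np.unique(merged, return_inverse=True)
    counts = np.zeros(codes.size, dtype=np.int64)
    np.add.at(counts, inverse, weights)
    n_capped = int((counts > cap).sum())
    counts = np.minimum(counts, cap)
    if min_count > 1:
        keep = counts >= min_count
        codes, counts = codes[keep], counts[keep]
    return MultiplicityTable(k=k, codes=codes, counts=counts, total_windows=total_windows, n_capped=n_capped, cap=cap)


def median_read_multiplicity(record: SeqRecord, table: MultiplicityTable) -> int:
    """Lower median of the whole-set multiplicities of a read's k-mers.

    Returns 0 (the flagged value) for reads with no valid window.
    """
    codes = _canonical_window_codes(record.seq, table.k)
    if codes.size == 0:
        return 0
    values = np.sort(table.lookup(codes))
    return int(values[(values.size - 1) // 2])


def annotate_multiplicities(records: Iterable[SeqRecord], table: MultiplicityTable) -> pd.Series:
    out = {rec.id: median_read_multiplicity(rec, table) for rec in records}
    return pd.Series(out, name="median_multiplicity", dtype=np.int64)


def coverage_histogram(table: MultiplicityTable) -> pd.Series:
    """Number of distinct k-mers at each multiplicity value.

    The entries sum to the table's distinct k-mer total, so the plot is
    the standard k-mer coverage (k-mer spectrum) histogram.
    """
    if table.codes.size == 0:
        return pd.Series(dtype=np.int64, name="n_distinct_kmers").rename_axis("coverage")
    values, tallies = np.unique(table.counts, return_counts=True)
    out = pd.Series(tallies.astype(np.int64), index=values.astype(np.int64), name="n_distinct_kmers")
    return out.rename_axis("coverage")


def logarithmic_bands(values: np.ndarray | pd.Series, base: float = 10.0) -> list[tuple[int, int]]:
    """Decade bands [1,9], [10,99], ... spanning the observed values."""
    arr = np.asarray(values)
    arr = arr[arr > 0]
    if arr.size == 0:
        return []
    top = int(np.floor(np.log(arr.max()) / np.log(base)))
    return [(int(base**i), int(base ** (i + 1)) - 1) for i in range(top + 1)]


def assign_coverage_bins(
    values: pd.Series,
    bands: list[tuple[int, int]] | None = None,
    scheme: str = "manual",
) -> pd.Series:
    """Label each read's multiplicity with its coverage band.

    ``bands`` are closed [low, high] intervals; they must be ordered
    and non-overlapping. Values falling in no band (including the 0
    used to flag windowless reads) get the label "outside". The
    "logarithmic" scheme derives decade bands from the data, matching
    the automated alternative to manually chosen bands.
    """
    if scheme == "logarithmic":
        bands = logarithmic_bands(values)
    if bands is None:
        raise ValueError("manual scheme requires explicit bands")
    prev_high = None
    for low, high in bands:
        if low > high:
            raise ValueError(f"band [{low}, {high}] is inverted")
        if prev_high is not None and low <= prev_high:
            raise ValueError("coverage bands overlap or are out of order")
        prev_high = high
    labels = pd.Series("outside", index=values.index, dtype=object, name="coverage_band")
    for low, high in bands:
        labels[(values >= low) & (values <= high)] = f"{low}-{high}"
    return labels
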