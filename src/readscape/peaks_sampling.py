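"""Density peaks in latent space, and read sampling around them.

Dense clusters of reads appear as local maxima of the 2D histogram of
encoder means. Peaks are found by topological persistence: sweep the
value level from high to low, track connected-component births with a
union-find, and score each birth cell by how long its component lives
before merging into a stronger one. Histogram equalisation (a rank
transform of the nonzero bins) stops the target genome's huge clusters
from drowning out small cobiont clusters.

A couple of reads sampled near each peak, exported as FASTA, is enough
to spot-check a cluster's identity with an external homology search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata


@dataclass
class LatentHistogram:
    """2D histogram over the mu bounding box (padded 1% per side)."""

    counts: np.ndarray  # (bins, bins) int64, raw read counts
    values: np.ndarray  # (bins, bins) float, equalised or equal to counts
    x_edges: np.ndarray
    y_edges: np.ndarray
    equalized: bool
    degenerate: bool = False  # all points identical

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    def bin_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            float((self.x_edges[ix] + self.x_edges[ix + 1]) / 2),
            float((self.y_edges[iy] + self.y_edges[iy + 1]) / 2),
        )

    def bin_indices(self, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin index per point; half-open bins, last bin closed."""
        ix = np.clip(np.searchsorted(self.x_edges, mu[:, 0], side="right") - 1, 0, self.bins - 1)
        iy = np.clip(np.searchsorted(self.y_edges, mu[:, 1], side="right") - 1, 0, self.bins - 1)
        return ix, iy


def _padded_edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0:
        span = max(abs(lo), 1.0) * 1e-6
    lo -= 0.01 * span
    hi += 0.01 * span
    return np.linspace(lo, hi, bins + 1)


def latent_histogram(
    embedding: pd.DataFrame,
    bins: int = 200,
    equalize: bool = True,
    smooth_sigma: float = 1.0,
) -> LatentHistogram:
    """Histogram the (mu1, mu2) embedding onto a bins x bins grid.

    Counts are conserved (every read lands in exactly one bin). The
    value surface used for peak finding is lightly Gaussian-smoothed
    (``smooth_sigma`` bins; 0 disables): without smoothing, isolated
    occupied bins on a sparse histogram never connect to their cluster
    and read as maximal-persistence peaks. With ``equalize``, nonzero
    smoothed bins are then rank-transformed to a uniform value scale in
    (0, 1]; zero bins stay zero. An embedding whose points all coincide
    yields a flagged degenerate histogram.
    """
    if len(embedding) == 0:
        raise ValueError("empty embedding")
    mu = embedding[["mu1", "mu2"]].to_numpy(dtype=np.float64)
    degenerate = bool(np.all(mu == mu[0]))
    x_edges = _padded_edges(mu[:, 0], bins)
    y_edges = _padded_edges(mu[:, 1], bins)
    counts, _, _ = np.histogram2d(mu[:, 0], mu[:, 1], bins=[x_edges, y_edges])
    counts = counts.astype(np.int64)
    values = counts.astype(np.float64)
    if smooth_sigma > 0:
        values = gaussian_filter(values, sigma=smooth_sigma)
        values[values < 1e-9] = 0.0
    if equalize:
        nz = values > 0
        if nz.any():
            ranks = rankdata(values[nz], method="average")
            values = values.copy()
            values[nz] = ranks / nz.sum()
    return LatentHistogram(counts=counts, values=values, x_edges=x_edges, y_edges=y_edges, equalized=equalize, degenerate=degenerate)


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_peaks_topology(
    hist: LatentHistogram,
    window: int = 20,
    min_persistence: float | None = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Persistence-ranked local maxima of the 2D histogram.

    Cells are activated from the highest value down; each new connected
    component is born at a local maximum, and dies when it merges into
    an older (higher-born) component. Persistence = birth - death;
    components alive at the end die at level 0. Candidate peaks closer
    than window/2 bins (Chebyshev) to a stronger peak are suppressed.
    ``min_persistence`` defaults to the median nonzero bin value.

    ``min_count`` additionally requires that many reads within the 5x5
    bin neighbourhood of the birth bin: on an equalised surface an
    isolated bin holding one or two reads is topologically a
    high-persistence component but is noise, not a cluster.

    Returns a PeakSet table sorted by descending persistence with
    columns rank, ix, iy, mu1, mu2, persistence.
    """
    V = hist.values
    n = hist.bins
    nz = V > 0
    # read mass in the 5x5 neighbourhood of each bin, via summed-area table
    sat = np.zeros((n + 1, n + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(hist.counts, axis=0), axis=1)

    def _local_mass(cx: int, cy: int, r: int = 2) -> int:
        x0, x1 = max(cx - r, 0), min(cx + r + 1, n)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, n)
        return int(sat[x1, y1] - sat[x0, y1] - sat[x1, y0] + sat[x0, y0])
    if min_persistence is None:
        min_persistence = float(np.median(V[nz])) if nz.any() else 0.0

    flat_idx = np.flatnonzero(nz.ravel())
    order = flat_idx[np.lexsort((flat_idx, -V.ravel()[flat_idx]))]

    parent = np.full(n * n, -1, dtype=np.int64)
    birth = np.zeros(n * n)
    persistence: dict[int, float] = {}

    def find(c: int) -> int:
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    for cell in order:
        v = V.flat[cell]
        cx, cy = divmod(int(cell), n)
        roots = []
        for dx, dy in _NEIGHBOURS:
            mx, my = cx + dx, cy + dy
            if 0 <= mx < n and 0 <= my < n:
                m = mx * n + my
                if parent[m] >= 0:
                    roots.append(find(m))
        if not roots:
            parent[cell] = cell
            birth[cell] = v
            continue
        roots = sorted(set(roots), key=lambda r: (-birth[r], r))
        survivor = roots[0]
        parent[cell] = survivor
        for dead in roots[1:]:
            persistence[dead] = birth[dead] - v
            parent[dead] = survivor

    for cell in order:
        if parent[cell] == cell:
            persistence[int(cell)] = birth[cell]  # never merged: dies at level 0

    rows = []
    for cell, pers in persistence.items():
        if pers < min_persistence:
            continue
        ix, iy = divmod(cell, n)
        if _local_mass(ix, iy) < min_count:
            continue
        mu1, mu2 = hist.bin_center(ix, iy)
        rows.append((ix, iy, mu1, mu2, pers))
    rows.sort(key=lambda r: (-r[4], r[0], r[1]))

    kept: list[tuple] = []
    radius = window / 2
    for row in rows:
        if all(max(abs(row[0] - k[0]), abs(row[1] - k[1])) >= radius for k in kept):
            kept.append(row)
    peaks = pd.DataFrame(kept, columns=["ix", "iy", "mu1", "mu2", "persistence"])
    peaks.insert(0, "rank", np.arange(1, len(peaks) + 1))
    return peaks


def sample_reads_near_peaks(
    peaks: pd.DataFrame,
    embedding: pd.DataFrame,
    hist: LatentHistogram,
    n_per_peak: int = 2,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Uniformly sample read ids around each peak (seeded, reproducible).

    Candidates start in the peak's own bin; if fewer than ``n_per_peak``
    reads fall there, the search radius grows one bin ring at a time
    (Chebyshev rings) until enough candidates exist. If the whole
    embedding holds fewer reads than requested, whatever exists is
    returned. Keyed by peak rank.
    """
    rng = np.random.default_rng(seed)
    mu = embedding[["mu1", "mu2"]].to_numpy(dtype=np.float64)
    ids = np.asarray(embedding.index, dtype=object)
    ix, iy = hist.bin_indices(mu)
    out: dict[int, list[str]] = {}
    for _, peak in peaks.sort_values("rank").iterrows():
        if n_per_peak == 0:
            out[int(peak["rank"])] = []
            continue
        dist = np.maximum(np.abs(ix - int(peak["ix"])), np.abs(iy - int(peak["iy"])))
        if dist.size == 0:
            out[int(peak["rank"])] = []
            continue
        take = min(n_per_peak, dist.size)
        radius = int(np.sort(dist)[take - 1])
        # reads strictly inside the final ring are all kept; the open
        # slots are sampled uniformly from the boundary ring itself
        inner = ids[dist < radius]
        boundary = ids[dist == radius]
        n_boundary = take - inner.size
        chosen = list(inner) + list(rng.choice(boundary, size=n_boundary, replace=False))
        out[int(peak["rank"])] = [str(c) for c in chosen]
    return out
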