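"""Static annotated views of the latent space and coverage spectrum.

Scatter rendering follows the large-data aggregation idiom: points are
binned onto a pixel grid, each pixel is coloured by its most frequent
category with brightness following log point density, and the image is
written directly as PNG. Millions of reads render in memory bounded by
the pixel grid, and identical inputs give byte-identical files.

Continuous statistics (coding density, GC, ...) are first binned into
quantiles so each colour carries an equal share of reads; coverage
bands share one palette between the scatter and the banded coverage
histogram so the two views cross-reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

UNASSIGNED_LABEL = "unassigned"
_UNASSIGNED_RGB = (128, 128, 128)


@dataclass
class QuantileBinning:
    """Quantile-edge binning of a continuous statistic.

    Duplicate quantile edges (mass points, typically zeros) collapse
    adjacent bins; ``merged_bins`` records how many requested bins were
    lost that way.
    """

    edges: np.ndarray
    labels: np.ndarray  # int bin per value, -1 for non-finite
    n_bins: int
    merged_bins: int
    single_bin: bool = False

    @property
    def label_names(self) -> list[str]:
        return [f"q{i}" for i in range(self.n_bins)]

    def label_strings(self) -> np.ndarray:
        return np.where(self.labels >= 0, np.char.add("q", self.labels.astype(str)), UNASSIGNED_LABEL)


def quantile_bins(values: np.ndarray | pd.Series, n_bins: int = 10) -> QuantileBinning:
    """Bin values at empirical quantiles (deciles by default)."""
    arr = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("need at least one finite value")
    qs = np.quantile(arr[finite], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    labels = np.full(arr.size, -1, dtype=np.int64)
    if edges.size < 2:
        labels[finite] = 0
        return QuantileBinning(edges=edges, labels=labels, n_bins=1, merged_bins=n_bins - 1, single_bin=True)
    inner = edges[1:-1]
    labels[finite] = np.searchsorted(inner, arr[finite], side="right")
    eff = edges.size - 1
    return QuantileBinning(edges=edges, labels=labels, n_bins=eff, merged_bins=n_bins - eff)


def category_palette(categories: list[str]) -> dict[str, tuple[int, int, int]]:
    """Stable label -> RGB map; the unassigned label is always gray."""
    cmap = colormaps["tab10"]
    out: dict[str, tuple[int, int, int]] = {}
    i = 0
    for cat in categories:
        if cat == UNASSIGNED_LABEL or cat == "outside":
            out[cat] = _UNASSIGNED_RGB
        else:
            r, g, b, _ = cmap(i % 10)
            out[cat] = (int(r * 255), int(g * 255), int(b * 255))
            i += 1
    return out


def render_scatter(
    embedding: pd.DataFrame,
    colors: pd.Series | None = None,
    out: str | Path = "scatter.png",
    size: int = 800,
    point_scale: str = "none",
    lengths: pd.Series | None = None,
    palette: dict[str, tuple[int, int, int]] | None = None,
) -> Path:
    """Rasterise the latent scatter by per-pixel category aggregation.

    Each pixel is coloured by its most frequent category (gray for
    unassigned) with intensity proportional to log point density.
    ``point_scale="by-length"`` weights each read by its length, the
    raster analogue of size-scaled markers. Colour labels must align
    with the embedding index; mismatches raise with the first offending
    ids named.
    """
    if len(embedding) == 0:
        raise ValueError("empty embedding")
    mu = embedding[["mu1", "mu2"]].to_numpy(dtype=np.float64)
    if colors is None:
        colors = pd.Series("all", index=embedding.index)
    missing = embedding.index.difference(colors.index)
    if len(missing) > 0:
        raise ValueError(f"color labels missing for ids: {list(missing[:5])}")
    labels = colors.reindex(embedding.index).fillna(UNASSIGNED_LABEL).astype(str).to_numpy()

    if point_scale == "by-length":
        if lengths is None:
            raise ValueError("point_scale='by-length' requires lengths")
        weights = lengths.reindex(embedding.index).fillna(0).to_numpy(dtype=np.float64)
    else:
        weights = np.ones(len(embedding))

    lo = mu.min(axis=0)
    hi = mu.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    px = np.clip(((mu[:, 0] - lo[0]) / span[0] * (size - 1)).astype(np.int64), 0, size - 1)
    py = np.clip(((mu[:, 1] - lo[1]) / span[1] * (size - 1)).astype(np.int64), 0, size - 1)

    cats = sorted(set(labels))
    if palette is None:
        palette = category_palette(cats)
    acc = np.zeros((len(cats), size, size))
    for ci, cat in enumerate(cats):
        sel = labels == cat
        np.add.at(acc[ci], (py[sel], px[sel]), weights[sel])
    total = acc.sum(axis=0)
    winner = acc.argmax(axis=0)
    intensity = np.zeros_like(total)
    occupied = total > 0
    if occupied.any():
        intensity[occupied] = np.log1p(total[occupied]) / np.log1p(total.max())

    rgb = np.zeros((size, size, 3), dtype=np.uint8)
    colors_arr = np.array([palette[c] for c in cats], dtype=np.float64)
    pixel_colors = colors_arr[winner] * intensity[..., None]
    rgb[occupied] = pixel_colors[occupied].astype(np.uint8)
    # image row 0 at the top: flip the y axis so mu2 increases upward
    img = Image.fromarray(rgb[::-1, :, :])
    out = Path(out)
    img.save(out, format="PNG")
    return out


def filter_by_coverage(
    embedding: pd.DataFrame,
    annotation: pd.DataFrame,
    low: float,
    high: float,
) -> pd.DataFrame:
    """Reads whose median k-mer multiplicity lies in the closed range."""
    if low > high:
        raise ValueError(f"inverted coverage range [{low}, {high}]")
    cov = annotation["median_multiplicity"].reindex(embedding.index)
    keep = (cov >= low) & (cov <= high)
    return embedding.loc[keep.fillna(False)]


def banded_coverage_plot(
    hist: pd.Series,
    bands: list[tuple[int, int]],
    out: str | Path = "coverage_hist.png",
    palette: dict[str, tuple[int, int, int]] | None = None,
    log_axes: bool = True,
) -> Path:
    """Coverage spectrum with bars coloured by coverage band.

    Shares :func:`category_palette` with the latent scatter, so a band
    has the same colour in both views.
    """
    if len(hist) == 0:
        raise ValueError("empty coverage histogram")
    band_labels = [f"{lo}-{hi}" for lo, hi in bands]
    if palette is None:
        palette = category_palette([*band_labels, "outside"])
    coverages = hist.index.to_numpy()
    bar_colors = []
    for c in coverages:
        label = "outside"
        for (lo_b, hi_b), name in zip(bands, band_labels):
            if lo_b <= c <= hi_b:
                label = name
                break
        bar_colors.append(tuple(v / 255 for v in palette[label]))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(coverages, hist.to_numpy(), color=bar_colors, width=np.maximum(1, 0.03 * coverages) if log_axes else 1)
    if log_axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("k-mer multiplicity (coverage)")
    ax.set_ylabel("distinct k-mers")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return out
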