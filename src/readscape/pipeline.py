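"""End-to-end workflow: counts -> annotations -> embedding -> peaks -> plots.

Every stage writes its table to the output directory and is skipped on
re-runs when its outputs already exist (use ``force`` to recompute).
All randomness fans out from one global seed by hashing stage names,
so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import read_seq_file, write_table, read_table, read_label_table, export_fasta_subset
from .kmer_features import (
    canonical_index,
    count_matrix,
    gc_content,
    unique_kmer_fraction,
    KmerFeatureMatrix,
)
from .coverage import (
    build_multiplicity_table,
    median_read_multiplicity,
    coverage_histogram,
    assign_coverage_bins,
)
from .coding_density import CodingConfig, HexamerTable, train_hexamer_table, coding_density
from .embedding import VAEConfig, preprocess_features, train_vae, encode, embedding_frame
from .peaks_sampling import latent_histogram, find_peaks_topology, sample_reads_near_peaks
from .visualization import quantile_bins, render_scatter, banded_coverage_plot, UNASSIGNED_LABEL
from .coverage import logarithmic_bands

logger = logging.getLogger("readscape")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the published workflow values."""

    reads: str
    outdir: str
    labels: str | None = None
    coding_fasta: str | None = None
    feature_k: int = 4
    coverage_k: int = 31
    unique_k: int = 8
    coding: CodingConfig = field(default_factory=CodingConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)
    bins: int = 200
    window: int = 20
    n_per_peak: int = 2
    seed: int = 0
    force: bool = False


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hashing the stage name decouples stages."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


def merge_annotations(tables: list[pd.Series | pd.DataFrame], labels: pd.Series | None = None) -> pd.DataFrame:
    """Outer-join per-stage statistics on read id.

    Missing statistics stay NaN (flagged); reads without a class label
    get "unassigned". Zero id overlap between tables is an error.
    """
    frames = [t.to_frame() if isinstance(t, pd.Series) else t for t in tables]
    merged = frames[0]
    for frame in frames[1:]:
        if len(merged.index.intersection(frame.index)) == 0:
            raise ValueError("annotation tables share no read ids")
        merged = merged.join(frame, how="outer")
    if labels is not None:
        merged["class_label"] = labels.reindex(merged.index).fillna(UNASSIGNED_LABEL)
    else:
        merged["class_label"] = UNASSIGNED_LABEL
    merged.index.name = "read_id"
    return merged


def run_all(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Stage order: count -> per-read stats (gc, length, distinct-8-mer
    fraction) -> coverage -> coding density -> embed -> merge ->
    peaks + sampling -> plots -> manifest.
    """
    reads_path = Path(config.reads)
    if not reads_path.exists():
        raise FileNotFoundError(f"reads file not found: {reads_path}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _config_dict(config), "stages": {}}

    def _done(*paths: Path) -> bool:
        return not config.force and all(p.exists() for p in paths)

    # ---- stage: canonical k-mer counts ---------------------------------
    counts_path = out / "counts.tsv"
    idx = canonical_index(config.feature_k)
    if _done(counts_path):
        logger.info("count: reusing %s", counts_path)
        matrix = KmerFeatureMatrix.read(counts_path)
    else:
        logger.info("count: canonical %d-mer counts", config.feature_k)
        matrix = count_matrix(read_seq_file(reads_path), idx, out=counts_path)
    manifest["stages"]["count"] = {"rows": len(matrix.ids), "too_short": int(matrix.too_short.sum())}

    # ---- stage: per-read sequence statistics ---------------------------
    stats_path = out / "read_stats.tsv"
    if _done(stats_path):
        stats = read_table(stats_path)
    else:
        rows = {}
        for rec in read_seq_file(reads_path):
            rows[rec.id] = {
                "length": rec.length,
                "gc": gc_content(rec),
                "unique_kmer_fraction": unique_kmer_fraction(rec, config.unique_k),
            }
        stats = pd.DataFrame.from_dict(rows, orient="index")
        stats.index.name = "read_id"
        write_table(stats, stats_path)
    manifest["stages"]["stats"] = {"rows": len(stats)}

    # ---- stage: coverage ------------------------------------------------
    cov_path = out / "median_multiplicity.tsv"
    hist_path = out / "coverage_histogram.tsv"
    if _done(cov_path, hist_path):
        medians = read_table(cov_path)["median_multiplicity"]
        cov_hist = read_table(hist_path)["n_distinct_kmers"]
    else:
        logger.info("coverage: building %d-mer multiplicity table", config.coverage_k)
        table = build_multiplicity_table(read_seq_file(reads_path), k=config.coverage_k)
        medians = pd.Series(
            {rec.id: median_read_multiplicity(rec, table) for rec in read_seq_file(reads_path)},
            name="median_multiplicity",
        )
        medians.index.name = "read_id"
        write_table(medians.to_frame(), cov_path)
        cov_hist = coverage_histogram(table)
        write_table(cov_hist.to_frame(), hist_path)
    manifest["stages"]["coverage"] = {"rows": len(medians), "distinct_kmers": int(cov_hist.sum())}

    # ---- stage: coding density ------------------------------------------
    hex_path = out / "hexamer_table.tsv"
    dens_path = out / "coding_density.tsv"
    if _done(dens_path):
        density = read_table(dens_path)["coding_density"]
    else:
        if _done(hex_path):
            table = HexamerTable.read(hex_path)
        elif config.coding_fasta is not None:
            table = train_hexamer_table(read_seq_file(config.coding_fasta), source=str(config.coding_fasta))
            table.write(hex_path)
        else:
            from .synthetic_data import simulate_coding_training_set

            logger.info("density: no coding FASTA given; training on synthetic coding sequence")
            table = train_hexamer_table(
                simulate_coding_training_set(seed=stage_seed(config.seed, "hexamer")),
                source="synthetic-codon-model",
            )
            table.write(hex_path)
        density = pd.Series(
            {rec.id: coding_density(rec, table, config.coding) for rec in read_seq_file(reads_path)},
            name="coding_density",
        )
        density.index.name = "read_id"
        write_table(density.to_frame(), dens_path)
    manifest["stages"]["density"] = {"rows": len(density)}

    # ---- stage: embedding -----------------------------------------------
    emb_path = out / "embedding.tsv"
    model_path = out / "model.npz"
    usable = ~matrix.too_short
    if _done(emb_path, model_path):
        emb = read_table(emb_path)
    else:
        logger.info("embed: training beta-VAE (beta=%g, %d epochs)", config.vae.beta, config.vae.epochs)
        features, scaler = preprocess_features(matrix.counts[usable])
        vae_cfg = VAEConfig(**{**asdict(config.vae), "seed": stage_seed(config.seed, "embed")})
        model, history = train_vae(features, vae_cfg, scaler=scaler)
        model.save(model_path)
        history.to_csv(out / "training_loss.tsv", sep="\t")
        enc = encode(features, model)
        emb = embedding_frame([i for i, u in zip(matrix.ids, usable) if u], enc)
        write_table(emb, emb_path)
    manifest["stages"]["embed"] = {"rows": len(emb), "excluded_too_short": int((~usable).sum())}

    # ---- stage: merged annotation table ---------------------------------
    ann_path = out / "annotation.tsv"
    labels = read_label_table(config.labels) if config.labels else None
    annotation = merge_annotations([stats, medians, density], labels=labels)
    write_table(annotation, ann_path)
    manifest["stages"]["merge"] = {"rows": len(annotation)}

    # ---- stage: peaks and sampling --------------------------------------
    peaks_path = out / "peaks.tsv"
    sampled_fasta = out / "sampled_reads.fasta"
    hist = latent_histogram(emb, bins=config.bins, equalize=True)
    peaks = find_peaks_topology(hist, window=config.window)
    samples = sample_reads_near_peaks(
        peaks, emb, hist, n_per_peak=config.n_per_peak, seed=stage_seed(config.seed, "peaks")
    )
    peaks["n_reads_sampled"] = [len(samples.get(r, [])) for r in peaks["rank"]]
    peaks.set_index("rank").to_csv(peaks_path, sep="\t")
    sampled_ids = [rid for ids in samples.values() for rid in ids]
    n_written = export_fasta_subset(reads_path, sampled_ids, sampled_fasta)
    with open(out / "peak_samples.tsv", "w") as fh:
        fh.write("rank\tread_id\n")
        for rank, ids in samples.items():
            for rid in ids:
                fh.write(f"{rank}\t{rid}\n")
    manifest["stages"]["peaks"] = {"n_peaks": len(peaks), "n_sampled": n_written}

    # ---- stage: plots ---------------------------------------------------
    dens_bins = quantile_bins(annotation.loc[emb.index, "coding_density"].to_numpy())
    render_scatter(
        emb,
        pd.Series(dens_bins.label_strings(), index=emb.index),
        out=out / "scatter_coding_density.png",
    )
    bands = logarithmic_bands(medians)
    band_labels = assign_coverage_bins(medians, bands)
    render_scatter(emb, band_labels.reindex(emb.index), out=out / "scatter_coverage.png")
    render_scatter(emb, annotation["class_label"].reindex(emb.index), out=out / "scatter_labels.png")
    banded_coverage_plot(cov_hist, bands, out=out / "coverage_histogram.png")
    manifest["stages"]["plots"] = {"n_png": 4}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
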