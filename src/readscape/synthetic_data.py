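"""Synthetic labelled read mixtures with the structure the method assumes.

A wild-caught sample behaves like: one large, compositionally
heterogeneous, low-coding-density host genome at moderate coverage;
one or more compact, homogeneous, coding-dense cobionts at distinct GC
and coverage; a tiny organelle at extreme coverage; optional low-
coverage contaminants; and repeat arrays inside the host. Every
generator here is deterministic given its seed and emits ground truth
(read id -> source component, position, strand) so each pipeline stage
can be scored without external data.

Genome lengths are scaled down ~100x from realistic values so full
pipeline runs take minutes; coverages stay realistic so coverage-based
contrasts survive the scaling. Coding sequence is simulated from a
seeded biased codon-usage model (shared codon bias, per-component GC),
which doubles as training material for the hexamer scoring table — a
synthetic stand-in for a real coding-sequence reference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_core import SeqRecord, write_fasta
from .kmer_features import revcomp

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in _STOPS]
# one fixed codon-preference draw shared by every component, so coding blocks
# carry a common hexamer signature regardless of their GC
_CODON_BIAS = np.random.default_rng(20240817).lognormal(mean=0.0, sigma=1.2, size=len(_CODONS))


def _component_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def codon_usage(gc: float) -> np.ndarray:
    """Codon probabilities with the shared bias, tuned to hit the GC target.

    The raw product of per-base probabilities and the fixed bias drifts
    off the GC target, so the effective base composition is found by
    bisection until the usage's expected GC matches ``gc``.
    """
    codon_gc = np.array([sum(b in "GC" for b in c) / 3 for c in _CODONS])

    def usage_for(g: float) -> np.ndarray:
        pb = {"A": (1 - g) / 2, "T": (1 - g) / 2, "G": g / 2, "C": g / 2}
        w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in _CODONS]) * _CODON_BIAS
        return w / w.sum()

    lo, hi = 0.02, 0.98
    for _ in range(50):
        mid = (lo + hi) / 2
        if float(usage_for(mid) @ codon_gc) < gc:
            lo = mid
        else:
            hi = mid
    return usage_for((lo + hi) / 2)


def sample_coding(n_bases: int, gc: float, rng: np.random.Generator) -> str:
    """Simulate in-frame coding sequence by drawing iid biased codons."""
    n_codons = int(np.ceil(n_bases / 3))
    picks = rng.choice(len(_CODONS), size=n_codons, p=codon_usage(gc))
    return "".join(_CODONS[i] for i in picks)[:n_bases]


def simulate_coding_training_set(
    n_records: int = 200,
    n_codons: int = 500,
    gc: float = 0.40,
    seed: int = 7,
) -> list[SeqRecord]:
    """Synthetic coding-sequence FASTA substitute for hexamer training."""
    rng = np.random.default_rng(seed)
    return [SeqRecord(id=f"cds_{i}", seq=sample_coding(3 * n_codons, gc, rng)) for i in range(n_records)]


@dataclass
class ComponentSpec:
    """One source genome of a mixture and its sequencing parameters."""

    name: str
    genome_length: int
    gc: float
    coverage: float
    markov_order: int = 1
    n_blocks: int = 1  # compositional heterogeneity: GC blocks
    gc_spread: float = 0.0
    coding_fraction: float = 0.0
    repeat_spec: tuple[int, int] | None = None  # (unit length, copy number)
    read_length_mean: int = 10_000
    read_length_sd: int = 1_500
    error_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.coding_fraction > 1:
            raise ValueError("coding_fraction cannot exceed 1")
        if self.markov_order not in (0, 1, 2):
            raise ValueError("markov_order must be 0, 1 or 2")


def _background(length: int, gc: float, markov_order: int, rng: np.random.Generator) -> np.ndarray:
    """GC-exact background: strong/weak drawn iid, within-group chain.

    The S/W (G+C vs A+T) choice is iid Bernoulli(gc), so realised GC
    concentrates tightly on the target. Within each group the base
    choice is a two-state chain whose repeat probability grows with the
    Markov order, giving order-dependent short-range structure without
    disturbing GC.
    """
    strong = rng.random(length) < gc
    out = np.empty(length, dtype="<U1")
    repeat_p = 0.5 + 0.12 * markov_order
    for is_strong, (b0, b1) in ((True, ("C", "G")), (False, ("A", "T"))):
        idx = np.flatnonzero(strong == is_strong)
        if idx.size == 0:
            continue
        flips = rng.random(idx.size) >= repeat_p
        flips[0] = rng.random() < 0.5
        state = np.cumsum(flips) % 2
        out[idx] = np.where(state == 0, b0, b1)
    return out


def _plant_coding_blocks(
    genome: np.ndarray,
    fraction: float,
    gc: float,
    rng: np.random.Generator,
    mean_block: int = 900,
) -> list[tuple[int, int, str]]:
    length = genome.size
    target = int(fraction * length)
    blocks: list[int] = []
    total = 0
    while total < target:
        b = int(np.clip(rng.exponential(mean_block), 300, 3000))
        b -= b % 3
        b = min(b, target - total) if target - total >= 300 else (target - total)
        if b < 6:
            break
        blocks.append(b)
        total += b
    if not blocks:
        return []
    gap_total = length - total
    cuts = np.sort(rng.integers(0, gap_total + 1, size=len(blocks)))
    gaps = np.diff(np.concatenate(([0], cuts, [gap_total])))
    coords: list[tuple[int, int, str]] = []
    pos = 0
    for gap, block in zip(gaps, blocks):
        pos += gap
        seq = sample_coding(block, gc, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        genome[pos : pos + block] = list(seq)
        coords.append((pos, pos + block, strand))
        pos += block
    return coords


def generate_genome(spec: ComponentSpec, seed: int | None = None) -> tuple[SeqRecord, dict]:
    """Simulate one component genome; returns the record plus feature coords.

    GC heterogeneity comes from ``n_blocks`` equal-sized blocks with GC
    values spread linearly over gc +/- gc_spread/2; coding blocks are
    planted at codon stride from the shared codon model; tandem repeat
    arrays overwrite a random window. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed if spec.seed is not None else seed)
    block_gcs = (
        np.linspace(spec.gc - spec.gc_spread / 2, spec.gc + spec.gc_spread / 2, spec.n_blocks)
        if spec.n_blocks > 1
        else np.array([spec.gc])
    )
    bounds = np.linspace(0, spec.genome_length, block_gcs.size + 1).astype(int)
    parts = [
        _background(hi - lo, g, spec.markov_order, rng)
        for lo, hi, g in zip(bounds[:-1], bounds[1:], block_gcs)
    ]
    genome = np.concatenate(parts)
    features: dict = {
        "blocks": [(int(lo), int(hi), float(g)) for lo, hi, g in zip(bounds[:-1], bounds[1:], block_gcs)],
        "coding": [],
        "repeats": [],
    }
    if spec.coding_fraction > 0:
        features["coding"] = _plant_coding_blocks(genome, spec.coding_fraction, spec.gc, rng)
    if spec.repeat_spec is not None:
        unit_len, copies = spec.repeat_spec
        array_len = unit_len * copies
        if array_len > spec.genome_length:
            raise ValueError("repeat array longer than genome")
        unit = _background(unit_len, spec.gc, spec.markov_order, rng)
        start = int(rng.integers(0, spec.genome_length - array_len + 1))
        genome[start : start + array_len] = np.tile(unit, copies)
        features["repeats"] = [(start, start + array_len)]
    return SeqRecord(id=spec.name, seq="".join(genome)), features


def simulate_reads(
    genome: SeqRecord,
    spec: ComponentSpec,
    rng: np.random.Generator,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """HiFi-like reads: long, near-exact, uniform starts, random strand.

    The genome is treated as circular (reads wrap around the origin),
    which gives uniform depth everywhere — exact for organelles and
    bacteria, and a harmless convenience for the scaled-down host.
    Lengths are truncated-normal, substitution errors only (no indels —
    at HiFi error rates substitutions are what stress 31-mer counting).
    Read count = coverage * genome length / mean read length.
    """
    L = genome.length
    if L <= spec.read_length_mean:
        raise ValueError("genome shorter than mean read length")
    n_reads = max(1, int(round(spec.coverage * L / spec.read_length_mean)))
    lmin = min(500, L)
    lengths = np.clip(
        np.round(rng.normal(spec.read_length_mean, spec.read_length_sd, size=n_reads)).astype(int), lmin, L
    )
    records: list[SeqRecord] = []
    truth_rows = []
    base_arr = np.frombuffer((genome.seq + genome.seq).encode(), dtype="S1")
    for i in range(n_reads):
        rl = int(lengths[i])
        start = int(rng.integers(0, L))
        seq_bytes = base_arr[start : start + rl].copy()
        if spec.error_rate > 0:
            n_err = rng.binomial(rl, spec.error_rate)
            if n_err:
                pos = rng.choice(rl, size=n_err, replace=False)
                originals = np.char.decode(seq_bytes[pos].astype("S1"))
                subs = _BASES[rng.integers(0, 3, size=n_err)]
                # shift picks that hit the original base so errors always change it
                clash = subs == originals
                subs[clash] = _BASES[(np.searchsorted(_BASES, originals[clash]) + 3) % 4]
                seq_bytes[pos] = np.char.encode(subs)
        seq = seq_bytes.tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"{spec.name}:{i}"
        records.append(SeqRecord(id=rid, seq=seq))
        truth_rows.append((rid, spec.name, start, strand))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "component", "start", "strand"]).set_index("read_id")
    return records, truth


def generate_mixture(
    specs: list[ComponentSpec],
    seed: int = 0,
    out_prefix: str | Path | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate all components and interleave their reads in random order.

    Per-component randomness derives from (seed, component name), so
    adding a component never changes the others' reads. Read ids are
    anonymised to read_NNNNNNN after shuffling; the truth table maps
    them back. With ``out_prefix``, writes FASTA, truth TSV and a YAML
    echo of the specs.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("component names must be unique")
    all_records: list[SeqRecord] = []
    truths: list[pd.DataFrame] = []
    for spec in specs:
        rng = _component_rng(seed, spec.name)
        genome, _features = generate_genome(spec, seed=int(rng.integers(2**31)))
        records, truth = simulate_reads(genome, spec, rng)
        all_records.extend(records)
        truths.append(truth)
    truth = pd.concat(truths)
    order = _component_rng(seed, "interleave").permutation(len(all_records))
    shuffled = [all_records[i] for i in order]
    new_ids = {rec.id: f"read_{i:07d}" for i, rec in enumerate(shuffled)}
    shuffled = [SeqRecord(id=new_ids[rec.id], seq=rec.seq) for rec in shuffled]
    truth = truth.rename(index=new_ids).loc[[rec.id for rec in shuffled]]
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(shuffled, prefix.with_suffix(".fasta"))
        truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t")
        with open(prefix.with_suffix(".spec.yaml"), "w") as fh:
            yaml.safe_dump({"seed": seed, "components": [asdict(s) for s in specs]}, fh, sort_keys=False)
    return shuffled, truth


def mixed_sample_preset() -> list[ComponentSpec]:
    """The bundled mixed-sample scenario used throughout the tests.

    Host: large (300 kb, ~100x scaled down), heterogeneous GC, sparse
    coding, tandem repeat array, 30x. Endosymbiont: compact, AT-shifted,
    coding-dense, 120x. Organelle: tiny, very AT-rich, 2000x.
    Contaminant: GC-rich bacterium at 3x.
    """
    return [
        ComponentSpec(
            name="host", genome_length=300_000, gc=0.40, coverage=30, n_blocks=5, gc_spread=0.10,
            coding_fraction=0.20, repeat_spec=(200, 100), error_rate=0.001,
        ),
        ComponentSpec(
            name="endosymbiont", genome_length=150_000, gc=0.28, coverage=120,
            coding_fraction=0.90, error_rate=0.001,
        ),
        ComponentSpec(
            name="organelle", genome_length=16_000, gc=0.18, coverage=2000,
            coding_fraction=0.35, read_length_mean=8_000, read_length_sd=1_000, error_rate=0.001,
        ),
        ComponentSpec(
            name="contaminant", genome_length=100_000, gc=0.58, coverage=3,
            coding_fraction=0.85, error_rate=0.001,
        ),
    ]


def gc_gradient_preset(
    n_components: int = 9,
    gc_low: float = 0.25,
    gc_high: float = 0.60,
    genome_length: int = 60_000,
    coverage: float = 20,
    read_length: int = 2_000,
) -> list[ComponentSpec]:
    """Homogeneous components spanning a GC gradient (latent-axis probe)."""
    return [
        ComponentSpec(
            name=f"gc{gc:.3f}", genome_length=genome_length, gc=float(gc), coverage=coverage,
            read_length_mean=read_length, read_length_sd=read_length // 8,
        )
        for gc in np.linspace(gc_low, gc_high, n_components)
    ]
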