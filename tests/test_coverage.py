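"""Multiplicity tables vs naive recount; coverage recovery on simulations."""

import numpy as np
import pandas as pd
import pytest

from readscape.io_core import SeqRecord
from readscape.coverage import (
    MultiplicityTable,
    build_multiplicity_table,
    median_read_multiplicity,
    coverage_histogram,
    assign_coverage_bins,
    logarithmic_bands,
)
from readscape.kmer_features import revcomp
from .conftest import random_record


def naive_multiplicity(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            key = min(w, revcomp(w))
            counts[key] = counts.get(key, 0) + 1
    return counts


def naive_median(seq: str, table: dict[str, int], k: int) -> int:
    values = sorted(
        table.get(min(seq[i : i + k], revcomp(seq[i : i + k])), 0)
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    )
    return values[(len(values) - 1) // 2]


def test_five_copy_toy_set(rng):
    base = random_record(rng, 1000, rid="g").seq
    records = [SeqRecord(f"c{i}", base) for i in range(5)]
    table = build_multiplicity_table(records)
    assert table.total_distinct == 970
    assert np.all(table.counts == 5)
    assert median_read_multiplicity(records[0], table) == 5
    hist = coverage_histogram(table)
    assert dict(hist) == {5: 970}


def test_single_read_conservation(rng):
    rec = random_record(rng, 800, rid="r")
    table = build_multiplicity_table([rec])
    assert np.all(table.counts >= 1)
    assert int(table.counts.sum()) == table.total_windows == 800 - 31 + 1


def test_revcomp_pair_equals_forward_pair(rng):
    rec = random_record(rng, 500, rid="f")
    t_fwd = build_multiplicity_table([rec, rec])
    t_rc = build_multiplicity_table([rec, SeqRecord("rc", revcomp(rec.seq))])
    assert np.array_equal(t_fwd.codes, t_rc.codes)
    assert np.array_equal(t_fwd.counts, t_rc.counts)


def test_table_matches_naive_oracle(rng):
    records = [random_record(rng, int(rng.integers(60, 300)), rid=f"r{i}") for i in range(15)]
    k = 31
    table = build_multiplicity_table(records, k=k)
    naive = naive_multiplicity([r.seq for r in records], k)
    assert table.total_distinct == len(naive)
    assert int(table.counts.sum()) == sum(naive.values())
    for rec in records[:5]:
        assert median_read_multiplicity(rec, table) == naive_median(rec.seq, naive, k)


def test_lower_median_on_even_and_skewed_counts():
    # construct a read whose windows have multiplicities [1, 1, 9]
    # via a direct synthetic table
    codes = np.array([5, 10, 20], dtype=np.uint64)
    counts = np.array([1, 1, 9], dtype=np.int64)
    table = MultiplicityTable(k=31, codes=codes, counts=counts, total_windows=11, n_capped=0)
    values = np.sort(table.lookup(codes))
    assert values[(values.size - 1) // 2] == 1


def test_even_k_rejected():
    with pytest.raises(ValueError):
        build_multiplicity_table([], k=30)


def test_empty_table_histogram():
    table = build_multiplicity_table([])
    assert len(coverage_histogram(table)) == 0


def test_two_disjoint_components_two_bars(rng):
    g1 = random_record(rng, 400, rid="g1", gc=0.3).seq
    g2 = random_record(rng, 400, rid="g2", gc=0.7).seq
    records = [SeqRecord(f"a{i}", g1) for i in range(5)] + [SeqRecord(f"b{i}", g2) for i in range(2)]
    table = build_multiplicity_table(records)
    hist = coverage_histogram(table)
    assert set(hist.index) == {2, 5}
    assert int(hist.sum()) == table.total_distinct


def test_count_cap_and_overflow_tally(rng):
    rec = random_record(rng, 200, rid="r")
    table = build_multiplicity_table([rec] * 10, cap=5)
    assert table.counts.max() == 5
    assert table.n_capped == table.total_distinct


def test_min_count_filter(rng):
    shared = random_record(rng, 100, rid="s").seq
    solo = random_record(rng, 100, rid="o").seq
    table = build_multiplicity_table([SeqRecord("a", shared), SeqRecord("b", shared), SeqRecord("c", solo)], min_count=2)
    assert np.all(table.counts >= 2)


def test_table_file_round_trip(tmp_path, rng):
    records = [random_record(rng, 200, rid=f"r{i}") for i in range(4)]
    table = build_multiplicity_table(records)
    path = tmp_path / "mult.tsv"
    table.write(path)
    back = MultiplicityTable.read(path)
    assert back.k == table.k
    assert np.array_equal(back.codes, table.codes)
    assert np.array_equal(back.counts, table.counts)
    assert back.total_windows == table.total_windows


def test_coverage_bins_manual_and_log():
    values = pd.Series([7, 50, 0, 1000], index=["a", "b", "c", "d"])
    labels = assign_coverage_bins(values, bands=[(1, 10), (11, 100)])
    assert labels["a"] == "1-10"
    assert labels["b"] == "11-100"
    assert labels["c"] == "outside"
    assert labels["d"] == "outside"
    with pytest.raises(ValueError):
        assign_coverage_bins(values, bands=[(1, 10), (5, 100)])
    with pytest.raises(ValueError):
        assign_coverage_bins(values, bands=[(10, 1)])
    log_labels = assign_coverage_bins(pd.Series([1, 10, 100]), scheme="logarithmic")
    assert log_labels.nunique() == 3
    assert logarithmic_bands(np.array([1, 10, 100])) == [(1, 9), (10, 99), (100, 999)]


def test_hifi_error_rate_barely_shifts_medians():
    # at 0.1% substitutions a 31-mer occurrence is error-free with
    # probability 0.999^31 ~ 0.97, so multiplicities (and the medians
    # built on them) drop by ~3% of coverage, not more
    from readscape.synthetic_data import ComponentSpec, generate_genome, simulate_reads

    means = {}
    for err in (0.0, 0.001):
        spec = ComponentSpec(
            name="e", genome_length=60_000, gc=0.4, coverage=25,
            read_length_mean=12_000, read_length_sd=500, error_rate=err, seed=33,
        )
        genome, _ = generate_genome(spec, seed=33)
        reads, _ = simulate_reads(genome, spec, np.random.default_rng(34))
        table = build_multiplicity_table(reads)
        means[err] = np.mean([median_read_multiplicity(r, table) for r in reads])
    shift = means[0.0] - means[0.001]
    assert 0 <= shift < 0.06 * means[0.0]


def test_poisson_coverage_recovery(rng):
    # error-free reads at 40x from a random circular genome: median
    # multiplicity tracks per-position depth (approximately Poisson(40));
    # circularity avoids the depth ramps of linear genome ends
    genome = random_record(rng, 100_000, rid="g").seq
    L, rl, cov = len(genome), 5_000, 40
    doubled = genome + genome
    n_reads = cov * L // rl
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, L))
        reads.append(SeqRecord(f"r{i}", doubled[start : start + rl]))
    table = build_multiplicity_table(reads)
    medians = np.array([median_read_multiplicity(r, table) for r in reads])
    # depth is correlated over the read span (only ~L/rl independent
    # depth patches), so the per-read in-band fraction fluctuates
    # between genome realisations; the mean and median are stable
    assert abs(medians.mean() - cov) / cov < 0.05
    assert abs(np.median(medians) - cov) <= 3
    assert np.mean((medians >= 30) & (medians <= 50)) >= 0.75
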