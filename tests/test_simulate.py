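import numpy as np
import pytest

from strsift.read_io import stream_reads
from strsift.repeats import find_runs
from strsift.simulate import (
    BACKGROUND_PRESETS,
    SimConfig,
    SimulatedLocus,
    background_read,
    evaluate_classifier,
    labelled_repeat_reads,
    make_locus,
    repeat_read,
    simulate_cohort,
    simulate_locus_reads,
)


def test_background_base_frequencies_converge(uniform_config):
    rng = np.random.default_rng(1)
    counts = {b: 0 for b in "ACGT"}
    n_reads, length = 2000, uniform_config.read_length
    for _ in range(n_reads):
        for base in background_read(uniform_config, rng).sequence:
            counts[base] += 1
    total = n_reads * length
    for base in "ACGT":
        assert counts[base] / total == pytest.approx(0.25, abs=0.005)


def test_degenerate_distribution_yields_homopolymer():
    config = SimConfig(background="custom", probs=(1.0, 0.0, 0.0, 0.0), read_length=80)
    assert background_read(config).sequence == "A" * 80


def test_same_seed_means_identical_reads(uniform_config):
    a = background_read(uniform_config)
    b = background_read(uniform_config)
    assert a.sequence == b.sequence


def test_presets_are_valid_distributions():
    for name, probs in BACKGROUND_PRESETS.items():
        assert sum(probs) == pytest.approx(1.0)
        SimConfig(background=name)  # validates


def test_informative_label_threshold(uniform_config):
    rng = np.random.default_rng(2)
    _, label44 = repeat_read(uniform_config, "AGC", 44, rng=rng)
    _, label45 = repeat_read(uniform_config, "AGC", 45, rng=rng)
    assert not label44
    assert label45


def test_pure_full_length_repeat_read(uniform_config):
    read, label = repeat_read(uniform_config, "AGC", 150, offset=0)
    assert read.sequence == "AGC" * 50
    assert label


def test_error_rate_produces_matching_mismatch_fraction():
    config = SimConfig(read_length=150, error_rate=0.01, seed=6)
    rng = config.rng()
    template = "AGC" * 50
    mismatches = total = 0
    for _ in range(700):
        read, _ = repeat_read(config, "AGC", 150, offset=0, rng=rng)
        mismatches += sum(a != b for a, b in zip(read.sequence, template))
        total += 150
    assert mismatches / total == pytest.approx(0.01, abs=0.002)


def test_motif_change_makes_impure_tracts(uniform_config):
    config = SimConfig(read_length=150, motif_change_prob=0.5, seed=8)
    read, _ = repeat_read(config, "AGC", 150, offset=0)
    template = "AGC" * 50
    changed = sum(a != b for a, b in zip(read.sequence, template))
    assert 0 < changed <= 50  # at most one substitution per copy


def test_error_free_repeat_reads_recoverable_by_detector(uniform_config):
    rng = np.random.default_rng(11)
    for repeat_nt in (45, 90, 150):
        read, _ = repeat_read(uniform_config, "TCAG", repeat_nt, rng=rng)
        runs = find_runs(read.sequence, min_tract=9)
        best = max(
            (r for r in runs if r.canonical_motif == "ACTG"),
            key=lambda r: r.tract_length,
        )
        # the inserted tract is recovered (flanking chance matches may extend it)
        assert best.tract_length >= repeat_nt


def test_repeat_read_precondition():
    with pytest.raises(ValueError):
        repeat_read(SimConfig(read_length=100), "AGC", 101)


def test_locus_assembly_geometry(uniform_config):
    rng = np.random.default_rng(4)
    locus = make_locus(uniform_config, "AGC", 50, flank_len=2500, rng=rng)
    assert len(locus.sequence) == 5150
    assert locus.insert_start == 2500
    assert not find_runs(locus.flank5, min_tract=15)
    assert not find_runs(locus.flank3, min_tract=15)


def test_locus_read_count_and_labelling(uniform_config):
    rng = np.random.default_rng(4)
    locus = make_locus(uniform_config, "AGC", 50, flank_len=2500, rng=rng)
    reads = simulate_locus_reads(locus, depth=30, config=uniform_config, rng=rng)
    assert len(reads) == round(30 * 5150 / 150)
    tract = locus.insert_start, locus.insert_start + 150
    for read, label in reads[:200]:
        assert read.length == 150
    # reads fully inside the tract are informative under zero error
    inside = [lab for read, lab in reads if "AGC" * 15 in read.sequence]
    assert inside and all(inside)


def test_simulate_cohort_reproducible_and_labelled(tmp_path):
    config = SimConfig(read_length=100, seed=5)
    m1 = simulate_cohort(2, 3, "AGC", 100, 50, config, tmp_path / "a")
    m2 = simulate_cohort(2, 3, "AGC", 100, 50, config, tmp_path / "b")
    text1 = sorted(p.read_bytes() for p in (tmp_path / "a").glob("*.fasta"))
    text2 = sorted(p.read_bytes() for p in (tmp_path / "b").glob("*.fasta"))
    assert text1 == text2  # byte-identical under one seed
    manifest = (tmp_path / "a" / "manifest.tsv").read_text().splitlines()
    assert manifest[0] == "sample_id\tpath\tlabel"
    assert sum(line.endswith("case") for line in manifest[1:]) == 2
    reads, stats = stream_reads(tmp_path / "a" / "case_00.fasta")
    assert sum(1 for _ in reads) == 50 and stats.read_length_mode == 100


def test_evaluate_classifier_protocols(uniform_config, toy_table):
    table = toy_table  # thresholds {50: 0.5, 150: 0.4}
    metrics = evaluate_classifier(uniform_config, table, 300, seed=3, protocol="informative")
    assert metrics.tp + metrics.fn == 300
    assert metrics.tn + metrics.fp == 300
    full = evaluate_classifier(uniform_config, table, 300, seed=3, protocol="full")
    # the full protocol has sub-45-nt tracts in the negative class
    assert full.tn + full.fp > 300
    with pytest.raises(ValueError):
        evaluate_classifier(uniform_config, table, 0, seed=3)
    with pytest.raises(ValueError):
        evaluate_classifier(uniform_config, table, 10, seed=3, protocol="other")
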