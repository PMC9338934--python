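import pytest

from strsift.profiles import (
    SampleProfile,
    assemble_cohort,
    build_profile,
    information_scores,
    read_manifest,
    read_profile,
    write_profile,
)
from strsift.read_io import LibraryStats, ReadRecord
from strsift.repeats import find_runs


def _stats(n, length):
    stats = LibraryStats()
    for _ in range(n):
        stats.add(length)
    return stats


def _profile(counts, n=1000, j=150, sample_id="s1"):
    return SampleProfile(sample_id=sample_id, library_size=n, read_length=j, counts=counts)


def test_build_profile_counts_single_full_length_run():
    reads = [(ReadRecord(f"r{i}", "ACGT" * 38), []) for i in range(9)]
    repeat_read = ReadRecord("r9", "AGC" * 50)
    reads.append((repeat_read, find_runs(repeat_read.sequence)))
    profile = build_profile(reads, _stats(10, 150), sample_id="s")
    assert profile.library_size == 10
    assert profile.counts == {"AGC": {150: 1}}


def test_build_profile_counts_every_run_in_a_read():
    read = ReadRecord("r", "AT" * 10 + "CG" * 15 + "ACGTACGTAC" * 10)
    runs = find_runs(read.sequence)
    profile = build_profile([(read, runs)], _stats(1, 150))
    assert profile.counts["AT"] == {20: 1}
    assert profile.counts["CG"] == {30: 1}


def test_build_profile_drops_motifs_longer_than_cap():
    read = ReadRecord("r", "ACGTCAG" * 21)  # period-7 run, 147 nt
    runs = find_runs(read.sequence)
    assert any(r.period == 7 for r in runs)
    profile = build_profile([(read, runs)], _stats(1, 147), max_motif_len=6)
    assert "ACGTCAG" not in {m for m in profile.counts}
    assert all(len(m) <= 6 for m in profile.counts)


def test_build_profile_rejects_tracts_longer_than_read_length():
    read = ReadRecord("r", "AGC" * 50)
    runs = find_runs(read.sequence)
    with pytest.raises(ValueError, match="read length"):
        build_profile([(read, runs)], _stats(1, 150), read_length=100)


def test_information_score_direct_substitution():
    profile = _profile({"AGC": {150: 2}}, n=1000, j=150)
    sv = information_scores(profile)
    assert sv.window == (112, 150)
    assert sv.scores["AGC"] == pytest.approx((2 * 150) / 1000)


def test_information_score_window_exclusion():
    profile = _profile({"AAG": {100: 5}}, n=1000, j=150)
    sv = information_scores(profile)
    assert sv.scores["AAG"] == 0.0


def test_information_score_empty_counts_and_bad_window():
    profile = _profile({}, n=10, j=150)
    assert information_scores(profile).scores == {}
    with pytest.raises(ValueError):
        information_scores(profile, i=100, j=50)


def test_score_linearity_over_file_concatenation():
    # union of two read sets: v adds, s_m is the depth-weighted average
    part1 = _profile({"AGC": {150: 2, 120: 1}}, n=100)
    part2 = _profile({"AGC": {150: 3}}, n=300)
    union = _profile({"AGC": {150: 5, 120: 1}}, n=400)
    s1 = information_scores(part1).scores["AGC"]
    s2 = information_scores(part2).scores["AGC"]
    s_union = information_scores(union).scores["AGC"]
    assert s_union == pytest.approx((100 * s1 + 300 * s2) / 400)


def test_score_invariant_under_read_duplication():
    single = _profile({"AAG": {140: 3, 115: 2}}, n=500)
    doubled = _profile({"AAG": {140: 6, 115: 4}}, n=1000)
    assert information_scores(doubled).scores["AAG"] == pytest.approx(
        information_scores(single).scores["AAG"]
    )


def test_score_monotone_in_window_counts():
    base = _profile({"AGC": {130: 1}}, n=100)
    more = _profile({"AGC": {130: 2}}, n=100)
    assert (
        information_scores(more).scores["AGC"] > information_scores(base).scores["AGC"]
    )


def test_assemble_cohort_fills_missing_motifs_with_zero():
    vectors = [
        information_scores(_profile({"AGC": {150: 1}}, sample_id="a")),
        information_scores(_profile({"AAG": {150: 2}}, sample_id="b")),
        information_scores(_profile({}, sample_id="c")),
    ]
    labels = {"a": "case", "b": "control", "c": "control"}
    matrix = assemble_cohort(vectors, labels)
    assert matrix.scores.shape == (3, 2)
    assert matrix.scores.at["c", "AGC"] == 0.0
    assert list(matrix.labels) == ["case", "control", "control"]


def test_assemble_cohort_rejects_duplicates_and_mixed_windows():
    sv = information_scores(_profile({"AGC": {150: 1}}, sample_id="a"))
    with pytest.raises(ValueError, match="duplicate"):
        assemble_cohort([sv, sv], {"a": "case"})
    other = information_scores(_profile({"AGC": {100: 1}}, j=100, sample_id="b"))
    with pytest.raises(ValueError, match="re-trim"):
        assemble_cohort([sv, other], {"a": "case", "b": "control"})


def test_profile_file_round_trip(tmp_path):
    profile = _profile({"AGC": {150: 2, 113: 1}, "AT": {20: 7}}, n=5000)
    path = tmp_path / "s1.profile.tsv"
    write_profile(profile, path)
    loaded = read_profile(path)
    assert loaded.sample_id == profile.sample_id
    assert loaded.library_size == profile.library_size
    assert loaded.read_length == profile.read_length
    assert loaded.counts == profile.counts


def test_manifest_reader_resolves_relative_paths(tmp_path):
    write_profile(_profile({}, sample_id="s1"), tmp_path / "s1.tsv")
    (tmp_path / "manifest.tsv").write_text(
        "sample_id\tpath\tlabel\ns1\ts1.tsv\tcontrol\n"
    )
    frame = read_manifest(tmp_path / "manifest.tsv")
    assert read_profile(frame["path"][0]).sample_id == "s1"
    (tmp_path / "dup.tsv").write_text(
        "sample_id\tpath\tlabel\ns1\ts1.tsv\tcase\ns1\ts1.tsv\tcontrol\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_manifest(tmp_path / "dup.tsv")
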