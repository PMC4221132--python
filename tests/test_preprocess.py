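"""Filter cascade: category rules, partition invariant, truth agreement."""

import numpy as np
import pytest

from tubemir import preprocess as pp
from tubemir import synthetic as syn
from tubemir.config import DEFAULT_ADAPTER_3P as A3
from tubemir.config import DEFAULT_ADAPTER_5P as A5
from tubemir.config import PreprocessConfig, percentage

GOOD_Q = "I"  # Phred 40


def _read(seq, qual=None, rid="r1"):
    return pp.RawRead(id=rid, sequence=seq, quality=qual or GOOD_Q * len(seq))


def classify(seq, qual=None):
    return pp.classify_and_trim(_read(seq, qual), A3, A5)


INSERT = "ACGTAGCTAGGCTTAGCCGTAA"  # 22 nt, complex, no adapter collision


@pytest.mark.parametrize("seq,qual,expected", [
    # adapter at the very start: empty insert
    (A3 + "ACGTACGTAC", None, "adapter3_null_or_insert_null"),
    # no adapter at all
    ("ACGTTGCA" * 5, None, "adapter3_null_or_insert_null"),
    # 22 consecutive A before the adapter
    ("A" * 22 + A3, None, "poly_nt"),
    # 3 N of 22 nt = 13.6% > 10%
    ("ACGTANGCTANGCTTANCCGTA" + A3, None, "high_N"),
    # low quality dominates everything else
    (A3 + "ACGT", "$" * (len(A3) + 4), "low_quality"),
    # 5' adapter contaminant checked before the 3' adapter
    (A5[:12] + INSERT + A3, None, "adapter5_contaminant"),
    # insert below 18 nt
    ("ACGTAGCTAGGC" + A3 + "ACGTACGT", None, "too_short_or_long"),
    # dinucleotide repeat: low complexity before the length check
    ("ACACACACACACACACACACAC" + A3, None, "low_complexity"),
    (INSERT + A3, None, "clean"),
])
def test_classification_categories(seq, qual, expected):
    category, insert = classify(seq, qual)
    assert category == expected
    if expected == "clean":
        assert insert == INSERT.replace("T", "U")
    else:
        assert insert is None


def test_malformed_read_names_the_culprit():
    with pytest.raises(ValueError, match="rogue"):
        pp.classify_and_trim(_read("ACGT", "II", rid="rogue"), A3, A5)


def test_leftmost_adapter_occurrence_wins():
    seq = INSERT + A3[:8] + "ACGT" + A3
    _, insert = classify(seq)
    assert insert == INSERT.replace("T", "U")


@pytest.mark.parametrize("count,denom,decimals,expected", [
    (3232436, 8053300, 2, "40.14%"),
    (4799733, 8053300, 2, "59.60%"),
    (19202, 8053300, 2, "0.24%"),
    (0, 100, 2, "0.00%"),
    (1, 8, 2, "12.50%"),
])
def test_percentage_formatting(count, denom, decimals, expected):
    assert percentage(count, denom, decimals) == expected


def test_percentage_rejects_bad_input():
    with pytest.raises(ValueError):
        percentage(1, 0)
    with pytest.raises(ValueError):
        percentage(5, 3)


def test_cascade_matches_generator_truth(small_library, small_clean):
    _, truth = small_library
    clean, report = small_clean
    expected = syn.expected_filter_counts(truth)
    assert report.total == len(truth)
    for category in pp.CATEGORIES:
        assert report.counts[category] == expected.get(category, 0)
    # collapsed reads conserve the clean total
    assert sum(r.copy_count for r in clean) == expected["clean"]


def test_cascade_is_order_invariant(small_library):
    reads, _ = small_library
    _, fwd = pp.run_cascade(reads)
    _, rev = pp.run_cascade(reads[::-1])
    assert fwd.counts == rev.counts


def test_all_clean_library(small_bundle):
    profile = syn.TissueProfile(
        "pure", syn.base_mirna_proportions(list(small_bundle.mature_mirnas)),
        {"miRNA": 1.0})
    reads, truth = syn.simulate_library(small_bundle, profile, 500, seed=23)
    _, report = pp.run_cascade(reads)
    assert report.counts["clean"] == report.total == 500
    assert set(truth["origin_class"]) == {"miRNA"}


def test_rerunning_clean_reads_without_adapters_yields_adapter_null(small_clean):
    clean, _ = small_clean
    as_raw = [pp.RawRead(r.id, r.insert.replace("U", "T"),
                         GOOD_Q * len(r.insert)) for r in clean[:50]]
    _, report = pp.run_cascade(as_raw)
    assert report.counts["adapter3_null_or_insert_null"] == len(as_raw)


def test_empty_stream_is_valid():
    clean, report = pp.run_cascade([])
    assert clean == [] and report.total == 0


def test_length_distribution_weighting():
    reads = [pp.CleanRead("a", "A" * 18, 5), pp.CleanRead("b", "C" * 22, 1)]
    by_reads = pp.length_distribution(reads, weight="reads").set_index("length")
    assert by_reads.loc[18, "count"] == 5
    assert by_reads["fraction"].sum() == pytest.approx(1.0)
    by_unique = pp.length_distribution(reads, weight="unique").set_index("length")
    assert by_unique.loc[18, "count"] == 1


def test_length_distribution_single_length():
    reads = [pp.CleanRead("a", "ACGUACGUACGUACGUACGUAC", 7)]
    df = pp.length_distribution(reads).set_index("length")
    assert df.loc[22, "fraction"] == 1.0


def test_length_distribution_tracks_generator_mix(small_bundle, small_clean,
                                                  small_library):
    """miRNA-origin read lengths follow the planted length mix within 4 sigma."""
    _, truth = small_library
    clean, _ = small_clean
    df = pp.length_distribution(clean).set_index("length")
    n = df["count"].sum()
    # the dominant planted length is 22 nt; binomial check on its fraction
    mirna_lengths = {m: len(s) for m, s in small_bundle.mature_mirnas.items()}
    clean_truth = truth[truth["expected_category"] == "clean"]
    expected22 = (clean_truth["source_name"].map(mirna_lengths) == 22).mean()
    sigma = (expected22 * (1 - expected22) / n) ** 0.5
    observed22 = df.loc[22, "fraction"]
    # loose: non-miRNA clean reads are uniform over 18-40, diluting the mode
    assert observed22 == pytest.approx(expected22, abs=max(4 * sigma, 0.12))
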