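"""Generator: determinism, conservation, self-consistency of planted truth."""

import numpy as np
import pandas as pd
import pytest

from tubemir import synthetic as syn
from tubemir import qpcr
from tubemir.novel_mirna import ReadCluster, evaluate_hairpin
from tubemir.preprocess import classify_and_trim
from tubemir.config import DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P

TINY = dict(n_mirnas=8, n_ncrna_per_class=2, n_scaffolds=1, scaffold_len=400,
            n_hairpins=2, n_transcripts=3, transcript_len=300,
            n_target_sites=2, n_target_mirnas=2)


def test_bundle_deterministic_for_fixed_seed():
    a = syn.make_reference_bundle(syn.BundleConfig(**TINY), seed=5)
    b = syn.make_reference_bundle(syn.BundleConfig(**TINY), seed=5)
    assert a.mature_mirnas == b.mature_mirnas
    assert a.scaffolds == b.scaffolds
    assert a.transcripts == b.transcripts
    assert a.hairpin_intervals == b.hairpin_intervals
    c = syn.make_reference_bundle(syn.BundleConfig(**TINY), seed=6)
    assert c.scaffolds != a.scaffolds


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="n_mirnas"):
        syn.make_reference_bundle(syn.BundleConfig(n_mirnas=0), seed=1)
    with pytest.raises(ValueError):
        syn.BundleConfig(n_hairpins=-1).validate()


def test_planted_hairpins_pass_their_detector(small_bundle):
    n = 0
    for scaffold, intervals in small_bundle.hairpin_intervals.items():
        seq = small_bundle.scaffolds[scaffold]
        for (start, end, name, mature) in intervals:
            assert seq[start - 1:end].startswith(mature)  # 1-based inclusive
            cluster = ReadCluster(0, len(mature), mature, 10,
                                  [(mature, 10, 0)])
            cand, reason = evaluate_hairpin(seq[start - 1:start - 1 + 70],
                                            cluster)
            assert cand is not None, reason
            n += 1
    assert n == small_bundle.config.n_hairpins


def test_zero_ncrna_fragments_supported():
    cfg = syn.BundleConfig(**{**TINY, "n_ncrna_per_class": 1})
    # the class-mix route: a profile without ncRNA classes never draws them
    bundle = syn.make_reference_bundle(cfg, seed=2)
    profile = syn.TissueProfile(
        "t", syn.base_mirna_proportions(list(bundle.mature_mirnas)),
        {"miRNA": 0.8, "other": 0.2})
    reads, truth = syn.simulate_library(bundle, profile, 300, seed=3)
    assert set(truth["origin_class"]) <= {"miRNA", "other"}


def test_library_conservation_and_determinism(small_bundle, small_profiles):
    reads, truth = syn.simulate_library(
        small_bundle, small_profiles["tube_foot"], 1000, seed=7)
    assert len(reads) == len(truth) == 1000
    reads2, truth2 = syn.simulate_library(
        small_bundle, small_profiles["tube_foot"], 1000, seed=7)
    assert [(r.id, r.sequence, r.quality) for r in reads] == \
           [(r.id, r.sequence, r.quality) for r in reads2]
    assert truth.equals(truth2)


def test_degenerate_mix_all_mirna(small_bundle):
    profile = syn.TissueProfile(
        "t", syn.base_mirna_proportions(list(small_bundle.mature_mirnas)),
        {"miRNA": 1.0})
    _, truth = syn.simulate_library(small_bundle, profile, 200, seed=9)
    assert (truth["origin_class"] == "miRNA").all()


def test_unknown_profile_mirna_rejected(small_bundle, small_profiles):
    profile = syn.TissueProfile(
        "t", {"not-a-mirna": 1.0}, dict(syn.DEFAULT_CATEGORY_MIX))
    with pytest.raises(ValueError, match="absent"):
        syn.simulate_library(small_bundle, profile, 10, seed=1)


def test_profile_validation():
    with pytest.raises(ValueError, match="sum"):
        syn.TissueProfile("t", {"a": 0.5}, {"miRNA": 1.0}).validate()
    with pytest.raises(ValueError, match="unknown"):
        syn.TissueProfile("t", {"a": 1.0}, {"plasmid": 1.0}).validate()


def test_class_counts_within_binomial_bounds(small_bundle, small_profiles):
    n = 20000
    _, truth = syn.simulate_library(
        small_bundle, small_profiles["tube_foot"], n, seed=13)
    observed = truth["origin_class"].value_counts()
    for cls, p in small_profiles["tube_foot"].category_mix.items():
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(observed.get(cls, 0) - n * p) <= 4 * sigma + 1


def test_every_read_classifies_to_its_expected_category(small_library):
    reads, truth = small_library
    expected = dict(zip(truth["read_id"], truth["expected_category"]))
    for read in reads[:400]:
        category, _ = classify_and_trim(read, DEFAULT_ADAPTER_3P,
                                        DEFAULT_ADAPTER_5P)
        assert category == expected[read.id]


def test_ct_table_noise_free_inversion():
    folds = {"g": {"tube_foot": 1.0, "haemocyte": 0.25, "intestine": 2.0}}
    table = syn.simulate_ct_table(folds, ct_noise_sd=0.0, seed=1)
    results = qpcr.summarize(table, "tube_foot", "b-actin")
    got = {r.tissue: r.fold for r in results}
    assert got["tube_foot"] == pytest.approx(1.0)
    assert got["haemocyte"] == pytest.approx(0.25)
    assert got["intestine"] == pytest.approx(2.0)


def test_ct_table_flat_folds_give_zero_ddct():
    folds = {"g": {"a": 1.0, "b": 1.0}}
    table = syn.simulate_ct_table(folds, ct_noise_sd=0.0, seed=1)
    results = qpcr.summarize(table, "a", "b-actin")
    assert all(r.fold == pytest.approx(1.0) for r in results)


def test_ct_table_rejects_nonpositive_fold():
    with pytest.raises(ValueError, match="positive"):
        syn.simulate_ct_table({"g": {"a": 0.0}}, seed=1)


def test_noisy_ct_recovery_within_propagated_error():
    rng = np.random.default_rng(21)
    errors = []
    for rep in range(40):
        fold_true = 4.0
        table = syn.simulate_ct_table(
            {"g": {"cal": 1.0, "t": fold_true}}, ct_noise_sd=0.2,
            seed=int(rng.integers(1, 2**31)))
        res = {r.tissue: r.fold for r in qpcr.summarize(table, "cal", "b-actin")}
        errors.append(abs(res["t"] - fold_true) / fold_true)
    # sd 0.2 over 3 replicates propagates to ~10% median relative error
    assert np.median(errors) < 0.3
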