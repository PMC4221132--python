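"""Target prediction: seed classes, aligner vs oracle, energies, intersection."""

import math

import numpy as np
import pytest

from tubemir import target_prediction as tp
from tubemir.config import TargetConfig, revcomp
from _oracles import align_oracle, duplex_energy_oracle, dinucleotide_shuffle

MIR = "UAGCACCAUCUGAAAUCGGUUA"  # 22 nt


def test_seed_match_8mer_from_revcomp():
    window = revcomp(MIR[:8])
    match = tp.seed_match(MIR, window, strict=True)
    assert match.kind == "8mer"
    assert match.gu_count == 0


def test_seed_mismatch_breaks_strict_match():
    window = list(revcomp(MIR[:8]))
    idx = 7 - 3  # antiparallel: miRNA position 4 pairs window index 4
    window[idx] = "A" if window[idx] != "A" else "G"
    assert tp.seed_match(MIR, "".join(window), strict=True).kind == "none"


def test_seed_gu_wobble_counted_when_loose():
    mir = "AGGGGGGGCCCCCCCCCCCCCC"  # seed positions 2-8 all G
    perfect = revcomp(mir[:8])             # all C partners
    wobble = list(perfect)
    wobble[3] = "U"                        # one G:U in the seed
    assert tp.seed_match(mir, "".join(wobble), strict=True).kind == "none"
    loose = tp.seed_match(mir, "".join(wobble), strict=False)
    assert loose.kind in ("7mer", "8mer")
    assert loose.gu_count == 1


def test_seed_window_too_short():
    assert tp.seed_match(MIR, "ACGUA", strict=False).kind == "none"


def test_perfect_duplex_alignment_score():
    # 22 WC pairs at +5 each, plus seed doubling over positions 2-8
    _, s = tp.duplex_align(MIR, revcomp(MIR))
    assert s == 5 * 22 + 5 * 7


def test_no_complementarity_scores_zero():
    _, s = tp.duplex_align("A" * 20, "A" * 24)
    assert s == 0.0


def test_correcting_a_mismatch_never_lowers_score():
    rng = np.random.default_rng(8)
    for _ in range(20):
        mir = "".join(rng.choice(list("ACGU"), size=20))
        site = list(revcomp(mir))
        pos = int(rng.integers(0, 20))
        broken = site.copy()
        broken[pos] = "A" if site[pos] != "A" else "G"
        _, s_broken = tp.duplex_align(mir, "".join(broken))
        _, s_fixed = tp.duplex_align(mir, "".join(site))
        assert s_fixed >= s_broken


def test_alignment_matches_exhaustive_oracle():
    rng = np.random.default_rng(12)
    cfg = TargetConfig()
    for _ in range(60):
        mir = "".join(rng.choice(list("ACGU"), size=int(rng.integers(17, 23))))
        win = "".join(rng.choice(list("ACGU"), size=int(rng.integers(7, 13))))
        _, s = tp.duplex_align(mir, win, cfg)
        assert s == pytest.approx(align_oracle(mir, win, cfg))


def test_duplex_energy_zero_without_pairs():
    assert tp.duplex_energy("AAAA", "AAAA") == 0.0


def test_gc_rich_perfect_duplex_clears_threshold():
    mir = "GCGCGCGCGCGCGCGCGCGC"  # 20 nt
    assert tp.duplex_energy(mir, revcomp(mir)) < -17.0


def test_duplex_energy_matches_exhaustive_oracle():
    rng = np.random.default_rng(14)
    for _ in range(60):
        mir = "".join(rng.choice(list("ACGU"), size=int(rng.integers(8, 13))))
        win = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 11))))
        assert tp.duplex_energy(mir, win) == pytest.approx(
            duplex_energy_oracle(mir, win))


def test_accessibility_open_site_equals_duplex_energy():
    # an A/G miRNA gives a C/U site that cannot pair with itself or with the
    # C flanks, so the opening cost is exactly zero
    mir = "AG" * 11
    site = revcomp(mir)
    transcript = "C" * 30 + site + "C" * 30
    ddg = tp.accessibility(mir, transcript, 31, 30 + len(site))
    assert ddg == pytest.approx(tp.duplex_energy(mir, site))


def test_burying_a_site_raises_ddg():
    site = revcomp(MIR)
    open_ctx = "A" * 30 + site + "A" * 30
    # the site's own complement upstream forces the site into a long stem
    buried_ctx = "A" * 8 + revcomp(site) + "AAAA" + site + "A" * 30
    ddg_open = tp.accessibility(MIR, open_ctx, 31, 30 + len(site))
    start = 8 + len(site) + 4 + 1
    ddg_buried = tp.accessibility(MIR, buried_ctx, start, start + len(site) - 1)
    assert ddg_buried > ddg_open


def test_threshold_boundary_on_alignment_score():
    cfg = TargetConfig()
    # a 20-nt perfect site scores 5*20 + 35 = 135 < 140: method A rejects
    short_mir = MIR[:20]
    transcripts = {"t": "A" * 20 + revcomp(short_mir) + "A" * 20}
    sites = tp.predict_targets({"m": short_mir}, transcripts, cfg)
    assert sites["A"] == []
    # the full 22-nt site scores 145 and passes
    transcripts = {"t": "A" * 20 + revcomp(MIR) + "A" * 20}
    sites = tp.predict_targets({"m": MIR}, transcripts, cfg)
    assert any(s.score >= cfg.s_min for s in sites["A"])


def test_tightening_thresholds_yields_subset():
    rng = np.random.default_rng(40)
    transcripts = {
        f"t{i}": "".join(rng.choice(list("ACGU"), size=150)) for i in range(3)
    }
    transcripts["planted"] = "A" * 30 + revcomp(MIR) + "A" * 30
    loose = tp.predict_targets({"m": MIR}, transcripts,
                               TargetConfig(s_min=100, dg_max=-5, ddg_max=-5))
    tight = tp.predict_targets({"m": MIR}, transcripts, TargetConfig())
    for method in "AB":
        loose_keys = {(s.transcript, s.start, s.end) for s in loose[method]}
        tight_keys = {(s.transcript, s.start, s.end) for s in tight[method]}
        assert tight_keys <= loose_keys


def test_intersection_rules():
    a = [tp.TargetSite("m", "t1", 10, 30, 150, -20, float("nan"), method="A"),
         tp.TargetSite("m", "t2", 10, 30, 150, -20, float("nan"), method="A")]
    b = [tp.TargetSite("m", "t1", 25, 45, 0, -20, -15, method="B"),
         tp.TargetSite("m", "t3", 10, 30, 0, -20, -15, method="B")]
    assert tp.intersect(a, b) == ["t1"]          # overlap required
    assert tp.intersect(a, []) == []             # A-only excluded
    assert tp.intersect(a, a) == ["t1", "t2"]    # identical sites count once
    assert tp.intersect(b, a) == ["t1"]          # order-invariant


def test_planted_sites_recovered_and_intersected(small_bundle):
    mirnas = {m: small_bundle.mature_mirnas[m] for m in small_bundle.target_mirnas}
    sites = tp.predict_targets(mirnas, small_bundle.transcripts,
                               utr_intervals=small_bundle.utr_intervals)
    both = set(tp.intersect(sites["A"], sites["B"]))
    planted = {t for t, ss in small_bundle.target_sites.items() if ss}
    assert planted <= both
    for t, ss in small_bundle.target_sites.items():
        for (m, s0, s1) in ss:
            for method in "AB":
                assert any(x.transcript == t and x.mirna == m
                           and x.start <= s1 and s0 <= x.end
                           for x in sites[method]), (t, m, method)


def test_shuffled_decoys_mostly_intersection_free(small_bundle):
    rng = np.random.default_rng(77)
    mirnas = {m: small_bundle.mature_mirnas[m] for m in small_bundle.target_mirnas}
    decoys = {f"decoy{i}_{name}": dinucleotide_shuffle(seq, rng)
              for i, (name, seq) in enumerate(small_bundle.transcripts.items())}
    sites = tp.predict_targets(mirnas, decoys)
    hit = set(tp.intersect(sites["A"], sites["B"]))
    assert len(hit) / len(decoys) <= 0.1
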