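import pytest

from tubemir import annotate as ann
from tubemir import preprocess as pp
from tubemir import synthetic as syn

TABLE3_ROWS = [
    # (provisional id, read count, mature, precursor) as printed for the six
    # novel candidates of the tube-foot study
    ("Scaffold2497_1173", 6984, "caucgccaccaaguguacuuca",
     "caucgccaccaaguguacuucaguggacauaugucguuuuuaaaucugagcacacuugguagcggug"),
    ("Scaffold912_781", 1292, "cuuucuguggcugucguguuaag",
     "cuuucuguggcugucguguuaagugugauucuaugaagacacuucacacacaaccacaggaaguu"),
    ("Scaffold1753_1055", 58, "gcaguggcuccuauuggucauu",
     "aguccaauagggagggcauugcaggugauauuugaaagcccugcaguggcuccuauuggucauu"),
    ("Scaffold759_703", 47, "uuugguccccuucaaccagccgu",
     "agcugguaaacgggaaccaaaucgugaaguaaaugcggauuugguccccuucaaccagccgu"),
    ("Scaffold690_666", 160, "gugagcggugggguggu",
     "cgcccccugaaccccacgccaauuagugaccugccagugucacaauuagguagugagcggugggguggu"),
    ("Scaffold2466_1170", 210, "uucgaugucggcucuuc",
     "gguugcuuguugcuauccuucgaugucggcucuuc"),
]


@pytest.fixture(scope="session")
def small_bundle():
    cfg = syn.BundleConfig(
        n_mirnas=20, n_ncrna_per_class=3, n_scaffolds=2, scaffold_len=700,
        n_hairpins=3, n_transcripts=6, transcript_len=400, n_target_sites=4)
    return syn.make_reference_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def small_profiles(small_bundle):
    return syn.make_tissue_profiles(small_bundle)


@pytest.fixture(scope="session")
def small_library(small_bundle, small_profiles):
    reads, truth = syn.simulate_library(
        small_bundle, small_profiles["tube_foot"], 3000, seed=17)
    return reads, truth


@pytest.fixture(scope="session")
def small_clean(small_library):
    reads, _ = small_library
    return pp.run_cascade(reads)


@pytest.fixture(scope="session")
def small_annotation(small_bundle, small_clean):
    clean, _ = small_clean
    mirna_index = ann.build_exact_index(small_bundle.mature_mirnas)
    ncrna = {
        cls: ann.build_exact_index(
            {n: s for n, (c, s) in small_bundle.ncrna_fragments.items() if c == cls})
        for cls in syn.NCRNA_CLASSES
    }
    return ann.annotate_reads(clean, mirna_index, ncrna, tissue="tube_foot")
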