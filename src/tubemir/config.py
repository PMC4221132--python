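"""Shared defaults and sequence helpers.

All tunable thresholds of the pipeline live here so that the YAML config,
the CLI and the library functions agree on one set of defaults.  Values are
the study conditions of a tube-foot-style multi-tissue small-RNA experiment:
clean-read window 18-40 nt, annotation priority miRNA > rRNA > tRNA > snRNA
> snoRNA > novel miRNA, fold-change threshold 2, miRanda-like alignment
score >= 140 and duplex dG <= -17 kcal/mol.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# alphabets
# ---------------------------------------------------------------------------

RNA_BASES = "ACGU"
DNA_TO_RNA = str.maketrans("Tt", "Uu")
RNA_TO_DNA = str.maketrans("Uu", "Tt")

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

#: canonical pairs (Watson-Crick plus the G:U wobble)
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
ALL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

#: default 3' adapter: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
#: default 5' adapter: Illumina TruSeq small-RNA 5' adapter (3' end portion)
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().translate(DNA_TO_RNA)


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T (file-output convention)."""
    return seq.upper().translate(RNA_TO_DNA)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return "".join(COMPLEMENT[b] for b in reversed(to_rna(seq)))


def percentage(count: int, denominator: int, decimals: int = 2) -> str:
    """Format ``100*count/denominator`` rounded half-up, e.g. ``"59.60%"``.

    Half-up (not banker's) rounding reproduces the conventional way summary
    tables are printed.  ``denominator`` must be positive and ``count`` must
    not exceed it.
    """
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    if count < 0 or count > denominator:
        raise ValueError("count must be within [0, denominator]")
    value = decimal.Decimal(100 * count) / decimal.Decimal(denominator)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return f"{value.quantize(quantum, rounding=decimal.ROUND_HALF_UP)}%"


# ---------------------------------------------------------------------------
# pipeline thresholds
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    #: low quality := mean Phred < min_mean_quality OR more than
    #: max_low_quality_bases bases with Phred < low_quality_phred
    min_mean_quality: float = 20.0
    low_quality_phred: int = 10
    max_low_quality_bases: int = 4
    #: adapters are located by their first adapter_seed_len bases
    adapter_seed_len: int = 8
    #: exact adapter seed match by default; set to 1 to tolerate a mismatch
    adapter_mismatches: int = 0
    min_len: int = 18
    max_len: int = 40
    poly_nt_fraction: float = 0.90
    max_n_fraction: float = 0.10
    #: dinucleotide-entropy cutoff (bits) for the low-complexity filter
    min_dinucleotide_entropy: float = 1.0


@dataclass
class NovelConfig:
    mfe_max: float = -18.0          # kcal/mol, whole precursor
    mfe_per_nt_max: float = -0.2    # kcal/mol per precursor nucleotide
    min_mature_paired: float = 0.60
    window_flank: int = 70          # candidate window length past the cluster
    max_star_overhang: int = 6      # tolerance on the 2-nt 3' overhang proxy
    min_read_count: int = 1


@dataclass
class TargetConfig:
    s_min: float = 140.0
    dg_max: float = -17.0
    ddg_max: float = -10.0
    strict: bool = True
    fold_window: int = 50
    #: alignment scoring (miRanda-like); seed columns are doubled
    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_start: int = 2             # miRNA positions (1-based, inclusive)
    seed_end: int = 8


@dataclass
class DiffexprConfig:
    threshold: float = 2.0
    #: pseudo-proportion applied only to zero terms, as a count of 0.5 reads
    pseudo_reads: float = 0.5


@dataclass
class QpcrConfig:
    calibrator_tissue: str = "tube_foot"
    reference_gene: str = "b-actin"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    novel: NovelConfig = field(default_factory=NovelConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    diffexpr: DiffexprConfig = field(default_factory=DiffexprConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    priority: tuple = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")
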