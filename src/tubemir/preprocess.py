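"""Raw-read filter cascade: adapter trimming and quality/composition filters.

Each raw read is assigned exactly one category, tested in a fixed order so
the categories partition the library:

1. ``low_quality``                 mean Phred or low-quality-base rule
2. ``adapter5_contaminant``        5' adapter sequence present
3. ``adapter3_null_or_insert_null`` no 3' adapter, or nothing before it
4. ``poly_nt``                     one nucleotide dominates the insert
5. ``high_N``                      more than 10% N in the insert
6. ``low_complexity``              dinucleotide entropy below threshold
7. ``too_short_or_long``           insert outside the 18-40 nt window
8. ``clean``

Clean inserts are collapsed to unique sequences with copy counts, the
in-memory unit every downstream stage consumes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

from .config import PreprocessConfig, percentage, to_rna

logger = logging.getLogger(__name__)

CATEGORIES = (
    "low_quality",
    "adapter5_contaminant",
    "adapter3_null_or_insert_null",
    "poly_nt",
    "high_N",
    "low_complexity",
    "too_short_or_long",
    "clean",
)


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: str  # Phred-33 encoded, same length as sequence

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.quality]


@dataclass
class CleanRead:
    id: str
    insert: str  # RNA alphabet, 18-40 nt
    copy_count: int = 1


@dataclass
class FilterReport:
    """Per-category read counts mirroring a sequencing summary table."""

    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.get(c, 0) for c in CATEGORIES)

    def percent(self, category: str, decimals: int = 2) -> str:
        return percentage(self.counts.get(category, 0), self.total, decimals)

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        total = self.total
        rows = [("total", total, percentage(total, total, decimals) if total else "0%")]
        for c in CATEGORIES:
            n = self.counts.get(c, 0)
            pct = percentage(n, total, decimals) if total else "0%"
            rows.append((c, n, pct))
        return pd.DataFrame(rows, columns=["category", "count", "percent"])


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping dinucleotide distribution."""
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i:i + 2] for i in range(len(seq) - 1))
    n = len(seq) - 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def find_adapter(seq: str, adapter: str, seed_len: int = 8,
                 mismatches: int = 0) -> int:
    """Leftmost start of the adapter's ``seed_len``-nt prefix, or -1.

    With ``mismatches`` > 0 a tolerant scan is used; exact matching is the
    default because it keeps classification deterministic.
    """
    seed = adapter[:seed_len]
    if mismatches == 0:
        return seq.find(seed)
    for p in range(len(seq) - len(seed) + 1):
        if sum(a != b for a, b in zip(seq[p:p + len(seed)], seed)) <= mismatches:
            return p
    return -1


def classify_and_trim(read: RawRead, adapter_3p: str, adapter_5p: str,
                      cfg: Optional[PreprocessConfig] = None,
                      ) -> tuple[str, Optional[str]]:
    """Assign the read to one category; return the insert only if clean."""
    cfg = cfg or PreprocessConfig()
    if len(read.sequence) != len(read.quality):
        raise ValueError(
            f"malformed read {read.id!r}: sequence/quality length mismatch")
    seq = read.sequence.upper()
    phred = read.phred()

    # 1. low quality
    mean_q = sum(phred) / len(phred) if phred else 0.0
    n_bad = sum(q < cfg.low_quality_phred for q in phred)
    if mean_q < cfg.min_mean_quality or n_bad > cfg.max_low_quality_bases:
        return "low_quality", None

    # 2. 5' adapter contaminant
    a5 = adapter_5p.upper().translate(str.maketrans("U", "T"))
    if find_adapter(seq, a5, cfg.adapter_seed_len, cfg.adapter_mismatches) >= 0:
        return "adapter5_contaminant", None

    # 3. 3' adapter missing, or empty insert
    a3 = adapter_3p.upper().translate(str.maketrans("U", "T"))
    pos = find_adapter(seq, a3, cfg.adapter_seed_len, cfg.adapter_mismatches)
    if pos <= 0:
        return "adapter3_null_or_insert_null", None
    insert = seq[:pos]

    # 4. poly A/T/G/C
    top = max(Counter(insert).values())
    if top / len(insert) >= cfg.poly_nt_fraction:
        return "poly_nt", None

    # 5. excessive N
    if insert.count("N") / len(insert) > cfg.max_n_fraction:
        return "high_N", None

    # 6. low complexity (simple-repeat stand-in)
    if dinucleotide_entropy(insert) < cfg.min_dinucleotide_entropy:
        return "low_complexity", None

    # 7. length window
    if not cfg.min_len <= len(insert) <= cfg.max_len:
        return "too_short_or_long", None

    return "clean", to_rna(insert)


def run_cascade(reads: Iterable[RawRead],
                cfg: Optional[PreprocessConfig] = None,
                ) -> tuple[list[CleanRead], FilterReport]:
    """Classify a read stream; collapse clean inserts to unique sequences."""
    cfg = cfg or PreprocessConfig()
    counts = {c: 0 for c in CATEGORIES}
    collapsed: Counter = Counter()
    n = 0
    for read in reads:
        n += 1
        category, insert = classify_and_trim(
            read, cfg.adapter_3p, cfg.adapter_5p, cfg)
        counts[category] += 1
        if insert is not None:
            collapsed[insert] += 1
    if n == 0:
        logger.warning("empty read stream: report has total 0")
    clean = [
        CleanRead(id=f"uniq{i + 1}_x{c}", insert=s, copy_count=c)
        for i, (s, c) in enumerate(sorted(collapsed.items()))
    ]
    return clean, FilterReport(counts=counts)


def length_distribution(clean: Iterable[CleanRead], weight: str = "reads",
                        ) -> pd.DataFrame:
    """Length histogram of clean inserts, read- or unique-sequence-weighted."""
    if weight not in ("reads", "unique"):
        raise ValueError("weight must be 'reads' or 'unique'")
    counts: Counter = Counter()
    for r in clean:
        counts[len(r.insert)] += r.copy_count if weight == "reads" else 1
    total = sum(counts.values())
    rows = [(length, c, c / total) for length, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["length", "count", "fraction"])


# --- file I/O ---------------------------------------------------------------


def read_fastq(path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield RawRead(id=rec.id, sequence=str(rec.seq), quality=qual)


def write_collapsed_fasta(clean: Iterable[CleanRead], path) -> None:
    """Collapsed clean reads as FASTA; header carries the copy count (_xN)."""
    from .config import to_dna
    with open(path, "w") as fh:
        for r in clean:
            fh.write(f">{r.id}\n{to_dna(r.insert)}\n")


def read_collapsed_fasta(path) -> list[CleanRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        copies = int(rec.id.rsplit("_x", 1)[1]) if "_x" in rec.id else 1
        out.append(CleanRead(id=rec.id, insert=to_rna(str(rec.seq)),
                             copy_count=copies))
    return out
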