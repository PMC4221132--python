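"""Priority-ordered exact-match annotation of clean reads.

Clean reads are looked up against reference sets (mature miRNAs first, then
rRNA, tRNA, snRNA and snoRNA fragments) by full-length exact sequence
identity after T/U normalisation — only perfect matches count as conserved
miRNAs.  A read matching several classes is assigned to the highest-priority
one; reads matching nothing feed the novel-miRNA screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import percentage, to_rna
from .preprocess import CleanRead

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")
ANNOTATION_CLASSES = DEFAULT_PRIORITY + ("others",)


class ExactIndex:
    """Exact full-length lookup: query sequence -> set of reference names."""

    def __init__(self, references: Mapping[str, str]):
        names = list(references)
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names")
        self._by_seq: dict[str, set[str]] = {}
        for name, seq in references.items():
            self._by_seq.setdefault(to_rna(seq), set()).add(name)

    def lookup(self, query: str) -> set[str]:
        return self._by_seq.get(to_rna(query), set())

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_seq.values())


def build_exact_index(references: Mapping[str, str]) -> ExactIndex:
    return ExactIndex(references)


@dataclass
class MiRNAProfile:
    """Per-miRNA read counts for one tissue."""

    tissue: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["mirna", "count"])


@dataclass
class AnnotationTable:
    """Read counts per annotation class, in copy-count (read) units."""

    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self, cls: str, decimals: int = 2) -> str:
        return percentage(self.counts.get(cls, 0), self.total, decimals)

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        rows = [("all_clean_reads", self.total,
                 percentage(self.total, self.total, 0) if self.total else "0%")]
        for cls in ANNOTATION_CLASSES:
            n = self.counts.get(cls, 0)
            pct = percentage(n, self.total, decimals) if self.total else "0%"
            rows.append((cls, n, pct))
        return pd.DataFrame(rows, columns=["class", "count", "percent"])


def annotate_reads(clean: Iterable[CleanRead],
                   mirna_index: ExactIndex,
                   ncrna_indices: Mapping[str, ExactIndex],
                   priority: Sequence[str] = DEFAULT_PRIORITY,
                   tissue: str = "tube_foot",
                   multimap: str = "fractional",
                   ) -> tuple[AnnotationTable, MiRNAProfile, list[CleanRead]]:
    """Assign each read the highest-priority matching class.

    ``multimap`` controls how a read matching k > 1 mature miRNAs is counted
    per name: ``"fractional"`` adds 1/k of its copies to each name (class
    totals stay conserved), ``"first"`` credits the lexicographically first
    name only.
    """
    indices: dict[str, ExactIndex] = {"miRNA": mirna_index, **ncrna_indices}
    missing = [c for c in indices if c not in priority]
    if missing:
        raise ValueError(f"priority list does not cover classes: {missing}")
    if multimap not in ("fractional", "first"):
        raise ValueError("multimap must be 'fractional' or 'first'")

    class_counts = {c: 0 for c in ANNOTATION_CLASSES}
    mirna_counts: dict[str, float] = {}
    unannotated: list[CleanRead] = []

    for read in clean:
        assigned = None
        for cls in priority:
            index = indices.get(cls)
            if index is None:
                continue
            names = index.lookup(read.insert)
            if names:
                assigned = cls
                if cls == "miRNA":
                    ordered = sorted(names)
                    if multimap == "first":
                        mirna_counts[ordered[0]] = (
                            mirna_counts.get(ordered[0], 0) + read.copy_count)
                    else:
                        w = read.copy_count / len(ordered)
                        for name in ordered:
                            mirna_counts[name] = mirna_counts.get(name, 0) + w
                break
        if assigned is None:
            assigned = "others"
            unannotated.append(read)
        class_counts[assigned] += read.copy_count

    profile = MiRNAProfile(tissue=tissue, counts=mirna_counts)
    return AnnotationTable(counts=class_counts), profile, unannotated


def abundance_summary(profile: MiRNAProfile, threshold: float = 100,
                      ) -> tuple[list[tuple[str, float]], int]:
    """Rank miRNAs by count (ties lexicographic); count those > threshold."""
    if not profile.counts:
        raise ValueError("empty miRNA profile")
    ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_above = sum(1 for _, c in ranked if c > threshold)
    return ranked, n_above
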