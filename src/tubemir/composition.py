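"""Nucleotide-bias statistics of miRNA-class reads.

Mature miRNAs start with uracil far more often than chance, and positions
flanking the seed show characteristic A+U / G+C biases; these statistics are
the standard quality evidence that a small-RNA library is miRNA-rich.
Fractions are read-weighted (copy counts) by default.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import pandas as pd

from .config import RNA_BASES
from .preprocess import CleanRead


def first_nucleotide_bias(reads: Iterable[CleanRead],
                          lengths: range = range(18, 26),
                          weight: str = "reads") -> pd.DataFrame:
    """Base fractions at position 1 per read length (rows: length)."""
    if weight not in ("reads", "unique"):
        raise ValueError("weight must be 'reads' or 'unique'")
    counts: dict[int, dict[str, float]] = defaultdict(lambda: dict.fromkeys(RNA_BASES, 0))
    for r in reads:
        L = len(r.insert)
        if L in lengths:
            counts[L][r.insert[0]] += r.copy_count if weight == "reads" else 1
    rows = []
    for L in sorted(counts):
        total = sum(counts[L].values())
        rows.append([L] + [counts[L][b] / total for b in RNA_BASES])
    return pd.DataFrame(rows, columns=["length", *RNA_BASES]).set_index("length")


def positional_composition(reads: Iterable[CleanRead], length: int = 22,
                           weight: str = "reads") -> pd.DataFrame:
    """Per-position base fractions for reads of one fixed length.

    Rows are 1-based positions 1..length with columns A, C, G, U plus the
    derived A+U and G+C fractions.  Every input read must have exactly the
    requested length.
    """
    if weight not in ("reads", "unique"):
        raise ValueError("weight must be 'reads' or 'unique'")
    counts = [dict.fromkeys(RNA_BASES, 0.0) for _ in range(length)]
    total = 0.0
    for r in reads:
        if len(r.insert) != length:
            raise ValueError(
                f"read {r.id!r} has length {len(r.insert)}, expected {length}")
        w = r.copy_count if weight == "reads" else 1
        total += w
        for pos, base in enumerate(r.insert):
            counts[pos][base] += w
    if total == 0:
        raise ValueError("no reads supplied")
    rows = []
    for pos in range(length):
        frac = {b: counts[pos][b] / total for b in RNA_BASES}
        rows.append([pos + 1, *[frac[b] for b in RNA_BASES],
                     frac["A"] + frac["U"], frac["G"] + frac["C"]])
    return pd.DataFrame(
        rows, columns=["position", *RNA_BASES, "AU", "GC"]).set_index("position")
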