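"""Cross-tissue miRNA specificity by normalized fold change.

Counts are normalized to the total reads of identified miRNAs within each
tissue; the fold change between the focus tissue and a comparison tissue is
the ratio of those proportions, reported with a signed-reciprocal convention
(a ratio r < 1 becomes -1/r, so "-2" means two-fold down).  A miRNA is
called tissue-specific when the same direction exceeds the threshold
against EVERY comparison tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotate import MiRNAProfile

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeCall:
    mirna: str
    folds: dict = field(default_factory=dict)  # comparison tissue -> signed fold
    direction: str = "none"                    # up | down | none
    significant: bool = False
    flags: tuple = ()


def normalize(profile: MiRNAProfile) -> dict[str, float]:
    """Proportion of each miRNA among all identified-miRNA reads."""
    total = profile.total
    if total <= 0:
        raise ValueError(f"profile {profile.tissue!r} has zero miRNA reads")
    return {name: count / total for name, count in profile.counts.items()}


def fold_change(p_focus: float, p_other: float, pseudo: float,
                ) -> tuple[float, bool]:
    """Signed fold change of two proportions; flag marks a double-zero.

    The pseudo-proportion is added only to terms that are exactly zero.  The
    ratio r = p_focus/p_other is returned as +r when r >= 1 and as -1/r
    otherwise, making two-fold depletion read as -2.
    """
    if p_focus < 0 or p_other < 0 or pseudo <= 0:
        raise ValueError("proportions must be >= 0 and pseudocount > 0")
    if p_focus == 0 and p_other == 0:
        return 1.0, True
    a = p_focus if p_focus > 0 else pseudo
    b = p_other if p_other > 0 else pseudo
    r = a / b
    return (r, False) if r >= 1 else (-1.0 / r, False)


def call_specific(focus: MiRNAProfile, others: Sequence[MiRNAProfile],
                  threshold: float = 2.0,
                  pseudo_reads: float = 0.5) -> list[FoldChangeCall]:
    """Tissue-specific calls for the focus tissue against all comparisons.

    Significant iff fold > +threshold against every comparison tissue (up)
    or fold < -threshold against every one (down).  miRNAs absent from all
    profiles are excluded.
    """
    if not others:
        raise ValueError("at least one comparison profile is required")
    p_focus = normalize(focus)
    p_others = {o.tissue: normalize(o) for o in others}
    pseudo = {o.tissue: pseudo_reads / o.total for o in others}
    names = set(focus.counts)
    for o in others:
        names |= set(o.counts)

    calls = []
    for name in sorted(names):
        pf = p_focus.get(name, 0.0)
        if pf == 0.0 and all(p.get(name, 0.0) == 0.0 for p in p_others.values()):
            logger.info("miRNA %s absent everywhere; excluded", name)
            continue
        folds, flags = {}, []
        for tissue, props in p_others.items():
            po = props.get(name, 0.0)
            # the pseudocount is scaled by the library whose term is zero
            eps = pseudo_reads / focus.total if pf == 0 else pseudo[tissue]
            f, flagged = fold_change(pf, po, eps)
            folds[tissue] = f
            if flagged:
                flags.append(tissue)
        up = all(f > threshold for f in folds.values())
        down = all(f < -threshold for f in folds.values())
        calls.append(FoldChangeCall(
            mirna=name, folds=folds,
            direction="up" if up else ("down" if down else "none"),
            significant=up or down, flags=tuple(flags)))
    return calls


def calls_to_frame(calls: Sequence[FoldChangeCall]) -> pd.DataFrame:
    tissues = sorted({t for c in calls for t in c.folds})
    rows = [
        [c.mirna, *[c.folds.get(t) for t in tissues], c.direction, c.significant]
        for c in calls
    ]
    return pd.DataFrame(rows, columns=[
        "mirna", *[f"fold_vs_{t}" for t in tissues], "direction", "significant"])


def profile_from_tsv(path, tissue: str) -> MiRNAProfile:
    """Read a per-miRNA count table (columns: mirna, count)."""
    df = pd.read_csv(path, sep="\t")
    return MiRNAProfile(tissue=tissue,
                        counts=dict(zip(df["mirna"], df["count"])))
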