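"""Novel-miRNA screening: precursor excision, folding and hairpin criteria.

Unannotated clean reads are mapped to genomic scaffolds by exact substring
match, clustered, and candidate precursor windows are excised around each
cluster (mature arm assumed on the 5' or the 3' arm in turn).  A window is
accepted as a novel-miRNA precursor when

(a) the fold is a single stem-loop around the mature arm (exactly one
    terminal loop on the path that contains the mature read),
(b) the mature arm pairs with a contiguous star region in a Dicer-like
    duplex geometry with short 3' overhangs, and
(c) the precursor is thermodynamically stable (MFE below an absolute and a
    per-nucleotide threshold) with at least 60% of the mature arm paired.

The support score is a simple monotone combination of read support,
stability and pairing; it is NOT the miRDeep2 probabilistic score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import NovelConfig, to_rna
from .fold import fold as fold_rna  # re-export: folding engine lives in fold.py
from .fold import hairpin_loops, pairs_from_dotbracket
from .preprocess import CleanRead

__all__ = [
    "fold_rna", "HairpinCandidate", "excise_candidates", "evaluate_hairpin",
    "is_single_stem_loop", "score_candidate", "screen_scaffolds",
    "candidates_to_frame",
]


@dataclass
class HairpinCandidate:
    provisional_id: str            # e.g. "Scaffold2497_1173" (scaffold + locus)
    mature: str                    # RNA string
    precursor: str                 # RNA string containing the mature arm
    structure: str                 # dot-bracket, same length as precursor
    mfe: float                     # kcal/mol
    read_count: int
    star_interval: tuple = (0, 0)  # 0-based half-open within precursor
    score: float = 0.0


@dataclass
class ReadCluster:
    """Reads mapped to one scaffold locus (0-based, half-open)."""

    start: int
    end: int
    mature: str            # most-supported read sequence
    read_count: int
    reads: list = field(default_factory=list)


def _map_reads(scaffold_rna: str, reads: Iterable[CleanRead]):
    """Exact substring hits of each read on the scaffold (all occurrences)."""
    hits = []
    for read in reads:
        insert = to_rna(read.insert)
        p = scaffold_rna.find(insert)
        while p >= 0:
            hits.append((p, p + len(insert), insert, read.copy_count))
            p = scaffold_rna.find(insert, p + 1)
    return sorted(hits)


def cluster_reads(scaffold_rna: str, reads: Iterable[CleanRead]) -> list[ReadCluster]:
    """Merge overlapping read hits into clusters."""
    hits = _map_reads(scaffold_rna, reads)
    clusters: list[ReadCluster] = []
    for start, end, seq, count in hits:
        if clusters and start < clusters[-1].end:
            c = clusters[-1]
            c.end = max(c.end, end)
            c.read_count += count
            c.reads.append((seq, count, start))
        else:
            clusters.append(ReadCluster(start=start, end=end, mature=seq,
                                        read_count=count, reads=[(seq, count, start)]))
    for c in clusters:
        c.mature = max(c.reads, key=lambda r: (r[1], -len(r[0]), r[0]))[0]
    return clusters


def excise_candidates(scaffold: str, reads: Iterable[CleanRead],
                      flank: int = 70) -> list[tuple[ReadCluster, int, int]]:
    """Candidate precursor windows (0-based half-open) per read cluster.

    Two windows are tried per cluster: mature on the 5' arm (cluster start
    forward) and mature on the 3' arm (cluster end backward), clipped to the
    scaffold.
    """
    rna = to_rna(scaffold)
    windows = []
    for c in cluster_reads(rna, reads):
        w5 = (c.start, min(len(rna), c.start + flank))
        w3 = (max(0, c.end - flank), c.end)
        windows.append((c, *w5))
        if w3 != w5:
            windows.append((c, *w3))
    return windows


def is_single_stem_loop(structure: str, mature_span: tuple[int, int]) -> bool:
    """Criterion (a): one terminal loop on the path containing the mature arm.

    ``mature_span`` is 0-based half-open on the folded sequence.  The check
    finds the outermost base pair involving a mature position and requires
    exactly one hairpin loop inside it.
    """
    m0, m1 = mature_span
    pairs = pairs_from_dotbracket(structure)
    touching = [(i, j) for i, j in pairs if (m0 <= i < m1) or (m0 <= j < m1)]
    if not touching:
        return False
    lo = min(i for i, _ in touching)
    hi = max(j for _, j in touching)
    loops = [(i, j) for i, j in hairpin_loops(structure) if lo <= i and j <= hi]
    return len(loops) == 1


def evaluate_hairpin(window: str, cluster: ReadCluster,
                     cfg: Optional[NovelConfig] = None,
                     provisional_id: str = "candidate",
                     ) -> tuple[Optional[HairpinCandidate], str]:
    """Apply the three acceptance criteria to a candidate window.

    Returns ``(candidate, "ok")`` on acceptance or ``(None, reason)`` on
    rejection; rejection is a normal outcome.
    """
    cfg = cfg or NovelConfig()
    rna = to_rna(window)
    mature = to_rna(cluster.mature)
    m0 = rna.find(mature)
    if m0 < 0:
        return None, "mature not in window"
    m1 = m0 + len(mature)

    structure, _ = fold_rna(rna)
    pairs = pairs_from_dotbracket(structure)
    partner = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i

    # (c) mature arm pairing fraction
    mature_paired = sorted(p for p in range(m0, m1) if p in partner)
    frac_paired = len(mature_paired) / len(mature)
    if frac_paired < cfg.min_mature_paired:
        return None, "mature arm insufficiently paired"

    # (a) single stem-loop on the mature path
    if not is_single_stem_loop(structure, (m0, m1)):
        return None, "no single stem-loop"

    # (b) Dicer-site proxy: the mature arm must be anchored close to both
    # ends (pairing starts within ~2 nt of each end, the proxy for the 2-nt
    # 3' overhang duplex geometry) and must pair with a contiguous,
    # disjoint star region.
    unanchored = (mature_paired[0] - m0) + (m1 - 1 - mature_paired[-1])
    if unanchored > cfg.max_star_overhang:
        return None, "no Dicer-like 2-nt overhang geometry"
    mature_partners = sorted(partner[p] for p in mature_paired)
    s_lo, s_hi = mature_partners[0], mature_partners[-1] + 1
    if not (s_hi <= m0 or s_lo >= m1):
        return None, "mature pairs with itself"
    if s_lo >= m1:  # mature on 5' arm; star 3' end points away from the loop
        star = (s_lo, min(len(rna), s_hi + 2))
    else:           # mature on 3' arm; star 3' end points into the loop
        star = (s_lo, min(m0, s_hi + 2))

    # trim the window to the stem-loop span and re-fold the precursor
    lo = min(m0, star[0])
    hi = max(m1, star[1])
    precursor = rna[lo:hi]
    structure, mfe = fold_rna(precursor)

    # (c) stability
    if mfe > cfg.mfe_max or mfe / len(precursor) > cfg.mfe_per_nt_max:
        return None, "insufficient minimum free energy"
    if not is_single_stem_loop(structure, (m0 - lo, m1 - lo)):
        return None, "no single stem-loop"

    candidate = HairpinCandidate(
        provisional_id=provisional_id,
        mature=mature,
        precursor=precursor,
        structure=structure,
        mfe=mfe,
        read_count=cluster.read_count,
        star_interval=(star[0] - lo, star[1] - lo),
    )
    candidate.score = score_candidate(candidate)
    return candidate, "ok"


def score_candidate(candidate: HairpinCandidate) -> float:
    """Support score: log10 read support + stability + pairing bonus.

    Monotone increasing in read count and in -MFE.  This is a ranking
    heuristic, not a probabilistic miRDeep2 score.
    """
    paired = sum(1 for c in candidate.structure if c in "()")
    pairing_bonus = paired / len(candidate.structure)
    return math.log10(max(candidate.read_count, 1)) - candidate.mfe / 10.0 + pairing_bonus


def screen_scaffolds(scaffolds: Mapping[str, str],
                     unannotated: Iterable[CleanRead],
                     cfg: Optional[NovelConfig] = None,
                     ) -> list[HairpinCandidate]:
    """Full screen over scaffolds; one best candidate per read cluster."""
    cfg = cfg or NovelConfig()
    reads = list(unannotated)
    accepted: list[HairpinCandidate] = []
    for name in sorted(scaffolds):
        rna = to_rna(scaffolds[name])
        best_by_cluster: dict[int, HairpinCandidate] = {}
        for cluster, lo, hi in excise_candidates(rna, reads, cfg.window_flank):
            if cluster.read_count < cfg.min_read_count:
                continue
            pid = f"{name}_{cluster.start + 1}"
            cand, _ = evaluate_hairpin(rna[lo:hi], cluster, cfg, pid)
            if cand is None:
                continue
            prev = best_by_cluster.get(cluster.start)
            if prev is None or cand.score > prev.score:
                best_by_cluster[cluster.start] = cand
        accepted.extend(best_by_cluster[k] for k in sorted(best_by_cluster))
    return accepted


def candidates_to_frame(candidates: Iterable[HairpinCandidate]) -> pd.DataFrame:
    rows = [(c.provisional_id, round(c.score, 2), c.read_count, c.mature,
             c.precursor, c.structure, c.mfe) for c in candidates]
    return pd.DataFrame(rows, columns=[
        "provisional_id", "score", "read_count", "mirna_sequence",
        "consensus_precursor", "structure", "mfe"])
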