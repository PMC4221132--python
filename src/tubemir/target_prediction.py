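"""Dual-criterion miRNA target prediction.

Two independent re-implemented scorers are intersected:

* **Method A (alignment + energy, miRanda-like).**  A local complementarity
  alignment between the miRNA (5'->3') and a candidate site window scores
  +5 per Watson-Crick pair, +1 per G:U, -3 per mismatch, affine gaps (-8
  open, -2 extend), with columns falling on miRNA seed positions 2-8
  doubled.  Sites pass with score S >= 140, duplex dG <= -17 kcal/mol and a
  strict (no G:U, no gap) seed match.

* **Method B (seed + accessibility, PITA-like).**  Sites need a seed match
  and ddG = dG_duplex - dG_open below a threshold, where dG_open is the
  energy gained by the local target structure when the site is free to pair
  (always <= 0; subtracting it penalises occluded sites).

A transcript is a potential target only when sites from both methods
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import ALL_PAIRS, TargetConfig, WC_PAIRS, WOBBLE_PAIRS, revcomp, to_rna
from .fold import fold as fold_rna

logger = logging.getLogger(__name__)


@dataclass
class SeedMatch:
    kind: str                # none | 6mer | 7mer | 8mer
    gu_count: int = 0
    positions: tuple = ()    # matched miRNA positions (1-based)


@dataclass
class TargetSite:
    mirna: str
    transcript: str
    start: int               # 1-based inclusive on the transcript
    end: int
    score: float             # alignment score S
    dg: float                # duplex free energy, kcal/mol
    ddg: float               # accessibility-corrected energy, kcal/mol
    region: str = "other"    # 3'UTR | 5'UTR | other
    method: str = "A"
    seed: Optional[SeedMatch] = None


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------


def seed_match(mirna: str, site_window: str, strict: bool = True) -> SeedMatch:
    """Best seed-region complementarity of the miRNA within a site window.

    The seed (miRNA positions 2-8, 1-based, 5'->3') must pair contiguously
    and antiparallel with the target.  ``strict`` forbids G:U wobbles in the
    seed.  The window is scanned at every offset; an 8mer (positions 1-8 all
    Watson-Crick) beats a 7mer (2-8) beats a 6mer (2-7).
    """
    mir = to_rna(mirna)
    win = to_rna(site_window)
    if len(win) < 7:
        return SeedMatch(kind="none")
    rank = {"none": 0, "6mer": 1, "7mer": 2, "8mer": 3}
    best = SeedMatch(kind="none")
    # t = window index pairing with miRNA position 1; miRNA position p pairs
    # window index t - (p - 1) (antiparallel)
    for t in range(len(win) - 1, -1, -1):
        def pairing(p: int):
            idx = t - (p - 1)
            if idx < 0 or idx >= len(win):
                return None
            duo = (mir[p - 1], win[idx])
            if duo in WC_PAIRS:
                return "wc"
            if duo in WOBBLE_PAIRS:
                return "gu"
            return None

        states = {p: pairing(p) for p in range(1, 9)}
        ok = lambda p: states[p] == "wc" or (not strict and states[p] == "gu")
        if all(ok(p) for p in range(2, 9)):
            if all(states[p] == "wc" for p in range(1, 9)):
                kind, pos = "8mer", tuple(range(1, 9))
            else:
                kind, pos = "7mer", tuple(range(2, 9))
        elif all(ok(p) for p in range(2, 8)):
            kind, pos = "6mer", tuple(range(2, 8))
        else:
            continue
        gu = sum(1 for p in pos if states[p] == "gu")
        if strict and gu:
            continue
        if rank[kind] > rank[best.kind]:
            best = SeedMatch(kind=kind, gu_count=gu, positions=pos)
    return best


# ---------------------------------------------------------------------------
# duplex alignment (Gotoh local alignment on complementarity)
# ---------------------------------------------------------------------------


def _column_score(a: str, b: str, seed: bool, cfg: TargetConfig) -> float:
    duo = (a, b)
    if duo in WC_PAIRS:
        s = cfg.match_wc
    elif duo in WOBBLE_PAIRS:
        s = cfg.match_gu
    else:
        s = cfg.mismatch
    return 2 * s if seed else s


def duplex_align(mirna: str, site_window: str,
                 cfg: Optional[TargetConfig] = None) -> tuple[dict, float]:
    """Best local complementarity alignment; returns (alignment, S).

    The site window is reversed internally so that both strands read in the
    same direction; scores are as configured, seed columns (miRNA positions
    2-8) doubled, gaps affine.  S is clipped at 0.  Ties resolve to the
    leftmost, shortest alignment by scan order.
    """
    cfg = cfg or TargetConfig()
    mir = to_rna(mirna)
    win = to_rna(site_window)[::-1]  # antiparallel
    n, m = len(mir), len(win)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in window
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in miRNA
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        seed = cfg.seed_start <= i <= cfg.seed_end
        for j in range(1, m + 1):
            s = _column_score(mir[i - 1], win[j - 1], seed, cfg)
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + cfg.gap_open,
                           Ix[i - 1][j] + cfg.gap_extend)
            Iy[i][j] = max(M[i][j - 1] + cfg.gap_open,
                           Iy[i][j - 1] + cfg.gap_extend)
            if M[i][j] > best:
                best, best_ij = M[i][j], (i, j)
    alignment = {"mirna_end": None, "window_end": None}
    if best_ij:
        i, j = best_ij
        # window indices reported on the original (unreversed) orientation
        alignment = {"mirna_end": i, "window_end": m - j + 1}
    return alignment, best


# ---------------------------------------------------------------------------
# duplex free energy
# ---------------------------------------------------------------------------

DUPLEX_LOOP_BASE = 1.5
DUPLEX_LOOP_PER_NT = 0.4

from .fold import stack_energy  # same stacking table as the folder


def duplex_energy(mirna: str, site_window: str) -> float:
    """Minimum free energy of the intermolecular duplex, kcal/mol (<= 0).

    Dynamic program over antiparallel monotone pairings restricted to
    admissible base pairs: adjacent paired columns gain stacking energy,
    interrupted ones pay a loop/bulge penalty.  Zero paired columns give 0.
    """
    mir = to_rna(mirna)
    win = to_rna(site_window)[::-1]
    allowed = [(i, j) for i in range(len(mir)) for j in range(len(win))
               if (mir[i], win[j]) in ALL_PAIRS]
    # E[k] = best energy of a duplex whose last paired column is allowed[k]
    E = {}
    best = 0.0
    for k, (i, j) in enumerate(allowed):
        e = 0.0  # a lone pair contributes nothing
        for l, (a, b) in enumerate(allowed[:k]):
            if a >= i or b >= j:
                continue
            if a == i - 1 and b == j - 1:
                trans = stack_energy((mir[a], win[b]), (mir[i], win[j]))
            else:
                u = (i - a - 1) + (j - b - 1)
                trans = DUPLEX_LOOP_BASE + DUPLEX_LOOP_PER_NT * u
            e = min(e, E[l] + trans)
        E[k] = e
        best = min(best, e)
    return round(best, 6)


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------


def accessibility(mirna: str, transcript: str, site_start: int, site_end: int,
                  fold_window: int = 50) -> float:
    """ddG = dG_duplex - dG_open for a site (1-based, inclusive interval).

    dG_open = MFE(local window) - MFE(window with the site held unpaired);
    it is <= 0, and the more structure the site is buried in, the more
    negative it gets, raising ddG.
    """
    rna = to_rna(transcript)
    s0, s1 = site_start - 1, site_end  # to 0-based half-open
    if s0 < 0 or s1 > len(rna):
        logger.warning("site interval exceeds transcript; truncating")
        s0, s1 = max(0, s0), min(len(rna), s1)
    pad = max(0, (fold_window - (s1 - s0)) // 2)
    lo, hi = max(0, s0 - pad), min(len(rna), s1 + pad)
    window = rna[lo:hi]
    site = range(s0 - lo, s1 - lo)
    _, mfe_free = fold_rna(window)
    _, mfe_constrained = fold_rna(window, forbidden=site)
    dg_open = mfe_free - mfe_constrained
    dg_duplex = duplex_energy(mirna, rna[s0:s1])
    return round(dg_duplex - dg_open, 6)


# ---------------------------------------------------------------------------
# site scanning, thresholds, intersection
# ---------------------------------------------------------------------------


def _regions(name: str, seq: str, utr_intervals) -> list[tuple[int, int, str]]:
    """(start, end, label) 1-based inclusive regions to scan."""
    if utr_intervals and name in utr_intervals:
        return [(s, e, label) for (s, e, label) in utr_intervals[name]]
    return [(1, len(seq), "other")]


def _candidate_sites(mirna_seq: str, region_seq: str, strict: bool):
    """Offsets (0-based) in the region where a seed match ends a site."""
    L = len(mirna_seq)
    sites = []
    for t in range(6, len(region_seq)):
        window = region_seq[max(0, t - 7):t + 1]
        if seed_match(mirna_seq, window, strict=strict).kind != "none":
            # site spans the full miRNA footprint ending at the seed
            start = max(0, t - L - 3)
            sites.append((start, t + 1))
    return sites


def predict_targets(mirnas: Mapping[str, str], transcripts: Mapping[str, str],
                    cfg: Optional[TargetConfig] = None,
                    utr_intervals: Optional[Mapping] = None,
                    ) -> dict[str, list[TargetSite]]:
    """Run both scorers; returns ``{"A": [...], "B": [...]}``.

    ``utr_intervals`` maps transcript name to a list of (start, end, label)
    1-based inclusive regions; without it whole transcripts are scanned.
    """
    cfg = cfg or TargetConfig()
    out: dict[str, list[TargetSite]] = {"A": [], "B": []}
    for t_name in sorted(transcripts):
        t_seq = to_rna(transcripts[t_name])
        for r_start, r_end, label in _regions(t_name, t_seq, utr_intervals):
            region = t_seq[r_start - 1:r_end]
            for m_name in sorted(mirnas):
                m_seq = to_rna(mirnas[m_name])
                # method B scans with wobble-tolerant seeds
                seen = set()
                for s0, s1 in (_candidate_sites(m_seq, region, True)
                               + _candidate_sites(m_seq, region, False)):
                    if (s0, s1) in seen:
                        continue
                    seen.add((s0, s1))
                    window = region[s0:s1]
                    start = r_start + s0          # 1-based on transcript
                    end = r_start + s1 - 1
                    strict_seed = seed_match(m_seq, window, strict=True)
                    loose_seed = seed_match(m_seq, window, strict=False)
                    _, score = duplex_align(m_seq, window, cfg)
                    dg = duplex_energy(m_seq, window)
                    site = dict(mirna=m_name, transcript=t_name, start=start,
                                end=end, score=score, dg=dg, region=label)
                    if (strict_seed.kind != "none" and score >= cfg.s_min
                            and dg <= cfg.dg_max):
                        out["A"].append(TargetSite(
                            **site, ddg=float("nan"), method="A",
                            seed=strict_seed))
                    if loose_seed.kind != "none":
                        ddg = accessibility(m_seq, t_seq, start, end,
                                            cfg.fold_window)
                        if ddg <= cfg.ddg_max:
                            out["B"].append(TargetSite(
                                **site, ddg=ddg, method="B", seed=loose_seed))
    return out


def intersect(sites_a: Sequence[TargetSite], sites_b: Sequence[TargetSite],
              same_transcript_only: bool = False) -> list[str]:
    """Transcripts hit by both methods with >= 1 nt overlapping sites.

    With ``same_transcript_only`` the overlap requirement is dropped and a
    transcript qualifies as soon as both methods report any site on it.
    """
    by_transcript_a: dict[str, list[TargetSite]] = {}
    for s in sites_a:
        by_transcript_a.setdefault(s.transcript, []).append(s)
    hits = set()
    for s in sites_b:
        for a in by_transcript_a.get(s.transcript, ()):
            if same_transcript_only or (s.start <= a.end and a.start <= s.end):
                hits.add(s.transcript)
                break
    return sorted(hits)


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = [(s.mirna, s.transcript, s.start, s.end, s.score, s.dg, s.ddg,
             s.region, s.method, s.seed.kind if s.seed else "none")
            for s in sites]
    return pd.DataFrame(rows, columns=[
        "mirna", "transcript", "start", "end", "S", "dG", "ddG", "region",
        "method", "seed"])
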