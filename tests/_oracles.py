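"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the production algorithms: structures are checked
by exhaustive enumeration of all admissible pair sets, alignments by a
quartic column dynamic program with explicit gap-run costs, and duplex
energies by depth-first enumeration of all monotone pairings.
"""

from __future__ import annotations

from tubemir.config import ALL_PAIRS, to_rna
from tubemir.fold import MIN_HAIRPIN, energy_of_structure, stack_energy
from tubemir.target_prediction import DUPLEX_LOOP_BASE, DUPLEX_LOOP_PER_NT


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free pair set (0-based tuples) for ``seq``."""
    rna = to_rna(seq)
    n = len(rna)

    memo: dict[tuple[int, int], list[tuple]] = {}

    def structures(i: int, j: int) -> list[tuple]:
        """All pair sets on the half-open interval [i, j)."""
        if j - i <= MIN_HAIRPIN + 1:
            return [()]
        key = (i, j)
        if key not in memo:
            out = list(structures(i + 1, j))  # i unpaired
            for k in range(i + MIN_HAIRPIN + 1, j):
                if (rna[i], rna[k]) not in ALL_PAIRS:
                    continue
                for inner in structures(i + 1, k):
                    for outer in structures(k + 1, j):
                        out.append(((i, k),) + inner + outer)
            memo[key] = out
        return memo[key]

    yield from structures(0, n)


def brute_force_mfe(seq: str) -> float:
    """Minimum of the model energy over all enumerated structures."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = energy_of_structure(seq, list(pairs))
        if e < best:
            best = e
    return round(best, 6)


def _gap_cost(d: int, open_: float, extend: float) -> float:
    return 0.0 if d == 0 else open_ + extend * (d - 1)


def align_oracle(mirna: str, site_window: str, cfg) -> float:
    """Best local complementarity alignment score by a column DP.

    Columns (i, j) align miRNA base i with reversed-window base j; any
    monotone chain of columns is an alignment, and unmatched bases strictly
    between consecutive columns pay explicit affine gap-run costs.
    """
    from tubemir.target_prediction import _column_score

    mir = to_rna(mirna)
    win = to_rna(site_window)[::-1]
    n, m = len(mir), len(win)
    score = [[0.0] * m for _ in range(n)]
    for i in range(n):
        seed = cfg.seed_start <= i + 1 <= cfg.seed_end
        for j in range(m):
            score[i][j] = _column_score(mir[i], win[j], seed, cfg)

    best_total = 0.0
    end = [[0.0] * m for _ in range(n)]  # best alignment ending at column (i, j)
    for i in range(n):
        for j in range(m):
            best_prev = 0.0
            for pi in range(i):
                for pj in range(j):
                    gaps = (_gap_cost(i - pi - 1, cfg.gap_open, cfg.gap_extend)
                            + _gap_cost(j - pj - 1, cfg.gap_open, cfg.gap_extend))
                    best_prev = max(best_prev, end[pi][pj] + gaps)
            end[i][j] = score[i][j] + best_prev
            best_total = max(best_total, end[i][j])
    return best_total


def duplex_energy_oracle(mirna: str, site_window: str) -> float:
    """Minimum duplex energy by DFS over all monotone complementary pairings."""
    mir = to_rna(mirna)
    win = to_rna(site_window)[::-1]
    allowed = [(i, j) for i in range(len(mir)) for j in range(len(win))
               if (mir[i], win[j]) in ALL_PAIRS]
    best = [0.0]

    def extend(idx: int, energy: float) -> None:
        i, j = allowed[idx]
        if energy < best[0]:
            best[0] = energy
        for nxt in range(len(allowed)):
            a, b = allowed[nxt]
            if a <= i or b <= j:
                continue
            if a == i + 1 and b == j + 1:
                trans = stack_energy((mir[i], win[j]), (mir[a], win[b]))
            else:
                u = (a - i - 1) + (b - j - 1)
                trans = DUPLEX_LOOP_BASE + DUPLEX_LOOP_PER_NT * u
            extend(nxt, energy + trans)

    for k in range(len(allowed)):
        extend(k, 0.0)
    return round(best[0], 6)


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Composition-preserving shuffle by Euler-path resampling of dinucleotides."""
    rna = to_rna(seq)
    if len(rna) < 3:
        return rna
    edges: dict[str, list[str]] = {}
    for a, b in zip(rna, rna[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # keep the last edge of the terminal vertex walkable: retry until the
    # greedy walk consumes every edge
    for _ in range(100):
        trial = {a: list(bs) for a, bs in edges.items()}
        for a in trial:
            rng.shuffle(trial[a])
        out = [rna[0]]
        cur = rna[0]
        ok = True
        for _ in range(len(rna) - 1):
            if not trial.get(cur):
                ok = False
                break
            cur = trial[cur].pop()
            out.append(cur)
        if ok:
            return "".join(out)
    return rna[::-1]  # degenerate fallback, still composition-preserving
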