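"""Minimum-free-energy RNA secondary-structure prediction.

A Zuker-style dynamic program over a deliberately simple stacking energy
model: helices gain energy per stacked pair (Watson-Crick and G:U pairs),
hairpin/interior/bulge/multibranch loops pay size-dependent penalties.
Structures are pseudoknot-free, hairpin loops hold at least 3 unpaired
nucleotides, and the empty structure scores 0, so the reported minimum free
energy is never positive.

The model is *not* the Turner nearest-neighbour parameter set; it is a
self-contained approximation adequate for hairpin detection and relative
stability ranking.  ``energy_of_structure`` is the definition of the model:
the dynamic program below returns the exact optimum of that function over
all admissible structures (verified against exhaustive enumeration in the
test suite).
"""

from __future__ import annotations

from .config import ALL_PAIRS, RNA_BASES, to_rna

# --- energy model parameters (kcal/mol) ------------------------------------

#: pair "strength" used to build the stack table
_STRENGTH = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}

HAIRPIN_BASE = 4.5
HAIRPIN_PER_NT = 0.3        # per unpaired nt beyond the 3-nt minimum
INTERIOR_BASE = 2.0
INTERIOR_PER_NT = 0.4       # per unpaired nt in a bulge/interior loop
MULTI_CLOSE = 4.0
MULTI_BRANCH = 1.0
MULTI_UNPAIRED = 0.2
MIN_HAIRPIN = 3
MAX_INTERIOR = 30           # loops larger than this are not considered

_INF = float("inf")


def stack_energy(outer: tuple, inner: tuple) -> float:
    """Energy of ``inner`` stacked directly on ``outer`` (negative)."""
    return -(0.5 * (_STRENGTH[outer] + _STRENGTH[inner]) + 0.5)


def hairpin_energy(size: int) -> float:
    return HAIRPIN_BASE + HAIRPIN_PER_NT * (size - MIN_HAIRPIN)


def interior_energy(unpaired: int) -> float:
    return INTERIOR_BASE + INTERIOR_PER_NT * unpaired


def _check_alphabet(seq: str) -> str:
    rna = to_rna(seq)
    bad = set(rna) - set(RNA_BASES)
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")
    return rna


# --- structure representation ----------------------------------------------


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Decode a dot-bracket string into a sorted list of 0-based pairs."""
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def energy_of_structure(seq: str, structure) -> float:
    """Free energy of a given structure under the package's model.

    ``structure`` is a dot-bracket string or a list of 0-based (i, j) pairs.
    Every pair must be an admissible base pair with a hairpin loop of at
    least 3 nt.  This function defines the energy model; ``fold`` minimises
    it.
    """
    rna = _check_alphabet(seq)
    if isinstance(structure, str):
        pairs = pairs_from_dotbracket(structure)
    else:
        pairs = sorted(structure)
    for i, j in pairs:
        if (rna[i], rna[j]) not in ALL_PAIRS:
            raise ValueError(f"inadmissible pair {rna[i]}:{rna[j]} at ({i},{j})")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError("hairpin loop below minimum size")

    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def loop_energy(i: int, j: int) -> float:
        """Energy of the loop closed by pair (i, j) plus its sub-loops."""
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            return hairpin_energy(j - i - 1)
        if len(children) == 1:
            (k, l), = children
            sub = loop_energy(k, l)
            if k == i + 1 and l == j - 1:
                return sub + stack_energy((rna[i], rna[j]), (rna[k], rna[l]))
            return sub + interior_energy(unpaired)
        total = MULTI_CLOSE + MULTI_BRANCH * len(children)
        total += MULTI_UNPAIRED * unpaired
        for k, l in children:
            total += loop_energy(k, l)
        return total

    # exterior loop: unpaired bases are free
    energy = 0.0
    seen = set()
    for i, j in pairs:
        enclosed = any(a < i and j < b for a, b in pairs)
        if not enclosed and i not in seen:
            energy += loop_energy(i, j)
            seen.add(i)
    return energy


# --- the dynamic program ----------------------------------------------------


def fold(seq: str, forbidden=None) -> tuple[str, float]:
    """Fold an RNA sequence; return ``(dot_bracket, mfe_kcal_per_mol)``.

    ``forbidden`` is an optional iterable of 0-based positions constrained
    to stay unpaired (used for target-site accessibility).  Deterministic:
    ties are broken by a fixed scan order.
    """
    rna = _check_alphabet(seq)
    n = len(rna)
    if n < MIN_HAIRPIN + 2:
        return "." * n, 0.0
    blocked = set(forbidden) if forbidden else set()

    def pairable(i: int, j: int) -> bool:
        return (
            j - i - 1 >= MIN_HAIRPIN
            and i not in blocked
            and j not in blocked
            and (rna[i], rna[j]) in ALL_PAIRS
        )

    V = [[_INF] * n for _ in range(n)]
    WM = [[_INF] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            # V: i pairs j
            if pairable(i, j):
                best = hairpin_energy(j - i - 1)
                outer = (rna[i], rna[j])
                # stack / interior / bulge
                kmax = min(j - 1, i + 1 + MAX_INTERIOR)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + MIN_HAIRPIN + 1,
                               j - 1 - (MAX_INTERIOR - (k - i - 1)))
                    for l in range(lmin, j):
                        if V[k][l] == _INF:
                            continue
                        u = (k - i - 1) + (j - l - 1)
                        if k == i + 1 and l == j - 1:
                            cand = V[k][l] + stack_energy(outer, (rna[k], rna[l]))
                        else:
                            cand = V[k][l] + interior_energy(u)
                        if cand < best:
                            best = cand
                # multibranch: >= 2 branches inside
                for r in range(i + 1, j - 1):
                    if WM[i + 1][r] == _INF or WM[r + 1][j - 1] == _INF:
                        continue
                    cand = MULTI_CLOSE + WM[i + 1][r] + WM[r + 1][j - 1]
                    if cand < best:
                        best = cand
                V[i][j] = best
            # WM: >= 1 branch in i..j in a multiloop context
            best = WM[i + 1][j] + MULTI_UNPAIRED if i + 1 <= j else _INF
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if V[i][k] == _INF:
                    continue
                branch = V[i][k] + MULTI_BRANCH
                tail = MULTI_UNPAIRED * (j - k)
                if k + 1 <= j and WM[k + 1][j] < tail:
                    tail = WM[k + 1][j]
                if branch + tail < best:
                    best = branch + tail
            WM[i][j] = best
        # spans shorter than the minimum still need WM defined
    for i in range(n):
        for j in range(i, min(n, i + MIN_HAIRPIN + 1)):
            WM[i][j] = _INF

    # exterior loop
    W = [0.0] * (n + 1)  # W[j+1] = best energy of prefix 0..j
    choice = [None] * (n + 1)
    for j in range(n):
        best = W[j]
        pick = None
        for k in range(0, j - MIN_HAIRPIN):
            if V[k][j] == _INF:
                continue
            cand = V[k][j] + W[k]
            if cand < best:
                best = cand
                pick = k
        W[j + 1] = best
        choice[j + 1] = pick

    mfe = W[n]
    if mfe >= 0.0:
        return "." * n, 0.0

    # --- traceback ---
    pairs: list[tuple[int, int]] = []

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i][j]
        outer = (rna[i], rna[j])
        if abs(target - hairpin_energy(j - i - 1)) < 1e-9:
            return
        kmax = min(j - 1, i + 1 + MAX_INTERIOR)
        for k in range(i + 1, kmax + 1):
            lmin = max(k + MIN_HAIRPIN + 1,
                       j - 1 - (MAX_INTERIOR - (k - i - 1)))
            for l in range(lmin, j):
                if V[k][l] == _INF:
                    continue
                u = (k - i - 1) + (j - l - 1)
                if k == i + 1 and l == j - 1:
                    cand = V[k][l] + stack_energy(outer, (rna[k], rna[l]))
                else:
                    cand = V[k][l] + interior_energy(u)
                if abs(cand - target) < 1e-9:
                    trace_V(k, l)
                    return
        for r in range(i + 1, j - 1):
            if WM[i + 1][r] == _INF or WM[r + 1][j - 1] == _INF:
                continue
            if abs(MULTI_CLOSE + WM[i + 1][r] + WM[r + 1][j - 1] - target) < 1e-9:
                trace_WM(i + 1, r)
                trace_WM(r + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        target = WM[i][j]
        if i + 1 <= j and abs(WM[i + 1][j] + MULTI_UNPAIRED - target) < 1e-9:
            trace_WM(i + 1, j)
            return
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if V[i][k] == _INF:
                continue
            branch = V[i][k] + MULTI_BRANCH
            if abs(branch + MULTI_UNPAIRED * (j - k) - target) < 1e-9:
                trace_V(i, k)
                return
            if k + 1 <= j and WM[k + 1][j] != _INF and \
                    abs(branch + WM[k + 1][j] - target) < 1e-9:
                trace_V(i, k)
                trace_WM(k + 1, j)
                return
        raise AssertionError("traceback failed in WM")  # pragma: no cover

    j = n
    while j > 0:
        k = choice[j]
        if k is None:
            j -= 1
        else:
            trace_V(k, j - 1)
            j = k

    return dotbracket_from_pairs(n, pairs), round(mfe, 6)


def hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """Closing pairs (0-based) of all terminal (hairpin) loops."""
    pairs = pairs_from_dotbracket(structure)
    loops = []
    for i, j in pairs:
        if all(c not in "()" for c in structure[i + 1:j]):
            loops.append((i, j))
    return loops
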