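"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (definitions, enumeration,
dynamic programming) and deliberately shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

_BASES = "ACGT"

# standard genetic code written out explicitly (independent of Biopython)
_CODE = {}
_AA_TABLE = [
    ("F", ["TTT", "TTC"]),
    ("L", ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]),
    ("I", ["ATT", "ATC", "ATA"]),
    ("M", ["ATG"]),
    ("V", ["GTT", "GTC", "GTA", "GTG"]),
    ("S", ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"]),
    ("P", ["CCT", "CCC", "CCA", "CCG"]),
    ("T", ["ACT", "ACC", "ACA", "ACG"]),
    ("A", ["GCT", "GCC", "GCA", "GCG"]),
    ("Y", ["TAT", "TAC"]),
    ("H", ["CAT", "CAC"]),
    ("Q", ["CAA", "CAG"]),
    ("N", ["AAT", "AAC"]),
    ("K", ["AAA", "AAG"]),
    ("D", ["GAT", "GAC"]),
    ("E", ["GAA", "GAG"]),
    ("C", ["TGT", "TGC"]),
    ("W", ["TGG"]),
    ("R", ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"]),
    ("G", ["GGT", "GGC", "GGA", "GGG"]),
    ("*", ["TAA", "TAG", "TGA"]),
]
for _aa, _codons in _AA_TABLE:
    for _c in _codons:
        _CODE[_c] = _aa
assert len(_CODE) == 64

STOPS = {c for c, a in _CODE.items() if a == "*"}


def bf_codon_sites(codon: str) -> Fraction:
    """Synonymous site count by direct enumeration of all 9 point changes."""
    aa = _CODE[codon]
    s = Fraction(0)
    for pos, alt in itertools.product(range(3), _BASES):
        if alt == codon[pos]:
            continue
        mut = codon[:pos] + alt + codon[pos + 1 :]
        if mut not in STOPS and _CODE[mut] == aa:
            s += Fraction(1, 3)
    return s


def bf_pair_diffs(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (synonymous, non-synonymous) difference counts."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return Fraction(0), Fraction(0)
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, through_stop = c1, Fraction(0), Fraction(0), False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOPS and nxt != c2:
                through_stop = True
            if cur in STOPS or nxt in STOPS:
                nd += 1
            elif _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    clean = [r for r in results if not r[2]]
    used = clean if clean else results
    sd = sum(r[0] for r in used) / len(used)
    nd = sum(r[1] for r in used) / len(used)
    return sd, nd


def bf_pair_divergence(a: str, b: str) -> dict:
    """NG86 divergence of two aligned rows by per-codon enumeration."""
    S = Fraction(0)
    N = Fraction(0)
    sd = Fraction(0)
    nd = Fraction(0)
    ndiff = 0
    ncod = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in STOPS or cb in STOPS:
            continue
        ncod += 1
        S += (bf_codon_sites(ca) + bf_codon_sites(cb)) / 2
        d = bf_pair_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
        ndiff += sum(x != y for x, y in zip(ca, cb))
    N = 3 * ncod - S

    def jc(p: Fraction) -> float:
        p = float(p)
        if p >= 0.75:
            return float("nan")
        return -0.75 * np.log1p(-4.0 * p / 3.0)

    pS = float(sd / S) if S else float("nan")
    pN = float(nd / N) if N else float("nan")
    p = ndiff / (3.0 * ncod) if ncod else float("nan")
    return {
        "pS": pS,
        "pN": pN,
        "p": p,
        "dS": jc(pS),
        "dN": jc(pN),
        "d": jc(p),
        "S": float(S),
        "N": float(N),
        "n_codons": ncod,
    }


def nw_align_score(a: str, b: str) -> float:
    """Gotoh affine-gap global alignment score with free end gaps.

    Same policy as the package aligner: match +1, mismatch -1, gap open -4
    (cost of the first gap base), extend -0.5; terminal gaps free.
    """
    MATCH, MISM, OPEN, EXT = 1.0, -1.0, -4.0, -0.5
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free left end gap
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISM
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + OPEN, X[i - 1, j] + EXT)
            Y[i, j] = max(M[i, j - 1] + OPEN, Y[i, j - 1] + EXT)
    # free right end gaps: best over last row/column
    best = max(M[n, m], X[n, m], Y[n, m])
    for i in range(n):
        best = max(best, M[i, m], Y[i, m])
    for j in range(m):
        best = max(best, M[n, j], X[n, j])
    return float(best)


def bf_dollo_min_cost(occupied: set, tree) -> int:
    """Minimum event count for one Dollo character by exhaustive search.

    ``tree`` is a rooted dendropy tree; ``occupied`` the tip labels where the
    character occurs.  One gain (any node) plus any subset of loss edges
    strictly below it; a scenario is consistent iff every occupied tip is
    below the gain with no loss on its path and every other tip is not.
    Pseudogenisation events are not modelled here (they are a constant).
    """
    if not occupied:
        return 0
    nodes = list(tree.preorder_node_iter())
    tips_of = {
        id(n): frozenset(lf.taxon.label for lf in n.leaf_iter()) for n in nodes
    }
    best = None
    for gain in nodes:
        if not occupied <= tips_of[id(gain)]:
            continue
        below = [n for n in gain.preorder_iter() if n is not gain]
        for r in range(len(below) + 1):
            if best is not None and 1 + r >= best:
                break
            for combo in itertools.combinations(below, r):
                lost = set()
                for n in combo:
                    lost |= tips_of[id(n)]
                covered = tips_of[id(gain)] - lost
                if covered == occupied:
                    best = 1 + r
                    break
            else:
                continue
            break
    assert best is not None
    return best
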