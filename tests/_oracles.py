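"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths (and Biopython):
set-based IUPAC matching, naive window enumeration for the site scanner, a
textbook Gotoh affine-gap DP for alignment scores, and combination
enumeration for the exact rank-sum null.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T", "N"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_match(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(window, pattern)
    )


_COMBO_FLANKS = {
    "cpf1_sp_sa": ("NGGRRT", (17, 25)),
    "cpf1_sp_nm": ("NGGNGATT", (17, 25)),
    "cpf1_nm_long": ("NNNNGATT", (24, 25)),
}


def brute_force_scan(seq: str, combo: str, lo: int = 17, hi: int = 25):
    """Every (start, end, strand) matched-site window, by naive enumeration."""
    flank3, cap = _COMBO_FLANKS[combo]
    lo, hi = max(lo, cap[0]), min(hi, cap[1])
    n = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        for L in range(lo, hi + 1):
            span = 4 + L + len(flank3)
            for i in range(n - span + 1):
                window = s[i : i + span]
                if "N" in window:
                    continue
                if not naive_match(window[:4], "TTTN"):
                    continue
                if not naive_match(window[4 + L :], flank3):
                    continue
                if strand == "+":
                    found.add((i + 4, i + 4 + L, "+"))
                else:
                    found.add((n - (i + 4 + L), n - (i + 4), "-"))
    return found


def gotoh_score(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Textbook Gotoh affine-gap DP, semi-global: gap runs in the read at
    either end of the reference (reference overhang) are free; read overhang
    is penalised. A gap of length k costs open + (k-1)*extend."""
    m, n = len(ref), len(read)
    M = [[-inf] * (n + 1) for _ in range(m + 1)]  # ends in (mis)match
    X = [[-inf] * (n + 1) for _ in range(m + 1)]  # ends in gap-in-read (D)
    Y = [[-inf] * (n + 1) for _ in range(m + 1)]  # ends in gap-in-ref (I)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0  # free leading reference overhang
    for j in range(1, n + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    # free trailing reference overhang: best over all reference prefixes
    return max(max(M[i][n], X[i][n], Y[i][n]) for i in range(m + 1))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def enumerate_rank_sum_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = list(a) + list(b)
    ranks = _midranks(pooled)
    na, n = len(a), len(pooled)
    w_obs = sum(ranks[:na])
    ew = na * (n + 1) / 2.0
    dev = abs(w_obs - ew)
    hits = sum(
        1
        for idx in combinations(range(n), na)
        if abs(sum(ranks[i] for i in idx) - ew) >= dev - 1e-12
    )
    return hits / comb(n, na)
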