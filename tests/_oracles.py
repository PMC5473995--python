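"""Independent reference implementations used only to check the package.

These deliberately share nothing with the production code paths beyond the
substitution-matrix constants: plain recursion that enumerates every
alignment, a hand-written quadratic Gotoh DP, subset enumeration for
chaining, and literal re-statements of the classification rule sets.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BL62 = substitution_matrices.load("BLOSUM62")


def sub_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_BL62[a, b])


def exhaustive_global_score(a: str, b: str, gap_open: float = 10.0,
                            gap_extend: float = 0.1) -> float:
    """Max score over *all* global alignments, by plain recursion.

    A gap of length L costs gap_open + gap_extend*L.  Exponential; only for
    sequences of length <= ~8.
    """
    first = gap_open + gap_extend

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, sub_score(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if last == "d" else first
            best = max(best, -cost + rec(i + 1, j, "d"))
        if j < len(b):
            cost = gap_extend if last == "i" else first
            best = max(best, -cost + rec(i, j + 1, "i"))
        return best

    return rec(0, 0, "")


def gotoh_global_score(a: str, b: str, gap_open: float = 10.0,
                       gap_extend: float = 0.1) -> float:
    """Quadratic affine-gap global alignment score (three-state Gotoh)."""
    NEG = float("-inf")
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = -(first + gap_extend * (i - 1))
    for j in range(1, m + 1):
        I[0][j] = -(first + gap_extend * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub_score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1],
                          I[i - 1][j - 1]) + s
            D[i][j] = max(M[i - 1][j] - first, D[i - 1][j] - gap_extend,
                          I[i - 1][j] - first)
            I[i][j] = max(M[i][j - 1] - first, I[i][j - 1] - gap_extend,
                          D[i][j - 1] - first)
    return max(M[n][m], D[n][m], I[n][m])


def sw_local_score(a: str, b: str, gap_open: float = 10.0,
                   gap_extend: float = 0.1) -> float:
    """Quadratic affine-gap Smith–Waterman optimal local score."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - first)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - first)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + sub_score(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def exhaustive_local_score(a: str, b: str, **kw) -> float:
    """Max over all substring pairs of the exhaustive global score, floored
    at 0 (the empty alignment).  Only for tiny sequences."""
    best = 0.0
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, exhaustive_global_score(a[i0:i1], b[j0:j1], **kw))
    return best


def best_chain_score_bruteforce(hits) -> float:
    """Max total score over all strictly-collinear hit subsets (<= ~12)."""
    best = 0.0
    idx = list(range(len(hits)))
    for r in range(1, len(hits) + 1):
        for combo in itertools.combinations(idx, r):
            sub = [hits[i] for i in combo]
            sub = sorted(sub, key=lambda h: (h.q_start, h.ref_start))
            ok = all(
                u.q_start < v.q_start and u.ref_start < v.ref_start
                for u, v in zip(sub, sub[1:])
            )
            if ok:
                best = max(best, sum(h.score for h in sub))
    return best


# ---------------------------------------------------------------------------
# Rule oracles

def intron_category_oracle(present_roles: list[str]) -> str:
    """Literal re-statement of the intron-site conservation categories,
    operating on the list of group roles of the genes carrying the site."""
    spider = sum(r == "spider" for r in present_roles)
    a3 = sum(r == "arthropod_typeIII" for r in present_roles)
    a4 = sum(r == "arthropod_typeIV" for r in present_roles)
    non = sum(r == "non_arthropod" for r in present_roles)
    other_arth = a3 + a4
    if spider > 0 and other_arth > 0 and non > 0:
        return "broadly_shared"
    if spider > 0 and non > 0 and other_arth == 0:
        return "spider_plus_nonarthropod"
    if spider == 0 and non == 0 and a3 > 0 and a4 > 0:
        return "typeIII_typeIV_shared"
    if non == 0 and spider > 0 and other_arth > 0:
        return "arthropod_specific"
    if non >= 2 and spider == 0 and other_arth == 0:
        return "nonarthropod_shared"
    return "unshared"


def conservation_status_oracle(occ: dict[str, float],
                               threshold: float = 0.8) -> str:
    labels = list(occ)
    high = {g for g in labels if occ[g] >= threshold}
    zero = {g for g in labels if occ[g] == 0.0}
    if high == set(labels):
        return "stable"
    if len(zero) == 1 and high == set(labels) - zero:
        return "lineage_loss"
    if len(high) == 1 and zero == set(labels) - high:
        return "lineage_gain"
    return "sporadic"
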