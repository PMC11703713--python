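"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: plain-Python dynamic
programming, hash maps and set algebra.
"""

from __future__ import annotations

from collections import Counter

NEG = float("-inf")


def affine_glocal_score(
    q: str,
    r: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> float:
    """Gotoh affine alignment score with free end gaps on both sequences.

    States: M (aligned pair), X (gap in r, consuming q), Y (gap in q,
    consuming r). Gaps lying along the matrix edges (before either sequence
    starts or after either ends) are free.
    """
    n, m = len(q), len(r)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading query overhang, free
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # leading reference overhang, free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if j == m:  # trailing query overhang, free
                X[i][j] = max(M[i - 1][j], X[i - 1][j], Y[i - 1][j])
            else:
                X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                              Y[i - 1][j] + gap_open)
            if i == n:  # trailing reference overhang, free
                Y[i][j] = max(M[i][j - 1], X[i][j - 1], Y[i][j - 1])
            else:
                Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                              X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def expected_miscalls_oracle(quals) -> float:
    total = 0.0
    for q in quals:
        total += 10.0 ** (-q / 10.0)
    return total


def dedup_oracle(seqs) -> list[tuple[str, int]]:
    counts = Counter(str(s) for s in seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def jaccard_oracle(a, b) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def venn_oracle(named_sets: dict) -> dict:
    sets = {k: set(v) for k, v in named_sets.items()}
    names = list(sets)
    out = {}
    universe = set().union(*sets.values()) if sets else set()
    for x in universe:
        members = frozenset(k for k in names if x in sets[k])
        out[members] = out.get(members, 0) + 1
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            out.setdefault(frozenset(combo), 0)
    return out
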