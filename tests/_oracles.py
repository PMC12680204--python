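"""Independent brute-force oracles used to cross-check package routines.

These are deliberately naive implementations kept free of any code sharing
with the package internals they verify.
"""

from __future__ import annotations

NEG = -(10 ** 6)


def brute_local_score(q: str, t: str) -> int:
    """Best local alignment score: match +1, mismatch -1, each gap opening -1
    with free extensions.  Plain cell-by-cell Gotoh, no vectorisation."""
    n, m = len(q), len(t)
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    P = [[NEG] * (m + 1) for _ in range(n + 1)]
    Q = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if (q[i - 1] == t[j - 1] and q[i - 1] in "ACGT") else -1
            D[i][j] = s + max(0, D[i - 1][j - 1], P[i - 1][j - 1], Q[i - 1][j - 1])
            P[i][j] = max(P[i][j - 1], D[i][j - 1] - 1, Q[i][j - 1] - 1)
            Q[i][j] = max(Q[i - 1][j], D[i - 1][j] - 1, P[i - 1][j] - 1)
            if D[i][j] > best:
                best = D[i][j]
    return best


def brute_maf(calls) -> float | None:
    """Allele-count MAF by direct enumeration of genotype codes."""
    alt = 0
    total = 0
    for c in calls:
        if c == -1:
            continue
        alt += int(c)
        total += 2
    if total == 0:
        return None
    f = alt / total
    return min(f, 1 - f)


def analytic_bin(maf: float) -> str:
    """Closed-form spectrum bin of a MAF value (duplicated deliberately)."""
    if maf == 0:
        return "Monomorphic"
    if maf < 0.01:
        return "<0.01"
    if maf < 0.05:
        return "0.01~0.05"
    if maf < 0.10:
        return "0.05~0.10"
    if maf < 0.20:
        return "0.10~0.20"
    if maf < 0.30:
        return "0.20~0.30"
    if maf <= 0.40:
        return "0.30~0.40"
    return "0.40>"
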