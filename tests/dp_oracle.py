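"""Brute-force affine-gap local alignment oracle.

A deliberately simple Gotoh dynamic program written independently of the
package's alignment engine, used to cross-check scores on small inputs.
Scoring convention matches AlignParams: a gap of length L costs
gap_open + L * gap_extend.
"""

NEG = float("-inf")


def local_score(q: str, t: str, match=1, mismatch=2, gap_open=3, gap_extend=1) -> int:
    """Best Smith-Waterman score with affine gaps (0 if nothing aligns)."""
    n, m = len(q), len(t)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend,
                E[i - 1][j] - gap_extend,
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend,
                F[i][j - 1] - gap_extend,
            )
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)
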