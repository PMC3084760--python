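"""Independent reference implementations used only to check the package.

These are deliberately naive (full-matrix Gotoh dynamic programming,
window-scan motif search) and share no code with the implementation under
test.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal Smith–Waterman score with affine gaps (cost open + L*extend)."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    match = [[0.0] * (m + 1) for _ in range(n + 1)]
    gap_a = [[NEG] * (m + 1) for _ in range(n + 1)]  # a-residue over gap
    gap_b = [[NEG] * (m + 1) for _ in range(n + 1)]  # b-residue over gap
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            match[i][j] = s + max(
                0.0, match[i - 1][j - 1], gap_a[i - 1][j - 1], gap_b[i - 1][j - 1]
            )
            gap_a[i][j] = max(match[i - 1][j] - first, gap_a[i - 1][j] - gap_extend)
            gap_b[i][j] = max(match[i][j - 1] - first, gap_b[i][j - 1] - gap_extend)
            best = max(best, match[i][j])
    return best


def gotoh_global_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal Needleman–Wunsch score with affine gaps, end gaps penalized."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    match = [[NEG] * (m + 1) for _ in range(n + 1)]
    gap_a = [[NEG] * (m + 1) for _ in range(n + 1)]
    gap_b = [[NEG] * (m + 1) for _ in range(n + 1)]
    match[0][0] = 0.0
    for i in range(1, n + 1):
        gap_a[i][0] = -first - (i - 1) * gap_extend
    for j in range(1, m + 1):
        gap_b[0][j] = -first - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            match[i][j] = s + max(
                match[i - 1][j - 1], gap_a[i - 1][j - 1], gap_b[i - 1][j - 1]
            )
            gap_a[i][j] = max(match[i - 1][j] - first, gap_a[i - 1][j] - gap_extend)
            gap_b[i][j] = max(match[i][j - 1] - first, gap_b[i][j - 1] - gap_extend)
    return max(match[n][m], gap_a[n][m], gap_b[n][m])


def scan_motif_1(s: str) -> bool:
    """H, any, aromatic, any, E — naive window scan."""
    return any(
        s[i] == "H" and s[i + 2] in "FYW" and s[i + 4] == "E"
        for i in range(len(s) - 4)
    )


def scan_motif_2(s: str) -> bool:
    """H, H, any, aromatic, aromatic, 17 arbitrary, E — naive window scan."""
    return any(
        s[i] == "H" and s[i + 1] == "H" and s[i + 3] in "FYW"
        and s[i + 4] in "FYW" and s[i + 22] == "E"
        for i in range(len(s) - 22)
    )
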