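"""Longest-common-subsequence primitives shared by the fuzzy matcher and simeval.

``lcs_length`` uses the bit-parallel algorithm of Crochemore, Iliopoulos &
Pinzon, which processes 64+ grid columns per machine word via Python's
arbitrary-precision integers. ``lcs_table`` is the plain quadratic DP kept for
traceback-based difference extraction.
"""

from __future__ import annotations

from collections import defaultdict

__all__ = ["lcs_length", "lcs_ratio", "lcs_matched_mask"]


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``."""
    if not a or not b:
        return 0
    # ensure the bit vector spans the shorter string
    if len(b) > len(a):
        a, b = b, a
    m = len(b)
    masks: defaultdict[str, int] = defaultdict(int)
    for j, ch in enumerate(b):
        masks[ch] |= 1 << j
    full = (1 << m) - 1
    row = full
    for ch in a:
        u = row & masks[ch]
        if u:
            row = ((row + u) | (row - u)) & full
    # zero bits of the final row count LCS symbols
    return m - bin(row).count("1")


def lcs_ratio(a: str, b: str) -> float:
    """SequenceMatcher-style similarity ``2*LCS/(len(a)+len(b))``; 1.0 for two empties."""
    denom = len(a) + len(b)
    if denom == 0:
        return 1.0
    return 2.0 * lcs_length(a, b) / denom


def lcs_matched_mask(reference: str, candidate: str) -> list[bool]:
    """Per-character mask of ``reference``: True where the character belongs to
    one fixed optimal LCS alignment with ``candidate``.

    Quadratic in time and memory; callers guard the input size.
    """
    n, m = len(reference), len(candidate)
    mask = [False] * n
    if n == 0 or m == 0:
        return mask
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        ri = reference[i]
        dpi, dpn = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            if ri == candidate[j]:
                dpi[j] = dpn[j + 1] + 1
            else:
                nxt = dpn[j]
                cur = dpi[j + 1]
                dpi[j] = nxt if nxt >= cur else cur
    i = j = 0
    while i < n and j < m:
        if reference[i] == candidate[j]:
            mask[i] = True
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return mask
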