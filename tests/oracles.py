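"""Independent brute-force oracles used by the test suite.

These stay deliberately naive (full quadratic dynamic programming, direct
counting) and independent of the package's implementations they check.
"""

from __future__ import annotations


def dp_lcs(a: str, b: str) -> int:
    """Textbook quadratic LCS table; returns the LCS length."""
    n, m = len(a), len(b)
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n):
        for j in range(m):
            if a[i] == b[j]:
                table[i + 1][j + 1] = table[i][j] + 1
            else:
                table[i + 1][j + 1] = max(table[i][j + 1], table[i + 1][j])
    return table[n][m]


def lcs_similarity_oracle(reference: str, candidate: str) -> float:
    if not reference:
        return 1.0
    return dp_lcs(reference, candidate) / len(reference)


def fuzzy_ratio_oracle(a: str, b: str) -> float:
    denom = len(a) + len(b)
    if denom == 0:
        return 1.0
    return 2.0 * dp_lcs(a, b) / denom


def count_chains(chains: list[list[str]]) -> tuple[dict, dict]:
    """Direct node/edge weight tally over label chains."""
    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], int] = {}
    for chain in chains:
        for label in chain:
            nodes[label] = nodes.get(label, 0) + 1
        for u, v in zip(chain, chain[1:]):
            edges[(u, v)] = edges.get((u, v), 0) + 1
    return nodes, edges
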