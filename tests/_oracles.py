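"""Independent brute-force oracles used by the tests.

These enumerate alignment paths explicitly (depth-first over the three moves
with the affine gap state carried along) so they share no code with the
dynamic-programming implementation they check.
"""

from __future__ import annotations

import math


def global_best_score(a: str, b: str, sc) -> float:
    """Max score over every global alignment path (end gaps penalised)."""
    best = -math.inf

    def rec(i: int, j: int, last: str, score: float):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "d", score + sc.score_pair(a[i], b[j]))
        if i < len(a):
            cost = sc.gap_extend if last == "u" else sc.gap_open
            rec(i + 1, j, "u", score - cost)
        if j < len(b):
            cost = sc.gap_extend if last == "l" else sc.gap_open
            rec(i, j + 1, "l", score - cost)

    rec(0, 0, "d", 0.0)
    return best


def local_best_score(a: str, b: str, sc) -> float:
    """Max over every local alignment path; 0 when nothing positive.

    A local alignment starts and ends on an aligned residue pair (gaps at the
    ends can only lower the score), so the enumeration starts a path at every
    (i, j) cell with a diagonal move and records the running score after each
    diagonal move.
    """
    best = 0.0

    def rec(i: int, j: int, last: str, score: float):
        nonlocal best
        if last == "d":
            best = max(best, score)
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "d", score + sc.score_pair(a[i], b[j]))
        if i < len(a) and last != "s":
            cost = sc.gap_extend if last == "u" else sc.gap_open
            rec(i + 1, j, "u", score - cost)
        if j < len(b) and last != "s":
            cost = sc.gap_extend if last == "l" else sc.gap_open
            rec(i, j + 1, "l", score - cost)

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, "s", 0.0)
    return best


def random_additive_matrix(n, rng):
    """Leaf distances from a random weighted unrooted binary tree."""
    import networkx as nx
    import numpy as np

    G = nx.Graph()
    G.add_edge("L0", "L1", weight=float(rng.uniform(0.5, 3)))
    inner = 0
    for k in range(2, n):
        edges = list(G.edges())
        u, v = edges[rng.integers(len(edges))]
        G.remove_edge(u, v)
        inner += 1
        mid = f"I{inner}"
        G.add_edge(u, mid, weight=float(rng.uniform(0.5, 3)))
        G.add_edge(mid, v, weight=float(rng.uniform(0.5, 3)))
        G.add_edge(mid, f"L{k}", weight=float(rng.uniform(0.5, 3)))
    leaves = [f"L{k}" for k in range(n)]
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            D[i, j] = lengths[a][b]
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return leaves, D
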