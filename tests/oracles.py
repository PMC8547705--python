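"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic-programming code paths:
alignment scores come from exhaustive enumeration of all global alignments,
and graph components from boolean transitive closure.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices


def _matrix_lookup() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    d = {(a, b): float(mat[a, b]) for a in alphabet for b in alphabet}
    for a in alphabet + "X":
        d[(a, "X")] = 0.0
        d[("X", a)] = 0.0
    return d


_MAT = _matrix_lookup()


def oracle_best_score(a: str, b: str, gap_open: float = 10.0,
                      gap_extend: float = 0.5) -> float:
    """Best global alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + (L-1) * gap_extend unless it
    touches the start or end of the alignment (terminal gaps are free).
    Every sequence of match / gap-in-b / gap-in-a moves is visited.
    """
    n, m = len(a), len(b)
    best = [-np.inf]

    def run_cost(run_len: int) -> float:
        return gap_open + (run_len - 1) * gap_extend

    def rec(i: int, j: int, score: float, run_len: int, run_seq: int,
            leading: bool) -> None:
        # run_seq: 0 no open gap run, 1 gap in a, 2 gap in b
        if i == n and j == m:
            # any pending run touches the end of the alignment: free
            best[0] = max(best[0], score)
            return
        at_start = i == 0 and j == 0
        closed = score if run_seq == 0 or leading else score - run_cost(run_len)
        if i < n and j < m:
            rec(i + 1, j + 1, closed + _MAT[a[i], b[j]], 0, 0, False)
        if i < n:  # a[i] against a gap in b
            if run_seq == 2:
                rec(i + 1, j, score, run_len + 1, 2, leading)
            else:
                rec(i + 1, j, closed, 1, 2, at_start)
        if j < m:  # b[j] against a gap in a
            if run_seq == 1:
                rec(i, j + 1, score, run_len + 1, 1, leading)
            else:
                rec(i, j + 1, closed, 1, 1, at_start)

    rec(0, 0, 0.0, 0, 0, False)
    return float(best[0])


def closure_components(n_nodes: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components via boolean transitive closure of the adjacency."""
    reach = np.eye(n_nodes, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
    while True:
        nxt = reach @ reach
        if (nxt == reach).all():
            break
        reach = nxt
    seen: set[int] = set()
    comps = []
    for i in range(n_nodes):
        if i not in seen:
            comp = set(np.nonzero(reach[i])[0].tolist())
            comps.append(comp)
            seen |= comp
    return comps
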