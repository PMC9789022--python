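"""Independent reference implementations used only to check the package.

These deliberately avoid the implementation's algorithms: the alignment
oracle enumerates raw edit paths (branch-and-bound over the path tree, no DP
matrices), the merging oracle materializes the full O(n^2) distance matrix,
and the WSN check is a regular expression.
"""

from __future__ import annotations

import itertools
import math
import re

WSN_RE = re.compile(r"(?:[AT][GC][ACGT]){10}\Z")


def oracle_align_cost(
    q: str, t: str, mm: float = 1.0, go: float = 2.5, ge: float = 0.5
) -> float:
    """Minimum alignment cost by exhaustive edit-path enumeration.

    Explores every global alignment path (diagonal / query-gap / template-gap)
    recursively, pruning only branches whose accumulated cost already reaches
    the best complete path found so far.
    """
    best = [float("inf")]

    def rec(i: int, j: int, prev: str, cost: float) -> None:
        if cost >= best[0]:
            return
        if i == len(q) and j == len(t):
            best[0] = cost
            return
        if i < len(q) and j < len(t):
            rec(i + 1, j + 1, "M", cost + (0.0 if q[i] == t[j] else mm))
        if i < len(q):
            rec(i + 1, j, "I", cost + (ge if prev == "I" else go))
        if j < len(t):
            rec(i, j + 1, "D", cost + (ge if prev == "D" else go))

    rec(0, 0, "M", 0.0)
    return best[0]


def oracle_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for i in range(len(a)) if a[i] != b[i])


def oracle_merge(counts: dict[str, int], max_dist: int):
    """Greedy count-descending absorption using a full pairwise distance matrix."""
    barcodes = sorted(counts, key=lambda bc: (-counts[bc], bc))
    dist = {
        (a, b): oracle_hamming(a, b)
        for a, b in itertools.product(barcodes, repeat=2)
    }
    reps: list[str] = []
    merged: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for bc in barcodes:
        candidates = sorted(
            (dist[bc, r], -counts[r], r) for r in reps if dist[bc, r] <= max_dist
        )
        if not candidates:
            reps.append(bc)
            merged[bc] = counts[bc]
        else:
            rep = candidates[0][2]
            merged[rep] += counts[bc]
            mapping[bc] = rep
    return merged, mapping


def oracle_entropy(proportions) -> float:
    return -sum(p * math.log(p) for p in proportions if p > 0)


def oracle_jsd(p: dict[str, float], q: dict[str, float]) -> float:
    support = set(p) | set(q)
    m = {k: 0.5 * (p.get(k, 0.0) + q.get(k, 0.0)) for k in support}
    return oracle_entropy(m.values()) - 0.5 * (
        oracle_entropy(p.values()) + oracle_entropy(q.values())
    )


def oracle_welch(a, b):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    return t_stat, df, p
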