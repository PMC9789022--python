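"""Minimum-mutation-score global alignment for stgRNA recording.

A self-targeting gRNA (stgRNA) directs Cas9 to cut its own encoding locus, so
expression-coupled Cas9 activity accumulates indels in the 20-nt protospacer.
The "mutation score" of a sequenced stgRNA variant is the cost of the cheapest
global alignment to the unedited template under an affine gap model:

* mismatched base          : 1.0
* first base of a gap      : 2.5   (insertion or deletion)
* each further gap base    : 0.5

so a contiguous k-base gap costs ``2.5 + 0.5 * (k - 1)``.  The alignment is
global with end gaps charged: the protospacer is flank-anchored, so a missing
terminal base is a real deletion and must be counted.

Among equal-cost alignments, operations are preferred in the order
mismatch (diagonal) > insertion > deletion, applied greedily left-to-right
along the alignment path.  The total decomposes into separate mismatch,
insertion and deletion components; downstream, only insertion + deletion is
used as the expression indicator (mismatches are dominated by sequencing /
synthesis noise rather than Cas9 activity).

Insertions are bases present in the query but not the template; deletions are
template bases absent from the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import inf

__all__ = ["ScoringParams", "MutationScore", "align_score", "DEFAULT_PARAMS"]

_EPS = 1e-9


@dataclass(frozen=True)
class ScoringParams:
    """Cost model for the mutation-score alignment.

    ``blacklist_threshold`` is the minimum total score at which a plasmid stg
    variant is treated as a wrong template (see :mod:`clonescribe.recording`).
    """

    mismatch_cost: float = 1.0
    gap_open_cost: float = 2.5
    gap_extend_cost: float = 0.5
    blacklist_threshold: float = 4.0

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.gap_open_cost, self.gap_extend_cost) <= 0:
            raise ValueError("alignment costs must be positive")
        if self.gap_extend_cost > self.gap_open_cost:
            raise ValueError("gap_extend_cost must not exceed gap_open_cost")


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class MutationScore:
    """Decomposed cost of a minimum-score alignment.

    ``path`` is the alignment run-length encoded over M (match), X (mismatch),
    I (insertion, query-only base) and D (deletion, template-only base),
    read left to right in template coordinates.
    """

    mismatch: float
    insertion: float
    deletion: float
    path: str

    @property
    def total(self) -> float:
        return self.mismatch + self.insertion + self.deletion

    @property
    def indel(self) -> float:
        """Insertion + deletion score: the expression indicator."""
        return self.insertion + self.deletion

    def ops(self) -> str:
        """Expand the RLE path into one character per alignment column."""
        out = []
        count = ""
        for ch in self.path:
            if ch.isdigit():
                count += ch
            else:
                out.append(ch * int(count))
                count = ""
        return "".join(out)


def _rle(ops: str) -> str:
    if not ops:
        return ""
    parts = []
    prev, run = ops[0], 1
    for ch in ops[1:]:
        if ch == prev:
            run += 1
        else:
            parts.append(f"{run}{prev}")
            prev, run = ch, 1
    parts.append(f"{run}{prev}")
    return "".join(parts)


# DP states: index of the previous emitted operation. Gap costs depend on it.
_DIAG, _INS, _DEL = 0, 1, 2


@lru_cache(maxsize=65536)
def _align(query: str, template: str, params: ScoringParams) -> MutationScore:
    n, m = len(query), len(template)
    mm = params.mismatch_cost
    go = params.gap_open_cost
    ge = params.gap_extend_cost

    # cost[s][i][j]: minimum cost to align query[i:] / template[j:] given the
    # previously emitted operation was of type s (suffix DP; enables a greedy
    # left-to-right traceback that realizes the tie-break order).
    cost = [[[inf] * (m + 1) for _ in range(n + 1)] for _ in range(3)]
    for s in range(3):
        cost[s][n][m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            diag = ins = dele = inf
            if i < n and j < m:
                diag = (0.0 if query[i] == template[j] else mm) + cost[_DIAG][i + 1][j + 1]
            if i < n:
                ins_step = cost[_INS][i + 1][j]
            if j < m:
                del_step = cost[_DEL][i][j + 1]
            for s in range(3):
                best = diag
                if i < n:
                    ins = (ge if s == _INS else go) + ins_step
                    if ins < best:
                        best = ins
                if j < m:
                    dele = (ge if s == _DEL else go) + del_step
                    if dele < best:
                        best = dele
                cost[s][i][j] = best

    # Greedy forward traceback: at each column take the first operation, in
    # preference order diagonal > insertion > deletion, consistent with an
    # optimal completion.
    i = j = 0
    state = _DIAG
    ops: list[str] = []
    while i < n or j < m:
        target = cost[state][i][j]
        if i < n and j < m:
            step = 0.0 if query[i] == template[j] else mm
            if abs(step + cost[_DIAG][i + 1][j + 1] - target) < _EPS:
                ops.append("M" if query[i] == template[j] else "X")
                i, j, state = i + 1, j + 1, _DIAG
                continue
        if i < n:
            step = ge if state == _INS else go
            if abs(step + cost[_INS][i + 1][j] - target) < _EPS:
                ops.append("I")
                i, state = i + 1, _INS
                continue
        step = ge if state == _DEL else go
        ops.append("D")
        j, state = j + 1, _DEL

    mismatch = mm * ops.count("X")
    insertion = deletion = 0.0
    for sym in "ID":
        run = 0
        score = 0.0
        for ch in ops + ["$"]:
            if ch == sym:
                run += 1
            elif run:
                score += go + ge * (run - 1)
                run = 0
        if sym == "I":
            insertion = score
        else:
            deletion = score
    return MutationScore(mismatch=mismatch, insertion=insertion, deletion=deletion, path=_rle("".join(ops)))


def align_score(query: str, template: str, params: ScoringParams = DEFAULT_PARAMS) -> MutationScore:
    """Align ``query`` to ``template`` and return the decomposed mutation score.

    Parameters
    ----------
    query : str
        Observed stgRNA variant (any positive length).
    template : str
        Unedited stgRNA template (typically 20 nt).
    params : ScoringParams
        Cost model; defaults to mismatch 1 / open 2.5 / extend 0.5.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not query or not template:
        raise ValueError("align_score requires non-empty sequences")
    return _align(query.upper(), template.upper(), params)
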