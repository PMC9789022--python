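"""Clone-level association between recorded expression and abundance.

Each clone is summarized by its total barcode reads and the read-weighted
mean indel score of its stgRNA reads (the cumulative-expression proxy).  The
association between the two is measured with a weighted Spearman correlation
— the weighted Pearson correlation of weighted ranks, weights being the
barcode read counts, following the cumulative-weight mid-rank convention of
the WeightedCorr/wCorr lineage.  For heatmap-style views, the top clones by
mutated-read count are tabulated across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneSummary",
    "summarize_clones",
    "weighted_rank",
    "weighted_spearman",
    "top_mutated_table",
]


@dataclass(frozen=True)
class CloneSummary:
    """Per-clone recording summary.

    mutated_reads counts reads with indel score > 0; mean_indel_score is the
    read-weighted mean indel score over the clone's stg reads.
    """

    barcode: str
    reads: int
    mutated_reads: int
    mean_indel_score: float

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("clone must have >= 1 read")
        if self.mean_indel_score < 0:
            raise ValueError("mean indel score must be >= 0")


def summarize_clones(scored: pd.DataFrame) -> list[CloneSummary]:
    """Collapse a scored triplet frame (see recording.score_triplets) to
    per-clone summaries, using valid reads only."""
    valid = scored[scored["status"] == "valid"] if "status" in scored else scored
    out = []
    for bc, grp in valid.groupby("barcode", sort=True):
        reads = int(grp["reads"].sum())
        mutated = int(grp.loc[grp["indel"] > 0, "reads"].sum())
        mean_score = float((grp["indel"] * grp["reads"]).sum() / reads)
        out.append(CloneSummary(bc, reads, mutated, mean_score))
    return out


def weighted_rank(values: Sequence[float], weights: Sequence[float]) -> np.ndarray:
    """Weighted mid-ranks: rank_i = W(x < x_i) + W(x == x_i) / 2.

    With unit weights this equals ordinary mid-ranks shifted by the constant
    1/2, which leaves any Pearson correlation of ranks unchanged.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("weighted_rank requires non-empty input")
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    ranks = np.empty_like(x)
    for i, xi in enumerate(x):
        below = w[x < xi].sum()
        ties = w[x == xi].sum()
        ranks[i] = below + 0.5 * ties
    return ranks


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wn = w / w.sum()
    mx, my = (wn * x).sum(), (wn * y).sum()
    cov = (wn * (x - mx) * (y - my)).sum()
    vx = (wn * (x - mx) ** 2).sum()
    vy = (wn * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def weighted_spearman(
    x: Sequence[float], y: Sequence[float], w: Sequence[float]
) -> float:
    """Weighted Spearman correlation of x and y with weights w.

    The weighted Pearson correlation of the weighted ranks of x and y.
    Returns NaN when either rank vector has zero weighted variance (the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size < 3:
        raise ValueError("weighted_spearman requires n >= 3")
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y, w must have equal length")
    return _weighted_pearson(weighted_rank(x, w), weighted_rank(y, w), w)


def top_mutated_table(
    samples: Mapping[str, Sequence[CloneSummary]], n: int = 10
) -> pd.DataFrame:
    """Matrix (clone x sample) of mean indel scores for top mutated clones.

    Per sample, the top ``n`` clones by mutated-read count are selected
    (ties: higher total reads, then lexicographic barcode); rows are the
    deduplicated union across samples, entries are mean_indel_score and 0
    where a clone was not selected-or-observed in a sample.
    """
    if not samples:
        raise ValueError("top_mutated_table requires at least one sample")
    union: list[str] = []
    seen: set[str] = set()
    by_sample: dict[str, dict[str, float]] = {}
    for sample_id, clones in samples.items():
        ranked = sorted(clones, key=lambda c: (-c.mutated_reads, -c.reads, c.barcode))[:n]
        by_sample[sample_id] = {c.barcode: c.mean_indel_score for c in clones}
        for c in ranked:
            if c.barcode not in seen:
                seen.add(c.barcode)
                union.append(c.barcode)
    mat = pd.DataFrame(0.0, index=pd.Index(union, name="barcode"), columns=list(samples))
    for sample_id in samples:
        scores = by_sample[sample_id]
        for bc in union:
            if bc in scores:
                mat.loc[bc, sample_id] = scores[bc]
    return mat
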