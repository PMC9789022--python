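"""Clonal diversity and composition statistics.

Diversity of a barcoded population is summarized by Shannon entropy (natural
log) and by its exponential — the *corrected barcode number*, the Hill number
of order 1: the number of equally abundant clones that would give the same
entropy.  This removes the skew of raw richness toward rare, possibly
artifactual barcodes.  Compositional similarity between samples is measured
by Jensen–Shannon divergence (natural log; 0 identical, ln 2 disjoint),
either over all barcodes or restricted to the union of each sample's top-10
barcodes.  Group comparisons use Welch's t-test with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .merging import CountTable

__all__ = [
    "shannon_entropy",
    "corrected_barcode_number",
    "top_n",
    "js_divergence",
    "js_matrix",
    "welch_bonferroni",
]


def _as_proportions(profile: Mapping[str, float] | CountTable) -> dict[str, float]:
    if isinstance(profile, CountTable):
        return profile.proportions()
    if not profile:
        raise ValueError("empty profile")
    total = float(sum(profile.values()))
    if total <= 0:
        raise ValueError("profile mass must be positive")
    return {k: v / total for k, v in profile.items() if v > 0}


def shannon_entropy(profile: Mapping[str, float] | CountTable) -> float:
    """H = -sum p_i ln p_i over the clone proportions (nats)."""
    p = np.fromiter(_as_proportions(profile).values(), dtype=float)
    return float(stats.entropy(p))


def corrected_barcode_number(profile: Mapping[str, float] | CountTable) -> float:
    """exp(H): the effective number of equally abundant clones."""
    return float(math.exp(shannon_entropy(profile)))


def top_n(table: CountTable | Mapping[str, float], n: int = 10) -> list[str]:
    """The n highest-count barcodes, ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = table.counts if isinstance(table, CountTable) else table
    return sorted(counts, key=lambda bc: (-counts[bc], bc))[:n]


def _entropy_vec(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def js_divergence(
    p: Mapping[str, float] | CountTable,
    q: Mapping[str, float] | CountTable,
    mode: str = "all",
    top_lists: Sequence[Sequence[str]] | None = None,
    renormalize: bool = True,
) -> float:
    """Jensen–Shannon divergence between two clonal profiles (nats).

    JSD(p, q) = H(m) - (H(p) + H(q)) / 2 with m = (p + q) / 2, computed over
    the union support; a barcode absent from a sample contributes 0.

    With ``mode="top10_union"`` the profiles are first restricted to the
    union of the supplied per-sample top-N lists and, by default,
    renormalized to sum to one (``renormalize=False`` keeps the raw restricted
    proportions, leaving an implicit "other" mass outside the comparison).
    """
    pp, qq = _as_proportions(p), _as_proportions(q)
    if mode == "top10_union":
        if top_lists is None:
            raise ValueError("mode='top10_union' requires top_lists")
        keep = set(itertools.chain.from_iterable(top_lists))
        pp = {k: v for k, v in pp.items() if k in keep}
        qq = {k: v for k, v in qq.items() if k in keep}
        if renormalize:
            if pp:
                tp = sum(pp.values())
                pp = {k: v / tp for k, v in pp.items()}
            if qq:
                tq = sum(qq.values())
                qq = {k: v / tq for k, v in qq.items()}
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    support = sorted(set(pp) | set(qq))
    if not support:
        raise ValueError("both profiles are empty on the comparison support")
    pv = np.array([pp.get(k, 0.0) for k in support])
    qv = np.array([qq.get(k, 0.0) for k in support])
    mv = 0.5 * (pv + qv)
    return _entropy_vec(mv) - 0.5 * (_entropy_vec(pv) + _entropy_vec(qv))


def js_matrix(
    tables: Sequence[CountTable],
    mode: str = "all",
    n_top: int = 10,
) -> pd.DataFrame:
    """Symmetric pairwise JSD matrix over samples (zero diagonal)."""
    if len(tables) < 2:
        raise ValueError("js_matrix requires at least two samples")
    ids = [t.sample_id for t in tables]
    top_lists = [top_n(t, n_top) for t in tables] if mode == "top10_union" else None
    out = np.zeros((len(tables), len(tables)))
    for i, j in itertools.combinations(range(len(tables)), 2):
        d = js_divergence(tables[i], tables[j], mode=mode, top_lists=top_lists)
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def welch_bonferroni(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> pd.DataFrame:
    """All pairwise Welch t-tests with Bonferroni-adjusted p-values.

    Unequal-variance t-test with Welch–Satterthwaite degrees of freedom; raw
    p-values are multiplied by the number of comparisons and capped at 1.
    Two groups with zero variance get p = 1 when their means are equal
    (no evidence of difference) and p = 0 when they differ.
    """
    if not isinstance(groups, Mapping):
        groups = {str(i): g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    pairs = list(itertools.combinations(arrays, 2))
    rows = []
    for a_name, b_name in pairs:
        a, b = arrays[a_name], arrays[b_name]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t_stat, df, p_raw = 0.0, float(a.size + b.size - 2), (1.0 if a.mean() == b.mean() else 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        rows.append(
            {
                "group1": a_name,
                "group2": b_name,
                "t": t_stat,
                "df": df,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * len(pairs)),
            }
        )
    return pd.DataFrame(rows, columns=["group1", "group2", "t", "df", "p_raw", "p_adj"])
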