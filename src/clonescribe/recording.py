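"""Expression-recording statistics over (barcode, stgRNA, reads) triplets.

The recording cassette couples Cas9 activity to the expression of a tagged
gene; the 20-nt stgRNA accumulates indels at the Cas9 cut site in proportion
to cumulative expression.  This module turns scored stgRNA variants into the
quantities used downstream:

* a *blacklist* of wrong-template plasmid variants (mutation score >= 4.0
  from the template) whose descendants must be ignored,
* per-read valid/wrong classification against that blacklist,
* percent mutation (fraction of valid reads carrying any indel),
* per-position mismatch/insertion/deletion rates along the template,
* the read-weighted empirical CDF of indel scores.

Mismatch scores are computed and reported but excluded from the expression
indicator: mismatches arise throughout the protospacer from synthesis and
sequencing noise rather than from Cas9 cutting, so only insertion + deletion
is interpreted as recorded expression.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import DEFAULT_PARAMS, MutationScore, ScoringParams, align_score
from .merging import StgTriplet

__all__ = [
    "build_blacklist",
    "classify_stg",
    "score_triplets",
    "percent_mutation",
    "position_profile",
    "score_cdf",
]

_EPS = 1e-9


def build_blacklist(
    plasmid_stg_counts: Mapping[str, int],
    template: str,
    params: ScoringParams = DEFAULT_PARAMS,
) -> set[str]:
    """Wrong-template stg variants observed in the plasmid library.

    Any plasmid stg variant whose total mutation score from the template is
    ``params.blacklist_threshold`` (default 4.0) or larger is enrolled.
    Variants that far from the template cannot plausibly be Cas9 edit
    products of it and instead mark mis-synthesized plasmids.
    """
    out = set()
    for stg in plasmid_stg_counts:
        if align_score(stg, template, params).total >= params.blacklist_threshold - _EPS:
            out.add(stg)
    return out


@lru_cache(maxsize=65536)
def _classify_cached(stg: str, template: str, blacklist: frozenset[str], params: ScoringParams) -> str:
    to_template = align_score(stg, template, params).total
    for member in blacklist:
        if align_score(stg, member, params).total < to_template - _EPS:
            return "wrong"
    return "valid"


def classify_stg(
    stg: str,
    template: str,
    blacklist: Iterable[str],
    params: ScoringParams = DEFAULT_PARAMS,
) -> str:
    """Classify one stg variant as ``"valid"`` or ``"wrong"``.

    A variant is *wrong* iff its mutation score to some blacklist member is
    strictly smaller than its score to the template — i.e. it more likely
    descends from a wrong-template plasmid.  Ties keep the read as valid.
    """
    return _classify_cached(stg, template, frozenset(blacklist), params)


def score_triplets(
    triplets: Iterable[StgTriplet],
    template: str,
    params: ScoringParams = DEFAULT_PARAMS,
    blacklist: Iterable[str] = (),
) -> pd.DataFrame:
    """Score and classify triplets; one row per (barcode, stg) with columns
    barcode, stg, reads, mismatch, insertion, deletion, total, indel, status."""
    blk = frozenset(blacklist)
    rows = []
    for t in triplets:
        s = align_score(t.stg, template, params)
        rows.append(
            {
                "barcode": t.barcode,
                "stg": t.stg,
                "reads": t.reads,
                "mismatch": s.mismatch,
                "insertion": s.insertion,
                "deletion": s.deletion,
                "total": s.total,
                "indel": s.indel,
                "status": _classify_cached(t.stg, template, blk, params),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["barcode", "stg", "reads", "mismatch", "insertion", "deletion", "total", "indel", "status"],
    )


def _valid_scored(scored: pd.DataFrame) -> pd.DataFrame:
    return scored[scored["status"] == "valid"]


def percent_mutation(
    triplets: Iterable[StgTriplet],
    template: str,
    params: ScoringParams = DEFAULT_PARAMS,
    blacklist: Iterable[str] = (),
    per_barcode: bool = False,
) -> float:
    """Percentage of valid reads whose alignment contains any indel.

    With ``per_barcode=True`` the mutated fraction is computed per barcode
    first (read-weighted within the clone) and then averaged across barcodes,
    giving each clone equal weight regardless of its abundance.
    """
    scored = _valid_scored(score_triplets(triplets, template, params, blacklist))
    if scored["reads"].sum() == 0:
        raise ValueError("percent_mutation: no valid reads")
    mutated = scored["indel"] > 0
    if per_barcode:
        per = scored.assign(mut_reads=scored["reads"].where(mutated, 0)).groupby("barcode")[["reads", "mut_reads"]].sum()
        return float(100.0 * (per["mut_reads"] / per["reads"]).mean())
    return float(100.0 * scored.loc[mutated, "reads"].sum() / scored["reads"].sum())


def position_profile(
    triplets: Iterable[StgTriplet],
    template: str,
    params: ScoringParams = DEFAULT_PARAMS,
    blacklist: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-template-position mutation rates.

    For each template position 1..len(template) and each mutation type, the
    read-weighted fraction of valid reads whose minimum-score alignment places
    that type at that position.  Insertions are assigned to the template
    position they precede (an insertion after the final base is assigned to
    the final position).
    """
    scored = _valid_scored(score_triplets(triplets, template, params, blacklist))
    m = len(template)
    hits = {k: np.zeros(m) for k in ("mismatch", "insertion", "deletion")}
    total = 0.0
    for _, row in scored.iterrows():
        seen = {k: np.zeros(m, dtype=bool) for k in hits}
        j = 0  # template bases consumed
        for op in _expand(row_path(row, template, params)):
            if op in "MX":
                if op == "X":
                    seen["mismatch"][j] = True
                j += 1
            elif op == "D":
                seen["deletion"][j] = True
                j += 1
            else:  # insertion precedes template position j+1 (1-based)
                seen["insertion"][min(j, m - 1)] = True
        for k in hits:
            hits[k] += row["reads"] * seen[k]
        total += row["reads"]
    if total == 0:
        raise ValueError("position_profile: no valid reads")
    return pd.DataFrame(
        {k: v / total for k, v in hits.items()},
        index=pd.RangeIndex(1, m + 1, name="position"),
    )


def row_path(row: pd.Series, template: str, params: ScoringParams) -> MutationScore:
    return align_score(row["stg"], template, params)


def _expand(score: MutationScore) -> str:
    return score.ops()


def score_cdf(
    triplets: Iterable[StgTriplet],
    template: str,
    params: ScoringParams = DEFAULT_PARAMS,
    blacklist: Iterable[str] = (),
) -> pd.DataFrame:
    """Read-weighted empirical CDF of indel scores over valid reads.

    Returns a frame with columns ``indel_score`` (sorted unique values) and
    ``cum_fraction`` (fraction of valid reads with indel score <= value).
    """
    scored = _valid_scored(score_triplets(triplets, template, params, blacklist))
    if scored["reads"].sum() == 0:
        raise ValueError("score_cdf: no valid reads")
    agg = scored.groupby("indel")["reads"].sum().sort_index()
    cum = agg.cumsum() / agg.sum()
    return pd.DataFrame({"indel_score": cum.index.to_numpy(float), "cum_fraction": cum.to_numpy(float)})
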