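"""Hamming-distance collapsing of sequencing-error barcode variants.

Each cell carries one 30-base lentiviral barcode; sequencing and synthesis
errors scatter reads of a true barcode across close variants, typically at
Hamming distance 1-2.  Variants within distance <= 2 of a more abundant
barcode are absorbed into it (greedy, count-descending, no transitive
chaining), the reference barcode set is the intersection of samples that
must all contain a real barcode, and (barcode, stg, reads) triplets are
canonicalized against reference representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CountTable",
    "StgTriplet",
    "hamming",
    "merge_barcodes",
    "select_reference",
    "filter_to_reference",
    "merge_triplets",
]


@dataclass
class CountTable:
    """Per-sample clonal census: barcode -> read count (counts > 0)."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bc, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"non-positive count for barcode {bc}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        tot = self.total_reads
        if tot == 0:
            raise ValueError("empty count table has no proportions")
        return {bc: c / tot for bc, c in self.counts.items()}


@dataclass(frozen=True)
class StgTriplet:
    """The recording unit: one (barcode, stg variant, read count) observation."""

    barcode: str
    stg: str
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("triplet reads must be >= 1")


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("Hamming distance undefined for unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def _hamming_within(a: str, b: str, limit: int) -> int | None:
    """Hamming distance if <= limit, else None (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def merge_barcodes(
    table: CountTable, max_dist: int = 2
) -> tuple[CountTable, dict[str, str]]:
    """Collapse error variants into representatives by Hamming distance.

    Barcodes are visited in descending read count (ties lexicographic).  Each
    becomes a new representative unless within ``max_dist`` of an existing
    one, in which case its reads are added to the closest representative
    (ties: highest own read count, then lexicographic).  Absorbed barcodes
    never absorb others (no transitive chaining), so representatives form an
    independent set at distance ``max_dist``.

    Returns the collapsed table and a map absorbed barcode -> representative.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    order = sorted(table.counts, key=lambda bc: (-table.counts[bc], bc))
    reps: list[str] = []
    merged: dict[str, int] = {}
    merge_map: dict[str, str] = {}
    for bc in order:
        best: tuple[int, int, str] | None = None  # (dist, -rep_own_count, rep)
        if max_dist > 0:
            for rep in reps:
                d = _hamming_within(bc, rep, max_dist)
                if d is None:
                    continue
                key = (d, -table.counts[rep], rep)
                if best is None or key < best:
                    best = key
        if best is None:
            reps.append(bc)
            merged[bc] = table.counts[bc]
        else:
            rep = best[2]
            merged[rep] += table.counts[bc]
            merge_map[bc] = rep
    return CountTable(table.sample_id, merged), merge_map


def select_reference(tables: Sequence[CountTable]) -> set[str]:
    """Barcodes detected in every provided sample (set intersection).

    Requiring presence in the plasmid library and in all independently
    barcoded cell pools removes barcodes fabricated by sequencing error.
    """
    if not tables:
        raise ValueError("select_reference requires at least one table")
    ref = set(tables[0].counts)
    for t in tables[1:]:
        ref &= set(t.counts)
    return ref


def filter_to_reference(
    table: CountTable, reference: Iterable[str]
) -> tuple[CountTable, int]:
    """Restrict a census to reference barcodes; also return discarded reads."""
    ref = set(reference)
    if not ref:
        raise ValueError("reference set is empty")
    kept = {bc: c for bc, c in table.counts.items() if bc in ref}
    discarded = table.total_reads - sum(kept.values())
    return CountTable(table.sample_id, kept), discarded


def merge_triplets(
    triplets: Iterable[StgTriplet],
    reference: Mapping[str, int] | Iterable[str],
    max_dist: int = 2,
) -> tuple[list[StgTriplet], int]:
    """Canonicalize triplet barcodes to reference representatives.

    ``reference`` is the representative barcode set built from the plasmid
    sample (optionally with read counts, used only for tie-breaking).  Each
    triplet's barcode is replaced by the closest representative within
    ``max_dist`` (ties: highest reference count, then lexicographic); reads
    are summed within identical (representative, stg) pairs, so distinct stg
    variants stay separate under one barcode.  Triplets with no representative
    within distance are dropped; their read total is returned.
    """
    if isinstance(reference, Mapping):
        ref_counts = dict(reference)
    else:
        ref_counts = {bc: 0 for bc in reference}
    reps = sorted(ref_counts)
    out: dict[tuple[str, str], int] = {}
    dropped = 0
    assign_cache: dict[str, str | None] = {}
    for t in triplets:
        if t.barcode in assign_cache:
            rep = assign_cache[t.barcode]
        else:
            best: tuple[int, int, str] | None = None
            for r in reps:
                if len(r) != len(t.barcode):
                    continue
                d = _hamming_within(t.barcode, r, max_dist)
                if d is None:
                    continue
                key = (d, -ref_counts[r], r)
                if best is None or key < best:
                    best = key
            rep = best[2] if best is not None else None
            assign_cache[t.barcode] = rep
        if rep is None:
            dropped += t.reads
            continue
        out[(rep, t.stg)] = out.get((rep, t.stg), 0) + t.reads
    merged = [StgTriplet(bc, stg, reads) for (bc, stg), reads in sorted(out.items())]
    return merged, dropped
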