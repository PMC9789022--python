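"""Plain-text TSV readers/writers for count tables and stg triplets."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .merging import CountTable, StgTriplet

__all__ = [
    "write_count_table",
    "read_count_tables",
    "write_triplets",
    "read_triplets",
]


def write_count_table(tables: CountTable | Sequence[CountTable], path: str | Path) -> None:
    """Write one or more count tables as TSV (sample, barcode, reads)."""
    if isinstance(tables, CountTable):
        tables = [tables]
    rows = [
        {"sample": t.sample_id, "barcode": bc, "reads": c}
        for t in tables
        for bc, c in sorted(t.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample", "barcode", "reads"]).to_csv(path, sep="\t", index=False)


def read_count_tables(path: str | Path) -> list[CountTable]:
    """Read a (sample, barcode, reads) TSV back into count tables."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barcode": str, "reads": int})
    return [
        CountTable(sample, dict(zip(grp["barcode"], grp["reads"])))
        for sample, grp in df.groupby("sample", sort=True)
    ]


def write_triplets(
    triplets: Iterable[StgTriplet], path: str | Path, sample_id: str = "sample"
) -> None:
    """Write triplets as TSV (sample, barcode, stg, reads)."""
    rows = [
        {"sample": sample_id, "barcode": t.barcode, "stg": t.stg, "reads": t.reads}
        for t in triplets
    ]
    pd.DataFrame(rows, columns=["sample", "barcode", "stg", "reads"]).to_csv(path, sep="\t", index=False)


def read_triplets(path: str | Path) -> dict[str, list[StgTriplet]]:
    """Read a triplet TSV back, grouped by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barcode": str, "stg": str, "reads": int})
    return {
        sample: [StgTriplet(r.barcode, r.stg, int(r.reads)) for r in grp.itertuples()]
        for sample, grp in df.groupby("sample", sort=True)
    }
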