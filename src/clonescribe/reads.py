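"""Read filtering and barcode / stgRNA extraction.

Native re-implementations of the processing stages normally delegated to
cutadapt (3' adapter removal at 20% mismatch tolerance), fastq_quality_trimmer
(3' quality trim at Q20, minimum length 25) and the q20/p80 quality filter,
followed by flank-anchored extraction of the 30-base barcode (tumor layout)
or of the (barcode, stgRNA) pair (recording layout, pre-merged reads).

Barcodes must be exactly 30 bases of unambiguous A/C/G/T; no WSN-pattern
restriction is applied, since synthesis errors put many real barcodes off
pattern.  The stg window may be any length up to a cap — indels are the
signal being recorded.

Adapter and flank matching are mismatch-only (no indels), with the flank
tolerance fixed at one mismatch; the amplicon architecture is configuration
(`AmpliconDesign`) shared between the simulator and the extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

from .merging import CountTable, StgTriplet

__all__ = [
    "ReadRecord",
    "AmpliconDesign",
    "DEFAULT_DESIGN",
    "ExtractionResult",
    "read_fastq",
    "trim_adapter",
    "quality_trim",
    "quality_filter",
    "extract_barcode",
    "extract_barcode_stg",
    "extract_reads",
    "count_barcodes",
    "collect_triplets",
]

_BASES = frozenset("ACGT")


@dataclass
class ReadRecord:
    """One sequencing read: id, sequence, per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


@dataclass(frozen=True)
class AmpliconDesign:
    """Amplicon architecture: flanks anchoring the barcode and stg windows.

    Layout (recording):  upstream_flank  BARCODE(30)  stg_flank  STG  downstream_flank
    Layout (tumor):      upstream_flank  BARCODE(30)  downstream_flank
    """

    upstream_flank: str = "ACCGGTCGCCAC"
    stg_flank: str = "GTTTAAGAGCTA"
    downstream_flank: str = "AGCTTGGCGTAA"
    barcode_length: int = 30
    stg_max_length: int = 40
    stg_template: str = "GTCACCTCCAATGACAAGCT"

    def __post_init__(self) -> None:
        if not (self.upstream_flank and self.downstream_flank):
            raise ValueError("flanks must be non-empty")
        if self.barcode_length != 30:
            raise ValueError("barcode length is fixed at 30")


DEFAULT_DESIGN = AmpliconDesign()


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of extracting one read.

    status is "pass" or "reject"; reason is "ok" for passes, otherwise one of
    missing_upstream / missing_barcode_flank / missing_downstream /
    bad_length / ambiguous_base / stg_too_long.
    """

    read_id: str
    barcode: str | None
    stg: str | None
    status: str
    reason: str


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate a Phred+33 FASTQ file as ReadRecords."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])


def _find_flank(seq: str, flank: str, start: int, max_mismatch: int) -> int:
    """Leftmost best occurrence of ``flank`` in ``seq[start:]`` with at most
    ``max_mismatch`` mismatches (no indels); -1 if absent."""
    best_pos, best_mm = -1, max_mismatch + 1
    for pos in range(start, len(seq) - len(flank) + 1):
        mm = 0
        for a, b in zip(seq[pos : pos + len(flank)], flank):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        else:
            if mm < best_mm:
                best_pos, best_mm = pos, mm
                if mm == 0:
                    break
    return best_pos


def trim_adapter(read: ReadRecord, adapter: str, error_tolerance: float = 0.2) -> ReadRecord:
    """Remove the best adapter occurrence and everything 3' of it.

    The adapter is matched by mismatch-only sliding comparison; an occurrence
    counts when its mismatch fraction is <= ``error_tolerance``.  The
    fewest-mismatch, leftmost occurrence wins.  Without an occurrence the
    read is returned unchanged.  Idempotent as long as the adapter does not
    occur in the retained prefix.
    """
    if not 0 <= error_tolerance < 0.5:
        raise ValueError("error_tolerance must be in [0, 0.5)")
    if not adapter:
        return read
    max_mm = int(error_tolerance * len(adapter))
    best_pos, best_mm = -1, max_mm + 1
    for pos in range(0, len(read.sequence) - len(adapter) + 1):
        mm = 0
        for a, b in zip(read.sequence[pos : pos + len(adapter)], adapter):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        else:
            if mm < best_mm:
                best_pos, best_mm = pos, mm
                if mm == 0:
                    break
    if best_pos < 0:
        return read
    return ReadRecord(read.id, read.sequence[:best_pos], read.qualities[:best_pos])


def quality_trim(read: ReadRecord, threshold: int = 20, min_length: int = 25) -> ReadRecord | None:
    """Trim 3' bases below ``threshold``; None (reject) if too short after.

    Mirrors fastq_quality_trimmer -t 20 -l 25: bases are removed from the 3'
    end while the terminal base quality is below the threshold.
    """
    end = len(read.qualities)
    while end > 0 and read.qualities[end - 1] < threshold:
        end -= 1
    if end < min_length:
        return None
    if end == len(read.qualities):
        return read
    return ReadRecord(read.id, read.sequence[:end], read.qualities[:end])


def quality_filter(read: ReadRecord, min_quality: int = 20, min_fraction: float = 0.8) -> bool:
    """True iff >= min_fraction of bases have quality >= min_quality
    (the q20/p80 filter); empty reads fail."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if not read.qualities:
        return False
    ok = sum(q >= min_quality for q in read.qualities)
    return ok / len(read.qualities) >= min_fraction


def _check_barcode(read_id: str, window: str, design: AmpliconDesign) -> ExtractionResult | None:
    if len(window) != design.barcode_length:
        return ExtractionResult(read_id, None, None, "reject", "bad_length")
    if not set(window) <= _BASES:
        return ExtractionResult(read_id, None, None, "reject", "ambiguous_base")
    return None


def extract_barcode(read: ReadRecord, design: AmpliconDesign = DEFAULT_DESIGN) -> ExtractionResult:
    """Extract the 30-base barcode between the two flanks (tumor layout).

    Each flank may carry at most one mismatch.  The window must be exactly 30
    unambiguous bases; anything else is rejected with a reason code.
    """
    seq = read.sequence
    up = _find_flank(seq, design.upstream_flank, 0, 1)
    if up < 0:
        return ExtractionResult(read.id, None, None, "reject", "missing_upstream")
    bc_start = up + len(design.upstream_flank)
    down = _find_flank(seq, design.downstream_flank, bc_start, 1)
    if down < 0:
        return ExtractionResult(read.id, None, None, "reject", "missing_downstream")
    window = seq[bc_start:down]
    bad = _check_barcode(read.id, window, design)
    if bad is not None:
        return bad
    return ExtractionResult(read.id, window, None, "pass", "ok")


def extract_barcode_stg(read: ReadRecord, design: AmpliconDesign = DEFAULT_DESIGN) -> ExtractionResult:
    """Extract (barcode, stg) from a pre-merged recording read.

    The barcode is positional: exactly 30 bases after the upstream flank,
    confirmed by the stg flank immediately following (<= 1 mismatch each).
    The stg window runs from the stg flank to the downstream flank and may
    have any length up to ``design.stg_max_length`` — indels are expected.
    """
    seq = read.sequence
    up = _find_flank(seq, design.upstream_flank, 0, 1)
    if up < 0:
        return ExtractionResult(read.id, None, None, "reject", "missing_upstream")
    bc_start = up + len(design.upstream_flank)
    mid_start = bc_start + design.barcode_length
    mid = seq[mid_start : mid_start + len(design.stg_flank)]
    if len(mid) < len(design.stg_flank) or sum(a != b for a, b in zip(mid, design.stg_flank)) > 1:
        return ExtractionResult(read.id, None, None, "reject", "missing_barcode_flank")
    barcode = seq[bc_start:mid_start]
    bad = _check_barcode(read.id, barcode, design)
    if bad is not None:
        return bad
    stg_start = mid_start + len(design.stg_flank)
    down = _find_flank(seq, design.downstream_flank, stg_start, 1)
    if down < 0:
        return ExtractionResult(read.id, None, None, "reject", "missing_downstream")
    stg = seq[stg_start:down]
    if len(stg) > design.stg_max_length:
        return ExtractionResult(read.id, None, None, "reject", "stg_too_long")
    if not set(stg) <= _BASES or not stg:
        return ExtractionResult(read.id, None, None, "reject", "ambiguous_base")
    return ExtractionResult(read.id, barcode, stg, "pass", "ok")


def extract_reads(
    reads: Iterable[ReadRecord],
    layout: str = "tumor",
    design: AmpliconDesign = DEFAULT_DESIGN,
    adapter: str | None = None,
    error_tolerance: float = 0.2,
    quality_threshold: int = 20,
    min_length: int = 25,
    min_fraction: float = 0.8,
) -> list[ExtractionResult]:
    """Full per-read pipeline: adapter trim, quality trim, quality filter,
    extraction.  Reads failing a quality stage are rejected with reason
    "low_quality"; pass + reject counts always equal the input read count."""
    if layout not in ("tumor", "recording"):
        raise ValueError("layout must be 'tumor' or 'recording'")
    extract = extract_barcode if layout == "tumor" else extract_barcode_stg
    out = []
    for read in reads:
        if adapter:
            read = trim_adapter(read, adapter, error_tolerance)
        trimmed = quality_trim(read, quality_threshold, min_length)
        if trimmed is None or not quality_filter(trimmed, quality_threshold, min_fraction):
            out.append(ExtractionResult(read.id, None, None, "reject", "low_quality"))
            continue
        out.append(extract(trimmed, design))
    return out


def count_barcodes(results: Iterable[ExtractionResult], sample_id: str) -> CountTable:
    """Tally passing extractions into a per-sample count table."""
    counts: dict[str, int] = {}
    for r in results:
        if r.status == "pass" and r.barcode is not None:
            counts[r.barcode] = counts.get(r.barcode, 0) + 1
    return CountTable(sample_id, counts)


def collect_triplets(results: Iterable[ExtractionResult]) -> list[StgTriplet]:
    """Aggregate passing (barcode, stg) extractions into read-count triplets."""
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        if r.status == "pass" and r.barcode is not None and r.stg is not None:
            counts[(r.barcode, r.stg)] = counts.get((r.barcode, r.stg), 0) + 1
    return [StgTriplet(bc, stg, n) for (bc, stg), n in sorted(counts.items())]
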