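"""Synthetic barcoded tumor populations with expression recording.

The generator emulates the data-generating process the analysis assumes:

* a plasmid barcode library of unique 30-base sequences built from the
  (W S N) x 10 degenerate design (W = A/T, S = G/C, N = any), with a
  configurable fraction of off-pattern barcodes mimicking oligo-synthesis
  error;
* clonal population dynamics — exponential growth with Dirichlet-multinomial
  dispersion, metastasis-founding bottlenecks (without-replacement sampling
  of founder cells), and treatment selection (binomial thinning, uniform or
  per-clone survival);
* Cas9/stgRNA expression recording — each unedited stg molecule acquires an
  indel at the cut site with probability 1 - exp(-rate * expression * days);
  indel lengths are geometric (mean 2, truncated at 10), deletions
  outnumbering insertions 3:1; a molecule whose cut-site window is already
  disrupted cannot be re-edited (the stgRNA destroys its own protospacer);
* FASTQ emission with flanking amplicon context, substitution / indel
  sequencing errors and Phred+33 qualities, plus a latent-truth table
  (read id -> clone) for parameter-recovery tests.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give byte-identical FASTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .reads import DEFAULT_DESIGN, AmpliconDesign

__all__ = [
    "LibrarySpec",
    "ErrorModel",
    "CloneSimState",
    "generate_library",
    "matches_wsn",
    "init_population",
    "simulate_growth",
    "simulate_bottleneck",
    "simulate_selection",
    "simulate_recording",
    "emit_fastq",
    "scenario_treatment",
    "scenario_bottleneck",
    "scenario_coupling",
]

_WEAK = "AT"
_STRONG = "GC"
_ALL = "ACGT"


@dataclass(frozen=True)
class LibrarySpec:
    """Barcode library parameters.

    off_pattern_rate is the fraction of barcodes carrying at least one base
    violating the strict (W S N) x 10 design, as happens in real oligo
    synthesis; per-base substitution positions are Binomial(30, error_rate)
    draws, redrawn until the pattern is actually violated.
    """

    n_barcodes: int
    off_pattern_rate: float = 0.0
    seed: int = 0
    per_base_error: float = 0.05

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if not 0 <= self.off_pattern_rate <= 1:
            raise ValueError("off_pattern_rate must be in [0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error model for FASTQ emission.

    Rates are per base; qualities default to a flat Q37 profile with a
    configurable linear 3' decay.  The adapter is appended 3' of the
    amplicon so adapter trimming is exercisable.
    """

    substitution_rate: float = 0.001
    indel_rate: float = 1e-5
    adapter: str = "AGATCGGAAGAGC"
    base_quality: int = 37
    quality_decay: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("error rates must be in [0, 1]")
        if not 2 <= self.base_quality <= 41:
            raise ValueError("base_quality must be a Phred score in [2, 41]")

    def quality_at(self, pos: int) -> int:
        return max(2, min(41, round(self.base_quality - self.quality_decay * pos)))


@dataclass
class CloneSimState:
    """Latent truth of a simulated clonal population.

    counts are cells per clone (support only: all > 0 after pruning);
    expression is the per-clone expression intensity of the recorded gene;
    stg_pools, when recording has been initialized, map stg variant -> number
    of molecules per clone and sum to the clone's cell count.
    """

    barcodes: list[str]
    counts: np.ndarray
    expression: np.ndarray
    stg_pools: list[dict[str, int]] | None = None
    stg_template: str = DEFAULT_DESIGN.stg_template
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.expression = np.asarray(self.expression, dtype=float)
        if not (len(self.barcodes) == self.counts.size == self.expression.size):
            raise ValueError("barcodes, counts, expression must align")
        if self.counts.size == 0:
            raise ValueError("population is empty")
        if np.any(self.counts < 0) or np.any(self.expression < 0):
            raise ValueError("counts and expression must be nonnegative")

    @property
    def n_clones(self) -> int:
        return len(self.barcodes)

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("population has no cells")
        return self.counts / total

    def count_map(self) -> dict[str, int]:
        return {bc: int(c) for bc, c in zip(self.barcodes, self.counts) if c > 0}

    def pruned(self) -> "CloneSimState":
        """Drop extinct clones (count 0)."""
        keep = self.counts > 0
        if keep.all():
            return self
        if not keep.any():
            raise ValueError("population went extinct")
        pools = None
        if self.stg_pools is not None:
            pools = [p for p, k in zip(self.stg_pools, keep) if k]
        return CloneSimState(
            [bc for bc, k in zip(self.barcodes, keep) if k],
            self.counts[keep],
            self.expression[keep],
            pools,
            self.stg_template,
            self.time,
        )


def matches_wsn(barcode: str) -> bool:
    """True iff the barcode satisfies the strict (W S N) x 10 design."""
    if len(barcode) != 30:
        return False
    for i, base in enumerate(barcode):
        k = i % 3
        if k == 0 and base not in _WEAK:
            return False
        if k == 1 and base not in _STRONG:
            return False
        if k == 2 and base not in _ALL:
            return False
    return True


def _wsn_draw(rng: np.random.Generator) -> str:
    out = []
    for _ in range(10):
        out.append(_WEAK[rng.integers(2)])
        out.append(_STRONG[rng.integers(2)])
        out.append(_ALL[rng.integers(4)])
    return "".join(out)


def generate_library(spec: LibrarySpec) -> list[str]:
    """Generate unique 30-base barcodes per the library spec.

    Exactly ceil(off_pattern_rate * n) barcodes violate the WSN pattern; the
    rest match it exactly.  Deterministic under the spec seed.
    """
    if spec.off_pattern_rate == 0 and spec.n_barcodes > 8**10:
        raise ValueError("n_barcodes exceeds the WSN x 10 design space (8^10)")
    rng = np.random.default_rng(spec.seed)
    n_off = math.ceil(spec.off_pattern_rate * spec.n_barcodes)
    seen: set[str] = set()
    on_pattern: list[str] = []
    off_pattern: list[str] = []
    guard = 0
    while len(on_pattern) < spec.n_barcodes - n_off:
        bc = _wsn_draw(rng)
        if bc not in seen:
            seen.add(bc)
            on_pattern.append(bc)
        guard += 1
        if guard > 100 * spec.n_barcodes + 10000:
            raise RuntimeError("library generation stalled; diversity exhausted")
    while len(off_pattern) < n_off:
        base = _wsn_draw(rng)
        bc = base
        while matches_wsn(bc):
            k = rng.binomial(30, spec.per_base_error)
            if k == 0:
                continue
            positions = rng.choice(30, size=k, replace=False)
            chars = list(base)
            for p in positions:
                chars[p] = _ALL[rng.integers(4)]
            bc = "".join(chars)
        if bc not in seen:
            seen.add(bc)
            off_pattern.append(bc)
        guard += 1
        if guard > 100 * spec.n_barcodes + 10000:
            raise RuntimeError("library generation stalled; diversity exhausted")
    return on_pattern + off_pattern


def init_population(
    barcodes: Sequence[str],
    cells_per_clone: int | Sequence[int] = 100,
    expression: float | Sequence[float] = 1.0,
    stg_template: str = DEFAULT_DESIGN.stg_template,
) -> CloneSimState:
    """Build a starting population over the given barcodes."""
    n = len(barcodes)
    counts = np.full(n, cells_per_clone) if np.isscalar(cells_per_clone) else np.asarray(cells_per_clone)
    expr = np.full(n, expression, dtype=float) if np.isscalar(expression) else np.asarray(expression, dtype=float)
    return CloneSimState(list(barcodes), counts, expr, None, stg_template, 0.0)


def _resize_pool(pool: dict[str, int], new_total: int, rng: np.random.Generator) -> dict[str, int]:
    variants = sorted(pool)
    weights = np.array([pool[v] for v in variants], dtype=float)
    draw = rng.multinomial(new_total, weights / weights.sum())
    return {v: int(k) for v, k in zip(variants, draw) if k > 0}


def _carry_pools(state: CloneSimState, new_counts: np.ndarray, rng: np.random.Generator):
    if state.stg_pools is None:
        return None
    return [
        _resize_pool(pool, int(c), rng) if c > 0 else {}
        for pool, c in zip(state.stg_pools, new_counts)
    ]


def simulate_growth(
    state: CloneSimState, fold: float, dispersion: float = 0.0, seed: int | None = None
) -> CloneSimState:
    """Grow the population ``fold``-fold.

    With dispersion 0, counts scale deterministically (frequencies exactly
    preserved).  With dispersion > 0, new clone probabilities are drawn from
    Dirichlet(frequencies / dispersion) and counts from a multinomial — a
    Dirichlet-multinomial resampling whose expectation leaves frequencies
    unchanged while clone-level growth variability rises with dispersion.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    new_total = int(round(state.n_cells * fold))
    if dispersion == 0:
        new_counts = np.round(state.counts * fold).astype(np.int64)
    else:
        alpha = state.frequencies / dispersion
        p = rng.dirichlet(alpha)
        new_counts = rng.multinomial(new_total, p).astype(np.int64)
    pools = _carry_pools(state, new_counts, rng)
    return CloneSimState(
        list(state.barcodes), new_counts, state.expression.copy(), pools, state.stg_template, state.time
    ).pruned()


def simulate_bottleneck(state: CloneSimState, founders: int, seed: int | None = None) -> CloneSimState:
    """Found a new lesion from ``founders`` cells sampled without replacement.

    Models metastasis founding; the resulting clone support has size at most
    ``founders``.
    """
    if founders < 1:
        raise ValueError("founders must be >= 1")
    if founders > state.n_cells:
        raise ValueError("founders exceeds the number of simulated cells")
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(state.counts, founders).astype(np.int64)
    pools = _carry_pools(state, new_counts, rng)
    return CloneSimState(
        list(state.barcodes), new_counts, state.expression.copy(), pools, state.stg_template, state.time
    ).pruned()


def simulate_selection(
    state: CloneSimState, survival: float | Sequence[float], seed: int | None = None
) -> CloneSimState:
    """Thin each clone binomially with its survival probability.

    A scalar survival models stochastic, clone-independent killing (drug
    pressure without pre-existing resistance); a per-clone vector models
    heritable resistance.
    """
    rng = np.random.default_rng(seed)
    surv = np.broadcast_to(np.asarray(survival, dtype=float), state.counts.shape)
    if np.any(surv < 0) or np.any(surv > 1):
        raise ValueError("survival probabilities must be in [0, 1]")
    new_counts = rng.binomial(state.counts, surv).astype(np.int64)
    pools = _carry_pools(state, new_counts, rng)
    return CloneSimState(
        list(state.barcodes), new_counts, state.expression.copy(), pools, state.stg_template, state.time
    ).pruned()


# --- Cas9/stgRNA recording ------------------------------------------------


def _is_editable(variant: str, template: str, cut_position: int) -> bool:
    """A molecule is editable while its cut-site +/-3 window is intact at its
    template position.  Any indel shifts or disrupts the window, so edited
    molecules are permanently withdrawn from further cutting."""
    if len(variant) != len(template):
        return False
    lo = max(0, cut_position - 4)
    hi = min(len(template), cut_position + 3)
    return variant[lo:hi] == template[lo:hi]


def _apply_deletion(variant: str, cut_position: int, length: int) -> str:
    start = max(0, min(cut_position - 1 - length // 2, len(variant) - length))
    return variant[:start] + variant[start + length :]


def _apply_insertion(variant: str, cut_position: int, insert: str) -> str:
    pos = min(cut_position - 1, len(variant))
    return variant[:pos] + insert + variant[pos:]


def _edit_spectrum(
    variant: str,
    cut_position: int,
    geom_p: float,
    max_len: int,
    deletion_fraction: float,
) -> tuple[list[str], np.ndarray]:
    """Possible edit outcomes of one molecule and their probabilities.

    Lengths are geometric(geom_p) with the tail mass lumped at ``max_len``;
    deletions take ``deletion_fraction`` of the mass.  Insertions are
    templated duplications of the bases immediately 5' of the cut — the
    dominant NHEJ insertion outcome — which keeps the variant space small.
    """
    probs = np.array([geom_p * (1 - geom_p) ** (k - 1) for k in range(1, max_len + 1)])
    probs[-1] += (1 - geom_p) ** max_len  # truncation mass
    outcomes: list[str] = []
    weights: list[float] = []
    for k, pk in enumerate(probs, start=1):
        outcomes.append(_apply_deletion(variant, cut_position, k))
        weights.append(deletion_fraction * pk)
        dup_start = max(0, cut_position - 1 - k)
        insert = variant[dup_start : cut_position - 1]
        if not insert:
            insert = variant[:1] * k
        outcomes.append(_apply_insertion(variant, cut_position, insert))
        weights.append((1 - deletion_fraction) * pk)
    w = np.asarray(weights)
    return outcomes, w / w.sum()


def simulate_recording(
    state: CloneSimState,
    gene_rate: float,
    days: float,
    cut_position: int = 16,
    seed: int | None = None,
    geom_p: float = 0.5,
    max_indel: int = 10,
    deletion_fraction: float = 0.75,
) -> CloneSimState:
    """Accumulate Cas9 edits in each clone's stg molecule pool.

    Each editable molecule acquires an indel with probability
    1 - exp(-gene_rate * expression * days): the waiting time to the first
    cut is exponential with rate proportional to expression.  Indel lengths
    are geometric with mean 1/geom_p (default 2) truncated at ``max_indel``,
    centered at the cut site; deletions outnumber insertions 3:1 by default,
    and insertions are templated duplications of the bases 5' of the cut.
    A molecule whose cut-site window is disrupted cannot be re-edited (the
    stgRNA destroys its own protospacer).
    """
    if not 1 <= cut_position <= len(state.stg_template):
        raise ValueError("cut_position outside the template")
    if gene_rate < 0:
        raise ValueError("gene_rate must be >= 0")
    rng = np.random.default_rng(seed)
    template = state.stg_template
    pools = (
        [{template: int(c)} for c in state.counts]
        if state.stg_pools is None
        else [dict(p) for p in state.stg_pools]
    )
    spectrum_cache: dict[str, tuple[list[str], np.ndarray]] = {}
    for idx, pool in enumerate(pools):
        p_edit = 1.0 - math.exp(-gene_rate * state.expression[idx] * days)
        if p_edit == 0.0:
            continue
        for variant in sorted(pool):
            if not _is_editable(variant, template, cut_position):
                continue
            n_mol = pool[variant]
            k = int(rng.binomial(n_mol, p_edit))
            if k == 0:
                continue
            pool[variant] = n_mol - k
            if variant not in spectrum_cache:
                spectrum_cache[variant] = _edit_spectrum(
                    variant, cut_position, geom_p, max_indel, deletion_fraction
                )
            outcomes, probs = spectrum_cache[variant]
            for edited, n_edit in zip(outcomes, rng.multinomial(k, probs)):
                if n_edit:
                    pool[edited] = pool.get(edited, 0) + int(n_edit)
            if pool[variant] == 0:
                del pool[variant]
    return CloneSimState(
        list(state.barcodes),
        state.counts.copy(),
        state.expression.copy(),
        pools,
        template,
        state.time + days,
    )


# --- FASTQ emission -------------------------------------------------------


def _apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    if model.substitution_rate == 0 and model.indel_rate == 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if model.substitution_rate > 0:
        hit = rng.random(codes.size) < model.substitution_rate
        if hit.any():
            lut = np.frombuffer(b"ACGT", dtype=np.uint8)  # sorted byte values
            cur = np.searchsorted(lut, codes[hit])  # current base index 0..3
            new = (cur + rng.integers(1, 4, size=cur.size)) % 4
            codes[hit] = lut[new]
    out = codes.tobytes().decode()
    if model.indel_rate > 0:
        n_events = rng.binomial(len(out), model.indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(len(out) + 1))
            if rng.random() < 0.5 and out:
                out = out[: pos % len(out)] + out[pos % len(out) + 1 :]  # deletion
            else:
                out = out[:pos] + _ALL[rng.integers(4)] + out[pos:]  # insertion
    return out


def emit_fastq(
    state: CloneSimState,
    depth: int,
    error_model: ErrorModel = ErrorModel(),
    layout: str = "tumor",
    seed: int | None = None,
    design: AmpliconDesign = DEFAULT_DESIGN,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """Emit ``depth`` amplicon reads and the latent truth table.

    Returns (records, truth) where records are (read_id, sequence, quality
    string) and truth rows are (read_id, clone barcode).  When paths are
    given, a 4-line Phred+33 FASTQ and a TSV truth table are also written;
    output is byte-identical under a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if layout not in ("tumor", "recording"):
        raise ValueError("layout must be 'tumor' or 'recording'")
    rng = np.random.default_rng(seed)
    clone_draws = rng.multinomial(depth, state.frequencies)
    pools = state.stg_pools
    if layout == "recording" and pools is None:
        pools = [{state.stg_template: int(c)} for c in state.counts]
    records: list[tuple[str, str, str]] = []
    truth: list[tuple[str, str]] = []
    read_no = 0
    for idx, n_reads in enumerate(clone_draws):
        for _ in range(int(n_reads)):
            read_no += 1
            rid = f"read_{read_no:07d}"
            core = design.upstream_flank + state.barcodes[idx]
            if layout == "recording":
                pool = pools[idx]
                variants = sorted(pool)
                weights = np.array([pool[v] for v in variants], dtype=float)
                stg = variants[rng.choice(len(variants), p=weights / weights.sum())]
                core += design.stg_flank + stg
            core += design.downstream_flank + error_model.adapter
            seq = _apply_errors(core, error_model, rng)
            qual = "".join(chr(33 + error_model.quality_at(i)) for i in range(len(seq)))
            records.append((rid, seq, qual))
            truth.append((rid, state.barcodes[idx]))
    # interleave deterministically so clone order does not imprint on file order
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = [truth[i] for i in order]
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tbarcode\n")
            for rid, bc in truth:
                fh.write(f"{rid}\t{bc}\n")
    return records, truth


# --- Scenario presets -----------------------------------------------------
# Study-condition defaults: clone numbers and dynamics are scaled-down
# analogues of the experiments the statistics are meant for (a few thousand
# clones per pool, ~200-fold tumor growth, few-founder metastases, 3
# replicate mice per arm).


def scenario_treatment(
    seed: int,
    n_clones: int = 2000,
    cells_per_clone: int = 50,
    fold: float = 200.0,
    dispersion: float = 2.5e-4,
    survival: float = 0.5,
) -> tuple[CloneSimState, CloneSimState]:
    """Grow one barcoded pool into a control and a drug-treated tumor.

    Both arms share the in-vitro pool and experience independent in-vivo
    growth noise; the treated arm is additionally thinned with uniform
    (clone-independent) survival.  Returns (control, treated).
    """
    rng = np.random.default_rng(seed)
    lib = generate_library(LibrarySpec(n_clones, 0.1, int(rng.integers(2**31))))
    pool = init_population(lib, cells_per_clone)
    control = simulate_growth(pool, fold, dispersion, int(rng.integers(2**31)))
    tumor = simulate_growth(pool, fold, dispersion, int(rng.integers(2**31)))
    treated = simulate_selection(tumor, survival, int(rng.integers(2**31)))
    return control, treated


def scenario_bottleneck(
    seed: int,
    n_clones: int = 1000,
    cells_per_clone: int = 100,
    founders: int = 2,
    outgrowth_fold: float = 1000.0,
) -> tuple[CloneSimState, CloneSimState]:
    """Primary tumor and one metastasis founded by ``founders`` cells.

    Returns (primary, metastasis) where the metastasis has been regrown to a
    sequencable size after the founding bottleneck.
    """
    rng = np.random.default_rng(seed)
    lib = generate_library(LibrarySpec(n_clones, 0.1, int(rng.integers(2**31))))
    primary = simulate_growth(
        init_population(lib, cells_per_clone), 20.0, 1e-3, int(rng.integers(2**31))
    )
    seeded = simulate_bottleneck(primary, founders, int(rng.integers(2**31)))
    met = simulate_growth(seeded, outgrowth_fold, 1e-3, int(rng.integers(2**31)))
    return primary, met


def scenario_coupling(
    seed: int,
    coupling: float,
    n_clones: int = 300,
    cells_per_clone: int = 200,
    gene_rate: float = 0.05,
    days: float = 14.0,
    fitness_noise_sd: float = 1.0,
) -> CloneSimState:
    """Population where expression confers a proliferation advantage.

    Per-clone expression is Gamma(2, 1/2) (mean 1); clones grow with relative
    fitness exp(coupling * z + eps) where z is the standardized expression
    and eps ~ Normal(0, fitness_noise_sd) is expression-independent growth
    variability, then record expression in their stg pools.  At coupling 0
    clone abundance carries no expression signal; as coupling rises the
    weighted Spearman between mean indel score and clone reads rises with it.
    """
    rng = np.random.default_rng(seed)
    lib = generate_library(LibrarySpec(n_clones, 0.1, int(rng.integers(2**31))))
    expr = rng.gamma(2.0, 0.5, size=n_clones)
    pool = init_population(lib, cells_per_clone, expr)
    z = (expr - expr.mean()) / expr.std()
    eps = rng.normal(0.0, fitness_noise_sd, size=n_clones)
    fitness = np.exp(coupling * z + eps)
    weights = pool.counts * fitness
    grown_counts = rng.multinomial(pool.n_cells * 20, weights / weights.sum())
    grown = CloneSimState(list(pool.barcodes), grown_counts, expr).pruned()
    return simulate_recording(grown, gene_rate, days, seed=int(rng.integers(2**31)))
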