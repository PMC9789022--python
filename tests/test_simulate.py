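"""Synthetic-data generator: library design, population dynamics, recording
and FASTQ emission."""

import math

import numpy as np
import pytest

from clonescribe import (
    ErrorModel,
    LibrarySpec,
    corrected_barcode_number,
    emit_fastq,
    extract_barcode_stg,
    generate_library,
    init_population,
    simulate_bottleneck,
    simulate_growth,
    simulate_recording,
    simulate_selection,
)
from clonescribe.reads import DEFAULT_DESIGN, ReadRecord

from ._oracles import WSN_RE


class TestGenerateLibrary:
    def test_all_pattern_when_rate_zero(self):
        lib = generate_library(LibrarySpec(1000, 0.0, seed=1))
        assert len(lib) == len(set(lib)) == 1000
        assert all(len(bc) == 30 for bc in lib)
        assert all(WSN_RE.match(bc) for bc in lib)

    def test_single_barcode(self):
        (bc,) = generate_library(LibrarySpec(1, 0.0, seed=7))
        assert len(bc) == 30

    def test_off_pattern_count_exact(self):
        lib = generate_library(LibrarySpec(500, 0.9, seed=2))
        off = [bc for bc in lib if not WSN_RE.match(bc)]
        assert len(off) == 450  # ceil(0.9 * 500)
        assert len(set(lib)) == 500

    def test_deterministic_under_seed(self):
        spec = LibrarySpec(200, 0.3, seed=11)
        assert generate_library(spec) == generate_library(spec)

    def test_capacity_guard(self):
        with pytest.raises(ValueError):
            generate_library(LibrarySpec(8**10 + 1, 0.0, seed=0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            LibrarySpec(0)
        with pytest.raises(ValueError):
            LibrarySpec(10, off_pattern_rate=1.5)


class TestGrowth:
    def test_zero_dispersion_identity_at_fold_one(self):
        state = init_population([f"b{i}" for i in range(10)], 100)
        grown = simulate_growth(state, 1.0, 0.0, seed=3)
        assert np.array_equal(grown.counts, state.counts)

    def test_zero_dispersion_preserves_frequencies(self):
        state = init_population(["a", "b", "c"], [10, 20, 70])
        grown = simulate_growth(state, 200.0, 0.0)
        assert np.allclose(grown.frequencies, state.frequencies)

    def test_single_clone_stays_single(self):
        state = init_population(["only"], 50)
        grown = simulate_growth(state, 37.0, 0.5, seed=1)
        assert grown.n_clones == 1
        assert grown.frequencies[0] == 1.0

    def test_dispersion_never_raises_expected_diversity(self):
        state = init_population([f"b{i}" for i in range(1000)], 10)
        before = corrected_barcode_number({f"b{i}": 10 for i in range(1000)})
        effs = []
        for seed in range(100):
            grown = simulate_growth(state, 200.0, 1e-3, seed=seed)
            effs.append(corrected_barcode_number(grown.count_map()))
        assert np.mean(effs) <= before + 1e-9

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth(init_population(["a"], 10), 0.5)


class TestBottleneck:
    def test_single_founder_single_clone(self):
        state = init_population([f"b{i}" for i in range(100)], 10)
        out = simulate_bottleneck(state, 1, seed=5)
        assert out.n_clones == 1 and out.n_cells == 1

    def test_support_bounded_by_founders(self):
        state = init_population([f"b{i}" for i in range(1000)], 5)
        for seed in range(20):
            out = simulate_bottleneck(state, 2, seed=seed)
            assert out.n_clones <= 2

    def test_matches_hypergeometric_support_distribution(self):
        # founders=50 from 50 clones x 1 cell: every cell survives exactly once
        state = init_population([f"b{i}" for i in range(50)], 1)
        out = simulate_bottleneck(state, 50, seed=9)
        assert out.n_clones == 50
        assert np.array_equal(out.counts, np.ones(50, dtype=np.int64))

    def test_no_new_barcodes(self):
        state = init_population([f"b{i}" for i in range(30)], 4)
        out = simulate_bottleneck(state, 10, seed=2)
        assert set(out.barcodes) <= set(state.barcodes)

    def test_founders_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_bottleneck(init_population(["a"], 3), 4)


class TestSelection:
    def test_survival_one_is_identity(self):
        state = init_population([f"b{i}" for i in range(20)], 10)
        out = simulate_selection(state, 1.0, seed=1)
        assert np.array_equal(out.counts, state.counts)

    def test_no_new_barcodes(self):
        state = init_population([f"b{i}" for i in range(100)], 10)
        out = simulate_selection(state, 0.3, seed=4)
        assert set(out.barcodes) <= set(state.barcodes)

    def test_resistant_clone_dominates(self):
        # expected survivors: resistant 1000, background 49 x 1000 x 0.001 ~ 49
        n = 50
        survival = np.full(n, 0.001)
        survival[17] = 1.0
        state = init_population([f"b{i}" for i in range(n)], 1000)
        out = simulate_selection(state, survival, seed=8)
        freq = dict(zip(out.barcodes, out.frequencies))
        assert freq["b17"] > 0.9

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            simulate_selection(init_population(["a"], 10), 1.5)


class TestRecording:
    def test_zero_rate_leaves_template(self, template):
        state = init_population(["b0"], 1000)
        out = simulate_recording(state, 0.0, days=14, seed=1)
        assert out.stg_pools[0] == {template: 1000}

    def test_zero_expression_unedited(self, template):
        state = init_population(["b0"], 1000, expression=0.0)
        out = simulate_recording(state, 0.5, days=14, seed=1)
        assert out.stg_pools[0] == {template: 1000}

    def test_halflife_gives_half_edited(self, template):
        # rate * expression * days = ln 2  ->  P(edited) = 1/2
        state = init_population(["b0"], 10_000)
        out = simulate_recording(state, math.log(2), days=1.0, seed=12)
        unedited = out.stg_pools[0].get(template, 0)
        assert unedited == pytest.approx(5000, abs=3 * 50)  # 3 sigma of Bin(1e4, .5)

    def test_monotone_in_days_and_expression(self, template):
        def edited_fraction(days, expr, seed):
            state = init_population(["b0"], 2000, expression=expr)
            out = simulate_recording(state, 0.05, days=days, seed=seed)
            pool = out.stg_pools[0]
            return 1 - pool.get(template, 0) / sum(pool.values())

        for seed in range(10):
            d = [edited_fraction(t, 1.0, seed) for t in (0.0, 7.0, 14.0)]
            assert d[0] <= d[1] <= d[2]
            e = [edited_fraction(7.0, x, seed) for x in (0.5, 1.0, 2.0)]
            assert e[0] <= e[2]

    def test_edited_molecules_stay_mutated(self, template):
        state = init_population(["b0"], 5000)
        once = simulate_recording(state, 10.0, days=10.0, seed=3)  # saturating
        again = simulate_recording(once, 10.0, days=10.0, seed=4)
        assert sum(once.stg_pools[0].values()) == 5000
        # a saturated pool no longer changes: no valid targets remain
        assert template not in once.stg_pools[0]
        assert again.stg_pools[0] == once.stg_pools[0]

    def test_sequential_recording_accumulates(self, template):
        state = init_population(["b0"], 10_000)
        day7 = simulate_recording(state, 0.05, days=7.0, seed=5)
        day14 = simulate_recording(day7, 0.05, days=7.0, seed=6)
        f7 = 1 - day7.stg_pools[0].get(template, 0) / 10_000
        f14 = 1 - day14.stg_pools[0].get(template, 0) / 10_000
        assert f14 > f7


class TestEmitFastq:
    def test_zero_error_reads_contain_exact_barcode(self):
        state = init_population(["A" * 30], 10)
        records, truth = emit_fastq(
            state, 100, ErrorModel(0.0, 0.0), layout="tumor", seed=1
        )
        assert len(records) == 100
        assert all("A" * 30 in seq for _, seq, _ in records)
        assert all(bc == "A" * 30 for _, bc in truth)

    def test_substitution_rate_mean_mismatches(self):
        bc = "A" * 30
        state = init_population([bc], 10)
        records, _ = emit_fastq(
            state, 2000, ErrorModel(0.01, 0.0, adapter=""), layout="tumor", seed=2
        )
        up = DEFAULT_DESIGN.upstream_flank
        mismatches = []
        for _, seq, _ in records:
            window = seq[len(up) : len(up) + 30]
            mismatches.append(sum(c != "A" for c in window))
        # Binomial(30, 0.01): mean 0.3
        assert np.mean(mismatches) == pytest.approx(0.3, abs=0.06)

    def test_recording_layout_round_trips(self, template):
        lib = generate_library(LibrarySpec(5, 0.0, seed=3))
        state = simulate_recording(init_population(lib, 100), 0.1, days=7, seed=4)
        records, truth = emit_fastq(
            state, 200, ErrorModel(0.0, 0.0), layout="recording", seed=5
        )
        truth_map = dict(truth)
        for rid, seq, qual in records:
            res = extract_barcode_stg(ReadRecord(rid, seq, [ord(c) - 33 for c in qual]))
            assert res.status == "pass"
            assert res.barcode == truth_map[rid]

    def test_byte_identical_under_seed(self, tmp_path):
        state = init_population(generate_library(LibrarySpec(20, 0.1, seed=6)), 50)
        paths = []
        for run in ("a", "b"):
            fq = tmp_path / f"{run}.fastq"
            emit_fastq(state, 300, ErrorModel(), layout="tumor", seed=99, fastq_path=fq)
            paths.append(fq.read_bytes())
        assert paths[0] == paths[1]

    def test_quality_profile_encoded_phred33(self):
        state = init_population(["A" * 30], 5)
        records, _ = emit_fastq(state, 10, ErrorModel(0.0, 0.0), seed=7)
        for _, seq, qual in records:
            assert len(seq) == len(qual)
            assert all(ord(c) - 33 == 37 for c in qual)
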