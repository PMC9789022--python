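"""Config-driven end-to-end pipeline: simulate -> extract -> merge -> stats.

A scenario preset is simulated, FASTQ is emitted with the shared amplicon
design, reads are re-extracted, barcodes are collapsed at Hamming distance
<= 2 against the appropriate reference, and diversity / recording summaries
are written as TSV next to a YAML run manifest.  Reruns with the same seed
and config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diversity import corrected_barcode_number, js_matrix, shannon_entropy
from .io import write_count_table, write_triplets
from .merging import filter_to_reference, merge_barcodes, select_reference
from .reads import DEFAULT_DESIGN, ReadRecord, collect_triplets, count_barcodes, extract_reads
from .recording import build_blacklist, percent_mutation, score_triplets
from .simulate import (
    CloneSimState,
    ErrorModel,
    emit_fastq,
    scenario_bottleneck,
    scenario_coupling,
    scenario_treatment,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Scenario and stage parameters; defaults match the analysis defaults
    (adapter tolerance 0.2, Q20/l25/p80 quality gates, 30-base barcodes,
    Hamming merge <= 2, alignment costs 1 / 2.5 / 0.5, blacklist 4.0,
    top-10 composition)."""

    scenario: str = "treatment"
    seed: int = 0
    depth: int = 20000
    max_dist: int = 2
    substitution_rate: float = 0.001
    indel_rate: float = 1e-5
    coupling: float = 1.0
    founders: int = 2
    out_dir: str = "clonescribe_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _states_for(config: PipelineConfig) -> dict[str, CloneSimState]:
    if config.scenario == "treatment":
        control, treated = scenario_treatment(config.seed, **config.extra)
        return {"control": control, "treated": treated}
    if config.scenario in ("metastasis", "bottleneck"):
        primary, met = scenario_bottleneck(config.seed, founders=config.founders, **config.extra)
        return {"primary": primary, "metastasis": met}
    if config.scenario in ("recording", "coupling"):
        state = scenario_coupling(config.seed, config.coupling, **config.extra)
        return {"recorded": state}
    if config.scenario == "growth":
        control, _ = scenario_treatment(config.seed, **config.extra)
        return {"tumor": control}
    raise ValueError(f"unknown scenario {config.scenario!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one scenario end to end; returns the result summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    error_model = ErrorModel(config.substitution_rate, config.indel_rate)
    layout = "recording" if config.scenario in ("recording", "coupling") else "tumor"
    states = _states_for(config)

    tables = []
    triplets_by_sample = {}
    for i, (name, state) in enumerate(states.items()):
        fastq = out / f"{name}.fastq"
        truth = out / f"{name}.truth.tsv"
        records, _ = emit_fastq(
            state, config.depth, error_model, layout, seed=config.seed * 1000 + i,
            fastq_path=fastq, truth_path=truth,
        )
        reads = [ReadRecord(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in records]
        results = extract_reads(reads, layout=layout, adapter=error_model.adapter)
        if layout == "tumor":
            table, _ = merge_barcodes(count_barcodes(results, name), config.max_dist)
            tables.append(table)
        else:
            triplets_by_sample[name] = collect_triplets(results)

    summary: dict = {"scenario": config.scenario, "seed": config.seed, "samples": {}}
    if layout == "tumor":
        if len(tables) > 1:
            reference = select_reference(tables)
            if reference:
                tables = [filter_to_reference(t, reference)[0] for t in tables]
        write_count_table(tables, out / "counts.tsv")
        for t in tables:
            summary["samples"][t.sample_id] = {
                "barcodes": len(t.counts),
                "shannon_entropy": shannon_entropy(t),
                "corrected_barcode_number": corrected_barcode_number(t),
            }
        if len(tables) > 1:
            js_matrix(tables).to_csv(out / "js_divergence.tsv", sep="\t")
    else:
        template = DEFAULT_DESIGN.stg_template
        for name, triplets in triplets_by_sample.items():
            write_triplets(triplets, out / f"{name}.triplets.tsv", name)
            blacklist = build_blacklist({}, template)
            scored = score_triplets(triplets, template, blacklist=blacklist)
            scored.to_csv(out / f"{name}.scores.tsv", sep="\t", index=False)
            summary["samples"][name] = {
                "triplets": len(triplets),
                "percent_mutation": percent_mutation(triplets, template),
            }

    manifest = {
        "clonescribe_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "samples": sorted(states),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
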