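"""End-to-end pipeline: simulate → blocks → calls → scrna → pathways.

Each stage reads the previous stage's plain-text outputs from the run
directory, so stages can also be run individually against external files
with the same layout. A run manifest records inputs, outputs, the
parameter hash and the seed; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import blocks as blk
from . import clones as cln
from . import pathways as pw
from . import scrna as sc
from . import simulate as sim
from .params import SimParams
from .simulate import InputError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "blocks", "calls", "scrna", "pathways")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the standard thresholds.

    β < ``beta_unmeth`` is unmethylated (complete demethylation when the
    baseline was full); β ≥ ``beta_full`` is fully methylated; a gene is
    inducible when no mock cell exceeds ``umi_inducible_max`` UMIs and
    upregulated in a cell at ≥ ``umi_upreg_min`` UMIs.
    """

    stages: tuple[str, ...] = STAGES
    out_dir: str = "epiclone_run"
    beta_unmeth: float = 0.2
    beta_full: float = 0.8
    umi_inducible_max: int = 2
    umi_upreg_min: int = 3
    top_k: int = 200
    sim: SimParams = field(default_factory=SimParams)
    seed: int = 0
    # optional external inputs (override simulate outputs)
    probe_table: str | None = None
    probe_manifest: str | None = None
    block_definitions: str | None = None
    mock_mtx_prefix: str | None = None
    treated_mtx_prefix: str | None = None
    gene_sets: str | None = None
    skip_missing_genes: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InputError(f"unknown stage(s): {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if isinstance(self.sim, dict):
            self.sim = SimParams.from_dict(self.sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def param_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.outputs: list[str] = []
        self.inputs: list[str] = []

    def path(self, name: str) -> Path:
        p = self.out / name
        self.outputs.append(name)
        return p


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    params = cfg.sim.with_(seed=cfg.seed)
    mock = sim.simulate_population(params, kind="mock")
    treated = sim.simulate_population(params, kind="treated")
    dead = sim.simulate_population(params, kind="dead")
    clones = sim.derive_clones(treated, params)

    profiles = [
        sim.derive_bulk(mock, "bulk-mock", "bulk-mock"),
        sim.derive_bulk(treated, "bulk-treated", "bulk-treated"),
        sim.derive_bulk(dead, "dead-pool", "dead-pool"),
        *clones,
    ]
    table, manifest = sim.emit_probe_table(profiles, params)
    blk.write_probe_table_tsv(table, run.path("probe_betas.tsv"))
    blk.write_manifest_tsv(manifest, run.path("probe_manifest.tsv"))

    # truth layers for oracle checks
    truth = pd.DataFrame({p.label: p.betas for p in profiles})
    truth.to_csv(run.path("truth_betas.tsv"), sep="\t", index_label="locus")

    roles: dict[str, str] = {}
    for locus in treated.silenced_loci:
        if locus in ("ERVMER61-1", "ERVW-1"):
            roles[locus] = "ERV"
        elif locus in sim.NAMED_SILENCED_LOCI:
            roles[locus] = "TSG"
    roles.update({"IFI16": "ISG", "IFI44": "ISG"})
    roles.update({f"HK{i:03d}": "background" for i in range(1, 51)})

    for condition, pop in (("mock", mock), ("treated", treated)):
        umis = sim.simulate_umi_matrix(pop, params, roles, condition=condition)
        sc.write_mtx(
            umis,
            run.path(f"umi_{condition}.mtx"),
            run.path(f"umi_{condition}.genes.tsv"),
            run.path(f"umi_{condition}.barcodes.tsv"),
        )
    params.to_yaml(run.path("sim_params.yaml"))


def _load_blocks_inputs(run: _Run):
    cfg = run.config
    table_path = cfg.probe_table or run.out / "probe_betas.tsv"
    manifest_path = cfg.probe_manifest or run.out / "probe_manifest.tsv"
    for p in (table_path, manifest_path):
        if not Path(p).exists():
            raise InputError(f"blocks stage: missing input {p}")
        run.inputs.append(str(p))
    return blk.read_probe_table_tsv(table_path), blk.read_manifest_tsv(manifest_path)


def _stage_blocks(run: _Run) -> None:
    table, manifest = _load_blocks_inputs(run)
    if run.config.block_definitions:
        defs = blk.read_block_definitions_tsv(run.config.block_definitions, manifest)
        run.inputs.append(run.config.block_definitions)
    else:
        defs = blk.assemble_blocks(manifest)
    betas = blk.aggregate_block_beta(table, defs)
    blk.write_block_definitions_tsv(defs, run.path("block_definitions.tsv"))
    blk.write_block_beta_tsv(betas, run.path("block_betas.tsv"))
    _json_dump(blk.block_totals(betas), run.path("block_totals.json"))


def _stage_calls(run: _Run) -> None:
    cfg = run.config
    betas = blk.read_block_beta_tsv(run.out / "block_betas.tsv")
    manifest = blk.read_manifest_tsv(cfg.probe_manifest or run.out / "probe_manifest.tsv")
    defs = blk.read_block_definitions_tsv(run.out / "block_definitions.tsv", manifest)

    baseline = blk.select_fully_methylated_tss200cgi(
        betas, defs, "bulk-mock", beta_full=cfg.beta_full
    )
    clone_cols = [c for c in betas.columns if c.startswith("clone")]
    calls = cln.call_complete_demethylation(
        betas[clone_cols], baseline, "bulk-mock", beta_unmeth=cfg.beta_unmeth
    )
    bulk_calls = cln.call_complete_demethylation(
        betas[["bulk-treated"]], baseline, "bulk-mock", beta_unmeth=cfg.beta_unmeth
    )

    cln.write_calls_tsv(calls, run.path("demeth_calls.tsv"))
    cln.write_overlap_tsv(cln.pairwise_overlap(calls), run.path("clone_overlap.tsv"))
    dend = cln.cluster_clone_profiles(betas.loc[baseline, clone_cols])
    run.path("clone_dendrogram.nwk").write_text(dend.to_newick() + "\n")

    summary = cln.summarize(calls)
    summary["bulk_treated_complete_calls"] = int(bulk_calls.calls.to_numpy().sum())
    summary["mean_delta_beta_surviving"] = cln.mean_delta_beta(
        betas["bulk-treated"], betas["bulk-mock"]
    )
    if "dead-pool" in betas.columns:
        delta_dead = cln.mean_delta_beta(betas["dead-pool"], betas["bulk-mock"])
        summary["mean_delta_beta_dead"] = delta_dead
        summary["dead_minus_surviving_delta_beta"] = (
            delta_dead - summary["mean_delta_beta_surviving"]
        )
    _json_dump(summary, run.path("clone_summary.json"))


def _load_mtx(run: _Run, prefix: str | Path, condition: str) -> sc.UMICountMatrix:
    prefix = str(prefix)
    paths = [f"{prefix}.mtx", f"{prefix}.genes.tsv", f"{prefix}.barcodes.tsv"]
    for p in paths:
        if not Path(p).exists():
            raise InputError(f"scrna stage: missing input {p}")
    run.inputs.extend(paths)
    return sc.read_mtx(*paths, condition=condition)


def _stage_scrna(run: _Run) -> None:
    cfg = run.config
    mock = _load_mtx(run, cfg.mock_mtx_prefix or run.out / "umi_mock", "mock")
    treated = _load_mtx(run, cfg.treated_mtx_prefix or run.out / "umi_treated", "treated")

    inducible = sc.select_inducible_genes(mock, cfg.umi_inducible_max)
    k = min(cfg.top_k, len(inducible))
    top = sc.top_upregulated(treated, inducible, k)
    report = sc.gene_panel_report(treated, inducible, cfg.umi_upreg_min)
    report.to_csv(run.path("gene_report.tsv"), sep="\t", index_label="gene")

    combined = sc.combine(mock, treated)
    embedding = sc.embed_cells(combined, genes=inducible, seed=cfg.seed)
    embedding.to_csv(run.path("embedding.tsv"), sep="\t", index_label="barcode")

    dend = sc.cluster_cells(combined, top)
    run.path("cell_dendrogram.nwk").write_text(dend.to_newick() + "\n")

    summary = {
        "n_inducible": len(inducible),
        "top_upregulated": top,
        "embedding_purity": sc.embedding_purity(embedding, seed=cfg.seed),
        "detected_genes_per_cell_mean": {
            "mock": float(sc.detected_genes_per_cell(mock).mean()),
            "treated": float(sc.detected_genes_per_cell(treated).mean()),
        },
        "zero_total_cells": combined.zero_total_cells(),
    }
    _json_dump(summary, run.path("scrna_summary.json"))


def _stage_pathways(run: _Run) -> None:
    cfg = run.config
    betas = blk.read_block_beta_tsv(run.out / "block_betas.tsv")
    manifest = blk.read_manifest_tsv(cfg.probe_manifest or run.out / "probe_manifest.tsv")
    defs = blk.read_block_definitions_tsv(run.out / "block_definitions.tsv", manifest)
    gene_sets = pw.load_gene_sets(cfg.gene_sets) if cfg.gene_sets else None
    clone_cols = [c for c in betas.columns if c.startswith("clone")]
    # CDKN2A-like genes carry no island block; resolve by exon-1 proximity
    gene_info = {"CDKN2A": pw.GeneInfo(exon1_start=500, strand="-")}
    table = pw.evaluate_pathways(
        betas,
        defs,
        clone_cols,
        gene_sets=gene_sets,
        gene_info=gene_info,
        beta_unmeth=cfg.beta_unmeth,
        skip_missing=cfg.skip_missing_genes,
    )
    pw.write_pathway_calls_tsv(table, run.path("pathway_calls.tsv"))
    _json_dump(table.to_json_dict(), run.path("pathway_calls.json"))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "blocks": _stage_blocks,
    "calls": _stage_calls,
    "scrna": _stage_scrna,
    "pathways": _stage_pathways,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``): inputs,
    outputs, parameter hash and seed.
    """
    run = _Run(config)
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    manifest = {
        "stages": list(config.stages),
        "inputs": sorted(set(run.inputs)),
        "outputs": sorted(set(run.outputs)),
        "param_hash": config.param_hash(),
        "seed": config.seed,
    }
    _json_dump(manifest, run.out / "manifest.json")
    return manifest
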