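"""End-to-end orchestration of the CAD-family analysis stages.

A single structured config drives: signature-site classification ->
NJ tree with bootstrap -> promoter element scan -> expression filter /
heatmap -> stress fold-change calls -> co-expression network.  Stages
whose inputs are absent are skipped.  All randomness flows from one
top-level seed, split deterministically per stage, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import expression as expr
from . import network as net
from . import phylo, promoters, sites

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; .stage names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_INPUT_KEYS = {
    "proteins",
    "alignment",
    "promoters",
    "expression",
    "stress_expression",
    "design",
    "seed_genes",
    "element_table",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline parameters; unknown keys are rejected."""

    inputs: dict = field(default_factory=dict)
    output_dir: str = "pipeline_out"
    seed: int = 0
    tolerance: dict = field(default_factory=dict)
    pattern_overrides: dict = field(default_factory=dict)
    distance_model: str = "poisson"
    gap_mode: str = "pairwise"
    bootstrap_replicates: int = 1000
    min_fpkm: float = 0.05
    min_samples: int = 7
    pos_threshold: float = 0.7
    neg_threshold: float = -0.5
    fold_change_threshold: float = 2.0
    pseudocount: float = 0.1
    low_expression: float = 1.0
    strands: str = "both"

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        if self.distance_model not in {"poisson", "p_distance", "p"}:
            raise ConfigError(f"unknown distance model {self.distance_model!r}")
        if self.gap_mode not in {"pairwise", "complete"}:
            raise ConfigError(f"unknown gap_mode {self.gap_mode!r}")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        if not (0 <= self.min_fpkm):
            raise ConfigError("min_fpkm must be >= 0")
        if self.min_samples < 1:
            raise ConfigError("min_samples must be >= 1")
        if not (0 < self.pos_threshold <= 1):
            raise ConfigError("pos_threshold must be in (0, 1]")
        if not (-1 <= self.neg_threshold < 0):
            raise ConfigError("neg_threshold must be in [-1, 0)")
        if self.fold_change_threshold <= 1:
            raise ConfigError("fold_change_threshold must be > 1")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.strands not in {"both", "forward"}:
            raise ConfigError("strands must be 'both' or 'forward'")
        for name, tol in self.tolerance.items():
            if name not in sites.DEFAULT_TOLERANCE:
                raise ConfigError(f"unknown site name in tolerance: {name!r}")
            if tol < 0:
                raise ConfigError("tolerances must be >= 0")


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ["bootstrap", "simulate", "spare1", "spare2"]
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage whose inputs are present; returns the output dir.

    Outputs: classification.tsv + accepted.fasta, distances.tsv + tree.nwk,
    promoter_hits.tsv + promoter_counts.tsv, filtered_fpkm.tsv +
    heatmap.tsv, fold_changes.tsv, network.tsv + network.sif, and
    manifest.json.  A stage failure aborts the run with the stage named;
    outputs of completed stages are retained next to a FAILED marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    inputs = {k: Path(v) for k, v in config.inputs.items()}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in {"inputs", "output_dir"}
        },
        "inputs": {k: str(v) for k, v in inputs.items()},
        "stages": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def run_stage(name: str, fn) -> None:
        try:
            produced = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(out, manifest)
            failed_marker.write_text(f"{name}: {exc}\n")
            raise StageError(name, str(exc)) from exc
        manifest["stages"][name] = {"status": "ok", "outputs": produced}
        logger.info("stage %s: ok (%s)", name, ", ".join(produced))

    patterns = sites.default_patterns(config.pattern_overrides or None)

    if "proteins" in inputs:

        def stage_identify() -> list[str]:
            records = sites.read_protein_fasta(inputs["proteins"])
            table = sites.classification_table(
                [
                    sites.classify(rec, patterns, config.tolerance or None)
                    for rec in records
                ]
            )
            table.to_csv(out / "classification.tsv", sep="\t", index=False)
            sites.write_accepted_fasta(records, table, out / "accepted.fasta")
            return ["classification.tsv", "accepted.fasta"]

        run_stage("identify", stage_identify)

    if "alignment" in inputs:

        def stage_tree() -> list[str]:
            aln = phylo.read_alignment_fasta(inputs["alignment"])
            dm = phylo.pairwise_distance(
                aln, config.distance_model, config.gap_mode
            )
            phylo.write_distance_matrix(dm, out / "distances.tsv")
            boot = phylo.bootstrap_support(
                aln,
                replicates=config.bootstrap_replicates,
                model=config.distance_model,
                seed=seeds["bootstrap"],
                gap_mode=config.gap_mode,
            )
            phylo.write_newick(boot.tree, out / "tree.nwk")
            return ["distances.tsv", "tree.nwk"]

        run_stage("tree", stage_tree)

    if "promoters" in inputs:

        def stage_promoters() -> list[str]:
            elements = (
                promoters.load_element_table(inputs["element_table"])
                if "element_table" in inputs
                else promoters.default_elements()
            )
            hits = promoters.scan_promoter_fasta(
                inputs["promoters"], elements, config.strands
            )
            promoters.hits_table(hits).to_csv(
                out / "promoter_hits.tsv", sep="\t", index=False
            )
            from Bio import SeqIO

            gene_ids = [
                rec.id for rec in SeqIO.parse(str(inputs["promoters"]), "fasta")
            ]
            promoters.element_count_matrix(hits, gene_ids, elements).to_csv(
                out / "promoter_counts.tsv", sep="\t"
            )
            return ["promoter_hits.tsv", "promoter_counts.tsv"]

        run_stage("promoters", stage_promoters)

    filtered = None
    if "expression" in inputs:

        def stage_expression() -> list[str]:
            nonlocal filtered
            em = expr.read_expression_tsv(inputs["expression"])
            filtered = expr.expression_filter(
                em, config.min_fpkm, config.min_samples
            )
            filtered.to_csv(out / "filtered_fpkm.tsv", sep="\t")
            expr.heatmap_matrix(filtered).to_csv(out / "heatmap.tsv", sep="\t")
            return ["filtered_fpkm.tsv", "heatmap.tsv"]

        run_stage("expression", stage_expression)

    if "stress_expression" in inputs and "design" in inputs:

        def stage_stress() -> list[str]:
            em = expr.read_expression_tsv(inputs["stress_expression"])
            design = expr.read_design_tsv(inputs["design"])
            table = expr.stress_response_table(
                em,
                design,
                up_threshold=config.fold_change_threshold,
                pseudocount=config.pseudocount,
                low_expr=config.low_expression,
            )
            table.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
            return ["fold_changes.tsv"]

        run_stage("stress", stage_stress)

    if filtered is not None and filtered.shape[0] >= 2:

        def stage_coexpress() -> list[str]:
            seed_genes: Optional[tuple[str, ...]] = None
            if "seed_genes" in inputs:
                seed_genes = tuple(
                    line.strip()
                    for line in inputs["seed_genes"].read_text().splitlines()
                    if line.strip()
                )
            spec = net.NetworkSpec(
                pos_threshold=config.pos_threshold,
                neg_threshold=config.neg_threshold,
                seed_genes=seed_genes,
            )
            edges = net.build_network(filtered, spec)
            net.export_network(edges, out / "network.tsv", "tsv")
            net.export_network(edges, out / "network.sif", "sif")
            return ["network.tsv", "network.sif"]

        run_stage("coexpress", stage_coexpress)

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
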