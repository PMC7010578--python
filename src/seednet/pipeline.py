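"""End-to-end orchestration: inputs -> enrichment -> cross-talk -> subnetwork.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
executed stage by stage with one structured log line per stage, and
summarised in a JSON manifest holding every output path with its SHA-256
checksum plus the headline counts.  Re-running an unchanged config over
unchanged inputs reproduces the checksums exactly.

Input modes:

* explicit paths to a seed list, a GMT collection and (optionally) an
  interactome edge list;
* ``fixtures: true`` — the bundled disease-study fixtures; the bundled
  pathway sets are already the enriched, seed-restricted memberships, so
  the enrichment stage is skipped and cross-talk runs on them directly;
* ``simulate: {...}`` — synthetic inputs generated into the output
  directory first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import crosstalk as ct
from . import enrichment as enr
from . import steiner as st
from .geneset_io import (GeneSetCollection, SeedList, load_mdd_fixtures,
                         read_gmt, read_seed_list, write_gmt)
from .interactome import Interactome, read_interactions
from .synthetic import SyntheticConfig, simulate_study

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "seednet_run"
    seeds_path: str | None = None
    gmt_path: str | None = None
    interactome_path: str | None = None
    fixtures: bool = False
    simulate: dict | None = None
    skip_enrichment: bool = False
    min_seed_genes: int = 5
    fdr_threshold: float = 0.05
    min_shared: int = 3
    score_cutoff: float | None = None
    induce_edges: bool = False
    forest_mode: bool = False
    node_weighted: bool = False
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0.0 <= self.fdr_threshold <= 1.0):
            raise ValueError(f"fdr_threshold={self.fdr_threshold} outside [0, 1]")
        if self.min_seed_genes < 1:
            raise ValueError("min_seed_genes must be >= 1")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        modes = sum([self.fixtures, self.simulate is not None,
                     self.gmt_path is not None])
        if modes != 1:
            raise ValueError("exactly one input mode required: "
                             "fixtures, simulate, or explicit paths")
        if self.gmt_path is not None and self.seeds_path is None:
            raise ValueError("explicit mode needs both gmt_path and seeds_path")
        for p in (self.seeds_path, self.gmt_path, self.interactome_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, dict] = field(default_factory=dict)
    counts: dict[str, int | None] = field(default_factory=dict)

    def add_output(self, key: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[key] = {"path": str(path), "sha256": digest}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"config": self.config, "counts": self.counts,
             "outputs": self.outputs}, indent=2, sort_keys=True) + "\n")
        return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: RunConfig, out: Path
                 ) -> tuple[SeedList, GeneSetCollection, Interactome | None]:
    if config.fixtures:
        seeds, pathways, _ = load_mdd_fixtures()
        net = (read_interactions(config.interactome_path)
               if config.interactome_path else None)
        return seeds, pathways, net
    if config.simulate is not None:
        sim = SyntheticConfig(**{**config.simulate, "rng_seed": config.rng_seed})
        paths = simulate_study(sim, out / "simulated")
        return (read_seed_list(paths["seeds"]),
                read_gmt(paths["annotations"]),
                read_interactions(paths["interactome"]))
    seeds = read_seed_list(config.seeds_path)
    pathways = read_gmt(config.gmt_path)
    net = (read_interactions(config.interactome_path)
           if config.interactome_path else None)
    return seeds, pathways, net


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; any failure aborts with the stage name and leaves
    a ``.failed`` marker next to the partial outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    stage = "load_inputs"
    try:
        seeds, pathways, net = _load_inputs(config, out)
        log.info("stage=%s seeds=%d sets=%d interactome=%s", stage,
                 len(seeds), len(pathways),
                 f"{net.n_nodes}n/{net.n_edges}e" if net else "none")
        manifest.counts["n_seeds"] = len(seeds)
        manifest.counts["n_sets_tested"] = len(pathways)

        stage = "enrichment"
        if config.fixtures or config.skip_enrichment:
            # bundled sets are already the enriched seed-restricted lists
            enriched_sets = pathways
            manifest.counts["n_enriched"] = len(pathways)
            log.info("stage=%s skipped (pre-filtered sets)", stage)
        else:
            records = enr.run_enrichment(
                seeds, pathways,
                min_seed_genes=config.min_seed_genes,
                fdr_threshold=config.fdr_threshold)
            path = enr.write_enrichment_tsv(records, out / "enrichment.tsv")
            manifest.add_output("enrichment", path)
            manifest.counts["n_enriched"] = len(records)
            log.info("stage=%s tested=%d kept=%d", stage, len(pathways),
                     len(records))
            surviving = {r.set_id for r in records}
            enriched_sets = GeneSetCollection(
                source_label=pathways.source_label + ":enriched",
                sets=[_restrict(pathways[sid], records) for sid in
                      sorted(surviving)])
            if len(enriched_sets):
                write_gmt(enriched_sets, out / "enriched_sets.gmt")
                manifest.add_output("enriched_sets", out / "enriched_sets.gmt")

        stage = "crosstalk"
        if len(enriched_sets) >= 2:
            net_ct = ct.build_crosstalk_network(
                enriched_sets, min_shared=config.min_shared,
                score_cutoff=config.score_cutoff)
            for fmt in ("tsv", "sif", "graphml"):
                p = ct.export_network(net_ct, out / f"crosstalk.{fmt}", fmt)
                manifest.add_output(f"crosstalk_{fmt}", p)
            manifest.counts["crosstalk_nodes"] = net_ct.n_nodes
            manifest.counts["crosstalk_edges"] = net_ct.n_edges
            log.info("stage=%s nodes=%d edges=%d", stage, net_ct.n_nodes,
                     net_ct.n_edges)
        else:
            manifest.counts["crosstalk_nodes"] = 0
            manifest.counts["crosstalk_edges"] = 0

        stage = "subnetwork"
        if net is not None:
            result = st.approximate_steiner_tree(
                net, seeds, node_weighted=config.node_weighted,
                forest=config.forest_mode, induce_edges=config.induce_edges)
            for p in st.export_subnetwork(result, seeds, out / "subnetwork"):
                manifest.add_output(p.name, p)
            manifest.counts["subnetwork_nodes"] = result.n_nodes
            manifest.counts["subnetwork_edges"] = result.n_edges
            manifest.counts["n_connectors"] = len(result.connectors)
            manifest.counts["n_unreachable_terminals"] = len(
                result.unreachable_terminals)
            log.info("stage=%s nodes=%d edges=%d connectors=%d", stage,
                     result.n_nodes, result.n_edges, len(result.connectors))
        else:
            manifest.counts["subnetwork_nodes"] = None
            manifest.counts["subnetwork_edges"] = None
            manifest.counts["n_connectors"] = None

        stage = "manifest"
        manifest.to_json(out / "manifest.json")
        return manifest
    except Exception as exc:
        (out / ".failed").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc


def _restrict(gene_set, records):
    for r in records:
        if r.set_id == gene_set.set_id:
            return dataclasses.replace(gene_set, members=frozenset(r.seed_members))
    raise KeyError(gene_set.set_id)
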