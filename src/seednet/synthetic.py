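"""Synthetic study generator with exact ground truth.

Emulates the three inputs of the pipeline at a reduced, testable scale:

* a sparse scale-free interactome (Barabási–Albert preferential attachment,
  standing in for a merged physical-interaction network whose full-scale
  analogue has on the order of 16k proteins and 228k interactions);
* gene-set annotations of realistic sizes (5–40 genes) drawn over the
  interactome's gene symbols, with a designated subset of "enriched"
  pathways that may be forced to overlap pairwise so cross-talk edges have
  known ground truth;
* a seed-gene list assembled from a fixed fraction of each enriched
  pathway's members plus uniform background genes, so downstream enrichment
  ranks are predictable.

A single ``rng_seed`` drives everything; each stage draws from its own
deterministic substream so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .geneset_io import (GeneSet, GeneSetCollection, SeedList, write_gmt,
                         write_seed_list)
from .interactome import Interactome, write_interactions

__all__ = ["SyntheticConfig", "GroundTruth", "generate_interactome",
           "generate_annotations", "generate_seed_list", "simulate_study"]

_STAGE = {"interactome": 0, "annotations": 1, "seeds": 2}


@dataclass
class SyntheticConfig:
    rng_seed: int = 0
    n_genes: int = 2000
    attachment_edges: int = 3
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (5, 40)
    n_seed_genes: int = 150
    n_enriched_pathways: int = 5
    enrichment_fraction: float = 0.6
    crosstalk_overlap: int | None = None   # force planted pathways to share genes
    connector_planting: dict | None = None  # {"hub": str, "n_leaves": int}

    def validate(self) -> None:
        problems = []
        if self.n_genes < self.attachment_edges + 1:
            problems.append("n_genes must exceed attachment_edges")
        if not (0 < self.enrichment_fraction <= 1):
            problems.append("enrichment_fraction must be in (0, 1]")
        if self.n_enriched_pathways > self.n_pathways:
            problems.append("n_enriched_pathways > n_pathways")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            problems.append("pathway_size_range infeasible for n_genes")
        if self.n_seed_genes > self.n_genes:
            problems.append("n_seed_genes > n_genes")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(_STAGE[stage],)))


@dataclass
class GroundTruth:
    enriched_pathway_ids: set[str] = field(default_factory=set)
    planted_seed_assignments: dict[str, list[str]] = field(default_factory=dict)
    planted_connectors: set[str] = field(default_factory=set)
    planted_terminals: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "enriched_pathway_ids": sorted(self.enriched_pathway_ids),
            "planted_seed_assignments": {k: sorted(v) for k, v in
                                         sorted(self.planted_seed_assignments.items())},
            "planted_connectors": sorted(self.planted_connectors),
            "planted_terminals": sorted(self.planted_terminals),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _symbol(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(config: SyntheticConfig) -> tuple[Interactome, GroundTruth]:
    """Connected preferential-attachment graph over synthetic gene symbols.

    Optionally plants a Steiner instance: ``connector_planting`` attaches
    ``n_leaves`` fresh terminal genes as leaves of a designated hub, making
    the hub the unique optimal connector for those terminals.
    """
    config.validate()
    rng = config.rng("interactome")
    g = nx.barabasi_albert_graph(config.n_genes, config.attachment_edges,
                                 seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: _symbol(i) for i in g.nodes})
    truth = GroundTruth()
    if config.connector_planting:
        hub = config.connector_planting["hub"].upper()
        n_leaves = int(config.connector_planting["n_leaves"])
        anchor = _symbol(0)  # keep the plant connected to the main graph
        g.add_edge(hub, anchor)
        leaves = [f"T{i:03d}" for i in range(n_leaves)]
        for leaf in leaves:
            g.add_edge(hub, leaf)
        truth.planted_connectors = {hub}
        truth.planted_terminals = set(leaves)
    return Interactome(graph=g), truth


def generate_annotations(
    config: SyntheticConfig, interactome: Interactome
) -> tuple[GeneSetCollection, GroundTruth]:
    """Draw ``n_pathways`` gene sets over the interactome's genes.

    The first ``n_enriched_pathways`` sets are the designated enriched ones;
    when ``crosstalk_overlap`` is set they all share that many core genes,
    guaranteeing pairwise cross-talk edges at any ``min_shared`` up to the
    core size.
    """
    config.validate()
    rng = config.rng("annotations")
    genes = sorted(interactome.nodes)
    lo, hi = config.pathway_size_range
    truth = GroundTruth()
    sets: list[GeneSet] = []
    core: list[str] = []
    if config.crosstalk_overlap:
        core = list(rng.choice(genes, size=config.crosstalk_overlap, replace=False))
    for i in range(config.n_pathways):
        pid = f"PW{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(genes, size=size, replace=False))
        if i < config.n_enriched_pathways:
            truth.enriched_pathway_ids.add(pid)
            if core:
                members |= set(core)
        sets.append(GeneSet(set_id=pid, name=f"synthetic pathway {i}",
                            members=frozenset(members)))
    return GeneSetCollection(source_label="synthetic", sets=sets), truth


def generate_seed_list(
    config: SyntheticConfig,
    annotations: GeneSetCollection,
    ground_truth: GroundTruth,
) -> SeedList:
    """Seed list = planted fraction of each enriched pathway + background.

    For every designated enriched pathway, ``enrichment_fraction`` of its
    members (rounded, at least one) join the seed list; the remainder up to
    ``n_seed_genes`` is drawn uniformly from unused genes.  The per-pathway
    assignments are recorded in ``ground_truth``.
    """
    config.validate()
    if not len(annotations):
        raise ValueError("annotations are empty")
    rng = config.rng("seeds")
    seeds: set[str] = set()
    for s in annotations:
        if s.set_id not in ground_truth.enriched_pathway_ids:
            continue
        members = sorted(s.members)
        n_pick = max(1, round(config.enrichment_fraction * len(members)))
        picked = list(rng.choice(members, size=n_pick, replace=False))
        ground_truth.planted_seed_assignments[s.set_id] = picked
        seeds |= set(picked)
    pool = sorted(annotations.all_genes - seeds)
    n_background = config.n_seed_genes - len(seeds)
    if n_background < 0:
        raise ValueError("planted seeds already exceed n_seed_genes; "
                         "raise n_seed_genes or lower enrichment_fraction")
    if n_background > len(pool):
        raise ValueError("not enough genes to fill the seed list")
    seeds |= set(rng.choice(pool, size=n_background, replace=False))
    return SeedList(label=f"synthetic-seeds-{config.rng_seed}",
                    genes=frozenset(seeds))


def simulate_study(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write all inputs plus the ground-truth JSON.

    Emits ``interactome.tsv``, ``annotations.gmt``, ``seeds.tsv`` and
    ``ground_truth.json``; byte-identical for a fixed ``rng_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth_net = generate_interactome(config)
    annotations, truth = generate_annotations(config, net)
    truth.planted_connectors = truth_net.planted_connectors
    truth.planted_terminals = truth_net.planted_terminals
    seeds = generate_seed_list(config, annotations, truth)
    paths = {
        "interactome": write_interactions(net, out / "interactome.tsv"),
        "annotations": write_gmt(annotations, out / "annotations.gmt"),
        "seeds": write_seed_list(seeds, out / "seeds.tsv"),
        "ground_truth": truth.to_json(out / "ground_truth.json"),
    }
    return paths
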