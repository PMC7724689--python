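"""End-to-end orchestration: candidate screen -> target sets -> overlap ->
PPI topology -> enrichment, with every artifact written to disk and a
stage-count log whose entries equal the corresponding artifact sizes."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from netpharm import chem, enrichment, ppi_network, target_sets
from netpharm.chem import BatmanThresholds, Candidate, TcmspThresholds
from netpharm.target_sets import GeneSet

__all__ = ["PipelineConfig", "Report", "load_config", "run_pipeline", "build_itd_network"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; defaults are the published thresholds."""

    ingredient_tables: list[dict] = field(default_factory=list)  # {path, dialect}
    target_map: str | None = None
    name_mapping: str | None = None
    disease_a: str | None = None
    disease_b: str | None = None
    ppi_edges: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # namespace -> GMT path
    out_dir: str = "results"

    ob: float = 30.0
    caco2: float = 0.4
    dl: float = 0.18
    score: float = 20.0
    adj_p: float = 0.05
    ppi_score: float = 0.4
    drop_isolated: bool = False
    fdr_cutoff: float = 0.05
    top_n_pathways: int = 25
    top_n_go: int = 10
    disease_label: str = "disease"
    seed: int = 0
    base_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 <= self.ob <= 100.0:
            raise ValueError("ob threshold outside [0, 100]")
        for name in ("adj_p", "ppi_score", "fdr_cutoff"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.top_n_pathways < 1 or self.top_n_go < 1:
            raise ValueError("top_n values must be >= 1")

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.base_dir = str(Path(path).parent)
    return cfg


@dataclass
class Report:
    candidates: list[Candidate]
    drug_targets: GeneSet
    disease_targets: GeneSet
    overlap: GeneSet
    venn: target_sets.VennSummary
    network_summary: ppi_network.NetworkSummary | None
    topology: list[ppi_network.TopologyRow]
    enrichment: dict[str, list[enrichment.EnrichmentRow]]
    tripartite: pd.DataFrame
    counts: dict[str, object]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def build_itd_network(
    candidates: Sequence[Candidate],
    ingredient_targets: dict[str, GeneSet],
    overlap: GeneSet,
    disease_label: str = "disease",
) -> pd.DataFrame:
    """Typed tripartite edge list: herb->ingredient, ingredient->target,
    and target->disease for overlap members only.  The ``is_overlap``
    column marks target nodes shared with the disease set."""
    overlap_set = set(overlap.genes)
    rows: list[dict] = []
    for cand in candidates:
        for herb in cand.herbs:
            rows.append(
                {"source": herb, "target": cand.name, "edge_type": "herb-ingredient", "is_overlap": False}
            )
    for ing_name, gs in ingredient_targets.items():
        for g in gs.genes:
            rows.append(
                {"source": ing_name, "target": g, "edge_type": "ingredient-target", "is_overlap": g in overlap_set}
            )
    for g in overlap.genes:
        rows.append({"source": g, "target": disease_label, "edge_type": "target-disease", "is_overlap": True})
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "is_overlap"])


@_stage("candidate screen")
def _run_chem(cfg: PipelineConfig) -> tuple[list[list[chem.Ingredient]], list[Candidate], int]:
    tables = []
    total = 0
    for entry in cfg.ingredient_tables:
        rows = chem.read_ingredient_tsv(cfg.resolve(entry["path"]), entry["dialect"])
        total += len(rows)
        tables.append(rows)
    cands = chem.select_candidates(
        tables,
        tcmsp=TcmspThresholds(cfg.ob, cfg.caco2, cfg.dl),
        batman=BatmanThresholds(cfg.score, cfg.adj_p),
    )
    return tables, cands, total


@_stage("target exploration")
def _run_targets(
    cfg: PipelineConfig, candidates: Sequence[Candidate]
) -> tuple[dict[str, GeneSet], GeneSet, int, dict[str, int]]:
    df = pd.read_csv(cfg.resolve(cfg.target_map), sep="\t")
    for col in ("herb", "ingredient", "target"):
        if col not in df.columns:
            raise ValueError(f"target map missing column {col!r}")
    cand_keys = {chem.normalize_name(c.name) for c in candidates}
    kept = df[df["ingredient"].map(lambda n: chem.normalize_name(str(n)) in cand_keys)]
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("dropped %d target-map rows for non-candidate ingredients", dropped)

    mapping = None
    if cfg.name_mapping:
        mapping = target_sets.read_mapping_tsv(cfg.resolve(cfg.name_mapping))

    per_ingredient: dict[str, GeneSet] = {}
    per_herb: dict[str, set[str]] = {}
    for (herb, ing), grp in kept.groupby(["herb", "ingredient"], sort=False):
        raw = list(grp["target"])
        if mapping is not None:
            gs, unmapped = target_sets.normalize_genes(raw, mapping, label=str(ing))
            if unmapped:
                logger.info("ingredient %s: %d unmapped raw target name(s)", ing, len(unmapped))
        else:
            gs = GeneSet(label=str(ing), genes=[str(r) for r in raw])
        if str(ing) in per_ingredient:
            for g in gs.genes:
                per_ingredient[str(ing)].add(g, [str(herb)])
        else:
            per_ingredient[str(ing)] = gs
        per_herb.setdefault(str(herb), set()).update(gs.genes)

    union = target_sets.union_targets(list(per_ingredient.values()), label="drug_targets")
    raw_total = sum(len(v) for v in per_herb.values())
    return per_ingredient, union, raw_total, {h: len(v) for h, v in per_herb.items()}


@_stage("disease integration")
def _run_disease(cfg: PipelineConfig) -> tuple[GeneSet, GeneSet, GeneSet]:
    set_a = target_sets.read_gene_list(cfg.resolve(cfg.disease_a), label="source_a")
    set_b = target_sets.read_gene_list(cfg.resolve(cfg.disease_b), label="source_b")
    disease = target_sets.integrate_disease_targets(set_a, set_b, label=cfg.disease_label)
    return set_a, set_b, disease


@_stage("venn")
def _run_venn(drug: GeneSet, disease: GeneSet):
    return target_sets.venn(drug, disease)


@_stage("ppi network")
def _run_ppi(cfg: PipelineConfig, overlap: GeneSet):
    edges = ppi_network.read_edge_table(cfg.resolve(cfg.ppi_edges))
    graph = ppi_network.build_graph(
        edges, score_threshold=cfg.ppi_score, drop_isolated=cfg.drop_isolated, node_universe=overlap
    )
    summary = ppi_network.summarize(graph) if graph.number_of_nodes() else None
    rows = ppi_network.rank_hubs(ppi_network.topology(graph))
    return graph, summary, rows


@_stage("enrichment")
def _run_enrichment(cfg: PipelineConfig, overlap: GeneSet):
    results: dict[str, list[enrichment.EnrichmentRow]] = {}
    for ns, path in cfg.annotations.items():
        table = enrichment.read_gmt(cfg.resolve(path), namespace=ns)
        rows, excluded = enrichment.enrich(overlap, table, fdr_cutoff=cfg.fdr_cutoff)
        if excluded:
            logger.info("%s: %d query gene(s) outside annotation universe", ns, len(excluded))
        results[ns] = rows
    return results


def run_pipeline(cfg: PipelineConfig) -> Report:
    """Execute every configured stage in order and write all artifacts.

    Deterministic: identical inputs and config produce byte-identical
    artifacts.  Any stage error aborts with the stage name attached.
    """
    out = Path(cfg.out_dir)
    if not out.is_absolute():
        out = Path(cfg.base_dir) / out
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    tables, candidates, n_rows = _run_chem(cfg)
    counts["n_ingredients_total"] = n_rows
    counts["n_ingredients_per_herb"] = [len(t) for t in tables]
    counts["n_candidates"] = len(candidates)
    cand_df = pd.DataFrame(
        {
            "name": [c.name for c in candidates],
            "herbs": [";".join(c.herbs) for c in candidates],
            "compound_id": [c.compound_id for c in candidates],
            "formula": [c.formula or "" for c in candidates],
        }
    )
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)

    per_ingredient, drug_targets, raw_total, per_herb_counts = _run_targets(cfg, candidates)
    counts["n_raw_targets_total"] = raw_total
    counts["n_raw_targets_per_herb"] = per_herb_counts
    counts["n_drug_targets"] = len(drug_targets)
    target_sets.write_gene_set_tsv(out / "drug_targets.tsv", drug_targets)

    set_a, set_b, disease = _run_disease(cfg)
    counts["n_disease_source_a"] = len(set_a)
    counts["n_disease_source_b"] = len(set_b)
    counts["n_disease_targets"] = len(disease)
    target_sets.write_gene_set_tsv(out / "disease_targets.tsv", disease)

    summary, overlap = _run_venn(drug_targets, disease)
    counts["n_overlap"] = summary.size_intersection
    counts["pct_of_disease"] = summary.pct_of_b
    target_sets.write_gene_set_tsv(out / "overlap_targets.tsv", overlap)
    with open(out / "venn.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(summary), fh, indent=2)
        fh.write("\n")

    graph = None
    net_summary = None
    topo_rows: list[ppi_network.TopologyRow] = []
    if cfg.ppi_edges:
        graph, net_summary, topo_rows = _run_ppi(cfg, overlap)
        counts["ppi_n_nodes"] = graph.number_of_nodes()
        counts["ppi_n_edges"] = graph.number_of_edges()
        ppi_network.write_topology_tsv(out / "topology.tsv", topo_rows)
        ppi_network.export_graph(graph, out / "network.sif", "SIF")
        ppi_network.export_graph(graph, out / "network.graphml", "GraphML")
        ppi_network.export_graph(graph, out / "network_edges.tsv", "TSV")
        if net_summary is not None:
            with open(out / "network_summary.json", "w", encoding="utf-8") as fh:
                json.dump(dataclasses.asdict(net_summary), fh, indent=2)
                fh.write("\n")

    enr: dict[str, list[enrichment.EnrichmentRow]] = {}
    if cfg.annotations:
        enr = _run_enrichment(cfg, overlap)
        for ns, rows in enr.items():
            counts[f"n_terms_tested_{ns}"] = len(rows)
            counts[f"n_significant_{ns}"] = sum(r.fdr < cfg.fdr_cutoff for r in rows)
            enrichment.write_enrichment_tsv(out / f"enrichment_{ns}.tsv", rows)
            top_n = cfg.top_n_pathways if ns == "PATHWAY" else cfg.top_n_go
            top = enrichment.top_terms(rows, top_n)
            enrichment.bubble_data(top).to_csv(out / f"bubble_{ns}.tsv", sep="\t", index=False)
            enrichment.chord_data(rows, top).to_csv(out / f"chord_{ns}.tsv", sep="\t")

    tripartite = build_itd_network(candidates, per_ingredient, overlap, cfg.disease_label)
    counts["n_target_disease_edges"] = int((tripartite["edge_type"] == "target-disease").sum())
    tripartite.to_csv(out / "tripartite_network.tsv", sep="\t", index=False)

    counts["seed"] = cfg.seed
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", counts)

    return Report(
        candidates=candidates,
        drug_targets=drug_targets,
        disease_targets=disease,
        overlap=overlap,
        venn=summary,
        network_summary=net_summary,
        topology=topo_rows,
        enrichment=enr,
        tripartite=tripartite,
        counts=counts,
    )
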