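"""Database-free input generators with planted, exactly-recoverable truth.

Every generator allocates memberships constructively first (so planted
counts are exact, not approximate) and randomizes identities and field
values second; regeneration from (seed, params) is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from netpharm.chem import (
    BatmanThresholds,
    Ingredient,
    TcmspThresholds,
    write_ingredient_tsv,
)
from netpharm.enrichment import AnnotationTable, write_gmt
from netpharm.target_sets import GeneSet, write_gene_list

__all__ = [
    "HerbSpec",
    "SyntheticTruth",
    "DEFAULT_HERBS",
    "gen_ingredients",
    "gen_target_maps",
    "gen_name_mapping",
    "gen_disease_lists",
    "gen_ppi",
    "gen_annotations",
    "gen_bundle",
]


@dataclass(frozen=True)
class HerbSpec:
    """One herb's table shape: row count, planted pass count, source dialect."""

    latin: str
    pinyin: str
    source: Literal["TCMSP", "BATMAN"]
    n_rows: int
    n_pass: int

    def __post_init__(self) -> None:
        if self.n_pass > self.n_rows:
            raise ValueError(f"{self.latin}: n_pass {self.n_pass} exceeds n_rows {self.n_rows}")


# The published study's table shapes: 47 + 17 + 10 rows, 3 + 2 + 5 passers.
DEFAULT_HERBS = (
    HerbSpec("Radix Scrophulariae", "XuanShen", "TCMSP", 47, 3),
    HerbSpec("Bulbus Fritillariae Ferganensis", "ZheBeiMu", "TCMSP", 17, 2),
    HerbSpec("Concha Ostreae", "ShengMuLi", "BATMAN", 10, 5),
)


@dataclass
class SyntheticTruth:
    """Planted parameters a generated dataset must let the pipeline recover."""

    seed: int
    planted_pass_names: dict[str, list[str]] = field(default_factory=dict)
    planted_duplicate_structure: dict[str, str] = field(default_factory=dict)
    planted_per_herb_targets: dict[str, int] = field(default_factory=dict)
    planted_target_union: int = 0
    planted_venn: dict[str, int] = field(default_factory=dict)
    planted_graph: dict[str, object] = field(default_factory=dict)
    planted_terms: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _draw_tcmsp_fields(rng: np.random.Generator, passing: bool, t: TcmspThresholds):
    if passing:
        return (
            rng.uniform(t.ob, 100.0),
            rng.uniform(t.caco2, 2.0),
            rng.uniform(t.dl, 1.0),
        )
    ob = rng.uniform(0.0, 100.0)
    caco2 = rng.uniform(-1.0, 2.0)
    dl = rng.uniform(0.0, 1.0)
    # force at least one criterion into its (strictly) failing region
    which = rng.integers(0, 3)
    if which == 0:
        ob = rng.uniform(0.0, t.ob * 0.999)
    elif which == 1:
        caco2 = rng.uniform(-1.0, t.caco2 * 0.999)
    else:
        dl = rng.uniform(0.0, t.dl * 0.999)
    return ob, caco2, dl


def _draw_batman_fields(rng: np.random.Generator, passing: bool, t: BatmanThresholds):
    if passing:
        return rng.uniform(t.score, 60.0), rng.uniform(0.0, t.adj_p * 0.999)
    score = rng.uniform(0.0, 60.0)
    adj_p = rng.uniform(0.0, 0.2)
    if rng.integers(0, 2) == 0:
        score = rng.uniform(0.0, t.score * 0.999)
    else:
        adj_p = rng.uniform(t.adj_p, 0.2)
    return score, adj_p


def gen_ingredients(
    herbs: Sequence[HerbSpec] = DEFAULT_HERBS,
    seed: int = 0,
    cross_herb_duplicates: Sequence[tuple[int, int]] = ((0, 1),),
    tcmsp: TcmspThresholds = TcmspThresholds(),
    batman: BatmanThresholds = BatmanThresholds(),
) -> tuple[dict[str, list[Ingredient]], SyntheticTruth]:
    """Per-herb ingredient tables with planted pass/fail structure.

    Each (i, j) in `cross_herb_duplicates` plants one shared passing
    compound name in herbs i and j (both herbs must have a passer to
    spare and the same source dialect is not required).  Failing rows
    are guaranteed to miss at least one criterion; passing rows are
    drawn from the passing region of every criterion.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    shared_names: dict[int, list[str]] = {i: [] for i in range(len(herbs))}
    for d_idx, (i, j) in enumerate(cross_herb_duplicates):
        if not (0 <= i < len(herbs) and 0 <= j < len(herbs) and i != j):
            raise ValueError(f"bad duplicate pair ({i}, {j})")
        name = f"SharedCompound-{d_idx + 1}"
        shared_names[i].append(name)
        shared_names[j].append(name)
    for idx, spec in enumerate(herbs):
        if len(shared_names[idx]) > spec.n_pass:
            raise ValueError(f"{spec.latin}: more planted duplicates than passers")

    tables: dict[str, list[Ingredient]] = {}
    for idx, spec in enumerate(herbs):
        rows: list[Ingredient] = []
        pass_names = list(shared_names[idx])
        n_own_pass = spec.n_pass - len(pass_names)
        pass_names += [f"{spec.pinyin}-pass-{j + 1}" for j in range(n_own_pass)]
        fail_names = [f"{spec.pinyin}-ing-{j + 1}" for j in range(spec.n_rows - spec.n_pass)]
        statuses = [(nm, True) for nm in pass_names] + [(nm, False) for nm in fail_names]
        perm = rng.permutation(len(statuses))
        for row_i, s_idx in enumerate(perm):
            nm, passing = statuses[s_idx]
            common = dict(
                herb_latin=spec.latin,
                herb_pinyin=spec.pinyin,
                name=nm,
                compound_id=f"SYN{idx}{row_i:04d}",
                formula=None,
                source_rule=spec.source,
            )
            if spec.source == "TCMSP":
                ob, caco2, dl = _draw_tcmsp_fields(rng, passing, tcmsp)
                rows.append(Ingredient(**common, ob=ob, caco2=caco2, dl=dl))
            else:
                score, adj_p = _draw_batman_fields(rng, passing, batman)
                rows.append(Ingredient(**common, score=score, adj_p=adj_p))
        tables[spec.latin] = rows
        truth.planted_pass_names[spec.latin] = sorted(pass_names)
    return tables, truth


def _symbol_pool(size: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(size)))
    return [f"{prefix}{i:0{width}d}" for i in range(size)]


def gen_target_maps(
    candidates_per_herb: dict[str, list[str]],
    per_herb_target_counts: dict[str, int],
    union_size: int,
    universe_size: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ingredient->target map with exact per-herb set sizes and union size.

    Coverage-first allocation: every union gene is assigned to the herb
    with the most remaining capacity, then leftover capacity is filled
    with already-covered genes, so both the per-herb counts and the
    union collapse are exact by construction.  Each herb's targets are
    distributed round-robin over its candidate ingredients.
    """
    herbs = list(candidates_per_herb)
    counts = [per_herb_target_counts[h] for h in herbs]
    if union_size > sum(counts):
        raise ValueError("union_size exceeds the sum of per-herb counts")
    if union_size < max(counts):
        raise ValueError("union_size below the largest per-herb count")
    if union_size > universe_size:
        raise ValueError("union_size exceeds universe_size")
    for h in herbs:
        if not candidates_per_herb[h]:
            raise ValueError(f"herb {h!r} has no candidate ingredients")

    rng = np.random.default_rng(seed)
    pool = _symbol_pool(universe_size)
    union_genes = [pool[i] for i in rng.permutation(universe_size)[:union_size]]

    remaining = dict(zip(herbs, counts))
    herb_sets: dict[str, list[str]] = {h: [] for h in herbs}
    for g in union_genes:
        h = max(herbs, key=lambda x: remaining[x])
        herb_sets[h].append(g)
        remaining[h] -= 1
    for h in herbs:
        if remaining[h]:
            others = [g for g in union_genes if g not in set(herb_sets[h])]
            picks = rng.permutation(len(others))[: remaining[h]]
            herb_sets[h].extend(others[i] for i in picks)
        assert len(herb_sets[h]) == per_herb_target_counts[h]

    records = []
    for h in herbs:
        ings = candidates_per_herb[h]
        for i, g in enumerate(herb_sets[h]):
            records.append({"herb": h, "ingredient": ings[i % len(ings)], "target": g})
    table = pd.DataFrame.from_records(records, columns=["herb", "ingredient", "target"])

    truth = SyntheticTruth(seed=seed)
    truth.planted_per_herb_targets = dict(per_herb_target_counts)
    truth.planted_target_union = union_size
    return table, truth


def gen_name_mapping(
    symbols: Sequence[str], n_raw: int, seed: int = 0
) -> tuple[list[str], dict[str, str]]:
    """Raw protein-style names collapsing onto `symbols` under mapping.

    Returns `n_raw` raw names (>= one per symbol; extras are planted
    duplicates of random symbols) plus the raw->symbol mapping table.
    """
    if n_raw < len(symbols):
        raise ValueError("n_raw must be at least the number of symbols")
    rng = np.random.default_rng(seed)
    raw_names: list[str] = []
    mapping: dict[str, str] = {}
    for i, sym in enumerate(symbols):
        raw = f"protein name {i} of {sym}"
        raw_names.append(raw)
        mapping[raw] = sym
    extra_targets = rng.integers(0, len(symbols), size=n_raw - len(symbols))
    for j, t in enumerate(extra_targets):
        raw = f"synonym {j} of {symbols[t]}"
        raw_names.append(raw)
        mapping[raw] = symbols[t]
    order = rng.permutation(len(raw_names))
    return [raw_names[i] for i in order], mapping


def gen_disease_lists(
    drug_set: Sequence[str],
    size_a: int = 245,
    size_b: int = 93,
    ab_overlap: int = 17,
    drug_overlap: int = 29,
    universe_size: int = 1000,
    seed: int = 0,
) -> tuple[GeneSet, GeneSet, SyntheticTruth]:
    """Two disease-target source lists with exact planted Venn structure.

    |A| = size_a, |B| = size_b, |A ∩ B| = ab_overlap, and exactly
    `drug_overlap` members of the A∪B union drawn from `drug_set`.
    """
    drug = list(dict.fromkeys(drug_set))
    union_size = size_a + size_b - ab_overlap
    if not 0 <= ab_overlap <= min(size_a, size_b):
        raise ValueError("ab_overlap out of range")
    if drug_overlap > min(len(drug), union_size):
        raise ValueError("drug_overlap exceeds drug set or disease union size")
    n_fresh = union_size - drug_overlap
    rng = np.random.default_rng(seed)
    from_drug = [drug[i] for i in rng.permutation(len(drug))[:drug_overlap]]
    fresh_pool = [s for s in _symbol_pool(universe_size, prefix="D") if s not in set(drug)]
    if n_fresh > len(fresh_pool):
        raise ValueError("universe_size too small for the requested disease union")
    fresh = [fresh_pool[i] for i in rng.permutation(len(fresh_pool))[:n_fresh]]
    union = from_drug + fresh
    union = [union[i] for i in rng.permutation(len(union))]

    both = union[:ab_overlap]
    only_a = union[ab_overlap:size_a]
    only_b = union[size_a:]
    set_a = GeneSet(label="disease_source_a", genes=both + only_a)
    set_b = GeneSet(label="disease_source_b", genes=both + only_b)

    truth = SyntheticTruth(seed=seed)
    truth.planted_venn = {
        "size_a": size_a,
        "size_b": size_b,
        "ab_overlap": ab_overlap,
        "disease_union": union_size,
        "drug_overlap": drug_overlap,
    }
    return set_a, set_b, truth


def gen_ppi(
    node_set: Sequence[str],
    model: Literal["gnm", "planted_module"] = "gnm",
    n_edges: int = 86,
    module_nodes: Sequence[str] | None = None,
    score_range: tuple[float, float] = (0.15, 0.999),
    score_threshold: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Scored random interaction table over `node_set`.

    ``gnm`` draws exactly `n_edges` distinct non-self pairs; scores are
    uniform in `score_range`.  ``planted_module`` additionally wires
    `module_nodes` into a clique whose scores always clear
    `score_threshold`.  Truth records the edge count and the nodes left
    connected after thresholding at `score_threshold`.
    """
    nodes = list(dict.fromkeys(node_set))
    n = len(nodes)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng = np.random.default_rng(seed)

    edges: dict[tuple[int, int], float] = {}
    if model == "planted_module":
        module = module_nodes if module_nodes is not None else nodes[: min(5, n)]
        midx = [nodes.index(v) for v in module]
        for a_pos in range(len(midx)):
            for b_pos in range(a_pos + 1, len(midx)):
                i, j = sorted((midx[a_pos], midx[b_pos]))
                edges[(i, j)] = float(rng.uniform(max(score_threshold, score_range[0]), score_range[1]))
    elif model != "gnm":
        raise ValueError(f"unknown model {model!r}")

    free = [p for p in pairs if p not in edges]
    n_random = n_edges if model == "gnm" else max(0, n_edges - len(edges))
    if n_random > len(free):
        raise ValueError(f"cannot place {n_random} edges among {len(free)} free pairs")
    chosen = rng.choice(len(free), size=n_random, replace=False) if n_random else []
    for c in chosen:
        edges[free[int(c)]] = float(rng.uniform(*score_range))

    records = [
        {"node1": nodes[i], "node2": nodes[j], "combined_score": s}
        for (i, j), s in sorted(edges.items())
    ]
    table = pd.DataFrame.from_records(records, columns=["node1", "node2", "combined_score"])

    connected = sorted(
        {r["node1"] for r in records if r["combined_score"] >= score_threshold}
        | {r["node2"] for r in records if r["combined_score"] >= score_threshold}
    )
    truth = SyntheticTruth(seed=seed)
    truth.planted_graph = {
        "n_nodes": n,
        "n_edges": len(edges),
        "score_threshold": score_threshold,
        "connected_nodes": connected,
        "module_nodes": sorted(module) if model == "planted_module" else [],
    }
    return table, truth


def gen_annotations(
    universe: Sequence[str],
    query: Sequence[str],
    namespace: str = "PATHWAY",
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 40),
    n_planted: int = 0,
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Annotation table with decoy terms and optionally planted signal.

    Decoy terms sample members uniformly from the universe; planted
    terms oversample query genes with probability weight
    `enrichment_factor` relative to non-query genes.  Factor 1 plants
    nothing (a null table).
    """
    uni = list(dict.fromkeys(universe))
    qset = [g for g in dict.fromkeys(query) if g in set(uni)]
    if n_planted > n_terms:
        raise ValueError("n_planted exceeds n_terms")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(uni):
        raise ValueError("bad term_size_range for this universe")
    rng = np.random.default_rng(seed)
    weights = np.array([enrichment_factor if g in set(qset) else 1.0 for g in uni])
    p = weights / weights.sum()

    effective_planted = 0 if enrichment_factor == 1.0 else n_planted
    terms: dict[str, list[str]] = {}
    truth = SyntheticTruth(seed=seed)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        planted = t < effective_planted
        if planted:
            idx = rng.choice(len(uni), size=size, replace=False, p=p)
            name = f"planted_term_{t + 1}"
            expected = size * (enrichment_factor * len(qset)) / (
                enrichment_factor * len(qset) + (len(uni) - len(qset))
            )
            truth.planted_terms[name] = {
                "enrichment_factor": enrichment_factor,
                "expected_overlap": expected,
            }
        else:
            idx = rng.choice(len(uni), size=size, replace=False)
            name = f"decoy_term_{t + 1}"
        terms[name] = [uni[int(i)] for i in idx]
    return AnnotationTable(namespace=namespace, terms=terms), truth


def gen_bundle(
    out_dir: str | Path,
    seed: int = 0,
    herbs: Sequence[HerbSpec] = DEFAULT_HERBS,
    cross_herb_duplicates: Sequence[tuple[int, int]] = ((0, 1),),
    per_herb_target_counts: Sequence[int] = (58, 46, 27),
    target_union: int = 71,
    disease_sizes: tuple[int, int, int] = (245, 93, 17),
    drug_overlap: int = 29,
    ppi_edges: int = 86,
    enrichment_factor: float = 6.0,
) -> tuple[Path, SyntheticTruth]:
    """Write a complete input bundle shaped like the published study.

    Emits per-herb ingredient TSVs, the ingredient->target map, the two
    disease source lists, a STRING-style interactions TSV over the
    planted drug∩disease overlap, GMT annotation files for all four
    namespaces, a ready-to-run pipeline config, and ``truth.json``.
    """
    from netpharm.chem import normalize_name, select_candidates

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = np.random.default_rng(seed)
    subseeds = [int(s) for s in rng_master.integers(0, 2**31 - 1, size=6)]

    tables, ing_truth = gen_ingredients(
        herbs, seed=subseeds[0], cross_herb_duplicates=cross_herb_duplicates
    )
    paths: dict[str, object] = {"ingredient_tables": []}
    for spec in herbs:
        fname = f"ingredients_{spec.pinyin.lower()}.tsv"
        write_ingredient_tsv(out / fname, tables[spec.latin], spec.source)
        paths["ingredient_tables"].append({"path": fname, "dialect": spec.source})

    candidates = select_candidates(list(tables.values()))
    cand_per_herb: dict[str, list[str]] = {}
    for spec in herbs:
        keys = {normalize_name(n) for n in ing_truth.planted_pass_names[spec.latin]}
        cand_per_herb[spec.latin] = sorted(
            {c.name for c in candidates if normalize_name(c.name) in keys}
        )

    counts = {spec.latin: per_herb_target_counts[i] for i, spec in enumerate(herbs)}
    target_map, map_truth = gen_target_maps(
        cand_per_herb, counts, union_size=target_union, seed=subseeds[1]
    )
    target_map.to_csv(out / "ingredient_targets.tsv", sep="\t", index=False)
    paths["target_map"] = "ingredient_targets.tsv"

    drug_genes = list(dict.fromkeys(target_map["target"]))
    size_a, size_b, ab_overlap = disease_sizes
    set_a, set_b, dis_truth = gen_disease_lists(
        drug_genes, size_a, size_b, ab_overlap, drug_overlap, seed=subseeds[2]
    )
    write_gene_list(out / "disease_source_a.txt", set_a)
    write_gene_list(out / "disease_source_b.txt", set_b)
    paths["disease_a"] = "disease_source_a.txt"
    paths["disease_b"] = "disease_source_b.txt"

    overlap_genes = sorted(set(drug_genes) & (set(set_a.genes) | set(set_b.genes)))
    ppi_table, ppi_truth = gen_ppi(overlap_genes, n_edges=ppi_edges, seed=subseeds[3])
    ppi_table.to_csv(out / "string_interactions.tsv", sep="\t", index=False)
    paths["ppi_edges"] = "string_interactions.tsv"

    universe = _symbol_pool(400) + overlap_genes
    paths["annotations"] = {}
    planted_truths: dict[str, dict[str, float]] = {}
    for i, ns in enumerate(("GO_CC", "GO_MF", "GO_BP", "PATHWAY")):
        table, ann_truth = gen_annotations(
            universe,
            overlap_genes,
            namespace=ns,
            n_terms=20,
            n_planted=1,
            enrichment_factor=enrichment_factor,
            seed=subseeds[4] + i,
        )
        fname = f"annotations_{ns.lower()}.gmt"
        write_gmt(out / fname, table)
        paths["annotations"][ns] = fname
        for k, v in ann_truth.planted_terms.items():
            planted_truths[f"{ns}:{k}"] = v

    truth = SyntheticTruth(seed=seed)
    truth.planted_pass_names = ing_truth.planted_pass_names
    truth.planted_per_herb_targets = map_truth.planted_per_herb_targets
    truth.planted_target_union = map_truth.planted_target_union
    truth.planted_venn = dis_truth.planted_venn
    truth.planted_graph = ppi_truth.planted_graph
    truth.planted_terms = planted_truths
    truth.to_json(out / "truth.json")

    config = {
        "ingredient_tables": paths["ingredient_tables"],
        "target_map": paths["target_map"],
        "disease_a": paths["disease_a"],
        "disease_b": paths["disease_b"],
        "ppi_edges": paths["ppi_edges"],
        "annotations": paths["annotations"],
        "out_dir": "results",
        "seed": seed,
    }
    import yaml

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out, truth
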