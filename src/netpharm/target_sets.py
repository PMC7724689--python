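"""Gene-set normalization, union, integration and overlap (Venn) analysis."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from netpharm.chem import round_half_up

__all__ = [
    "GeneSet",
    "VennSummary",
    "normalize_genes",
    "union_targets",
    "integrate_disease_targets",
    "venn",
    "read_gene_list",
    "write_gene_list",
    "read_mapping_tsv",
    "write_gene_set_tsv",
]


@dataclass
class GeneSet:
    """A named, provenance-tagged, ordered collection of gene symbols.

    Symbols are upper-cased, whitespace-free and unique; insertion order
    is preserved so downstream artifacts are deterministic.
    """

    label: str
    genes: list[str] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            sym = _clean_symbol(g)
            if sym in seen:
                continue
            seen.add(sym)
            cleaned.append(sym)
        self.genes = cleaned
        prov = {}
        for g, tags in self.provenance.items():
            prov[_clean_symbol(g)] = list(tags)
        self.provenance = {g: prov.get(g, [self.label]) for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return _clean_symbol(symbol) in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def add(self, symbol: str, tags: Iterable[str]) -> None:
        sym = _clean_symbol(symbol)
        if sym not in self.provenance:
            self.genes.append(sym)
            self.provenance[sym] = []
        for t in tags:
            if t not in self.provenance[sym]:
                self.provenance[sym].append(t)


def _clean_symbol(raw: str) -> str:
    sym = "".join(raw.split()).upper()
    if not sym:
        raise ValueError("empty gene symbol")
    return sym


def normalize_genes(
    raw_names: Sequence[str],
    mapping: Mapping[str, str],
    label: str = "normalized",
) -> tuple[GeneSet, list[str]]:
    """Map raw protein/gene names to official symbols and deduplicate.

    Mapping keys are matched case-insensitively on the whitespace-
    stripped raw name.  Unmapped names are returned separately, never
    silently dropped into the set.  Duplicate raw names collapsing to
    one symbol merge their provenance.
    """
    folded = {k.strip().casefold(): v for k, v in mapping.items()}
    out = GeneSet(label=label)
    unmapped: list[str] = []
    for raw in raw_names:
        key = raw.strip().casefold()
        if key in folded:
            out.add(folded[key], [raw.strip()])
        else:
            unmapped.append(raw)
    return out, unmapped


def union_targets(per_ingredient_sets: Sequence[GeneSet], label: str = "union") -> GeneSet:
    """Set union with per-contributor provenance, first-seen ordering."""
    out = GeneSet(label=label)
    for gs in per_ingredient_sets:
        for g in gs.genes:
            out.add(g, [gs.label])
    return out


def integrate_disease_targets(source_a: GeneSet, source_b: GeneSet, label: str = "disease") -> GeneSet:
    """Union of two disease-target sources; shared genes carry both tags."""
    return union_targets([source_a, source_b], label=label)


@dataclass(frozen=True)
class VennSummary:
    size_a: int
    size_b: int
    size_intersection: int
    size_union: int
    pct_of_b: float

    def __post_init__(self) -> None:
        if self.size_union != self.size_a + self.size_b - self.size_intersection:
            raise ValueError("inclusion-exclusion identity violated")
        if not 0 <= self.size_intersection <= min(self.size_a, self.size_b):
            raise ValueError("intersection size out of range")


def venn(drug_targets: GeneSet, disease_targets: GeneSet) -> tuple[VennSummary, GeneSet]:
    """Overlap analysis of a query set against a reference set.

    `pct_of_b` is 100 x |intersection| / |disease set|, rounded half-up
    to 2 decimals for reporting.
    """
    if len(disease_targets) == 0:
        raise ValueError("empty disease target set: overlap percentage undefined")
    b_members = set(disease_targets.genes)
    overlap = GeneSet(label=f"{drug_targets.label}∩{disease_targets.label}")
    for g in drug_targets.genes:
        if g in b_members:
            tags = drug_targets.provenance.get(g, []) + disease_targets.provenance.get(g, [])
            overlap.add(g, tags)
    n_int = len(overlap)
    summary = VennSummary(
        size_a=len(drug_targets),
        size_b=len(disease_targets),
        size_intersection=n_int,
        size_union=len(drug_targets) + len(disease_targets) - n_int,
        pct_of_b=round_half_up(100.0 * n_int / len(disease_targets), 2),
    )
    return summary, overlap


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """One symbol per line; blank lines and '#' comments ignored."""
    label = label or Path(path).stem
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneSet(label=label, genes=genes)


def write_gene_list(path: str | Path, gs: GeneSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gs.genes:
            fh.write(g + "\n")


def read_mapping_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``raw_name<TAB>symbol`` with header row."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"{path}: expected header 'raw_name<TAB>symbol'")
        for row in reader:
            if len(row) >= 2 and row[0]:
                mapping[row[0]] = row[1]
    return mapping


def write_gene_set_tsv(path: str | Path, gs: GeneSet) -> None:
    """TSV dump with a provenance column (comma-joined source tags)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["symbol", "provenance"])
        for g in gs.genes:
            writer.writerow([g, ",".join(gs.provenance.get(g, []))])
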