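"""Local over-representation analysis: hypergeometric tails, BH FDR,
significance filtering, top-N selection and plot-data exports.

Replaces a web enrichment service with a desk-scale equivalent: flat
annotation terms (GMT files), a configurable background universe, and
per-namespace multiple-testing correction.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from netpharm.target_sets import GeneSet

__all__ = [
    "NAMESPACES",
    "AnnotationTable",
    "EnrichmentRow",
    "hypergeom_p",
    "bh_fdr",
    "enrich",
    "top_terms",
    "bubble_data",
    "chord_data",
    "read_gmt",
    "write_gmt",
    "write_enrichment_tsv",
]

NAMESPACES = ("GO_CC", "GO_MF", "GO_BP", "PATHWAY")


@dataclass
class AnnotationTable:
    """Flat annotation terms for one namespace.

    `universe` is the union of all term gene sets (the default ORA
    background); a wider background may be passed to :func:`enrich`.
    """

    namespace: str
    terms: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}")
        for name, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {name!r} has an empty gene set")
            self.terms[name] = list(dict.fromkeys(genes))

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out.update(genes)
        return out


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result.

    k = overlap count ("Count"), K = term size in universe, n =
    effective query size, N = universe size.
    """

    term: str
    namespace: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError(f"term {self.term!r}: k={self.k} exceeds min(K={self.K}, n={self.n})")
        if self.fdr < self.p_value - 1e-12:
            raise ValueError(f"term {self.term!r}: fdr below raw p")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated (marked) count, n the draw
    (query) size.  Evaluated via the survival function, which works in
    log-space internally, so deep tails keep precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got k={k}, K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    Monotonicity is enforced by the running-minimum sweep from the
    largest p; tied p-values share the adjustment of their best
    (largest) sorted rank, as the step-up procedure implies.
    """
    m = len(p_values)
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def enrich(
    query: GeneSet | Sequence[str],
    annotations: AnnotationTable,
    fdr_cutoff: float = 0.05,
    universe: set[str] | None = None,
    test_all_terms: bool = False,
) -> tuple[list[EnrichmentRow], list[str]]:
    """Hypergeometric ORA of `query` against every term of one namespace.

    The effective query is the intersection with the background
    universe; out-of-universe query genes are returned as the second
    element, excluded from n.  Terms with zero overlap are not tested
    (and do not count toward the BH m) unless `test_all_terms`.  Rows
    come back sorted by fdr asc, then k desc, then term name; use
    `fdr < fdr_cutoff` for the significance call.
    """
    query_genes = list(query)
    bg = set(universe) if universe is not None else annotations.universe
    effective = [g for g in dict.fromkeys(query_genes) if g in bg]
    excluded = [g for g in dict.fromkeys(query_genes) if g not in bg]
    n, N = len(effective), len(bg)
    if n == 0:
        raise ValueError("no query gene lies in the annotation universe")
    eff_set = set(effective)

    tested: list[tuple[str, int, int, tuple[str, ...]]] = []
    for term, genes in annotations.terms.items():
        members = [g for g in genes if g in bg]
        overlap = tuple(g for g in members if g in eff_set)
        if overlap or test_all_terms:
            tested.append((term, len(overlap), len(members), overlap))

    pvals = [hypergeom_p(k, K, n, N) for _, k, K, _ in tested]
    fdrs = bh_fdr(pvals)
    rows = [
        EnrichmentRow(
            term=term,
            namespace=annotations.namespace,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            fdr=f,
            genes=overlap,
        )
        for (term, k, K, overlap), p, f in zip(tested, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.fdr, -r.k, r.term))
    return rows, excluded


def top_terms(rows: Sequence[EnrichmentRow], top_n: int) -> list[EnrichmentRow]:
    """First `top_n` rows per namespace under the enrich ordering."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    out: list[EnrichmentRow] = []
    taken: dict[str, int] = {}
    for r in rows:
        if taken.get(r.namespace, 0) < top_n:
            out.append(r)
            taken[r.namespace] = taken.get(r.namespace, 0) + 1
    return out


def bubble_data(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """(term, count, -log10 fdr) table behind a bubble diagram."""
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "namespace": [r.namespace for r in rows],
            "count": [r.k for r in rows],
            "neg_log10_fdr": [-math.log10(r.fdr) if r.fdr > 0 else math.inf for r in rows],
        }
    )


def chord_data(rows: Sequence[EnrichmentRow], selected: Sequence[EnrichmentRow] | None = None) -> pd.DataFrame:
    """Binary gene x term membership over the overlap genes of selected terms."""
    selected = list(selected if selected is not None else rows)
    genes: list[str] = []
    for r in selected:
        for g in r.genes:
            if g not in genes:
                genes.append(g)
    data = {r.term: [1 if g in r.genes else 0 for g in genes] for r in selected}
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def read_gmt(path: str | Path, namespace: str) -> AnnotationTable:
    """GMT: one term per line — name, description, then member genes."""
    terms: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
                continue
            name, _desc, *genes = parts
            terms[name] = [g for g in genes if g]
    return AnnotationTable(namespace=namespace, terms=terms)


def write_gmt(path: str | Path, table: AnnotationTable, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in table.terms.items():
            desc = descriptions.get(name, table.namespace)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_enrichment_tsv(path: str | Path, rows: Sequence[EnrichmentRow]) -> None:
    """STRING-category-style TSV: term, counts, p, fdr, matching genes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["term", "namespace", "observed_gene_count", "background_gene_count", "p_value", "fdr", "matching_genes"]
        )
        for r in rows:
            writer.writerow([r.term, r.namespace, r.k, r.K, repr(r.p_value), repr(r.fdr), ",".join(r.genes)])
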