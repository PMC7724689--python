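"""Molecular formulas, masses, and pharmacokinetic candidate screening.

Covers formula parsing (Hill-style strings, with ``C_20_H_28_O_2_``
subscript markup accepted), average and monoisotopic mass computation
from an embedded atomic-weight table, the two pharmacokinetic filter
rules (absorption/permeability/drug-likeness thresholds for one source
dialect, score/adjusted-P for the other), and cross-herb candidate
deduplication by normalized ingredient name.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "AtomicWeightTable",
    "DEFAULT_WEIGHTS",
    "FormulaError",
    "Ingredient",
    "TcmspThresholds",
    "BatmanThresholds",
    "Candidate",
    "parse_formula",
    "molecular_mass",
    "round_half_up",
    "passes_filter",
    "select_candidates",
    "normalize_name",
    "read_ingredient_tsv",
]


class FormulaError(ValueError):
    """Raised for empty, garbled, or unknown-element formulas."""


@dataclass(frozen=True)
class AtomicWeightTable:
    """Immutable per-element average weights and monoisotopic masses (Da)."""

    average: Mapping[str, float]
    monoisotopic: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.average) != set(self.monoisotopic):
            raise ValueError("average and monoisotopic tables must cover the same elements")
        for el in self.average:
            avg, mono = self.average[el], self.monoisotopic[el]
            if avg <= 0 or mono <= 0:
                raise ValueError(f"non-positive mass for element {el!r}")
            if mono > avg + 1:
                raise ValueError(f"monoisotopic mass implausibly above average for {el!r}")

    def __contains__(self, element: str) -> bool:
        return element in self.average

    def get(self, element: str, mode: str) -> float:
        table = self.average if mode == "average" else self.monoisotopic
        if element not in table:
            raise FormulaError(f"element {element!r} missing from weight table")
        return table[element]


# CODATA/IUPAC 2005-era standard atomic weights (average) and
# principal-isotope masses (monoisotopic).  Embedded, never fetched.
DEFAULT_WEIGHTS = AtomicWeightTable(
    average={
        "H": 1.00794,
        "C": 12.0107,
        "N": 14.0067,
        "O": 15.9994,
        "F": 18.9984032,
        "Na": 22.98976928,
        "Mg": 24.3050,
        "Al": 26.9815386,
        "Si": 28.0855,
        "P": 30.973762,
        "S": 32.065,
        "Cl": 35.453,
        "K": 39.0983,
        "Ca": 40.078,
        "Mn": 54.938045,
        "Fe": 55.845,
        "Cu": 63.546,
        "Zn": 65.38,
        "Br": 79.904,
        "I": 126.90447,
    },
    monoisotopic={
        "H": 1.0078250319,
        "C": 12.0,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "F": 18.9984032,
        "Na": 22.98976928,
        "Mg": 23.9850417,
        "Al": 26.98153863,
        "Si": 27.9769265325,
        "P": 30.97376163,
        "S": 31.972071,
        "Cl": 34.96885268,
        "K": 38.96370668,
        "Ca": 39.9625909,
        "Mn": 54.9380451,
        "Fe": 55.9349375,
        "Cu": 62.9295975,
        "Zn": 63.9291422,
        "Br": 78.9183371,
        "I": 126.904473,
    },
)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str, weights: AtomicWeightTable = DEFAULT_WEIGHTS) -> dict[str, int]:
    """Parse a Hill-style molecular formula into an element->count mapping.

    Subscript markup of the form ``C_29_H_50_O`` is stripped before
    tokenizing; an element without an explicit count has count 1.

    Raises
    ------
    FormulaError
        If the string is empty, contains anything besides element
        tokens, or names an element not in `weights`.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula string")
    cleaned = formula.strip().replace("_", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"garbled formula {formula!r} at position {pos}")
        symbol, digits = m.groups()
        if symbol not in weights:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"non-positive count for {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round half away from zero at `ndigits` decimals (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def molecular_mass(
    counts: Mapping[str, int],
    mode: Literal["average", "monoisotopic"] = "average",
    weights: AtomicWeightTable = DEFAULT_WEIGHTS,
) -> float:
    """Sum of count x per-element mass in the chosen mode, full precision.

    Use :func:`round_half_up` for the 3-decimal display convention.
    """
    if mode not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass mode {mode!r}")
    if not counts:
        raise FormulaError("empty element counts")
    return sum(n * weights.get(el, mode) for el, n in counts.items())


@dataclass(frozen=True)
class TcmspThresholds:
    ob: float = 30.0
    caco2: float = 0.4
    dl: float = 0.18


@dataclass(frozen=True)
class BatmanThresholds:
    score: float = 20.0
    adj_p: float = 0.05


@dataclass
class Ingredient:
    """One compound row with herb provenance and pharmacokinetic fields.

    Exactly the fields demanded by `source_rule` must be present:
    TCMSP -> ob, caco2, dl; BATMAN -> score, adj_p.
    """

    herb_latin: str
    herb_pinyin: str
    name: str
    compound_id: str = ""
    formula: str | None = None
    ob: float | None = None
    caco2: float | None = None
    dl: float | None = None
    score: float | None = None
    adj_p: float | None = None
    source_rule: Literal["TCMSP", "BATMAN"] = "TCMSP"

    def validate(self) -> None:
        if self.source_rule == "TCMSP":
            missing = [f for f in ("ob", "caco2", "dl") if getattr(self, f) is None]
        elif self.source_rule == "BATMAN":
            missing = [f for f in ("score", "adj_p") if getattr(self, f) is None]
        else:
            raise ValueError(f"unknown source_rule {self.source_rule!r}")
        if missing:
            raise ValueError(
                f"ingredient {self.name!r} ({self.source_rule}) missing required "
                f"field(s): {', '.join(missing)}"
            )
        if self.ob is not None and not 0.0 <= self.ob <= 100.0:
            raise ValueError(f"ingredient {self.name!r}: OB {self.ob} outside [0, 100]")
        if self.adj_p is not None and not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"ingredient {self.name!r}: adj_p {self.adj_p} outside [0, 1]")


def passes_filter(
    ing: Ingredient,
    tcmsp: TcmspThresholds = TcmspThresholds(),
    batman: BatmanThresholds = BatmanThresholds(),
) -> bool:
    """Apply the pharmacokinetic candidate rule for the row's source.

    TCMSP: OB, Caco-2 and DL all at-or-above their thresholds
    (inclusive).  BATMAN: score at-or-above (inclusive) and adjusted P
    strictly below its cutoff.  A missing required field is an error,
    never a silent pass or fail.
    """
    ing.validate()
    if ing.source_rule == "TCMSP":
        return ing.ob >= tcmsp.ob and ing.caco2 >= tcmsp.caco2 and ing.dl >= tcmsp.dl
    return ing.score >= batman.score and ing.adj_p < batman.adj_p


_WS_RE = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Dedup key: case-folded, whitespace-collapsed; Greek letters kept."""
    return _WS_RE.sub(" ", name.strip()).casefold()


@dataclass
class Candidate:
    """A deduplicated candidate ingredient with per-herb provenance."""

    name: str
    herbs: list[str] = field(default_factory=list)
    rows: list[Ingredient] = field(default_factory=list)

    @property
    def compound_id(self) -> str:
        return self.rows[0].compound_id if self.rows else ""

    @property
    def formula(self) -> str | None:
        return self.rows[0].formula if self.rows else None


def select_candidates(
    tables: Sequence[Sequence[Ingredient]],
    tcmsp: TcmspThresholds = TcmspThresholds(),
    batman: BatmanThresholds = BatmanThresholds(),
    apply_filter: bool = True,
) -> list[Candidate]:
    """Filter per-herb ingredient tables and deduplicate across herbs.

    Each inner sequence is one herb's table (rows carry their own herb
    fields).  Rows surviving the filter are merged by normalized name;
    a compound found in several herbs is kept once with every
    contributing herb recorded.  Output order is deterministic: herb
    order as given, then input row order.  Set ``apply_filter=False``
    for tables that are already pre-filtered.
    """
    by_key: dict[str, Candidate] = {}
    for table in tables:
        for ing in table:
            if apply_filter and not passes_filter(ing, tcmsp, batman):
                continue
            key = normalize_name(ing.name)
            cand = by_key.get(key)
            if cand is None:
                cand = by_key[key] = Candidate(name=ing.name)
            if ing.herb_latin not in cand.herbs:
                cand.herbs.append(ing.herb_latin)
            cand.rows.append(ing)
    return list(by_key.values())


_TCMSP_COLS = ["herb_latin", "herb_pinyin", "name", "compound_id", "formula", "OB", "caco2", "DL"]
_BATMAN_COLS = ["herb_latin", "herb_pinyin", "name", "compound_id", "formula", "score", "adj_p"]


def read_ingredient_tsv(path: str | Path, dialect: Literal["TCMSP", "BATMAN"]) -> list[Ingredient]:
    """Read a TCMSP- or BATMAN-style ingredient table (UTF-8 TSV, header row)."""
    expected = _TCMSP_COLS if dialect == "TCMSP" else _BATMAN_COLS
    rows: list[Ingredient] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = [c for c in expected if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing} for {dialect} dialect")
        for rec in reader:
            common = dict(
                herb_latin=rec["herb_latin"],
                herb_pinyin=rec["herb_pinyin"],
                name=rec["name"],
                compound_id=rec["compound_id"],
                formula=rec["formula"] or None,
                source_rule=dialect,
            )
            if dialect == "TCMSP":
                ing = Ingredient(
                    **common,
                    ob=float(rec["OB"]),
                    caco2=float(rec["caco2"]),
                    dl=float(rec["DL"]),
                )
            else:
                ing = Ingredient(
                    **common,
                    score=float(rec["score"]),
                    adj_p=float(rec["adj_p"]),
                )
            ing.validate()
            rows.append(ing)
    return rows


def write_ingredient_tsv(
    path: str | Path, rows: Iterable[Ingredient], dialect: Literal["TCMSP", "BATMAN"]
) -> None:
    cols = _TCMSP_COLS if dialect == "TCMSP" else _BATMAN_COLS
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for ing in rows:
            base = [ing.herb_latin, ing.herb_pinyin, ing.name, ing.compound_id, ing.formula or ""]
            if dialect == "TCMSP":
                writer.writerow(base + [repr(ing.ob), repr(ing.caco2), repr(ing.dl)])
            else:
                writer.writerow(base + [repr(ing.score), repr(ing.adj_p)])
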