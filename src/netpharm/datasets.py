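"""Packaged reference data.

``candidate_ingredients.tsv`` ships the published worked example: the
ten pre-filtered candidate ingredient rows across the three herbs, with
their reported masses (``mass_mode`` records whether the printed mass
is an average or a monoisotopic value — the published table mixes the
two conventions).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from netpharm.chem import Ingredient

__all__ = ["load_candidate_table", "candidate_ingredient_lists"]


def load_candidate_table() -> pd.DataFrame:
    """Return the packaged candidate-ingredient worked example as a DataFrame."""
    ref = resources.files("netpharm.data").joinpath("candidate_ingredients.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"compound_id": str})


def candidate_ingredient_lists() -> list[list[Ingredient]]:
    """The packaged rows grouped per herb, as pre-filtered Ingredient lists.

    Pharmacokinetic fields are absent (the published table records
    post-filter chemistry only), so feed these to
    ``select_candidates(..., apply_filter=False)``.
    """
    df = load_candidate_table()
    tables: list[list[Ingredient]] = []
    seen: dict[str, int] = {}
    for _, rec in df.iterrows():
        herb = rec["herb_latin"]
        if herb not in seen:
            seen[herb] = len(tables)
            tables.append([])
        tables[seen[herb]].append(
            Ingredient(
                herb_latin=herb,
                herb_pinyin=rec["herb_pinyin"],
                name=rec["name"],
                compound_id=rec["compound_id"],
                formula=rec["formula"],
            )
        )
    return tables
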