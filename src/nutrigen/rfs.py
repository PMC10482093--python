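"""Unweighted Recommended Food Score (RFS) and the binary item-indicator matrix.

One point per recommended food eaten at least once a week, plus one point for
a regular three-meals-a-day pattern; 46 points attainable. The indicator
matrix (subjects x 46 items, panel column order) is the input to both
weighted-score models (HisCoM, PLS-DA).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import (
    FREQUENCY_CATEGORIES,
    MEAL_CATEGORIES,
    MEAL_SCORING_CATEGORY,
    WEEKLY_CUT_INDEX,
    FoodPanel,
    default_panel,
)


def item_indicator(category: str, item_kind: str = "food") -> int:
    """Score a single item's frequency category as 0 or 1.

    Food items score 1 when consumed at least once a week, i.e. at
    "one to two times a week" or any more frequent category (the nine-level
    scale has no plain "once a week" level; this is the documented cut).
    The meals item scores 1 only for "three meals a day".

    Raises ``ValueError`` for a category outside the closed vocabulary.
    """
    if item_kind == "meals":
        if category not in MEAL_CATEGORIES:
            raise ValueError(f"unknown meal-frequency category: {category!r}")
        return int(category == MEAL_SCORING_CATEGORY)
    if item_kind != "food":
        raise ValueError(f"item_kind must be 'food' or 'meals', got {item_kind!r}")
    if category not in FREQUENCY_CATEGORIES:
        raise ValueError(f"unknown frequency category: {category!r}")
    return int(FREQUENCY_CATEGORIES.index(category) >= WEEKLY_CUT_INDEX)


def compute_rfs(response: Mapping[str, str], panel: FoodPanel | None = None) -> int:
    """Total RFS (integer in [0, 46]) for one subject's responses.

    ``response`` maps item identifier -> frequency category and must cover
    every panel item; a missing item is a hard error naming the item (no
    silent imputation, which would contaminate the score bounds).
    """
    panel = panel or default_panel()
    score = 0
    for item in panel.items:
        if item not in response:
            raise KeyError(f"response missing panel item {item!r}")
        score += item_indicator(response[item], panel.item_kind(item))
    return score


def indicator_matrix(
    responses: pd.DataFrame | Iterable[Mapping[str, str]],
    panel: FoodPanel | None = None,
) -> pd.DataFrame:
    """Binary n x 46 item-indicator matrix, columns in panel order.

    ``responses`` is a DataFrame indexed by subject id with one column per
    item (or an iterable of per-subject mappings). Row sums equal
    :func:`compute_rfs` per subject. Duplicated subject ids are an error.
    Empty input yields an empty 0 x 46 frame.
    """
    panel = panel or default_panel()
    if not isinstance(responses, pd.DataFrame):
        responses = pd.DataFrame(list(responses))
    if responses.index.has_duplicates:
        dups = responses.index[responses.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated subject ids: {dups}")
    missing = [it for it in panel.items if it not in responses.columns]
    if missing:
        raise KeyError(f"responses missing panel items: {missing}")
    out = np.empty((len(responses), len(panel.items)), dtype=np.int8)
    for j, item in enumerate(panel.items):
        kind = panel.item_kind(item)
        vocab = MEAL_CATEGORIES if kind == "meals" else FREQUENCY_CATEGORIES
        col = responses[item]
        bad = ~col.isin(vocab)
        if bad.any():
            raise ValueError(
                f"item {item!r}: unknown categories {sorted(col[bad].unique())}"
            )
        if kind == "meals":
            out[:, j] = (col == MEAL_SCORING_CATEGORY).to_numpy()
        else:
            idx = col.map({c: i for i, c in enumerate(FREQUENCY_CATEGORIES)})
            out[:, j] = (idx.to_numpy() >= WEEKLY_CUT_INDEX)
    return pd.DataFrame(out, index=responses.index, columns=list(panel.items))


def rfs_scores(
    responses: pd.DataFrame, panel: FoodPanel | None = None
) -> pd.Series:
    """Vector of RFS totals (row sums of the indicator matrix)."""
    g = indicator_matrix(responses, panel)
    return g.sum(axis=1).astype(int).rename("rfs")
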