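"""Food panel: the 46 scored items, their groups and per-group point totals.

The Recommended Food Score (RFS) variant modelled here tallies 46 components:
45 recommended food items in 10 food groups plus one "regular meals" item
(three meals a day). Each component contributes at most one point, so the
score ranges 0-46. The panel object carries the item ordering used by every
downstream matrix (item-indicator matrix, HisCoM weights, PLS-DA loadings).

The questionnaire records each food on a nine-level frequency scale and the
daily meal pattern on a five-level scale; both vocabularies are closed and
ordered from least to most frequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Nine ordered consumption-frequency categories for food items.
FREQUENCY_CATEGORIES: tuple[str, ...] = (
    "never or seldom",
    "once a month",
    "one to two times a week",
    "two to three times a week",
    "three to four times a week",
    "five to six times a week",
    "once daily",
    "twice daily",
    "more than three times daily",
)

# Index of the first category that counts as "at least once a week".
WEEKLY_CUT_INDEX = FREQUENCY_CATEGORIES.index("one to two times a week")

# Five daily-meal-frequency categories; only "three meals a day" scores.
MEAL_CATEGORIES: tuple[str, ...] = (
    "one meal a day",
    "two meals a day",
    "three meals a day",
    "more than four meals a day",
    "irregular",
)
MEAL_SCORING_CATEGORY = "three meals a day"

# Group -> number of scored items (= points attainable from that group).
GROUP_POINTS: dict[str, int] = {
    "meals": 1,
    "grains": 1,
    "legumes": 4,
    "vegetables": 16,
    "seaweeds": 2,
    "fruits_juices": 12,
    "fish": 5,
    "dairy": 3,
    "nuts": 1,
    "tea": 1,
}

N_ITEMS = sum(GROUP_POINTS.values())  # 46


@dataclass(frozen=True)
class FoodPanel:
    """Ordered item list with the item->group map and group point totals.

    Invariants (checked at construction): every item belongs to exactly one
    group, each group's item count equals its point total, and the totals sum
    to 46.
    """

    items: tuple[str, ...]
    group_of_item: dict[str, str]
    group_points: dict[str, int] = field(default_factory=lambda: dict(GROUP_POINTS))

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item identifiers in panel")
        if set(self.items) != set(self.group_of_item):
            raise ValueError("items and group_of_item must cover the same items")
        counts: dict[str, int] = {}
        for item, grp in self.group_of_item.items():
            if grp not in self.group_points:
                raise ValueError(f"item {item!r} assigned to unknown group {grp!r}")
            counts[grp] = counts.get(grp, 0) + 1
        if counts != dict(self.group_points):
            raise ValueError(
                f"group item counts {counts} do not match group points {self.group_points}"
            )
        if sum(self.group_points.values()) != len(self.items):
            raise ValueError("group points must sum to the number of items")

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in first-appearance (panel) order."""
        seen: list[str] = []
        for item in self.items:
            g = self.group_of_item[item]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def group_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.groups)}

    def items_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(it for it in self.items if self.group_of_item[it] == group)

    def item_kind(self, item: str) -> str:
        """'meals' for the daily-meal-frequency item, 'food' otherwise."""
        return "meals" if self.group_of_item[item] == "meals" else "food"

    @property
    def max_score(self) -> int:
        return len(self.items)


def default_panel() -> FoodPanel:
    """The shipped 46-item template panel.

    Item identities are schema-driven (users may substitute their own names);
    the template uses ``<group>_<k>`` placeholders with the stated group
    sizes: meals 1, grains 1, legumes 4, vegetables 16, seaweeds 2,
    fruits/juices 12, fish 5, dairy 3, nuts 1, tea 1.
    """
    items: list[str] = []
    group_of_item: dict[str, str] = {}
    for grp, npts in GROUP_POINTS.items():
        if npts == 1:
            names = [grp if grp in ("meals",) else f"{grp}_1"]
        else:
            names = [f"{grp}_{i}" for i in range(1, npts + 1)]
        for name in names:
            items.append(name)
            group_of_item[name] = grp
    return FoodPanel(items=tuple(items), group_of_item=group_of_item)
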