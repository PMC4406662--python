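"""Cross-comparison classification of differential calls.

Given the up/down/ns calls of the same items (genes or gene sets) under
two comparisons — typically the strain difference at baseline and the
strain difference after treatment — each item falls in exactly one
category:

- ``baseline_only`` ("normalized"): significant at baseline, ns after;
- ``second_only`` ("new"): ns at baseline, significant after;
- ``both_same_direction`` / ``both_opposite``: significant in both, with
  concordant or discordant signs;
- ``neither``: ns in both.

"Opposite direction" therefore requires significance in BOTH comparisons
with discordant signs. Every percentage is reported together with its
denominator, since the interesting fractions use different denominators
(items significant at baseline, items significant in both, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

CATEGORIES = (
    "baseline_only",
    "second_only",
    "both_same_direction",
    "both_opposite",
    "neither",
)

SIGNIFICANT = frozenset({"up", "down"})


@dataclass(frozen=True)
class Percentage:
    """A percentage carried with the numerator/denominator it came from."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def percent_of(numerator: int, denominator: int) -> Percentage:
    return Percentage(numerator=numerator, denominator=denominator)


def percent_decrease(before: int, after: int) -> Percentage:
    """Relative decrease from ``before`` to ``after``, in percent of ``before``."""
    return Percentage(numerator=before - after, denominator=before)


@dataclass
class CrossComparison:
    """Per-item categories plus category counts over a shared universe."""

    table: pd.DataFrame  # columns: call_1, call_2, category
    counts: dict[str, int]

    @property
    def universe_size(self) -> int:
        return len(self.table)

    def items(self, category: str) -> pd.Index:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return self.table.index[self.table["category"] == category]

    def percentage(self, category: str, denominator: str = "universe") -> Percentage:
        """Category share of the universe, or of ``significant_first``."""
        n = self.counts[category]
        if denominator == "universe":
            return percent_of(n, self.universe_size)
        if denominator == "significant_first":
            d = sum(
                self.counts[c]
                for c in ("baseline_only", "both_same_direction", "both_opposite")
            )
            return percent_of(n, d)
        raise ValidationError(f"unknown denominator {denominator!r}")


def _validated(calls_1: pd.Series, calls_2: pd.Series) -> tuple[pd.Series, pd.Series]:
    s1, s2 = pd.Series(calls_1), pd.Series(calls_2)
    only_1 = s1.index.difference(s2.index)
    only_2 = s2.index.difference(s1.index)
    if len(only_1) or len(only_2):
        raise ValidationError(
            "call maps cover different universes; "
            f"only in first: {list(only_1[:5])}, only in second: {list(only_2[:5])}"
        )
    return s1, s2.reindex(s1.index)


def cross_classify(calls_1: pd.Series, calls_2: pd.Series) -> CrossComparison:
    """Partition the item universe by joint significance/direction status.

    Calls other than ``up``/``down`` (``ns``, ``excluded``) count as not
    significant. The categories partition the universe exactly.
    """
    s1, s2 = _validated(calls_1, calls_2)
    sig1, sig2 = s1.isin(SIGNIFICANT), s2.isin(SIGNIFICANT)
    category = pd.Series("neither", index=s1.index, name="category")
    category[sig1 & ~sig2] = "baseline_only"
    category[~sig1 & sig2] = "second_only"
    both = sig1 & sig2
    category[both & (s1 == s2)] = "both_same_direction"
    category[both & (s1 != s2)] = "both_opposite"
    counts = {c: int((category == c).sum()) for c in CATEGORIES}
    table = pd.DataFrame({"call_1": s1, "call_2": s2, "category": category})
    return CrossComparison(table=table, counts=counts)


@dataclass(frozen=True)
class DirectionStats:
    """Fraction of coincident significant items with opposite direction."""

    n_coincident: int
    n_opposite: int

    @property
    def defined(self) -> bool:
        return self.n_coincident > 0

    @property
    def fraction(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_opposite / self.n_coincident


def direction_stats(calls_1: pd.Series, calls_2: pd.Series) -> DirectionStats:
    """Among items significant in both comparisons, the discordant fraction."""
    cc = cross_classify(calls_1, calls_2)
    coincident = cc.counts["both_same_direction"] + cc.counts["both_opposite"]
    return DirectionStats(n_coincident=coincident, n_opposite=cc.counts["both_opposite"])


@dataclass(frozen=True)
class VennSummary:
    """Region counts for a two-comparison up/down Venn rendering.

    ``first_only``/``second_only`` split the exclusive regions by
    direction; the intersection is split into concordant up, concordant
    down, and opposed items.
    """

    first_only_up: int
    first_only_down: int
    second_only_up: int
    second_only_down: int
    both_up: int
    both_down: int
    opposed: int

    @property
    def total_significant(self) -> int:
        return (self.first_only_up + self.first_only_down + self.second_only_up
                + self.second_only_down + self.both_up + self.both_down + self.opposed)


def venn_summary(calls_1: pd.Series, calls_2: pd.Series) -> VennSummary:
    """Direction-resolved region counts, consistent with cross_classify."""
    cc = cross_classify(calls_1, calls_2)
    t = cc.table
    return VennSummary(
        first_only_up=int(((t["category"] == "baseline_only") & (t["call_1"] == "up")).sum()),
        first_only_down=int(((t["category"] == "baseline_only") & (t["call_1"] == "down")).sum()),
        second_only_up=int(((t["category"] == "second_only") & (t["call_2"] == "up")).sum()),
        second_only_down=int(((t["category"] == "second_only") & (t["call_2"] == "down")).sum()),
        both_up=int(((t["category"] == "both_same_direction") & (t["call_1"] == "up")).sum()),
        both_down=int(((t["category"] == "both_same_direction") & (t["call_1"] == "down")).sum()),
        opposed=cc.counts["both_opposite"],
    )


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion tallies of calls against simulation ground truth.

    Positive = called significant. A significant call with a null truth
    direction, or with the wrong sign, counts as a false positive.
    ``by_direction`` holds per-direction true/false positive counts.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    by_direction: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else float("nan")

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")


def evaluate_calls(calls: pd.Series, expected: pd.Series) -> ConfusionSummary:
    """Score calls against expected directions (``up``/``down``/``null``)."""
    calls = pd.Series(calls)
    expected = pd.Series(expected)
    unknown = calls.index.difference(expected.index)
    if len(unknown):
        raise ValidationError(f"calls for ids missing from truth: {list(unknown[:5])}")
    expected = expected.reindex(calls.index)
    sig = calls.isin(SIGNIFICANT)
    true_effect = expected != "null"
    tp_mask = sig & true_effect & (calls == expected)
    fp_mask = sig & ~tp_mask
    fn_mask = ~sig & true_effect
    tn_mask = ~sig & ~true_effect
    by_direction = {
        d: {
            "tp": int((tp_mask & (calls == d)).sum()),
            "fp": int((fp_mask & (calls == d)).sum()),
        }
        for d in ("up", "down")
    }
    return ConfusionSummary(
        tp=int(tp_mask.sum()), fp=int(fp_mask.sum()),
        tn=int(tn_mask.sum()), fn=int(fn_mask.sum()),
        by_direction=by_direction,
    )
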