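import numpy as np
import pandas as pd
import pytest

from zrpage import (
    ValidationError,
    cross_classify,
    direction_stats,
    evaluate_calls,
    percent_decrease,
    percent_of,
    venn_summary,
)
from zrpage.compare import CATEGORIES, DirectionStats


def _calls(mapping):
    return pd.Series(mapping)


def _random_calls(rng, items, p_sig=0.4):
    values = rng.choice(["up", "down", "ns"], size=len(items),
                        p=[p_sig / 2, p_sig / 2, 1 - p_sig])
    return pd.Series(values, index=items)


def test_direct_rule_application():
    c1 = _calls({"A": "up", "B": "down", "C": "ns"})
    c2 = _calls({"A": "ns", "B": "down", "C": "ns"})
    cc = cross_classify(c1, c2)
    assert list(cc.items("baseline_only")) == ["A"]
    assert list(cc.items("both_same_direction")) == ["B"]
    assert list(cc.items("second_only")) == []
    assert list(cc.items("both_opposite")) == []
    assert list(cc.items("neither")) == ["C"]


def test_all_ns_second_comparison_means_full_normalization():
    c1 = _calls({"A": "up", "B": "down", "C": "ns", "D": "up"})
    c2 = pd.Series("ns", index=c1.index)
    cc = cross_classify(c1, c2)
    assert cc.counts["baseline_only"] == 3
    pct = cc.percentage("baseline_only", denominator="significant_first")
    assert pct.value == 100.0 and pct.denominator == 3


@pytest.mark.parametrize("seed", range(5))
def test_counts_match_per_item_enumeration(seed):
    """1000 random items: category counts equal an exhaustive item-by-item
    classification, and the categories partition the universe."""
    rng = np.random.default_rng(seed)
    items = [f"I{i:04d}" for i in range(1000)]
    c1, c2 = _random_calls(rng, items), _random_calls(rng, items)
    cc = cross_classify(c1, c2)
    expected = dict.fromkeys(CATEGORIES, 0)
    for i in items:
        s1, s2 = c1[i] in ("up", "down"), c2[i] in ("up", "down")
        if s1 and not s2:
            expected["baseline_only"] += 1
        elif s2 and not s1:
            expected["second_only"] += 1
        elif s1 and s2 and c1[i] == c2[i]:
            expected["both_same_direction"] += 1
        elif s1 and s2:
            expected["both_opposite"] += 1
        else:
            expected["neither"] += 1
    assert cc.counts == expected
    assert sum(cc.counts.values()) == len(items)


def test_swap_symmetry():
    rng = np.random.default_rng(9)
    items = [f"I{i}" for i in range(400)]
    c1, c2 = _random_calls(rng, items), _random_calls(rng, items)
    a, b = cross_classify(c1, c2), cross_classify(c2, c1)
    assert a.counts["baseline_only"] == b.counts["second_only"]
    assert a.counts["second_only"] == b.counts["baseline_only"]
    assert a.counts["both_same_direction"] == b.counts["both_same_direction"]
    assert a.counts["both_opposite"] == b.counts["both_opposite"]


def test_universe_mismatch_lists_ids():
    c1 = _calls({"A": "up", "B": "ns"})
    c2 = _calls({"A": "up", "C": "ns"})
    with pytest.raises(ValidationError, match="B.*C"):
        cross_classify(c1, c2)


def test_direction_stats_hand_counts():
    # 8 coincident significant items, 4 with discordant signs -> 0.50
    c1 = _calls({f"I{i}": "up" for i in range(8)} | {"X": "ns"})
    c2 = _calls({f"I{i}": ("down" if i < 4 else "up") for i in range(8)} | {"X": "up"})
    ds = direction_stats(c1, c2)
    assert ds == DirectionStats(n_coincident=8, n_opposite=4)
    assert ds.fraction == 0.5

    empty = direction_stats(_calls({"A": "up"}), _calls({"A": "ns"}))
    assert not empty.defined
    assert np.isnan(empty.fraction)


def test_direction_stats_enumeration_oracle():
    rng = np.random.default_rng(3)
    items = [f"I{i}" for i in range(20)]
    c1, c2 = _random_calls(rng, items, 0.7), _random_calls(rng, items, 0.7)
    ds = direction_stats(c1, c2)
    sig = lambda c: c in ("up", "down")
    coincident = [i for i in items if sig(c1[i]) and sig(c2[i])]
    opposite = [i for i in coincident if c1[i] != c2[i]]
    assert ds.n_coincident == len(coincident)
    assert ds.n_opposite == len(opposite)


def test_venn_regions_consistent_with_cross_classify():
    rng = np.random.default_rng(5)
    items = [f"I{i}" for i in range(500)]
    c1, c2 = _random_calls(rng, items), _random_calls(rng, items)
    v = venn_summary(c1, c2)
    cc = cross_classify(c1, c2)
    assert v.first_only_up + v.first_only_down == cc.counts["baseline_only"]
    assert v.second_only_up + v.second_only_down == cc.counts["second_only"]
    assert v.both_up + v.both_down == cc.counts["both_same_direction"]
    assert v.opposed == cc.counts["both_opposite"]
    assert v.total_significant + cc.counts["neither"] == len(items)


def test_venn_degenerate_cases():
    c1 = _calls({"A": "up", "B": "ns", "C": "ns"})
    c2 = _calls({"A": "ns", "B": "down", "C": "ns"})
    v = venn_summary(c1, c2)
    assert (v.both_up, v.both_down, v.opposed) == (0, 0, 0)
    v_same = venn_summary(c1, c1)
    assert (v_same.first_only_up, v_same.second_only_up, v_same.opposed) == (0, 0, 0)
    assert v_same.both_up == 1


def test_evaluate_calls_perfect_and_blind():
    truth = pd.Series({"A": "up", "B": "down", "C": "null", "D": "null"})
    perfect = pd.Series({"A": "up", "B": "down", "C": "ns", "D": "ns"})
    cs = evaluate_calls(perfect, truth)
    assert (cs.tp, cs.fp, cs.tn, cs.fn) == (2, 0, 2, 0)
    assert cs.fpr == 0.0 and cs.tpr == 1.0

    blind = pd.Series("ns", index=truth.index)
    assert evaluate_calls(blind, truth).tpr == 0.0


def test_evaluate_calls_constructed_confusion():
    """10 items with exactly 2 false positives and 1 false negative."""
    truth = pd.Series(
        {"A": "up", "B": "up", "C": "down", "D": "null", "E": "null",
         "F": "null", "G": "null", "H": "null", "I": "null", "J": "null"}
    )
    calls = pd.Series(
        {"A": "up", "B": "up", "C": "ns",      # C missed -> FN
         "D": "up", "E": "down",               # 2 FP
         "F": "ns", "G": "ns", "H": "ns", "I": "ns", "J": "ns"}
    )
    cs = evaluate_calls(calls, truth)
    assert (cs.tp, cs.fp, cs.tn, cs.fn) == (2, 2, 5, 1)
    assert cs.total == 10
    assert cs.by_direction["up"] == {"tp": 2, "fp": 1}
    assert cs.by_direction["down"] == {"tp": 0, "fp": 1}


def test_wrong_sign_counts_as_false_positive():
    truth = pd.Series({"A": "up", "B": "null"})
    calls = pd.Series({"A": "down", "B": "ns"})
    cs = evaluate_calls(calls, truth)
    assert (cs.tp, cs.fp, cs.tn, cs.fn) == (0, 1, 1, 0)


def test_evaluate_calls_unknown_ids_rejected():
    with pytest.raises(ValidationError, match="ZZZ"):
        evaluate_calls(pd.Series({"ZZZ": "up"}), pd.Series({"A": "null"}))


def test_percentage_helpers_carry_denominators():
    p = percent_of(9709, 24613)
    assert p.value == pytest.approx(39.4, abs=0.05)
    assert p.denominator == 24613
    d = percent_decrease(151, 99)
    assert d.value == pytest.approx(34.4, abs=0.05)
    assert not percent_of(3, 0).defined
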