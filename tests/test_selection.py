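import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primerforge.selection import (
    Characteristic,
    SelectionSpec,
    multi_objective_score,
    sigmoid,
    sort_candidates,
)


def spec_of(*chars, method="prioritised", keep_suboptimal=True):
    return SelectionSpec(characteristics=chars, method=method, keep_suboptimal=keep_suboptimal)


class TestSigmoid:
    def test_midpoint_is_half(self):
        for k in (0.1, 1.0, 7.3):
            for o in (-2.0, 0.0, 5.0):
                assert sigmoid(o, k, o) == pytest.approx(0.5)

    def test_asymptotes(self):
        assert sigmoid(1e6, 1.0, 0.0) == pytest.approx(1.0)
        assert sigmoid(-1e6, 1.0, 0.0) == pytest.approx(0.0)
        assert math.isfinite(sigmoid(1e308, 1.0, 0.0))

    def test_default_gain_is_one(self):
        assert Characteristic("x", priority=1).gain == 1.0

    @settings(derandomize=True)
    @given(st.floats(-30, 30), st.floats(0.01, 5))
    def test_strictly_increasing(self, a, delta):
        # strict within the non-saturated region; beyond |x| ~ 37 the
        # double-precision value is exactly 0 or 1 by design
        assert sigmoid(a) < sigmoid(a + delta)


class TestMultiObjective:
    def test_zero_weights_score_zero(self):
        spec = spec_of(Characteristic("a", 1, weight=0), Characteristic("b", 2, weight=0))
        assert multi_objective_score({"a": 3.0, "b": 9.0}, spec) == 0.0

    def test_lower_penalties_score_lower(self):
        spec = spec_of(Characteristic("a", 1, weight=1), Characteristic("b", 2, weight=1))
        good = multi_objective_score({"a": 0.0, "b": 0.0}, spec)
        bad = multi_objective_score({"a": 10.0, "b": 10.0}, spec)
        assert good < bad

    def test_missing_characteristic_named_in_error(self):
        spec = spec_of(Characteristic("tm", 1, weight=1))
        with pytest.raises(KeyError, match="tm"):
            multi_objective_score({"gc": 1.0}, spec)

    def test_invariant_under_characteristic_permutation(self, rng):
        chars = [Characteristic(n, i + 1, weight=w) for i, (n, w) in enumerate(
            [("a", 1.0), ("b", 0.5), ("c", 2.0)]
        )]
        item = {"a": 1.2, "b": -0.3, "c": 4.5}
        base = multi_objective_score(item, spec_of(*chars))
        for _ in range(5):
            shuffled = chars[:]
            rng.shuffle(shuffled)
            assert multi_objective_score(item, spec_of(*shuffled)) == pytest.approx(base)

    def test_single_weight_ordering_equals_single_key_ordering(self, rng):
        """With one nonzero weight the multi-objective order must reduce to
        ordering by that characteristic's penalty (sigmoid is monotone)."""
        for trial in range(100):
            items = [
                {"a": rng.uniform(0, 10), "b": rng.uniform(0, 10)} for _ in range(12)
            ]
            spec = spec_of(
                Characteristic("a", 1, weight=rng.uniform(0.1, 5)),
                Characteristic("b", 2, weight=0.0),
                method="multi_objective",
            )
            ranked = [r.item for r in sort_candidates(items, spec)]
            assert [i["a"] for i in ranked] == sorted(i["a"] for i in items)


class TestPrioritisedSort:
    def test_stability_on_equal_keys(self):
        items = [{"a": 1.0, "tag": t} for t in "abcde"]
        spec = spec_of(Characteristic("a", 1))
        ranked = sort_candidates(items, spec)
        assert [r.item["tag"] for r in ranked] == list("abcde")

    def test_higher_priority_key_dominates(self):
        """A candidate with a unique binding site outranks one with better
        Tm but two sites when binding has priority 1."""
        unique = {"binding": 0, "tm": 5.0, "name": "unique"}
        lowtm = {"binding": 1, "tm": 0.5, "name": "lowtm"}
        third = {"binding": 1, "tm": 0.1, "name": "third"}
        spec = spec_of(Characteristic("binding", 1), Characteristic("tm", 2))
        ranked = sort_candidates([lowtm, third, unique], spec)
        assert [r.item["name"] for r in ranked] == ["unique", "third", "lowtm"]

    def test_threshold_soundness_without_fallback(self, rng):
        items = [{"dimer": rng.uniform(0, 20), "tm": rng.uniform(0, 5)} for _ in range(40)]
        spec = spec_of(
            Characteristic("dimer", 1, threshold=10.0),
            Characteristic("tm", 2),
            keep_suboptimal=False,
        )
        ranked = sort_candidates(items, spec)
        survivors = [r for r in ranked if not r.rejected]
        assert all(r.item["dimer"] <= 10.0 for r in survivors)
        assert all(r.item["dimer"] > 10.0 for r in ranked if r.rejected)

    def test_suboptimal_fallback_returns_everything_flagged_and_ordered(self):
        items = [{"dimer": 15.0 + i} for i in range(5)]
        spec = spec_of(Characteristic("dimer", 1, threshold=10.0))
        ranked = sort_candidates(items, spec)
        assert len(ranked) == 5
        assert all(r.suboptimal for r in ranked)
        assert [r.item["dimer"] for r in ranked] == [15.0, 16.0, 17.0, 18.0, 19.0]

    def test_fallback_non_empty_whenever_input_non_empty(self, rng):
        for _ in range(30):
            n = rng.randint(1, 10)
            items = [{"x": rng.uniform(100, 200)} for _ in range(n)]
            spec = spec_of(Characteristic("x", 1, threshold=1.0))
            ranked = sort_candidates(items, spec)
            assert len(ranked) == n and not any(r.rejected for r in ranked)

    def test_empty_input_empty_output(self):
        assert sort_candidates([], spec_of(Characteristic("x", 1))) == []

    def test_raising_priority_never_hurts_the_best(self, rng):
        """Promoting a characteristic to priority 1 puts the candidate
        uniquely best in it at the top (the secondary-binding
        reprioritisation workflow)."""
        for _ in range(20):
            items = [
                {"binding": rng.randint(1, 3), "tm": rng.uniform(0, 5)} for _ in range(10)
            ]
            items[0]["binding"] = 0  # uniquely best
            promoted = spec_of(Characteristic("binding", 1), Characteristic("tm", 2))
            ranked = sort_candidates(items, promoted)
            assert ranked[0].item is items[0]

    def test_combined_mode_orders_survivors_by_f(self):
        items = [
            {"dimer": 1.0, "tm": 4.0},
            {"dimer": 1.0, "tm": 1.0},
            {"dimer": 99.0, "tm": 0.0},
        ]
        spec = spec_of(
            Characteristic("dimer", 1, threshold=10.0, weight=1.0),
            Characteristic("tm", 2, weight=1.0),
            method="prioritised_then_multi_objective",
            keep_suboptimal=False,
        )
        ranked = sort_candidates(items, spec)
        assert ranked[0].item["tm"] == 1.0
        assert ranked[-1].rejected  # the dimer-violating candidate at the bottom
        assert ranked[0].score is not None and ranked[0].score < ranked[1].score


def test_spec_validation():
    with pytest.raises(ValueError):
        SelectionSpec(characteristics=())
    with pytest.raises(ValueError):
        SelectionSpec(
            characteristics=(Characteristic("a", 1), Characteristic("b", 1))
        )
    with pytest.raises(ValueError):
        Characteristic("a", 1, gain=0.0)
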