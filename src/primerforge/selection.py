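"""Candidate ranking: prioritised stable sorting, thresholds with a
sub-optimal fallback, and sigmoid-weighted multi-objective scoring.

Every characteristic is expressed as a penalty (0 is ideal, larger is
worse) before ranking — e.g. |Tm - preferred Tm|, a dimer score, or the
number of binding sites beyond the first.

Prioritised mode runs one stable sorting pass per characteristic, from the
least important to the most important, so the highest-priority key dominates
the final order while ties preserve earlier passes.  Before each pass,
candidates whose penalty exceeds that characteristic's threshold are moved
to the bottom of the list and flagged rejected.  If thresholding would
reject everything and ``keep_suboptimal`` is set, the full list is retained,
re-ranked without thresholds and flagged sub-optimal — the caller gets the
best available sub-optimal candidates rather than none at all.

Multi-objective mode scalarises the characteristics into
``F = sum_i w_i * g(x_i)`` with the sigmoid ``g(x) = 1/(1 + exp(-k(x-o)))``
(gain ``k`` default 1.0; offset ``o`` pushes typical penalties into the
steep, most discriminating region of the sigmoid) and orders candidates by
ascending F.  It is best applied as the last step, after prioritised
thresholding has pruned the list.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Any, Sequence as Seq


@dataclass(frozen=True)
class Characteristic:
    """One scored dimension of a candidate.

    name       key of the penalty value on the candidate (mapping key or
               attribute); the value must already be a penalty, 0 = ideal.
    priority   rank order for prioritised sorting; 1 is most important.
    threshold  optional rejection bound: penalty > threshold rejects.
    weight     multi-objective weight w_i (>= 0).
    gain       sigmoid gain k (> 0, default 1.0).
    offset     sigmoid offset o (default 0.0).
    """

    name: str
    priority: int
    threshold: float | None = None
    weight: float = 0.0
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class SelectionSpec:
    characteristics: tuple[Characteristic, ...]
    method: str = "prioritised"  # prioritised | multi_objective | prioritised_then_multi_objective
    keep_suboptimal: bool = True

    def __post_init__(self) -> None:
        if not self.characteristics:
            raise ValueError("at least one characteristic is required")
        prios = [c.priority for c in self.characteristics]
        if len(set(prios)) != len(prios):
            raise ValueError("priorities must be unique")
        if self.method not in (
            "prioritised",
            "multi_objective",
            "prioritised_then_multi_objective",
        ):
            raise ValueError(f"unknown selection method {self.method!r}")
        object.__setattr__(self, "characteristics", tuple(self.characteristics))


@dataclass
class RankedCandidate:
    """A candidate with its resolved penalties and selection flags."""

    item: Any
    penalties: dict[str, float]
    rejected: bool = False
    rejected_by: str | None = None
    suboptimal: bool = False
    score: float | None = None  # multi-objective F when computed


def sigmoid(x: float, k: float = 1.0, o: float = 0.0) -> float:
    """1 / (1 + exp(-k (x - o))); strictly increasing, saturating at 0/1."""
    z = k * (x - o)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _penalty(item: Any, name: str) -> float:
    if isinstance(item, Mapping):
        if name not in item:
            raise KeyError(f"candidate is missing characteristic {name!r}")
        return float(item[name])
    try:
        return float(getattr(item, name))
    except AttributeError as exc:
        raise KeyError(f"candidate is missing characteristic {name!r}") from exc


def multi_objective_score(item: Any, spec: SelectionSpec) -> float:
    """F = sum_i w_i * sigmoid(x_i, k_i, o_i); lower is better."""
    return sum(
        c.weight * sigmoid(_penalty(item, c.name), c.gain, c.offset)
        for c in spec.characteristics
    )


def _prioritised_passes(
    ranked: list[RankedCandidate],
    chars: Seq[Characteristic],
    apply_thresholds: bool,
) -> tuple[list[RankedCandidate], list[RankedCandidate]]:
    """Run stable sorting passes from least to most important; return
    (surviving-in-order, rejected-in-order)."""
    active = list(ranked)
    rejected: list[RankedCandidate] = []
    for ch in sorted(chars, key=lambda c: -c.priority):
        if apply_thresholds and ch.threshold is not None:
            keep: list[RankedCandidate] = []
            for r in active:
                if r.penalties[ch.name] > ch.threshold:
                    r.rejected = True
                    r.rejected_by = ch.name
                    rejected.append(r)
                else:
                    keep.append(r)
            active = keep
        active.sort(key=lambda r: r.penalties[ch.name])  # list.sort is stable
    return active, rejected


def sort_candidates(
    candidates: Seq[Any],
    spec: SelectionSpec,
) -> list[RankedCandidate]:
    """Rank *candidates* under *spec*; returns every input item, survivors
    first in rank order, rejected items flagged at the bottom.

    Candidates may be mappings (name -> penalty) or objects with penalty
    attributes.
    """
    ranked = [
        RankedCandidate(
            item=c,
            penalties={ch.name: _penalty(c, ch.name) for ch in spec.characteristics},
        )
        for c in candidates
    ]
    if not ranked:
        return []

    if spec.method == "multi_objective":
        for r in ranked:
            r.score = multi_objective_score(r.penalties, spec)
        out = list(ranked)
        out.sort(key=lambda r: r.score)
        return out

    active, rejected = _prioritised_passes(ranked, spec.characteristics, True)

    if not active and spec.keep_suboptimal:
        # Everything violated some threshold: fall back to the best
        # available sub-optimal candidates, ordered without thresholds.
        for r in ranked:
            r.suboptimal = True
            r.rejected = False
            r.rejected_by = None
        active, _ = _prioritised_passes(ranked, spec.characteristics, False)
        rejected = []

    if spec.method == "prioritised_then_multi_objective":
        for r in active:
            r.score = multi_objective_score(r.penalties, spec)
        active.sort(key=lambda r: r.score)

    return active + rejected
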