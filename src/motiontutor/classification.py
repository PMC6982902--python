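"""kNNModel classification of the current multi-dimensional signal.

The distance between a multi-dimensional pattern and the current signal is
the arithmetic mean of the per-signal h distances:

    dist(P_u, S_cur) = (1/N) · Σ_{i∈K} h(P_{i,u}, S_i)

The class decision takes the k nearest bank entries, partitions them by
label into subsets Q_r, and returns the label of the subset with the
greatest cardinality; ties break on the smaller mean distance within the
subset, then on bank order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .matching import MatchGrid, h_distance
from .patterns import PatternBank, PatternMD
from .signals import MultiSignal


@dataclass
class ClassDecision:
    """Outcome of one kNNModel vote."""

    label: str
    neighbor_set: List[Tuple[int, str, float]]  # (bank position, label, dist)
    subset_cards: Dict[str, int]
    mean_dists: Dict[str, float]

    @property
    def min_dist(self) -> float:
        return min(d for _, _, d in self.neighbor_set)


def dist_md(
    P_u: PatternMD,
    S_cur: MultiSignal,
    grid: MatchGrid | None = None,
    n: int | None = None,
    role: str | None = "class",
) -> float:
    """Mean h distance over the member signals shared with the pattern."""
    members = P_u.with_role(role) if role else dict(P_u.members)
    missing = set(members) - set(S_cur.signals)
    if missing:
        raise ConfigurationError(f"signal indices missing from S_cur: {missing}")
    hs = [
        h_distance(members[i], S_cur[i], grid=grid, n=n)[0] for i in sorted(members)
    ]
    return float(np.mean(hs))


def classify_knn(
    bank: PatternBank,
    S_cur: MultiSignal,
    k: int = 3,
    grid: MatchGrid | None = None,
    n: int | None = None,
) -> ClassDecision:
    """kNNModel vote of the k nearest labelled patterns.

    ``k`` defaults to 3, the smallest majority-capable neighbourhood.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > bank.n_pairs:
        raise InvalidInputError(f"k={k} exceeds the bank size {bank.n_pairs}")

    dists = [
        (pos, entry.label, dist_md(entry, S_cur, grid=grid, n=n))
        for pos, entry in enumerate(bank.entries)
    ]
    # nearest k; ties on distance resolved by bank order (stable sort)
    nearest = sorted(dists, key=lambda t: t[2])[:k]

    cards: Dict[str, int] = {}
    sums: Dict[str, float] = {}
    for _, label, d in nearest:
        cards[label] = cards.get(label, 0) + 1
        sums[label] = sums.get(label, 0.0) + d
    means = {r: sums[r] / cards[r] for r in cards}

    first_pos = {}
    for pos, label, _ in nearest:
        first_pos.setdefault(label, pos)
    winner = min(
        cards, key=lambda r: (-cards[r], means[r], first_pos[r])
    )
    return ClassDecision(
        label=winner, neighbor_set=nearest, subset_cards=cards, mean_dists=means
    )
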