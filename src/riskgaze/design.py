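"""Stimulus space for two-outcome lottery experiments.

A lottery pays ``amount`` with probability ``prob`` and nothing otherwise.
The experimental design crosses a small set of amount levels with a set of
probability levels, pairs the resulting lotteries, removes stochastically
dominated pairings (keeping a few as catch trials) and classifies the
remaining trade-off problems by riskiness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

Relation = Literal["tradeoff", "a_dominates", "b_dominates", "equal"]

#: Default amount levels (ILS).
DEFAULT_AMOUNT_LEVELS = (3.0, 6.0, 15.0, 24.0, 30.0)
#: Default probability levels.
DEFAULT_PROB_LEVELS = (0.1, 0.2, 0.5, 0.8, 1.0)


@dataclass(frozen=True, order=True)
class Lottery:
    """A simple gamble: win ``amount`` with probability ``prob``, else 0."""

    amount: float
    prob: float

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if not 0 < self.prob <= 1:
            raise ValueError(f"prob must be in (0, 1], got {self.prob}")

    @property
    def expected_value(self) -> float:
        return self.amount * self.prob


@dataclass(frozen=True)
class ChoiceProblem:
    """A pairing of two lotteries presented as one binary choice."""

    id: str
    option_a: Lottery
    option_b: Lottery
    relation: Relation
    is_catch: bool = False

    def __post_init__(self) -> None:
        expected = classify_pair(self.option_a, self.option_b)
        if self.relation != expected:
            raise ValueError(
                f"relation {self.relation!r} inconsistent with options "
                f"(expected {expected!r})"
            )
        if self.is_catch and self.relation not in ("a_dominates", "b_dominates"):
            raise ValueError("catch trials must be dominated pairs")

    @property
    def delta_ev(self) -> float:
        """EV(option A) − EV(option B)."""
        return self.option_a.expected_value - self.option_b.expected_value

    def option(self, label: str) -> Lottery:
        if label == "A":
            return self.option_a
        if label == "B":
            return self.option_b
        raise KeyError(label)


@dataclass(frozen=True)
class DesignConfig:
    """Levels and counts defining the experiment's stimulus grid."""

    amount_levels: Sequence[float] = DEFAULT_AMOUNT_LEVELS
    prob_levels: Sequence[float] = DEFAULT_PROB_LEVELS
    n_catch: int = 10
    problem_subset: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        for name, levels in (("amount_levels", self.amount_levels),
                             ("prob_levels", self.prob_levels)):
            if len(levels) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.n_catch < 0:
            raise ValueError("n_catch must be >= 0")

    @property
    def amount_default(self) -> float:
        """Mid-range amount, used as the unscanned-attribute default."""
        return (min(self.amount_levels) + max(self.amount_levels)) / 2.0

    @property
    def prob_default(self) -> float:
        return (min(self.prob_levels) + max(self.prob_levels)) / 2.0

    @property
    def amount_range(self) -> tuple[float, float]:
        return (min(self.amount_levels), max(self.amount_levels))

    @property
    def prob_range(self) -> tuple[float, float]:
        return (min(self.prob_levels), max(self.prob_levels))


def build_grid(config: DesignConfig) -> list[Lottery]:
    """Cross amount levels with probability levels into a lottery grid."""
    amounts = list(config.amount_levels)
    probs = list(config.prob_levels)
    if len(set(amounts)) != len(amounts) or len(set(probs)) != len(probs):
        raise ValueError("duplicate levels")
    return [Lottery(a, p) for a in amounts for p in probs]


def classify_pair(a: Lottery, b: Lottery) -> Relation:
    """Dominance relation between two lotteries.

    ``a_dominates`` iff a is at least as good on both attributes and
    strictly better on one; symmetric for ``b``; identical pairs are
    ``equal``; everything else is a genuine trade-off.
    """
    if a.amount == b.amount and a.prob == b.prob:
        return "equal"
    if a.amount >= b.amount and a.prob >= b.prob:
        return "a_dominates"
    if b.amount >= a.amount and b.prob >= a.prob:
        return "b_dominates"
    return "tradeoff"


def expected_value(lottery: Lottery) -> float:
    """EV = amount · prob."""
    return lottery.amount * lottery.prob


def delta_ev(problem: ChoiceProblem) -> float:
    """EV difference, option A minus option B."""
    return problem.delta_ev


def enumerate_problems(config: DesignConfig,
                       rng_seed: int = 0) -> list[ChoiceProblem]:
    """All unordered trade-off pairs plus seeded-sampled dominated catch pairs.

    Problem ids are stable across runs: ``T###`` for trade-offs (ordered by
    grid position), ``C###`` for catch trials.
    """
    grid = build_grid(config)
    tradeoffs: list[tuple[Lottery, Lottery]] = []
    dominated: list[tuple[Lottery, Lottery]] = []
    for a, b in itertools.combinations(grid, 2):
        rel = classify_pair(a, b)
        if rel == "tradeoff":
            tradeoffs.append((a, b))
        elif rel in ("a_dominates", "b_dominates"):
            dominated.append((a, b))
    if config.n_catch > len(dominated):
        raise ValueError(
            f"n_catch={config.n_catch} exceeds {len(dominated)} dominated pairs"
        )

    problems = [
        ChoiceProblem(f"T{i:03d}", a, b, classify_pair(a, b))
        for i, (a, b) in enumerate(tradeoffs)
    ]
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(dominated), size=config.n_catch, replace=False)
    for j, i in enumerate(sorted(idx)):
        a, b = dominated[i]
        problems.append(
            ChoiceProblem(f"C{j:03d}", a, b, classify_pair(a, b), is_catch=True)
        )

    if config.problem_subset is not None:
        by_id = {p.id: p for p in problems}
        missing = [pid for pid in config.problem_subset if pid not in by_id]
        if missing:
            raise ValueError(f"unknown problem ids in subset: {missing}")
        problems = [by_id[pid] for pid in config.problem_subset]
    return problems


def risk_classification(problem: ChoiceProblem) -> dict:
    """Identify the riskier option and the probability domain of a trade-off.

    The riskier option is the higher-amount/lower-probability one.  The
    problem is in the ``low`` probability domain when either lottery has
    p < .25, otherwise ``medium_high``.
    """
    if problem.relation != "tradeoff":
        raise ValueError("risk is undefined for non-trade-off pairs")
    a, b = problem.option_a, problem.option_b
    riskier = "A" if a.amount > b.amount else "B"
    domain = "low" if min(a.prob, b.prob) < 0.25 else "medium_high"
    return {"riskier_option": riskier, "probability_domain": domain}


def problems_to_frame(problems: Sequence[ChoiceProblem]) -> pd.DataFrame:
    """Flat table of problems (the CSV interchange schema)."""
    return pd.DataFrame(
        {
            "problem_id": [p.id for p in problems],
            "x_a": [p.option_a.amount for p in problems],
            "p_a": [p.option_a.prob for p in problems],
            "x_b": [p.option_b.amount for p in problems],
            "p_b": [p.option_b.prob for p in problems],
            "relation": [p.relation for p in problems],
            "is_catch": [p.is_catch for p in problems],
        }
    )


def problems_from_frame(df: pd.DataFrame) -> list[ChoiceProblem]:
    required = {"problem_id", "x_a", "p_a", "x_b", "p_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"problem table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        a = Lottery(float(row.x_a), float(row.p_a))
        b = Lottery(float(row.x_b), float(row.p_b))
        is_catch = bool(getattr(row, "is_catch", False))
        out.append(ChoiceProblem(str(row.problem_id), a, b,
                                 classify_pair(a, b), is_catch=is_catch))
    return out
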