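"""Static valuation models: EV/EU/CPT utilities, the Luce choice rule,
deterministic heuristics and gaze-modulated regression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ChoiceProblem, Lottery

GAZE_FLOOR = 1e-3  # zero-gaze floor in the regression models


@dataclass(frozen=True)
class StaticParams:
    """Parameters of the static (non-dynamic) valuation models."""

    alpha: float = 1.0  # utility curvature, u(x) = x^alpha
    gamma: float = 1.0  # probability-weighting curvature
    beta: float = 1.0  # choice sensitivity
    tau: float = 0.0  # gaze saturation exponent

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def utility(x, alpha: float):
    """Power utility u(x) = x^alpha (gains only)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("amounts must be > 0 in this gains-only design")
    return x ** alpha


def prob_weight(p, gamma: float):
    """Inverse-S probability weighting: p^g / (p^g + (1-p)^g)^(1/g)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("probabilities must be in (0, 1]")
    pg = p ** gamma
    return pg / (pg + (1.0 - p) ** gamma) ** (1.0 / gamma)


def subjective_utility(lottery: Lottery, params: StaticParams,
                       model: str = "CPT") -> float:
    """Value of a lottery under EV, EU or CPT."""
    if model == "EV":
        return lottery.amount * lottery.prob
    if model == "EU":
        return float(utility(lottery.amount, params.alpha) * lottery.prob)
    if model == "CPT":
        return float(utility(lottery.amount, params.alpha)
                     * prob_weight(lottery.prob, params.gamma))
    raise ValueError(f"unknown model {model!r}")


def luce_prob(u1, u2, beta: float):
    """P(choose option 1) = 1 / (1 + exp(-beta (u1 - u2)))."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = np.clip(beta * (np.asarray(u1, dtype=float) - np.asarray(u2, dtype=float)),
                -700, 700)
    return 1.0 / (1.0 + np.exp(-z))


def fixation_regression_value(lottery: Lottery, gaze: float,
                              params: StaticParams, base: str = "EU") -> float:
    """Base subjective utility scaled by gaze^tau.

    ``gaze`` is the per-option fixation count (or dwell time in seconds);
    zero gaze is floored at a small epsilon so the value stays positive.
    """
    if gaze < 0:
        raise ValueError("gaze must be >= 0")
    g = max(gaze, GAZE_FLOOR)
    return subjective_utility(lottery, params, base) * g ** params.tau


# --- heuristics ----------------------------------------------------------

#: Probability-of-minimum difference at which the priority heuristic stops.
PH_PROB_CRITERION = 0.1
#: Amount criterion as a fraction of the largest maximum outcome.
PH_AMOUNT_FRACTION = 0.1


def _worst_outcome(l: Lottery) -> tuple[float, float]:
    """(worst outcome, its probability) of a simple (x, p; 0, 1-p) lottery."""
    if l.prob < 1.0:
        return 0.0, 1.0 - l.prob
    return l.amount, 1.0


def heuristic_choice(problem: ChoiceProblem, heuristic: str) -> str:
    """Deterministic heuristic choice: 'A', 'B' or 'indifferent'."""
    a, b = problem.option_a, problem.option_b
    if heuristic == "maximax":
        if a.amount == b.amount:
            return "indifferent"
        return "A" if a.amount > b.amount else "B"

    if heuristic == "least_likely":
        _, pa = _worst_outcome(a)
        _, pb = _worst_outcome(b)
        if pa == pb:
            return "indifferent"
        return "A" if pa < pb else "B"

    if heuristic == "priority":
        min_a, pmin_a = _worst_outcome(a)
        min_b, pmin_b = _worst_outcome(b)
        amount_crit = PH_AMOUNT_FRACTION * max(a.amount, b.amount)
        # 1. minimum gains: prefer the larger minimum
        if abs(min_a - min_b) >= amount_crit and min_a != min_b:
            return "A" if min_a > min_b else "B"
        # 2. probability of the minimum gain: prefer the smaller
        if abs(pmin_a - pmin_b) >= PH_PROB_CRITERION and pmin_a != pmin_b:
            return "A" if pmin_a < pmin_b else "B"
        # 3. maximum gain: prefer the larger
        if a.amount == b.amount:
            return "indifferent"
        return "A" if a.amount > b.amount else "B"

    raise ValueError(f"unknown heuristic {heuristic!r}")
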