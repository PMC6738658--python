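"""Integration-to-boundary layer: boundary families, stochastic trial
termination, and the Monte-Carlo likelihood of (choice, decision time)
conditioned on fixations.

Decision time is counted in fixation steps.  Because every variant's
alternative-level recursion is linear given the fixation sequence
(Y(t+1) = (1-lam) Y(t) + I(t) + sigma eps(t)), noisy trajectories are the
deterministic drive plus leak-filtered Gaussian noise, which lets the
Monte-Carlo paths be simulated in one vectorized pass and reused across
boundary evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .accumulators import ProcessParams, layer2_inputs
from .design import ChoiceProblem, DesignConfig
from .gaze import Trial

MAX_STEPS_DEFAULT = 100

RT_QUANTILE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)


@dataclass(frozen=True)
class BoundaryParams:
    """Decision boundary: fixed, or exponentially collapsing to b_inf."""

    family: str
    b0: float
    b_inf: float = 0.0
    tau_c: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("fixed", "collapsing"):
            raise ValueError(f"unknown boundary family {self.family!r}")
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")
        if self.family == "collapsing":
            if self.b_inf < 0 or self.b_inf > self.b0:
                raise ValueError("need 0 <= b_inf <= b0")
            if self.tau_c <= 0:
                raise ValueError("tau_c must be > 0")


def boundary_value(t, bp: BoundaryParams):
    """Boundary height at fixation step t (t >= 1)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("t must be >= 1")
    if bp.family == "fixed":
        return np.full_like(t, bp.b0)
    return bp.b_inf + (bp.b0 - bp.b_inf) * np.exp(-t / bp.tau_c)


def transition_matrix_from_sequence(aoi_seq: Sequence[int],
                                    smoothing: float = 0.5) -> np.ndarray:
    """Empirical 4x4 AOI transition matrix (zero diagonal, smoothed rows)."""
    m = np.full((4, 4), smoothing)
    np.fill_diagonal(m, 0.0)
    seq = np.asarray(aoi_seq, dtype=np.intp)
    for a, b in zip(seq, seq[1:]):
        if a != b:
            m[a, b] += 1.0
    return m / m.sum(axis=1, keepdims=True)


def extend_sequence(aoi_seq: Sequence[int], target_len: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Extend an AOI sequence to ``target_len`` by resampling its own
    empirical transition statistics (first-order Markov, no repeats)."""
    seq = list(np.asarray(aoi_seq, dtype=np.intp))
    if not seq:
        raise ValueError("cannot extend an empty sequence")
    tm = transition_matrix_from_sequence(seq)
    while len(seq) < target_len:
        seq.append(int(rng.choice(4, p=tm[seq[-1]])))
    return np.asarray(seq[:target_len], dtype=np.intp)


class MarkovFixationSource:
    """Open-ended AOI stream from a first-fixation law and transition matrix."""

    def __init__(self, first_dist: Sequence[float], transition: np.ndarray,
                 rng: np.random.Generator):
        self.first_dist = np.asarray(first_dist, dtype=float)
        self.transition = np.asarray(transition, dtype=float)
        self.rng = rng
        self._last: Optional[int] = None

    def __iter__(self) -> Iterator[int]:
        return self

    def __next__(self) -> int:
        if self._last is None:
            k = int(self.rng.choice(4, p=self.first_dist))
        else:
            k = int(self.rng.choice(4, p=self.transition[self._last]))
        self._last = k
        return k


def simulate_paths(inputs: np.ndarray, lam: float, sigma: float,
                   eps: np.ndarray) -> np.ndarray:
    """Monte-Carlo layer-2 paths from deterministic inputs.

    ``inputs`` is (T, 2); ``eps`` is (M, T, 2) standard normal.  Returns
    Y of shape (M, T, 2) with Y[:, t] the state after step t+1.
    """
    M, T, _ = eps.shape
    keep = 1.0 - lam
    Y = np.empty((M, T, 2))
    state = np.zeros((M, 2))
    for t in range(T):
        state = keep * state + inputs[t] + sigma * eps[:, t]
        Y[:, t] = state
    return Y


def crossing_times(paths: np.ndarray, bounds: np.ndarray,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First boundary crossing of each Monte-Carlo path.

    Returns (t_cross, winner, censored): t_cross counts fixations (1-based,
    undefined where censored); winner is 0/1 (A/B), ties split by coin flip.
    """
    M, T, _ = paths.shape
    ymax = paths.max(axis=2)
    crossed = ymax >= bounds[None, :]
    any_cross = crossed.any(axis=1)
    first = np.where(any_cross, crossed.argmax(axis=1), T - 1)
    at = paths[np.arange(M), first]  # (M, 2)
    winner = (at[:, 1] > at[:, 0]).astype(np.intp)
    ties = at[:, 0] == at[:, 1]
    if ties.any():
        flips = (rng or np.random.default_rng(0)).integers(0, 2, ties.sum())
        winner[ties] = flips
    return first + 1, winner, ~any_cross


def simulate_to_termination(problem: ChoiceProblem, params: ProcessParams,
                            variant: str, bp: BoundaryParams,
                            fixation_source: Iterable[int],
                            rng: np.random.Generator,
                            config: DesignConfig,
                            max_steps: int = MAX_STEPS_DEFAULT) -> dict:
    """Race the accumulators against the boundary along a fixation stream."""
    it = iter(fixation_source)
    aoi_seq = []
    for _ in range(max_steps):
        aoi_seq.append(next(it))
    aoi_seq = np.asarray(aoi_seq, dtype=np.intp)
    inputs = layer2_inputs(problem, aoi_seq, params, variant, config)
    eps = (rng.standard_normal((1, max_steps, 2)) if params.sigma > 0
           else np.zeros((1, max_steps, 2)))
    paths = simulate_paths(inputs, params.lam, params.sigma, eps)
    bounds = boundary_value(np.arange(1, max_steps + 1), bp)
    t_cross, winner, censored = crossing_times(paths, bounds, rng)
    return {
        "choice": "AB"[int(winner[0])],
        "n_fixations": int(t_cross[0]),
        "censored": bool(censored[0]),
        "trace": paths[0],
        "aoi_seq": aoi_seq,
    }


def trial_paths(trial: Trial, params: ProcessParams, variant: str,
                config: DesignConfig, M: int, rng: np.random.Generator,
                max_steps: int = MAX_STEPS_DEFAULT) -> np.ndarray:
    """Monte-Carlo paths for one observed trial, its sequence extended by
    the trial's own transition statistics where needed."""
    if M < 1:
        raise ValueError("M must be >= 1")
    aoi_ext = extend_sequence(trial.aoi_indices, max_steps, rng)
    inputs = layer2_inputs(trial.problem, aoi_ext, params, variant, config)
    eps = rng.standard_normal((M, max_steps, 2))
    return simulate_paths(inputs, params.lam, params.sigma, eps)


def likelihood_from_paths(paths: np.ndarray, bp: BoundaryParams,
                          t_obs: int, choice_obs: int,
                          rng: Optional[np.random.Generator] = None) -> float:
    """Laplace-smoothed P(first crossing at t_obs with the observed winner)."""
    M, T, _ = paths.shape
    bounds = boundary_value(np.arange(1, T + 1), bp)
    t_cross, winner, censored = crossing_times(paths, bounds, rng)
    hits = int(np.sum(~censored & (t_cross == t_obs) & (winner == choice_obs)))
    return (hits + 1) / (M + 2)


def choice_rt_likelihood(trial: Trial, params: ProcessParams, variant: str,
                         bp: BoundaryParams, M: int,
                         rng: np.random.Generator,
                         config: DesignConfig,
                         max_steps: int = MAX_STEPS_DEFAULT) -> float:
    """Monte-Carlo likelihood of the observed (choice, fixation count)."""
    paths = trial_paths(trial, params, variant, config, M, rng, max_steps)
    choice_obs = 0 if trial.choice == "A" else 1
    return likelihood_from_paths(paths, bp, trial.n_fixations, choice_obs, rng)


def vincentized_quantiles(rt_samples: Sequence[Sequence[float]],
                          levels: Sequence[float] = RT_QUANTILE_LEVELS
                          ) -> np.ndarray:
    """Group quantiles: per-participant quantiles averaged across participants."""
    if len(rt_samples) == 0:
        raise ValueError("need at least one participant")
    qs = []
    for samples in rt_samples:
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("empty RT sample")
        qs.append(np.quantile(samples, levels))
    return np.mean(qs, axis=0)
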