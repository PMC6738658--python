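"""Synthetic experiments: participants, fixation sequences, choices and RTs.

The gaze generator is a first-order Markov process over the four AOIs with
no immediate repeats.  Transition weights are set per category (within-
alternative, within-attribute, diagonal) and tilted by per-participant
biases: an overall amount-vs-probability preference, a preference for the
larger amount (and larger probability), and a small value-dependence that
makes an amount AOI more likely to be fixated the higher its own
probability.  Fixation counts are negative-binomial; durations log-normal.

Ground-truth parameters are emitted alongside the data and are never read
by any fitting code path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .accumulators import ProcessParams, run_sequence
from .decision import BoundaryParams, simulate_to_termination
from .design import ChoiceProblem, DesignConfig
from .gaze import AOIS, Fixation, Trial
from .values import luce_prob

#: AOI index of the other attribute of the same option (within-alternative).
_ALT = (1, 0, 3, 2)
#: Same attribute, other option (within-attribute).
_ATTR = (2, 3, 0, 1)
#: Other attribute of the other option (diagonal).
_DIAG = (3, 2, 1, 0)


@dataclass(frozen=True)
class GazeModelParams:
    """Statistical model of one participant's fixation behavior."""

    first_fix_dist: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    w_alt: float = 1.0    # within-alternative transition weight
    w_attr: float = 0.55  # within-attribute transition weight
    w_diag: float = 0.27  # diagonal transition weight
    amount_pref: float = 0.0       # log-weight tilt toward amount AOIs
    high_amount_bias: float = 0.0  # log-weight tilt toward the larger amount
    high_prob_bias: float = 0.0    # log-weight tilt toward the larger probability
    value_dependence: float = 0.0  # amount weight grows with its own probability
    return_penalty: float = 0.25  # weight multiplier for revisiting the AOI
                                  # fixated two steps back (inhibition of return)
    unseen_boost: float = 3.0     # weight multiplier for AOIs not yet fixated
                                  # this trial (drives four-AOI coverage)
    count_mean: float = 9.05
    count_sd: float = 3.56
    min_count: int = 4
    duration_mean_ms: float = 407.0
    duration_sd_ms: float = 244.0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.first_fix_dist), 1.0):
            raise ValueError("first_fix_dist must sum to 1")
        if min(self.w_alt, self.w_attr, self.w_diag) < 0:
            raise ValueError("category weights must be >= 0")
        if self.count_mean < 1 or self.min_count < 1:
            raise ValueError("fixation counts must be >= 1")


@dataclass(frozen=True)
class SimParticipant:
    id: str
    process: ProcessParams
    gaze: GazeModelParams
    variant: str = "two_layer"


def aoi_weight_factors(problem: ChoiceProblem, gp: GazeModelParams) -> np.ndarray:
    """Multiplicative AOI attractiveness (4,) for one problem."""
    a, b = problem.option_a, problem.option_b
    f = np.ones(4)
    f[[0, 2]] *= np.exp(gp.amount_pref)
    if a.amount != b.amount and gp.high_amount_bias:
        hi = 0 if a.amount > b.amount else 2
        f[hi] *= np.exp(gp.high_amount_bias)
        f[2 - hi] *= np.exp(-gp.high_amount_bias)
    if a.prob != b.prob and gp.high_prob_bias:
        hi = 1 if a.prob > b.prob else 3
        f[hi] *= np.exp(gp.high_prob_bias)
        f[4 - hi] *= np.exp(-gp.high_prob_bias)
    if gp.value_dependence:
        pbar = (a.prob + b.prob) / 2.0
        f[0] *= max(1.0 + gp.value_dependence * (a.prob - pbar), 1e-6)
        f[2] *= max(1.0 + gp.value_dependence * (b.prob - pbar), 1e-6)
    return f


def transition_matrix(problem: ChoiceProblem, gp: GazeModelParams) -> np.ndarray:
    """Row-stochastic 4x4 AOI transition matrix (zero diagonal)."""
    f = aoi_weight_factors(problem, gp)
    m = np.zeros((4, 4))
    for k in range(4):
        m[k, _ALT[k]] = gp.w_alt * f[_ALT[k]]
        m[k, _ATTR[k]] = gp.w_attr * f[_ATTR[k]]
        m[k, _DIAG[k]] = gp.w_diag * f[_DIAG[k]]
        m[k] /= m[k].sum()
    return m


def first_fixation_dist(problem: ChoiceProblem, gp: GazeModelParams) -> np.ndarray:
    d = np.asarray(gp.first_fix_dist) * aoi_weight_factors(problem, gp)
    return d / d.sum()


def _sample_count(gp: GazeModelParams, rng: np.random.Generator) -> int:
    m, var = gp.count_mean, gp.count_sd ** 2
    if var > m:  # negative binomial matching both moments
        r = m * m / (var - m)
        n = rng.negative_binomial(r, r / (r + m))
    else:
        n = rng.poisson(m)
    return max(int(n), gp.min_count)


def _sample_durations(n: int, gp: GazeModelParams,
                      rng: np.random.Generator) -> np.ndarray:
    mu_ln = np.log(gp.duration_mean_ms ** 2
                   / np.sqrt(gp.duration_mean_ms ** 2 + gp.duration_sd_ms ** 2))
    sd_ln = np.sqrt(np.log(1 + (gp.duration_sd_ms / gp.duration_mean_ms) ** 2))
    return np.maximum(rng.lognormal(mu_ln, sd_ln, size=n), 50.0)


def _next_aoi(prev2: Optional[int], prev: int, tm: np.ndarray,
              gp: GazeModelParams, rng: np.random.Generator,
              seen: Optional[np.ndarray] = None) -> int:
    w = tm[prev].copy()
    if prev2 is not None:  # inhibition of return: avoid ping-pong revisits
        w[prev2] *= gp.return_penalty
    if seen is not None and not seen.all():
        w[~seen] *= gp.unseen_boost
    return int(rng.choice(4, p=w / w.sum()))


def sample_gaze_sequence(problem: ChoiceProblem, gp: GazeModelParams,
                         rng: np.random.Generator,
                         n_fixations: Optional[int] = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One trial's AOI sequence (indices) and fixation durations (ms)."""
    n = n_fixations if n_fixations is not None else _sample_count(gp, rng)
    tm = transition_matrix(problem, gp)
    seq = np.empty(n, dtype=np.intp)
    seen = np.zeros(4, dtype=bool)
    seq[0] = rng.choice(4, p=first_fixation_dist(problem, gp))
    seen[seq[0]] = True
    for t in range(1, n):
        prev2 = int(seq[t - 2]) if t >= 2 else None
        seq[t] = _next_aoi(prev2, int(seq[t - 1]), tm, gp, rng, seen)
        seen[seq[t]] = True
    return seq, _sample_durations(n, gp, rng)


def make_gaze_sampler(gp: GazeModelParams) -> Callable:
    """Bind gaze params into a ``(problem, rng) -> (aoi_seq, durations)``."""
    return lambda problem, rng: sample_gaze_sequence(problem, gp, rng)


def fixation_source(problem: ChoiceProblem, gp: GazeModelParams,
                    rng: np.random.Generator):
    """Open-ended AOI stream for boundary-crossing simulation (same law as
    :func:`sample_gaze_sequence`)."""
    tm = transition_matrix(problem, gp)
    first = first_fixation_dist(problem, gp)

    def stream():
        prev2 = None
        seen = np.zeros(4, dtype=bool)
        prev = int(rng.choice(4, p=first))
        seen[prev] = True
        yield prev
        while True:
            nxt = _next_aoi(prev2, prev, tm, gp, rng, seen)
            seen[nxt] = True
            prev2, prev = prev, nxt
            yield nxt

    return stream()


#: Per-parameter (low, high) ranges for heterogeneous populations.
DEFAULT_POPULATION: dict[str, tuple[float, float]] = {
    "alpha": (0.4, 1.1),
    "gamma": (0.3, 1.2),
    "theta": (0.1, 0.9),
    "lam": (0.25, 0.85),
    "beta": (0.25, 1.2),
    "w_attr": (0.3, 0.9),
    "w_diag": (0.1, 0.45),
    "amount_pref": (-0.4, 0.4),
    "high_amount_bias": (-0.6, 0.6),
    "high_prob_bias": (-0.4, 0.4),
    "value_dependence": (0.0, 0.05),
}


#: Population for individual-difference analyses: fixed group-mean process
#: parameters, heterogeneous gaze biases, and an engagement trait coupling
#: systematic scanning with choice consistency (see sample_participant).
INDIVIDUAL_DIFFERENCES_POPULATION: dict[str, tuple[float, float]] = {
    "alpha": (0.75, 0.75), "gamma": (0.65, 0.65), "theta": (0.2, 0.2),
    "lam": (0.58, 0.58), "beta": (0.3, 3.0),
    "w_attr": (0.15, 1.4), "w_diag": (0.1, 0.8),
    "high_amount_bias": (-0.7, 0.7), "high_prob_bias": (-0.25, 0.25),
    "amount_pref": (-0.3, 0.3), "value_dependence": (0.0, 0.0),
}

ENGAGEMENT_COUPLING_DEFAULT = 0.9


def sample_participant(population: dict[str, tuple[float, float]],
                       rng: np.random.Generator, pid: str = "sim000",
                       variant: str = "two_layer",
                       sigma: float = 0.0,
                       engagement_coupling: float = 0.0) -> SimParticipant:
    """Draw one participant's process and gaze parameters uniformly.

    ``engagement_coupling`` in [0, 1] introduces a latent engagement trait
    that couples systematic within-alternative scanning (low within-attribute
    and diagonal weights) with consistent choices (high beta), reproducing
    the empirically observed covariation between scan patterns and choice
    quality.  0 leaves all draws independent.
    """
    pop = {**DEFAULT_POPULATION, **population}
    c = engagement_coupling
    if not 0 <= c <= 1:
        raise ValueError("engagement_coupling must be in [0, 1]")
    e = rng.uniform()  # latent engagement
    draw = {}
    for k, (lo, hi) in pop.items():
        u = rng.uniform()
        if c:
            if k in ("w_attr", "w_diag"):
                u = (1 - c) * u + c * (1 - e)
            elif k == "beta":
                u = (1 - c) * u + c * e
        draw[k] = float(lo + (hi - lo) * u)
    process = ProcessParams(alpha=draw["alpha"], gamma=draw["gamma"],
                            theta=draw["theta"], lam=draw["lam"],
                            beta=draw["beta"], sigma=sigma)
    gaze_keys = ("w_attr", "w_diag", "amount_pref", "high_amount_bias",
                 "high_prob_bias", "value_dependence")
    gaze = GazeModelParams(**{k: draw[k] for k in gaze_keys if k in draw})
    return SimParticipant(id=pid, process=process, gaze=gaze, variant=variant)


def simulate_choices_step1(problems: Sequence[ChoiceProblem],
                           params: dict | ProcessParams, variant: str,
                           config: DesignConfig, gaze_sampler: Callable,
                           rng: np.random.Generator,
                           participant_id: str = "sim000") -> list[Trial]:
    """Step-1 generative mode: full sequences, Luce choice at sequence end."""
    if isinstance(params, dict):
        params = ProcessParams(**{k: v for k, v in params.items()
                                  if k in ProcessParams.__dataclass_fields__})
    trials = []
    for j, prob in enumerate(problems):
        seq, durs = gaze_sampler(prob, rng)
        res = run_sequence(prob, seq, params, variant, config)
        p_a = luce_prob(res["Y_A"], res["Y_B"], params.beta)
        choice = "A" if rng.random() < p_a else "B"
        onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        fixations = tuple(Fixation(AOIS[k], float(o), float(d))
                          for k, o, d in zip(seq, onsets, durs))
        trials.append(Trial(problem=prob, fixations=fixations, choice=choice,
                            rt=float(durs.sum()), participant_id=participant_id,
                            trial_id=f"{participant_id}_t{j:03d}"))
    return trials


def simulate_trials_step2(problems: Sequence[ChoiceProblem],
                          participant: SimParticipant, config: DesignConfig,
                          boundary: BoundaryParams,
                          rng: np.random.Generator,
                          max_steps: int = 100) -> list[Trial]:
    """Step-2 generative mode: accumulate with noise to boundary crossing."""
    proc = participant.process
    if proc.sigma <= 0:
        proc = ProcessParams(**{**proc.__dict__, "sigma": 1.0})
    trials = []
    for j, prob in enumerate(problems):
        src = fixation_source(prob, participant.gaze, rng)
        res = simulate_to_termination(prob, proc, participant.variant,
                                      boundary, src, rng, config, max_steps)
        n = res["n_fixations"]
        seq = res["aoi_seq"][:n]
        durs = _sample_durations(n, participant.gaze, rng)
        onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        fixations = tuple(Fixation(AOIS[k], float(o), float(d))
                          for k, o, d in zip(seq, onsets, durs))
        trials.append(Trial(problem=prob, fixations=fixations,
                            choice=res["choice"], rt=float(durs.sum()),
                            participant_id=participant.id,
                            trial_id=f"{participant.id}_t{j:03d}"))
    return trials


def trials_to_frames(trials: Sequence[Trial]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(trial table, fixation table) in the empirical CSV schema."""
    trows, frows = [], []
    for t in trials:
        trows.append({"participant_id": t.participant_id,
                      "trial_id": t.trial_id,
                      "problem_id": t.problem.id, "choice": t.choice,
                      "rt_ms": t.rt})
        for f in t.fixations:
            frows.append({"participant_id": t.participant_id,
                          "trial_id": t.trial_id, "aoi": f.aoi,
                          "onset_ms": f.onset, "duration_ms": f.duration})
    return pd.DataFrame(trows), pd.DataFrame(frows)


def simulate_experiment(problems: Sequence[ChoiceProblem],
                        config: DesignConfig, n_participants: int,
                        rng: np.random.Generator,
                        population: Optional[dict] = None,
                        variant: str = "two_layer", mode: str = "step1",
                        boundary: Optional[BoundaryParams] = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full synthetic experiment.

    Returns (trial table, fixation table, ground truth).  Ground truth maps
    participant id to generative parameters and is written separately from
    the data so fitting code never touches it.
    """
    population = population or {}
    all_trials: list[Trial] = []
    truth: dict[str, dict] = {}
    for i in range(n_participants):
        pid = f"sim{i:03d}"
        part = sample_participant(population, rng, pid=pid, variant=variant)
        if mode == "step1":
            trials = simulate_choices_step1(
                problems, part.process, variant, config,
                make_gaze_sampler(part.gaze), rng, participant_id=pid)
        elif mode == "step2":
            bp = boundary or BoundaryParams("fixed", 50.0)
            trials = simulate_trials_step2(problems, part, config, bp, rng)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        all_trials.extend(trials)
        truth[pid] = {"process": asdict(part.process),
                      "gaze": asdict(part.gaze), "variant": variant,
                      "mode": mode}
    trial_df, fix_df = trials_to_frames(all_trials)
    return trial_df, fix_df, truth
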