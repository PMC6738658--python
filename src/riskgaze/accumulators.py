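"""Gaze-driven leaky-accumulation dynamics.

Five variants share one stepping interface.  Each fixation updates a pair of
alternative-level accumulators (Y_A, Y_B); the two-layer variants interpose
four attribute-level leaky accumulators whose paired products feed the
alternative layer.

Variants
--------
``wa_normalized``
    accumulate min-max-normalized differences of the fixated attribute.
``wa_categorical``
    accumulate unit counts from categorical comparisons of the fixated
    attribute.
``one_layer``
    accumulate the CPT-style subjective utility of each alternative, the
    unfixated alternative attenuated by theta.
``two_layer``
    attribute-level accumulators receive attentionally weighted subjective
    values; alternative accumulators integrate the product of their pair.
``hybrid``
    two_layer plus mutual inhibition (iota) between same-attribute units,
    activations rectified at 0.

Attributes not yet fixated enter as mid-range defaults until their first
fixation, in all variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .design import ChoiceProblem, DesignConfig
from .gaze import PAIRED_AOI, Trial
from .values import luce_prob, prob_weight, utility

VARIANTS = ("wa_normalized", "wa_categorical", "one_layer", "two_layer", "hybrid")
#: Variants that use the four attribute-level (layer-1) accumulators.
LAYERED_VARIANTS = ("two_layer", "hybrid")

_PAIR = np.array(PAIRED_AOI)


@dataclass(frozen=True)
class ProcessParams:
    """Free parameters of the accumulation process."""

    alpha: float = 1.0  # utility curvature
    gamma: float = 1.0  # probability-weighting curvature
    theta: float = 0.5  # attentional attenuation of unfixated inputs
    lam: float = 0.0  # leak: accumulators decay by (1 - lam) per step
    beta: float = 1.0  # choice sensitivity (Luce rule)
    iota: float = 0.0  # mutual inhibition (hybrid only)
    sigma: float = 0.0  # per-step Gaussian noise on layer-2 accumulators

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must be in [0, 1]")
        if self.iota < 0 or self.sigma < 0 or self.beta < 0:
            raise ValueError("iota, sigma, beta must be >= 0")


@dataclass
class AttributeInputs:
    """Per-attribute input values with default substitution.

    ``raw_true`` holds the problem's actual attribute values in AOI order
    (x_a, p_a, x_b, p_b); ``raw_default`` the mid-range defaults.  ``seen``
    flags attributes whose first fixation has occurred (the fixated
    attribute's true value applies from the fixation that reaches it).
    """

    raw_true: np.ndarray
    raw_default: np.ndarray
    seen: np.ndarray
    amount_range: tuple[float, float]
    prob_range: tuple[float, float]

    def raw(self) -> np.ndarray:
        return np.where(self.seen, self.raw_true, self.raw_default)

    def subjective(self, alpha: float, gamma: float) -> np.ndarray:
        v = self.raw()
        out = np.empty(4)
        out[[0, 2]] = utility(v[[0, 2]], alpha)
        out[[1, 3]] = prob_weight(v[[1, 3]], gamma)
        return out

    def normalized(self) -> np.ndarray:
        v = self.raw()
        a_lo, a_hi = self.amount_range
        p_lo, p_hi = self.prob_range
        out = np.empty(4)
        out[[0, 2]] = (v[[0, 2]] - a_lo) / (a_hi - a_lo)
        out[[1, 3]] = (v[[1, 3]] - p_lo) / (p_hi - p_lo)
        return out


@dataclass
class AccumulatorState:
    layer1: np.ndarray = field(default_factory=lambda: np.zeros(4))
    layer2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    step: int = 0


def init_inputs(problem: ChoiceProblem,
                config: DesignConfig) -> AttributeInputs:
    """Inputs with every attribute at its mid-range default (nothing seen)."""
    a, b = problem.option_a, problem.option_b
    return AttributeInputs(
        raw_true=np.array([a.amount, a.prob, b.amount, b.prob]),
        raw_default=np.array([config.amount_default, config.prob_default,
                              config.amount_default, config.prob_default]),
        seen=np.zeros(4, dtype=bool),
        amount_range=config.amount_range,
        prob_range=config.prob_range,
    )


def step(state: AccumulatorState, fixation_aoi: int, inputs: AttributeInputs,
         params: ProcessParams, variant: str,
         noise_draws: Optional[np.ndarray] = None) -> AccumulatorState:
    """Advance the accumulators by one fixation.

    ``inputs.seen`` must already include the current fixation.  ``noise_draws``
    (2,) are standard-normal deviates scaled by sigma and added to the
    updated layer-2 accumulators.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if not inputs.seen[fixation_aoi]:
        raise ValueError("inputs.seen must include the current fixation")
    th, lam = params.theta, params.lam
    keep = 1.0 - lam
    fix_option = 0 if fixation_aoi < 2 else 1
    other = 1 - fix_option
    Y = keep * state.layer2
    layer1 = state.layer1

    if variant in ("two_layer", "hybrid"):
        s = inputs.subjective(params.alpha, params.gamma)
        w = np.full(4, th)
        w[fixation_aoi] = 1.0
        a = keep * state.layer1 + w * s
        if variant == "hybrid":
            a = a - params.iota * state.layer1[_PAIR]
            a = np.maximum(a, 0.0)
        layer1 = a
        Y = Y + np.array([a[0] * a[1], a[2] * a[3]])
    elif variant == "one_layer":
        s = inputs.subjective(params.alpha, params.gamma)
        su = np.array([s[0] * s[1], s[2] * s[3]])
        w = np.full(2, th)
        w[fix_option] = 1.0
        Y = Y + w * su
    elif variant == "wa_normalized":
        v = inputs.normalized()
        d = v[fixation_aoi] - th * v[_PAIR[fixation_aoi]]
        inc = np.zeros(2)
        inc[fix_option], inc[other] = d, -d
        Y = Y + inc
    else:  # wa_categorical
        v = inputs.raw()
        vf, vo = v[fixation_aoi], v[_PAIR[fixation_aoi]]
        inc = np.zeros(2)
        if vf > th * vo:
            inc[fix_option] = 1.0
        elif vf < th * vo:
            inc[other] = 1.0
        Y = Y + inc

    if noise_draws is not None and params.sigma > 0:
        Y = Y + params.sigma * np.asarray(noise_draws)
    return AccumulatorState(layer1=layer1, layer2=Y, step=state.step + 1)


def run_sequence(problem: ChoiceProblem, aoi_seq: Sequence[int],
                 params: ProcessParams, variant: str, config: DesignConfig,
                 rng: Optional[np.random.Generator] = None,
                 default_substitution: bool = True) -> dict:
    """Run the accumulators over a fixation sequence.

    Returns the final preferences and a trace with per-step layer-1 and
    layer-2 activations.  When ``default_substitution`` is off, true values
    apply from the first step (used by closed-form checks).
    """
    aoi_seq = np.asarray(aoi_seq, dtype=np.intp)
    if aoi_seq.size == 0:
        raise ValueError("empty fixation sequence")
    inputs = init_inputs(problem, config)
    if not default_substitution:
        inputs.seen[:] = True
    state = AccumulatorState()
    trace_l1 = np.empty((aoi_seq.size, 4))
    trace_l2 = np.empty((aoi_seq.size, 2))
    for t, k in enumerate(aoi_seq):
        inputs.seen[k] = True
        draws = rng.standard_normal(2) if (rng is not None and params.sigma > 0) else None
        state = step(state, int(k), inputs, params, variant, draws)
        trace_l1[t] = state.layer1
        trace_l2[t] = state.layer2
    return {
        "Y_A": float(state.layer2[0]),
        "Y_B": float(state.layer2[1]),
        "trace_layer1": trace_l1,
        "trace_layer2": trace_l2,
        "aoi_seq": aoi_seq,
    }


def run_trial(trial: Trial, params: ProcessParams, variant: str,
              config: DesignConfig, **kw) -> dict:
    return run_sequence(trial.problem, trial.aoi_indices, params, variant,
                        config, **kw)


def choice_prob_from_final(y_a: float, y_b: float, beta: float) -> float:
    """Luce choice probability of option A from final accumulator states."""
    return float(luce_prob(y_a, y_b, beta))


def layer2_inputs(problem: ChoiceProblem, aoi_seq: Sequence[int],
                  params: ProcessParams, variant: str,
                  config: DesignConfig) -> np.ndarray:
    """Deterministic per-step layer-2 inputs I(t), shape (T, 2).

    The layer-2 recursion is Y(t+1) = (1-lam) Y(t) + I(t) (+ sigma eps) for
    every variant, so noisy trajectories decompose into this deterministic
    drive plus leak-filtered noise; the decision-time machinery relies on
    that decomposition.
    """
    res = run_sequence(problem, aoi_seq, replace(params, sigma=0.0),
                       variant, config)
    y = res["trace_layer2"]
    prev = np.vstack([np.zeros(2), y[:-1]])
    return y - (1.0 - params.lam) * prev


# --- vectorized batch evaluation (used by the fitting routines) -----------

@dataclass
class TrialBatch:
    """Array view of a participant's trials for fast likelihood evaluation."""

    aoi: np.ndarray       # (n, T) AOI indices, -1 padded
    n_fix: np.ndarray     # (n,)
    raw: np.ndarray       # (n, 4) x_a, p_a, x_b, p_b
    seen: np.ndarray      # (n, T, 4) attribute fixated at or before step t
    choice: np.ndarray    # (n,) 0 = A, 1 = B
    counts: np.ndarray    # (n, 2) fixations per option
    dwell: np.ndarray     # (n, 2) dwell seconds per option
    delta_ev: np.ndarray  # (n,)
    config: DesignConfig

    @property
    def n_trials(self) -> int:
        return self.aoi.shape[0]


def make_batch(trials: Sequence[Trial], config: DesignConfig) -> TrialBatch:
    n = len(trials)
    n_fix = np.array([t.n_fixations for t in trials], dtype=np.intp)
    T = int(n_fix.max())
    aoi = np.full((n, T), -1, dtype=np.intp)
    seen = np.zeros((n, T, 4), dtype=bool)
    counts = np.zeros((n, 2))
    dwell = np.zeros((n, 2))
    raw = np.empty((n, 4))
    choice = np.empty(n, dtype=np.intp)
    dev = np.empty(n)
    for i, tr in enumerate(trials):
        idx = tr.aoi_indices
        aoi[i, : idx.size] = idx
        s = np.zeros(4, dtype=bool)
        for t, k in enumerate(idx):
            s[k] = True
            seen[i, t] = s
        opt = (idx >= 2).astype(int)
        np.add.at(counts[i], opt, 1)
        np.add.at(dwell[i], opt,
                  np.array([f.duration for f in tr.fixations]) / 1000.0)
        p = tr.problem
        raw[i] = (p.option_a.amount, p.option_a.prob,
                  p.option_b.amount, p.option_b.prob)
        choice[i] = 0 if tr.choice == "A" else 1
        dev[i] = p.delta_ev
    return TrialBatch(aoi=aoi, n_fix=n_fix, raw=raw, seen=seen, choice=choice,
                      counts=counts, dwell=dwell, delta_ev=dev, config=config)


def batch_final_states(batch: TrialBatch, params: ProcessParams,
                       variant: str) -> np.ndarray:
    """Final (Y_A, Y_B) for every trial in the batch; matches run_sequence."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    cfg = batch.config
    n, T = batch.aoi.shape
    th, lam = params.theta, params.lam
    keep = 1.0 - lam
    rows = np.arange(n)

    raw_def = np.array([cfg.amount_default, cfg.prob_default,
                        cfg.amount_default, cfg.prob_default])
    if variant in ("two_layer", "hybrid", "one_layer"):
        s_true = np.empty_like(batch.raw)
        s_true[:, [0, 2]] = utility(batch.raw[:, [0, 2]], params.alpha)
        s_true[:, [1, 3]] = prob_weight(batch.raw[:, [1, 3]], params.gamma)
        s_def = np.empty(4)
        s_def[[0, 2]] = utility(raw_def[[0, 2]], params.alpha)
        s_def[[1, 3]] = prob_weight(raw_def[[1, 3]], params.gamma)
        vals_true, vals_def = s_true, s_def
    elif variant == "wa_normalized":
        a_lo, a_hi = cfg.amount_range
        p_lo, p_hi = cfg.prob_range
        vals_true = np.empty_like(batch.raw)
        vals_true[:, [0, 2]] = (batch.raw[:, [0, 2]] - a_lo) / (a_hi - a_lo)
        vals_true[:, [1, 3]] = (batch.raw[:, [1, 3]] - p_lo) / (p_hi - p_lo)
        vals_def = np.empty(4)
        vals_def[[0, 2]] = (raw_def[[0, 2]] - a_lo) / (a_hi - a_lo)
        vals_def[[1, 3]] = (raw_def[[1, 3]] - p_lo) / (p_hi - p_lo)
    else:
        vals_true, vals_def = batch.raw, raw_def

    Y = np.zeros((n, 2))
    a = np.zeros((n, 4))
    for t in range(T):
        active = t < batch.n_fix
        k = np.where(active, batch.aoi[:, t], 0)
        v = np.where(batch.seen[:, t], vals_true, vals_def)
        fixA = k < 2
        Y_new = keep * Y
        if variant in ("two_layer", "hybrid"):
            w = np.full((n, 4), th)
            w[rows, k] = 1.0
            a_new = keep * a + w * v
            if variant == "hybrid":
                a_new = np.maximum(a_new - params.iota * a[:, _PAIR], 0.0)
            Y_new[:, 0] += a_new[:, 0] * a_new[:, 1]
            Y_new[:, 1] += a_new[:, 2] * a_new[:, 3]
            a = np.where(active[:, None], a_new, a)
        elif variant == "one_layer":
            su = np.stack([v[:, 0] * v[:, 1], v[:, 2] * v[:, 3]], axis=1)
            w = np.full((n, 2), th)
            w[rows, np.where(fixA, 0, 1)] = 1.0
            Y_new += w * su
        else:
            vf = v[rows, k]
            vo = v[rows, _PAIR[k]]
            if variant == "wa_normalized":
                d = vf - th * vo  # fixated option's accumulator gains d
            else:  # categorical: winner (if any) gains one unit
                d = (vf > th * vo).astype(float) - (vf < th * vo).astype(float)
            inc_fix = d if variant == "wa_normalized" else np.maximum(d, 0.0)
            inc_oth = -d if variant == "wa_normalized" else np.maximum(-d, 0.0)
            Y_new[:, 0] += np.where(fixA, inc_fix, inc_oth)
            Y_new[:, 1] += np.where(fixA, inc_oth, inc_fix)
        Y = np.where(active[:, None], Y_new, Y)
    return Y
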