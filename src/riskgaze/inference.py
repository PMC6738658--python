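"""Two-step maximum-likelihood fitting and model comparison.

Step 1 fits each model's parameters to choices alone (noise-free final
accumulator states, Luce likelihood).  Step 2 freezes those parameters and
fits boundary parameters to the joint (choice, decision-time) Monte-Carlo
likelihood.  Model comparison uses AIC, prediction accuracy and stratified
k-fold cross-validation; deterministic heuristics are scored by accuracy
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import decision as dec
from .accumulators import (ProcessParams, TrialBatch, batch_final_states,
                           make_batch)
from .design import DesignConfig
from .gaze import Trial
from .values import GAZE_FLOOR, heuristic_choice, luce_prob, prob_weight, utility

log = logging.getLogger(__name__)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 2.0),
    "gamma": (0.2, 2.0),
    "theta": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "iota": (0.0, 1.0),
    "tau": (0.0, 2.0),
}

HEURISTICS = ("maximax", "least_likely", "priority")


@dataclass(frozen=True)
class ModelSpec:
    """A fittable choice model: static valuation or accumulator process."""

    name: str
    kind: str  # "static" | "process"
    param_names: tuple[str, ...]
    variant: Optional[str] = None  # accumulator variant (process models)
    base: Optional[str] = None     # EV / EU / CPT (static models)
    gaze_mode: Optional[str] = None  # None / "count" / "dwell"

    @property
    def k(self) -> int:
        return len(self.param_names)


MODELS: dict[str, ModelSpec] = {
    "EV": ModelSpec("EV", "static", ("beta",), base="EV"),
    "EU": ModelSpec("EU", "static", ("alpha", "beta"), base="EU"),
    "CPT": ModelSpec("CPT", "static", ("alpha", "gamma", "beta"), base="CPT"),
    "EU_fix": ModelSpec("EU_fix", "static", ("alpha", "tau", "beta"),
                        base="EU", gaze_mode="count"),
    "CPT_fix": ModelSpec("CPT_fix", "static", ("alpha", "gamma", "tau", "beta"),
                         base="CPT", gaze_mode="count"),
    "EU_dwell": ModelSpec("EU_dwell", "static", ("alpha", "tau", "beta"),
                          base="EU", gaze_mode="dwell"),
    "CPT_dwell": ModelSpec("CPT_dwell", "static", ("alpha", "gamma", "tau", "beta"),
                           base="CPT", gaze_mode="dwell"),
    "wa_normalized": ModelSpec("wa_normalized", "process",
                               ("theta", "lam", "beta"), variant="wa_normalized"),
    "wa_categorical": ModelSpec("wa_categorical", "process",
                                ("theta", "lam", "beta"), variant="wa_categorical"),
    "one_layer": ModelSpec("one_layer", "process",
                           ("alpha", "gamma", "theta", "lam", "beta"),
                           variant="one_layer"),
    "two_layer": ModelSpec("two_layer", "process",
                           ("alpha", "gamma", "theta", "lam", "beta"),
                           variant="two_layer"),
    "hybrid": ModelSpec("hybrid", "process",
                        ("alpha", "gamma", "theta", "lam", "beta", "iota"),
                        variant="hybrid"),
}

#: The Step-1 comparison set (Table-style model table).
COMPARISON_MODELS = ("EV", "EU", "CPT", "EU_fix", "CPT_fix",
                     "wa_normalized", "wa_categorical", "one_layer", "two_layer")


@dataclass
class FitResult:
    participant_id: str
    model_id: str
    params: dict[str, float]
    loglik: float
    aic: float
    accuracy: float
    n_trials: int
    cv_neg2ll: Optional[float] = None
    cv_accuracy: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 loglik."""
    return 2.0 * k - 2.0 * loglik


def _static_values(batch: TrialBatch, spec: ModelSpec,
                   params: dict[str, float]) -> np.ndarray:
    """Option values (n, 2) for a static model."""
    x = batch.raw[:, [0, 2]]
    p = batch.raw[:, [1, 3]]
    u = x if spec.base == "EV" else utility(x, params["alpha"])
    w = prob_weight(p, params["gamma"]) if spec.base == "CPT" else p
    vals = u * w
    if spec.gaze_mode is not None:
        gaze = batch.counts if spec.gaze_mode == "count" else batch.dwell
        vals = vals * np.maximum(gaze, GAZE_FLOOR) ** params["tau"]
    return vals


def model_choice_probs(batch: TrialBatch, spec: ModelSpec,
                       params: dict[str, float]) -> np.ndarray:
    """P(choose A) per trial under a model at given parameters."""
    if spec.kind == "static":
        vals = _static_values(batch, spec, params)
    else:
        pp = ProcessParams(**{k: params.get(k, d) for k, d in
                              [("alpha", 1.0), ("gamma", 1.0), ("theta", 0.5),
                               ("lam", 0.0), ("beta", 1.0), ("iota", 0.0)]},
                           sigma=0.0)
        vals = batch_final_states(batch, pp, spec.variant)
    return np.asarray(luce_prob(vals[:, 0], vals[:, 1], params["beta"]))


def _neg_loglik(batch: TrialBatch, spec: ModelSpec, params: dict[str, float],
                lapse: float = 0.0) -> float:
    p_a = model_choice_probs(batch, spec, params)
    if lapse:
        p_a = lapse / 2.0 + (1.0 - lapse) * p_a
    p_chosen = np.where(batch.choice == 0, p_a, 1.0 - p_a)
    return -float(np.sum(np.log(np.clip(p_chosen, 1e-300, None))))


def prediction_accuracy(p_a: np.ndarray, choice: np.ndarray) -> float:
    """Fraction of trials on which the chosen option is the modal prediction;
    exact P = .5 scores half."""
    p_chosen = np.where(choice == 0, p_a, 1.0 - p_a)
    return float(np.mean((p_chosen > 0.5) + 0.5 * (p_chosen == 0.5)))


#: Random probe points evaluated before local optimization.
N_PROBE = 192

def _starts(spec: ModelSpec, bounds: dict, n_starts: int,
            rng: np.random.Generator, nll: Callable[[np.ndarray], float],
            extra: Sequence[np.ndarray] = (),
            probe_extras: Sequence[np.ndarray] = ()) -> list[np.ndarray]:
    """Start points: the neutral point, any warm starts, and the best of a
    cheap probe of the parameter box (random points plus ``probe_extras``)."""
    lo = np.array([bounds[p][0] for p in spec.param_names])
    hi = np.array([bounds[p][1] for p in spec.param_names])
    neutral = {"alpha": 1.0, "gamma": 1.0, "theta": 0.5, "lam": 0.3,
               "beta": 1.0, "tau": 0.5, "iota": 0.1}
    pts = [np.array([neutral[p] for p in spec.param_names])]
    pts += [np.clip(np.asarray(e, dtype=float), lo, hi) for e in extra]
    n_probe_starts = max(0, n_starts - len(pts))
    if n_probe_starts:
        probes = lo + (hi - lo) * rng.random((N_PROBE, len(lo)))
        if len(probe_extras):
            extras = np.clip(np.asarray(probe_extras, dtype=float), lo, hi)
            probes = np.vstack([probes, extras])
        scores = [nll(p) for p in probes]
        pts += [probes[i] for i in np.argsort(scores)[:n_probe_starts]]
    return pts


def fit_choice(trials: Sequence[Trial], model: str | ModelSpec,
               config: DesignConfig, n_starts: int = 10, seed: int = 0,
               bounds: Optional[dict] = None,
               batch: Optional[TrialBatch] = None,
               extra_starts: Sequence[np.ndarray] = (),
               probe_extras: Sequence[np.ndarray] = (),
               fixed: Optional[dict[str, float]] = None,
               lapse: float = 0.0) -> FitResult:
    """Step-1 fit: maximize the choice log-likelihood over model parameters.

    Multi-start bounded L-BFGS-B; deterministic given ``seed``.  Parameters
    named in ``fixed`` are clamped and excluded from the free vector (and
    from the parameter count used for AIC).
    """
    spec = MODELS[model] if isinstance(model, str) else model
    if batch is None:
        batch = make_batch(trials, config)
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    rng = np.random.default_rng(seed)
    fixed = fixed or {}
    names = tuple(p for p in spec.param_names if p not in fixed)
    if not names:
        raise ValueError("no free parameters")
    free_spec = ModelSpec(spec.name, spec.kind, names, variant=spec.variant,
                          base=spec.base, gaze_mode=spec.gaze_mode) \
        if fixed else spec

    def nll_vec(v: np.ndarray) -> float:
        return _neg_loglik(batch, spec, {**fixed, **dict(zip(names, v))},
                           lapse=lapse)

    if spec.kind == "process" and {"alpha", "gamma"} <= set(names) \
            and not len(probe_extras):
        # warm the probe pool from a quick CPT fit: its curvature estimates
        # land near the process model's, which rescues fits whose optimum
        # sits in a narrow near-separation basin
        cpt = fit_choice(trials, "CPT", config, n_starts=3, seed=seed,
                         batch=batch)
        # CPT curvature overstates the process model's (attention and leak
        # absorb part of it), so anchor probes at CPT and shrunken-CPT values
        anchors = [(cpt.params["alpha"], cpt.params["gamma"]),
                   (0.7 * cpt.params["alpha"], 0.7 * cpt.params["gamma"]),
                   (0.7, 0.7)]
        grid = []
        for al, gm in anchors:
            for th in (0.1, 0.3, 0.5, 0.7, 0.9):
                for lm in (0.2, 0.35, 0.5, 0.65, 0.8):
                    for bt in (0.4, 1.5):
                        pt = {"alpha": al, "gamma": gm, "theta": th,
                              "lam": lm, "beta": bt, "iota": 0.1}
                        grid.append(np.array([pt[p] for p in names]))
        probe_extras = grid

    box = [bnds[p] for p in names]
    best = None
    n_fail = 0
    for x0 in _starts(free_spec, bnds, n_starts, rng, nll_vec, extra_starts,
                      probe_extras):
        try:
            res = minimize(nll_vec, x0, method="L-BFGS-B", bounds=box)
        except Exception:  # pragma: no cover - optimizer blow-up
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"optimizer failed on all starts for {spec.name}")
    # gradient-free polish: guards against sharp ridges where the numerical
    # gradient misleads L-BFGS-B
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    polish = minimize(lambda v: nll_vec(np.clip(v, lo, hi)), best.x,
                      method="Nelder-Mead",
                      options={"maxiter": 200 * len(names), "fatol": 1e-8,
                               "xatol": 1e-6})
    if polish.fun < best.fun:
        polish.x = np.clip(polish.x, lo, hi)
        best = polish
    params = {**fixed, **dict(zip(names, (float(v) for v in best.x)))}
    p_a = model_choice_probs(batch, spec, params)
    ll = -float(best.fun)
    pid = trials[0].participant_id if trials else ""
    return FitResult(
        participant_id=pid, model_id=spec.name, params=params, loglik=ll,
        aic=aic(ll, len(names)),
        accuracy=prediction_accuracy(p_a, batch.choice),
        n_trials=batch.n_trials,
        diagnostics={"n_failed_starts": n_fail, "success": bool(best.success),
                     "fixed": dict(fixed)},
    )


def evaluate_heuristic(trials: Sequence[Trial], heuristic: str) -> FitResult:
    """Accuracy-only scoring of a deterministic heuristic (ties score half)."""
    score = 0.0
    for t in trials:
        pred = heuristic_choice(t.problem, heuristic)
        score += 0.5 if pred == "indifferent" else float(pred == t.choice)
    acc = score / len(trials)
    return FitResult(participant_id=trials[0].participant_id,
                     model_id=heuristic, params={}, loglik=np.nan,
                     aic=np.nan, accuracy=acc, n_trials=len(trials),
                     cv_accuracy=acc)


def _ev_quantile_strata(batch: TrialBatch, n_strata: int = 5) -> np.ndarray:
    """Stratum label per trial from |delta EV| quantiles."""
    adev = np.abs(batch.delta_ev)
    ranks = np.argsort(np.argsort(adev, kind="stable"), kind="stable")
    return (ranks * n_strata) // len(adev)


def cross_validate(trials: Sequence[Trial], model: str | ModelSpec,
                   config: DesignConfig, k_folds: int = 5, seed: int = 0,
                   n_starts: int = 6,
                   bounds: Optional[dict] = None) -> dict[str, float]:
    """Stratified k-fold CV: out-of-fold -2 log-likelihood (summed) and
    accuracy (trial-weighted mean)."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    spec = MODELS[model] if isinstance(model, str) else model
    batch = make_batch(trials, config)
    rng = np.random.default_rng(seed)
    strata = _ev_quantile_strata(batch)
    fold = np.empty(len(trials), dtype=np.intp)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k_folds
    neg2ll = 0.0
    n_correct = 0.0
    for f in range(k_folds):
        test = np.flatnonzero(fold == f)
        train = np.flatnonzero(fold != f)
        if test.size < 2 or train.size < 2:
            raise ValueError("fold with fewer than 2 trials")
        fit = fit_choice([trials[i] for i in train], spec, config,
                         n_starts=n_starts, seed=seed + f, bounds=bounds)
        test_batch = make_batch([trials[i] for i in test], config)
        p_a = model_choice_probs(test_batch, spec, fit.params)
        p_chosen = np.where(test_batch.choice == 0, p_a, 1.0 - p_a)
        neg2ll += -2.0 * float(np.sum(np.log(np.clip(p_chosen, 1e-300, None))))
        n_correct += prediction_accuracy(p_a, test_batch.choice) * test.size
    return {"cv_neg2ll": neg2ll, "cv_accuracy": n_correct / len(trials)}


def compare_models(trials: Sequence[Trial], config: DesignConfig,
                   models: Sequence[str] = COMPARISON_MODELS,
                   heuristics: Sequence[str] = (), n_starts: int = 6,
                   seed: int = 0, cv_folds: int = 0) -> list[FitResult]:
    """Fit a set of models to one participant's trials.

    Nested static models are warm-started from their restrictions
    (EV -> EU -> CPT, EU -> EU_fix, CPT -> CPT_fix) so the likelihood
    ordering of nested models holds at the optimizer tolerance.
    """
    batch = make_batch(trials, config)
    fits: dict[str, FitResult] = {}
    warm_from = {"EU": ("EV", {"alpha": 1.0}),
                 "CPT": ("EU", {"gamma": 1.0}),
                 "EU_fix": ("EU", {"tau": 0.0}),
                 "CPT_fix": ("CPT", {"tau": 0.0}),
                 "EU_dwell": ("EU", {"tau": 0.0}),
                 "CPT_dwell": ("CPT", {"tau": 0.0}),
                 "two_layer": ("one_layer", {}),
                 "hybrid": ("two_layer", {"iota": 0.0})}
    for name in models:
        spec = MODELS[name]
        extra = []
        if name in warm_from and warm_from[name][0] in fits:
            parent, fill = warm_from[name]
            src = {**fits[parent].params, **fill}
            extra.append(np.array([src[p] for p in spec.param_names]))
        fits[name] = fit_choice(trials, spec, config, n_starts=n_starts,
                                seed=seed, batch=batch, extra_starts=extra)
        if cv_folds >= 2:
            cv = cross_validate(trials, spec, config, k_folds=cv_folds,
                                seed=seed, n_starts=max(2, n_starts // 2))
            fits[name].cv_neg2ll = cv["cv_neg2ll"]
            fits[name].cv_accuracy = cv["cv_accuracy"]
    out = list(fits.values())
    out += [evaluate_heuristic(trials, h) for h in heuristics]
    return out


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"participant_id": f.participant_id, "model_id": f.model_id,
               "loglik": f.loglik, "aic": f.aic, "accuracy": f.accuracy,
               "cv_neg2ll": f.cv_neg2ll, "cv_accuracy": f.cv_accuracy,
               "n_trials": f.n_trials}
        row.update({f"param_{k}": v for k, v in f.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def group_table(fits_frame: pd.DataFrame) -> pd.DataFrame:
    """Pooled model table: AIC and CV -2LL summed, accuracies averaged."""
    return fits_frame.groupby("model_id").agg(
        aic=("aic", "sum"), accuracy=("accuracy", "mean"),
        cv_neg2ll=("cv_neg2ll", "sum"), cv_accuracy=("cv_accuracy", "mean"),
        n_participants=("participant_id", "nunique"),
    ).reset_index()


# --- Step 2: boundary fitting --------------------------------------------

def _boundary_nll(all_paths: list[np.ndarray], obs: list[tuple[int, int]],
                  bp: dec.BoundaryParams, rng: np.random.Generator) -> float:
    nll = 0.0
    for paths, (t_obs, c_obs) in zip(all_paths, obs):
        lik = dec.likelihood_from_paths(paths, bp, t_obs, c_obs, rng)
        nll -= np.log(lik)
    return nll


def fit_boundary(trials: Sequence[Trial], step1_params: ProcessParams,
                 variant: str, config: DesignConfig, family: str = "fixed",
                 M: int = 200, seed: int = 0,
                 max_steps: int = dec.MAX_STEPS_DEFAULT,
                 grid_size: int = 40) -> FitResult:
    """Step-2 fit: optimize boundary parameters on the Monte-Carlo
    (choice, decision-time) likelihood with Step-1 parameters frozen.

    Common random numbers: paths are simulated once per trial and reused for
    every boundary evaluation, so the objective is deterministic.
    """
    params = step1_params if step1_params.sigma > 0 else \
        ProcessParams(**{**step1_params.__dict__, "sigma": 1.0})
    rng = np.random.default_rng(seed)
    all_paths = [dec.trial_paths(t, params, variant, config, M, rng, max_steps)
                 for t in trials]
    obs = [(t.n_fixations, 0 if t.choice == "A" else 1) for t in trials]
    tie_rng = np.random.default_rng(seed + 1)

    hi = max(float(p.max()) for p in all_paths)
    b_grid = np.geomspace(max(hi * 1e-3, 1e-9), hi, grid_size)

    def nll_fixed(b0: float) -> float:
        return _boundary_nll(all_paths, obs,
                             dec.BoundaryParams("fixed", b0), tie_rng)

    scores = [nll_fixed(b) for b in b_grid]
    i = int(np.argmin(scores))
    lo_i, hi_i = max(0, i - 1), min(grid_size - 1, i + 1)
    fine = np.geomspace(b_grid[lo_i], b_grid[hi_i], grid_size)
    fine_scores = [nll_fixed(b) for b in fine]
    j = int(np.argmin(fine_scores))
    b0_fixed, nll_best = float(fine[j]), float(fine_scores[j])

    if family == "fixed":
        best_params = {"b0": b0_fixed}
        best_nll = nll_best
        k = 1
    else:
        def nll_collapsing(v: np.ndarray) -> float:
            b0, frac, tau_c = v
            if b0 <= 0 or not 0 <= frac <= 1 or tau_c <= 0:
                return np.inf
            bp = dec.BoundaryParams("collapsing", b0, b_inf=frac * b0,
                                    tau_c=tau_c)
            return _boundary_nll(all_paths, obs, bp, tie_rng)

        best_v, best_nll = None, np.inf
        for frac0 in (0.3, 0.9):
            for tau0 in (3.0, 15.0):
                res = minimize(nll_collapsing,
                               np.array([b0_fixed * 1.5, frac0, tau0]),
                               method="Nelder-Mead",
                               options={"maxiter": 200, "xatol": 1e-3,
                                        "fatol": 1e-4})
                if res.fun < best_nll:
                    best_v, best_nll = res.x, float(res.fun)
        b0, frac, tau_c = best_v
        best_params = {"b0": float(b0), "b_inf": float(frac * b0),
                       "tau_c": float(tau_c)}
        k = 3

    pid = trials[0].participant_id if trials else ""
    return FitResult(
        participant_id=pid, model_id=f"{variant}+{family}",
        params=best_params, loglik=-best_nll, aic=aic(-best_nll, k),
        accuracy=np.nan, n_trials=len(trials),
        diagnostics={"family": family, "M": M, "frozen": step1_params.__dict__},
    )


# --- parameter recovery ---------------------------------------------------

def recover_parameters(model: str | ModelSpec, generative_sets: Sequence[dict],
                       problems, gaze_sampler: Callable, config: DesignConfig,
                       seed: int = 0, n_starts: int = 6,
                       fixed: Optional[dict[str, float]] = None,
                       bounds: Optional[dict] = None,
                       lapse: float = 0.0) -> pd.DataFrame:
    """Simulate-and-refit recovery harness.

    For each generative parameter set, one synthetic participant's choices
    over ``problems`` are generated (fixations from ``gaze_sampler(problem,
    rng)``, choices from the model's Luce rule on final states) and the model
    refit.  Returns a long table of generative vs recovered values.
    """
    from .synthetic import simulate_choices_step1  # local import: no cycle

    if len(generative_sets) < 2:
        raise ValueError("need at least 2 generative parameter sets")
    spec = MODELS[model] if isinstance(model, str) else model
    rows = []
    for i, gen in enumerate(generative_sets):
        rng = np.random.default_rng(seed + 1000 * i)
        gen_full = {**gen, **(fixed or {})}
        trials = simulate_choices_step1(problems, gen_full, spec.variant,
                                        config, gaze_sampler, rng,
                                        participant_id=f"sim{i:03d}")
        fit = fit_choice(trials, spec, config, n_starts=n_starts,
                         seed=seed + i, fixed=fixed, bounds=bounds,
                         lapse=lapse)
        for p in spec.param_names:
            if fixed and p in fixed:
                continue
            rows.append({"participant": i, "param": p,
                         "generative": gen_full[p], "recovered": fit.params[p]})
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter Pearson correlation and mean bias of the recovery."""
    out = []
    for p, g in report.groupby("param"):
        if g["generative"].nunique() < 2 or g["recovered"].nunique() < 2:
            r = np.nan  # degenerate spread: correlation undefined
        else:
            r = float(np.corrcoef(g["generative"], g["recovered"])[0, 1])
        out.append({"param": p, "r": r,
                    "bias": float((g["recovered"] - g["generative"]).mean())})
    return pd.DataFrame(out)
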