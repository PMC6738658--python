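"""Descriptive choice / eye-movement analyses and model-based normativity
measures."""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .design import ChoiceProblem, risk_classification
from .gaze import Trial, classify_transitions, gaze_stats

log = logging.getLogger(__name__)

SLOPE_FLAG_LIMIT = 50.0  # |logistic slope| beyond this is flagged as separation


def ev_psychometrics(trials: Sequence[Trial]) -> dict:
    """Logistic slope of choice on ΔEV and the RT / |ΔEV| correlation.

    The RT correlation uses problem-level mean RTs (Pearson).  Degenerate
    choice patterns (perfect separation) are flagged and the slope reported
    as +/- inf.
    """
    if len(trials) < 10:
        raise ValueError("need at least 10 trials")
    dev = np.array([t.problem.delta_ev for t in trials])
    chose_a = np.array([1.0 if t.choice == "A" else 0.0 for t in trials])

    import statsmodels.api as sm
    flagged = False
    if len(set(chose_a[dev > 0])) <= 1 and len(set(chose_a[dev < 0])) <= 1 \
            and len(chose_a[dev > 0]) and len(chose_a[dev < 0]) \
            and chose_a[dev > 0].mean() != chose_a[dev < 0].mean():
        slope = np.inf if chose_a[dev > 0].mean() > 0.5 else -np.inf
        flagged = True
    else:
        try:
            model = sm.GLM(chose_a, sm.add_constant(dev),
                           family=sm.families.Binomial())
            slope = float(model.fit().params[1])
            if abs(slope) > SLOPE_FLAG_LIMIT:
                flagged = True
        except Exception:
            slope, flagged = np.nan, True

    df = pd.DataFrame({"pid": [t.problem.id for t in trials],
                       "rt": [t.rt for t in trials],
                       "adev": np.abs(dev)})
    means = df.groupby("pid").mean()
    if means["rt"].nunique() <= 1 or means["adev"].nunique() <= 1:
        rt_corr = 0.0
    else:
        rt_corr = float(np.corrcoef(means["adev"], means["rt"])[0, 1])
    return {"slope": slope, "slope_flagged": flagged, "rt_correlation": rt_corr}


def risk_preference(trials: Sequence[Trial], ev_window: float = 1.0) -> dict:
    """Fraction of riskier-option choices among near-equal-EV trade-offs,
    split by probability domain (either p < .25 vs both >= .25)."""
    counts = {"low": [0, 0], "medium_high": [0, 0]}
    for t in trials:
        if t.problem.relation != "tradeoff":
            continue
        if abs(t.problem.delta_ev) > ev_window:
            continue
        rc = risk_classification(t.problem)
        dom = rc["probability_domain"]
        counts[dom][1] += 1
        if t.choice == rc["riskier_option"]:
            counts[dom][0] += 1
    total = counts["low"][1] + counts["medium_high"][1]
    if total == 0:
        raise ValueError("no trade-off trials within the EV window")
    out = {}
    for dom, (k, n) in counts.items():
        out[dom] = k / n if n else np.nan
    out["overall"] = (counts["low"][0] + counts["medium_high"][0]) / total
    return out


def gaze_advantage_residual(trials: Sequence[Trial], p_model_a: np.ndarray,
                            mode: str = "count") -> float:
    """Choice-probability advantage of the more-fixated option after
    removing the value-model prediction.

    Residual per trial = 1{chose A} - P_model(A); the measure is the mean
    residual over trials with a positive option-A gaze advantage minus the
    mean over negative-advantage trials.  NaN (and a log warning) when one
    side is empty.
    """
    if mode not in ("count", "dwell"):
        raise ValueError("mode must be 'count' or 'dwell'")
    key = f"{mode}_advantage"
    adv = np.array([gaze_stats(t)[key] for t in trials], dtype=float)
    resid = np.array([1.0 if t.choice == "A" else 0.0 for t in trials]) \
        - np.asarray(p_model_a, dtype=float)
    pos, neg = resid[adv > 0], resid[adv < 0]
    if pos.size == 0 or neg.size == 0:
        log.warning("gaze advantage undefined: one side empty")
        return np.nan
    return float(pos.mean() - neg.mean())


def recency_curve(trials: Sequence[Trial], k_last: int = 4) -> np.ndarray:
    """Fraction of trials whose fixation at each backward position (1 = last)
    is on an attribute of the chosen option."""
    eligible = [t for t in trials if t.n_fixations >= k_last]
    if not eligible:
        raise ValueError(f"no trials with >= {k_last} fixations")
    out = np.empty(k_last)
    for pos in range(1, k_last + 1):
        hits = [(t.aoi_indices[-pos] < 2) == (t.choice == "A")
                for t in eligible]
        out[pos - 1] = float(np.mean(hits))
    return out


def _preference_table(problems: Sequence[ChoiceProblem],
                      choices: Sequence[str]) -> dict:
    prefs = {}
    for prob, c in zip(problems, choices):
        a = (prob.option_a.amount, prob.option_a.prob)
        b = (prob.option_b.amount, prob.option_b.prob)
        winner, loser = (a, b) if c == "A" else (b, a)
        prefs[frozenset((a, b))] = (winner, loser)
    return prefs


def transitivity_violations(problems: Sequence[ChoiceProblem],
                            choices: Sequence[str]) -> float:
    """Fraction of lottery triplets (all three pairs observed) forming a
    strict preference cycle.  NaN when no complete triplet exists."""
    prefs = _preference_table(problems, choices)
    lotteries = sorted({l for pair in prefs for l in pair})
    n_triplets = n_cycles = 0
    for x, y, z in itertools.combinations(lotteries, 3):
        keys = [frozenset((x, y)), frozenset((y, z)), frozenset((x, z))]
        if not all(k in prefs for k in keys):
            continue
        n_triplets += 1
        # strict cycle iff the three pairwise winners are all distinct
        winners = [prefs[k][0] for k in keys]
        if len(set(winners)) == 3:
            n_cycles += 1
    if n_triplets == 0:
        log.warning("no complete triplets for transitivity analysis")
        return np.nan
    return n_cycles / n_triplets


def ev_choice_fraction(problems: Sequence[ChoiceProblem],
                       choices: Sequence[str]) -> float:
    """Fraction of choices picking the higher-EV option (equal-EV halves)."""
    score = n = 0.0
    for prob, c in zip(problems, choices):
        d = prob.delta_ev
        n += 1
        if d == 0:
            score += 0.5
        else:
            score += float((d > 0) == (c == "A"))
    return score / n


def ev_quantile_accuracy(model_probs: dict[str, np.ndarray],
                         trials: Sequence[Trial],
                         n_quantiles: int = 5) -> pd.DataFrame:
    """Prediction accuracy per |ΔEV| quantile bin per model."""
    adev = np.array([abs(t.problem.delta_ev) for t in trials])
    if n_quantiles > len(np.unique(adev)):
        raise ValueError("more quantiles than distinct |dEV| values")
    choice = np.array([0 if t.choice == "A" else 1 for t in trials])
    ranks = np.argsort(np.argsort(adev, kind="stable"), kind="stable")
    bins = (ranks * n_quantiles) // len(adev)
    rows = []
    for name, p_a in model_probs.items():
        p_chosen = np.where(choice == 0, p_a, 1.0 - np.asarray(p_a))
        correct = (p_chosen > 0.5) + 0.5 * (p_chosen == 0.5)
        for q in range(n_quantiles):
            rows.append({"model": name, "quantile": q + 1,
                         "accuracy": float(correct[bins == q].mean()),
                         "n": int((bins == q).sum())})
    return pd.DataFrame(rows)


def simulate_model_choices(trials: Sequence[Trial],
                           prob_fn: Callable[[Sequence[Trial]], np.ndarray],
                           rng: np.random.Generator) -> list[str]:
    """Bernoulli choices from a model's per-trial P(choose A)."""
    p_a = np.asarray(prob_fn(trials), dtype=float)
    return ["A" if rng.random() < p else "B" for p in p_a]


def normativity_comparison(trials: Sequence[Trial],
                           model_prob_fns: dict[str, Callable],
                           rng: np.random.Generator,
                           n_reps: int = 1) -> pd.DataFrame:
    """EV-choice fraction and transitivity-violation fraction per model,
    simulating choices on the given fixation sequences."""
    problems = [t.problem for t in trials]
    rows = []
    for name, fn in model_prob_fns.items():
        evf, tvf = [], []
        for _ in range(n_reps):
            choices = simulate_model_choices(trials, fn, rng)
            evf.append(ev_choice_fraction(problems, choices))
            tvf.append(transitivity_violations(problems, choices))
        rows.append({"model": name, "ev_choice_fraction": float(np.mean(evf)),
                     "transitivity_violation_fraction": float(np.nanmean(tvf))})
    return pd.DataFrame(rows)


def participant_summary(trials: Sequence[Trial]) -> dict:
    """One participant's descriptive summary row."""
    psy = ev_psychometrics(trials)
    tc_total = {"within_alternative": 0, "within_attribute": 0, "diagonal": 0}
    stats = []
    for t in trials:
        tc = classify_transitions(t.fixations)
        for k in tc_total:
            tc_total[k] += getattr(tc, k)
        stats.append(gaze_stats(t))
    total = sum(tc_total.values())
    risk = risk_preference(trials) if any(
        t.problem.relation == "tradeoff" and abs(t.problem.delta_ev) <= 1
        for t in trials) else {"low": np.nan, "medium_high": np.nan,
                               "overall": np.nan}
    problems = [t.problem for t in trials]
    choices = [t.choice for t in trials]
    return {
        "participant_id": trials[0].participant_id,
        "ev_logistic_slope": psy["slope"],
        "rt_ev_correlation": psy["rt_correlation"],
        "risky_fraction_low": risk["low"],
        "risky_fraction_medium_high": risk["medium_high"],
        "amount_share": float(np.mean([s["amount_share"] for s in stats])),
        "higher_amount_share": float(np.nanmean(
            [s["higher_amount_share"] for s in stats])),
        "higher_prob_share": float(np.nanmean(
            [s["higher_prob_share"] for s in stats])),
        "prop_within_alternative": tc_total["within_alternative"] / total
        if total else np.nan,
        "prop_within_attribute": tc_total["within_attribute"] / total
        if total else np.nan,
        "prop_diagonal": tc_total["diagonal"] / total if total else np.nan,
        "ev_choice_fraction": ev_choice_fraction(problems, choices),
        "transitivity_violation_fraction":
            transitivity_violations(problems, choices),
        "mean_fixations": float(np.mean([t.n_fixations for t in trials])),
        "mean_rt_ms": float(np.mean([t.rt for t in trials])),
    }
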