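"""Fixation preprocessing: AOI assignment, cleaning, trial filtering and
transition/gaze summary statistics.

Fixations are classified into four areas of interest (AOIs), one per
attribute of each option: ``amount_a``, ``prob_a``, ``amount_b``, ``prob_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import ChoiceProblem

#: Canonical AOI order; indices into this tuple are used throughout.
AOIS = ("amount_a", "prob_a", "amount_b", "prob_b")
AOI_INDEX = {name: i for i, name in enumerate(AOIS)}

#: AOI index of the same attribute on the other option (0<->2, 1<->3).
PAIRED_AOI = (2, 3, 0, 1)

MIN_FIX_DURATION_MS = 50.0
AOI_RADIUS_PX = 100.0
MAX_RT_MS = 10_000.0
MIN_RT_MS = 500.0


@dataclass(frozen=True)
class Fixation:
    aoi: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.aoi not in AOI_INDEX:
            raise ValueError(f"unknown AOI {self.aoi!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class Trial:
    """One choice trial: problem, cleaned fixation sequence, choice, RT."""

    problem: ChoiceProblem
    fixations: tuple[Fixation, ...]
    choice: str  # "A" or "B"
    rt: float  # ms
    participant_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ValueError(f"choice must be 'A' or 'B', got {self.choice!r}")

    @property
    def aoi_indices(self) -> np.ndarray:
        return np.array([AOI_INDEX[f.aoi] for f in self.fixations], dtype=np.intp)

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)


@dataclass(frozen=True)
class TransitionCounts:
    within_alternative: int = 0
    within_attribute: int = 0
    diagonal: int = 0

    @property
    def total(self) -> int:
        return self.within_alternative + self.within_attribute + self.diagonal

    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"within_alternative": np.nan, "within_attribute": np.nan,
                    "diagonal": np.nan}
        return {
            "within_alternative": self.within_alternative / t,
            "within_attribute": self.within_attribute / t,
            "diagonal": self.diagonal / t,
        }


def assign_aoi(point: tuple[float, float],
               layout: dict[str, tuple[float, float]],
               radius_px: float = AOI_RADIUS_PX) -> Optional[str]:
    """Nearest AOI center within ``radius_px`` of ``point``, else None.

    Ties (exactly equal distances inside the radius) are broken by the
    canonical AOI order.
    """
    if set(layout) != set(AOIS):
        raise ValueError(f"layout must define exactly the AOIs {AOIS}")
    centers = [np.asarray(layout[a], dtype=float) for a in AOIS]
    for i, ci in enumerate(centers):
        for cj in centers[i + 1:]:
            if np.allclose(ci, cj):
                raise ValueError("degenerate layout: coincident AOI centers")
    p = np.asarray(point, dtype=float)
    dists = [float(np.hypot(*(p - c))) for c in centers]
    best = min(range(4), key=lambda i: (dists[i], i))
    return AOIS[best] if dists[best] <= radius_px else None


def clean_fixations(seq: Sequence[Fixation],
                    min_duration: float = MIN_FIX_DURATION_MS,
                    rt: Optional[float] = None) -> tuple[Fixation, ...]:
    """Drop sub-threshold fixations, then merge consecutive same-AOI runs.

    Durations of merged runs are summed and the earliest onset kept.  When
    ``rt`` is given, a fixation overlapping trial end is truncated at the
    response time.  Input must be time-ordered.
    """
    onsets = [f.onset for f in seq]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("fixations must be ordered by onset")
    out: list[Fixation] = []
    for f in seq:
        if rt is not None and f.onset + f.duration > rt:
            f = replace(f, duration=max(0.0, rt - f.onset))
        if f.duration < min_duration:
            continue
        if out and out[-1].aoi == f.aoi:
            prev = out[-1]
            out[-1] = replace(prev, duration=prev.duration + f.duration)
        else:
            out.append(f)
    return tuple(out)


def filter_trials(trials: Sequence[Trial],
                  max_rt: float = MAX_RT_MS,
                  min_rt: float = MIN_RT_MS) -> tuple[list[Trial], pd.DataFrame]:
    """Apply the trial-level exclusion rules.

    Excludes trials with rt outside [min_rt, max_rt] and trials whose cleaned
    sequence does not cover all four AOIs.  Returns retained trials and a
    per-trial exclusion report; a trial failing both rules is reported under
    ``duration`` (duration checked first), with a joint tally in the report's
    attrs for either ordering.
    """
    retained: list[Trial] = []
    rows = []
    n_dur = n_cov = n_both = 0
    for t in trials:
        bad_dur = t.rt > max_rt or t.rt < min_rt
        covered = {f.aoi for f in t.fixations}
        bad_cov = covered != set(AOIS)
        if bad_dur and bad_cov:
            n_both += 1
        if bad_dur:
            n_dur += 1
            rows.append((t.participant_id, t.trial_id, "duration"))
        elif bad_cov:
            n_cov += 1
            rows.append((t.participant_id, t.trial_id, "coverage"))
        else:
            retained.append(t)
    report = pd.DataFrame(rows, columns=["participant_id", "trial_id", "reason"])
    report.attrs["counts"] = {
        "duration_first": {"duration": n_dur, "coverage": len(rows) - n_dur},
        "coverage_first": {"coverage": n_cov + n_both,
                           "duration": len(rows) - (n_cov + n_both)},
    }
    return retained, report


def transition_category(a: str, b: str) -> Optional[str]:
    """Label a transition between two AOIs; None for a repeat."""
    i, j = AOI_INDEX[a], AOI_INDEX[b]
    if i == j:
        return None
    same_option = (i < 2) == (j < 2)
    same_attribute = (i % 2) == (j % 2)
    if same_option:
        return "within_alternative"
    if same_attribute:
        return "within_attribute"
    return "diagonal"


def classify_transitions(seq: Sequence[Fixation]) -> TransitionCounts:
    """Count within-alternative / within-attribute / diagonal transitions."""
    counts = {"within_alternative": 0, "within_attribute": 0, "diagonal": 0}
    for f, g in zip(seq, seq[1:]):
        cat = transition_category(f.aoi, g.aoi)
        if cat is None:
            raise ValueError("sequence not cleaned: consecutive same-AOI fixations")
        counts[cat] += 1
    return TransitionCounts(**counts)


def gaze_stats(trial: Trial) -> dict:
    """Per-trial gaze summary used by the behavioral analyses.

    Includes per-option fixation counts and dwell totals, attribute shares,
    the share of amount (probability) fixations landing on the larger
    amount (probability), and the option of the final fixation.
    """
    if not trial.fixations:
        raise ValueError("empty fixation sequence")
    idx = trial.aoi_indices
    durs = np.array([f.duration for f in trial.fixations])
    on_a = idx < 2
    on_amount = idx % 2 == 0

    p = trial.problem
    stats = {
        "n_fixations": len(idx),
        "count_a": int(on_a.sum()),
        "count_b": int((~on_a).sum()),
        "dwell_a": float(durs[on_a].sum()),
        "dwell_b": float(durs[~on_a].sum()),
        "amount_share": float(on_amount.mean()),
        "final_option": "A" if on_a[-1] else "B",
    }
    stats["count_advantage"] = stats["count_a"] - stats["count_b"]
    stats["dwell_advantage"] = stats["dwell_a"] - stats["dwell_b"]

    n_amount = int(on_amount.sum())
    if n_amount and p.option_a.amount != p.option_b.amount:
        hi_is_a = p.option_a.amount > p.option_b.amount
        hits = on_amount & (on_a if hi_is_a else ~on_a)
        stats["higher_amount_share"] = float(hits.sum() / n_amount)
    else:
        stats["higher_amount_share"] = np.nan
    n_prob = len(idx) - n_amount
    if n_prob and p.option_a.prob != p.option_b.prob:
        hi_is_a = p.option_a.prob > p.option_b.prob
        hits = ~on_amount & (on_a if hi_is_a else ~on_a)
        stats["higher_prob_share"] = float(hits.sum() / n_prob)
    else:
        stats["higher_prob_share"] = np.nan
    return stats
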