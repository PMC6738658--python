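import numpy as np
import pytest

from riskgaze.design import (ChoiceProblem, DesignConfig, Lottery,
                             classify_pair, enumerate_problems)
from riskgaze.gaze import AOIS, Fixation, Trial


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def problems(config):
    return enumerate_problems(config, rng_seed=0)


@pytest.fixture(scope="session")
def tradeoff_problems(problems):
    return [p for p in problems if not p.is_catch]


def make_problem(xa, pa, xb, pb, pid="p"):
    a, b = Lottery(xa, pa), Lottery(xb, pb)
    return ChoiceProblem(pid, a, b, classify_pair(a, b))


def make_trial(problem, aoi_seq, choice="A", dur=300.0, pid="s0", tid="t0"):
    """Trial from AOI indices with constant-duration fixations."""
    fixations = tuple(
        Fixation(AOIS[k], onset=i * dur, duration=dur)
        for i, k in enumerate(aoi_seq)
    )
    return Trial(problem=problem, fixations=fixations, choice=choice,
                 rt=dur * len(aoi_seq), participant_id=pid, trial_id=tid)


def random_clean_sequence(rng, n):
    """AOI index sequence with no immediate repeats."""
    seq = [int(rng.integers(4))]
    while len(seq) < n:
        nxt = int(rng.integers(4))
        if nxt != seq[-1]:
            seq.append(nxt)
    return seq


@pytest.fixture
def rng():
    return np.random.default_rng(0)
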