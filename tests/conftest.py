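import numpy as np
import pytest

from cogdiag.cohort import CohortConfig, DEFAULT_CLASS_EFFECTS, generate_cohort
from cogdiag.evaluation import build_context
from cogdiag.induction import parse_rules
from cogdiag.textmarkers import parse_text_rules


@pytest.fixture(scope="session")
def default_cohort():
    """The study-emulation cohort: 124 participants, seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_ctx(default_cohort):
    """Markers, scaling, thresholds, and split for the default cohort."""
    return build_context(default_cohort, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_total=20, n_healthy=12, n_mci=8, n_female=14, extra_days_max=2, seed=7)
    return generate_cohort(cfg), cfg


def noise_effects():
    """Class effects with every knob equalized: label carries no signal."""
    return {k: (v[0], v[0]) for k, v in DEFAULT_CLASS_EFFECTS.items()}


def big_config(seed, noise=False):
    return CohortConfig(
        n_total=2000,
        n_healthy=1200,
        n_mci=800,
        n_female=1435,
        class_effects=noise_effects() if noise else {},
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort2000():
    """One large planted-effects cohort shared by the heavy property tests."""
    return generate_cohort(big_config(0))


BOX2_NUMERIC = """\
if shape_score_sd > 2.5 then more likely mild cognitive impairment
if shape_score_sd <= 2.5 then more likely healthy
if shape_score_sd > 2.5 and shape_learning_rate > 1.5 then more likely mild cognitive impairment
"""
BOX2_TEXT = """\
if journal_text has a large vocabulary, long sentences, and/or high sentence complexity then more likely healthy
if some interview_assessment ratings are <= 3 then more likely mild cognitive impairment
"""


@pytest.fixture()
def sloan():
    """The worked-example participant: scaled markers, journal, ratings, and
    the five-rule subset used in the example prompt."""
    rules = parse_rules(BOX2_NUMERIC) + parse_text_rules(BOX2_TEXT)
    markers = {"shape_learning_rate": 9, "shape_score_sd": 6}
    journal = [
        "made a list and went to the store and got everything on it and didn't alter from it"
    ]
    ratings = {"Category Fluency (Animals)": 2, "Letter Fluency (F)": 3}
    return markers, journal, ratings, rules


def perm_pvalue(x, y, rng, n_perm=1999):
    """Two-sample location permutation test (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n].mean() - pooled[n:].mean()) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
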