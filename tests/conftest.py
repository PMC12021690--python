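import numpy as np
import pytest
from hypothesis import settings

from rateragree.records import InterpretationRecord, ScoreMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_matrix(values, participant_ids=None, evaluator_ids=None, n_items=None):
    """Build a ScoreMatrix from a nested list/array of scores."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    return ScoreMatrix(
        participant_ids=tuple(participant_ids or (f"P{i+1}" for i in range(n))),
        evaluator_ids=tuple(evaluator_ids or (f"E{r+1}" for r in range(k))),
        values=v,
        n_items_per_participant=tuple(n_items or [1] * n),
    )


def rec(p, i, e, category):
    return InterpretationRecord(participant_id=p, item_id=i, evaluator_id=e,
                                category=category)


@pytest.fixture
def hand_matrix_3x2():
    """3 participants x 2 evaluators with hand-computed ANOVA:
    grand mean 58.33, MSB = 5416.67, MSW = 416.67, ICC1 = 0.857."""
    return make_matrix([[100, 100], [50, 100], [0, 0]])


@pytest.fixture
def two_rater_records():
    """3 participants x 2 items x 2 evaluators; row means 100, 75, 0."""
    out = []
    scores = {
        ("P1", "I1"): ("correct", "correct"),
        ("P1", "I2"): ("correct", "correct"),
        ("P2", "I1"): ("correct", "correct"),
        ("P2", "I2"): ("major", "correct"),
        ("P3", "I1"): ("major", "major"),
        ("P3", "I2"): ("major", "major"),
    }
    for (p, i), (c1, c2) in scores.items():
        out.append(rec(p, i, "E1", c1))
        out.append(rec(p, i, "E2", c2))
    return out
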