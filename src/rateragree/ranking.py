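"""Participant ranking and item-level accuracy stratification."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import InterpretationRecord, ScoreMatrix
from .agreement import anova_mean_squares


@dataclass(frozen=True)
class ParticipantRank:
    participant_id: str
    mean_accuracy: float
    sd_accuracy: float  # SD across the k per-evaluator means
    per_evaluator_means: tuple[float, ...]
    rank: int  # 1 = highest mean accuracy


@dataclass(frozen=True)
class ItemSummary:
    item_id: str
    label: str
    mean_accuracy: float
    sd_across_participants: float
    sd_across_evaluators: float
    n_participants: int
    n_records: int


def rank_participants(matrix: ScoreMatrix) -> list[ParticipantRank]:
    """Rank participants by mean accuracy, best first.

    Ties are broken by participant id in lexicographic order so the ranking
    is stable and reproducible.  The per-participant SD is taken across the
    k evaluator means (the spread of the panel about that participant).
    """
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    order = sorted(
        range(matrix.n),
        key=lambda i: (-means[i], matrix.participant_ids[i]),
    )
    return [
        ParticipantRank(
            participant_id=matrix.participant_ids[i],
            mean_accuracy=float(means[i]),
            sd_accuracy=float(sds[i]),
            per_evaluator_means=tuple(float(v) for v in matrix.values[i]),
            rank=pos,
        )
        for pos, i in enumerate(order, start=1)
    ]


def variance_decomposition(matrix: ScoreMatrix) -> tuple[float, float, float]:
    """Between- vs within-participant variance components and their ratio.

    Returns ``(between, within, ratio)`` where ``within = MSW`` (the mean of
    the per-participant variances across evaluators) and ``between`` is the
    one-way ANOVA between-participant variance component
    ``(MSB - MSW) / k`` — the estimate of the participant-skill variance net
    of rater noise, so that ``ratio`` estimates sigma_b^2 / sigma_w^2 (which
    equals ICC/(1-ICC) for the single-rater reliability).  A zero within
    component yields an infinite ratio.
    """
    ms = anova_mean_squares(matrix)
    within = ms.msw
    between = max((ms.msb - ms.msw) / ms.k, 0.0)
    if within == 0.0:
        return between, 0.0, math.inf
    return between, within, between / within


def per_item_accuracy(records: Sequence[InterpretationRecord],
                      labels: Mapping[str, str] | None = None
                      ) -> list[ItemSummary]:
    """Accuracy summary per item (e.g. per ECG diagnosis).

    The item mean pools all (participant, evaluator) scores.  Two spread
    measures are reported separately: the SD across participant means (how
    much examinees differ on this item) and the SD across evaluator means
    (how much the panel disagrees on it).  Items are returned in first-seen
    order; an item absent from ``labels`` falls back to its own id.
    """
    labels = dict(labels or {})
    by_item: dict[str, list[InterpretationRecord]] = {}
    for rec in records:
        by_item.setdefault(rec.item_id, []).append(rec)
    out: list[ItemSummary] = []
    for item_id, recs in by_item.items():
        scores = np.array([r.score for r in recs], dtype=float)
        by_part: dict[str, list[float]] = {}
        by_eval: dict[str, list[float]] = {}
        for r in recs:
            by_part.setdefault(r.participant_id, []).append(r.score)
            by_eval.setdefault(r.evaluator_id, []).append(r.score)
        pmeans = np.array([np.mean(v) for v in by_part.values()])
        emeans = np.array([np.mean(v) for v in by_eval.values()])
        out.append(ItemSummary(
            item_id=item_id,
            label=labels.get(item_id, item_id),
            mean_accuracy=float(scores.mean()),
            sd_across_participants=(
                float(pmeans.std(ddof=1)) if pmeans.size > 1 else 0.0),
            sd_across_evaluators=(
                float(emeans.std(ddof=1)) if emeans.size > 1 else 0.0),
            n_participants=len(by_part),
            n_records=len(recs),
        ))
    return out
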