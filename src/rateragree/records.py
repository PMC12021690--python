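"""Long-format assessment records and their aggregation.

The unit of raw data is one evaluator's categorical accuracy judgment of one
participant's interpretation of one item (e.g. one ECG tracing).  Accuracy is
scored on a 3-point ordinal scale: ``correct`` (100%), ``minor_misdiagnosis``
(50%, over- or under-diagnosis of a minor abnormality) and
``major_misdiagnosis`` (0%, over- or under-diagnosis of a major abnormality).

All agreement statistics downstream operate on the participant x evaluator
:class:`ScoreMatrix` of mean accuracy scores built here.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical category -> score (percent) image of the 3-point accuracy scale
ACCURACY_SCALE: dict[str, int] = {
    "correct": 100,
    "minor_misdiagnosis": 50,
    "major_misdiagnosis": 0,
}

#: score -> canonical category (inverse of the scale)
SCORE_TO_CATEGORY: dict[int, str] = {v: k for k, v in ACCURACY_SCALE.items()}

#: accepted synonyms (case-insensitive) for each canonical category
CATEGORY_SYNONYMS: dict[str, str] = {
    "correct": "correct",
    "full": "correct",
    "100": "correct",
    "minor": "minor_misdiagnosis",
    "minor_misdiagnosis": "minor_misdiagnosis",
    "50": "minor_misdiagnosis",
    "major": "major_misdiagnosis",
    "major_misdiagnosis": "major_misdiagnosis",
    "0": "major_misdiagnosis",
}

CSV_HEADER = ["participant_id", "item_id", "evaluator_id", "category", "score"]

#: response-count bin edges used for cohort summaries (upper bounds inclusive)
RESPONSE_BINS: list[tuple[int, float]] = [
    (1, 4),
    (5, 10),
    (11, 15),
    (16, 20),
    (21, math.inf),
]


class FormatError(ValueError):
    """Malformed input file (missing column, bad value, category/score clash)."""


class UniquenessError(ValueError):
    """Duplicate (participant, item, evaluator) key in a dataset."""


class CompletenessError(ValueError):
    """A (participant, item) pair lacks a record from some evaluator."""


def encode_accuracy(category: str) -> int:
    """Map a category label (canonical or synonym, any case) to its percent score."""
    key = str(category).strip().lower()
    if key not in CATEGORY_SYNONYMS:
        raise ValueError(
            f"unknown accuracy category {category!r}; expected one of "
            f"{sorted(set(CATEGORY_SYNONYMS))}"
        )
    return ACCURACY_SCALE[CATEGORY_SYNONYMS[key]]


def decode_accuracy(score: float) -> str:
    """Map a score in {0, 50, 100} back to its canonical category label."""
    s = float(score)
    if s not in (0.0, 50.0, 100.0):
        raise ValueError(f"score {score!r} is not on the 0/50/100 accuracy scale")
    return SCORE_TO_CATEGORY[int(s)]


@dataclass(frozen=True)
class InterpretationRecord:
    """One evaluator's accuracy judgment of one participant's interpretation."""

    participant_id: str
    item_id: str
    evaluator_id: str
    category: str
    score: int = field(default=-1)
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical = CATEGORY_SYNONYMS.get(str(self.category).strip().lower())
        if canonical is None:
            raise ValueError(f"unknown accuracy category {self.category!r}")
        object.__setattr__(self, "category", canonical)
        expected = ACCURACY_SCALE[canonical]
        if self.score == -1:
            object.__setattr__(self, "score", expected)
        elif int(self.score) != expected:
            raise ValueError(
                f"score {self.score} conflicts with category {canonical!r} "
                f"(expected {expected})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.item_id, self.evaluator_id)


@dataclass(frozen=True)
class ScoreMatrix:
    """Participants x evaluators matrix of mean accuracy scores (percent).

    ``values[i, r]`` is the mean of evaluator ``r``'s scores over every item
    participant ``i`` submitted.  The matrix is complete by construction: every
    submitted item carries a score from every evaluator.
    """

    participant_ids: tuple[str, ...]
    evaluator_ids: tuple[str, ...]
    values: np.ndarray  # shape (n, k), float64
    n_items_per_participant: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n, k = vals.shape
        if n != len(self.participant_ids) or k != len(self.evaluator_ids):
            raise ValueError("matrix shape does not match id lists")
        if len(self.n_items_per_participant) != n:
            raise ValueError("n_items_per_participant length mismatch")
        if np.any(~np.isfinite(vals)):
            raise ValueError("score matrix contains non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def evaluator_index(self, evaluator_id: str) -> int:
        try:
            return self.evaluator_ids.index(evaluator_id)
        except ValueError:
            raise KeyError(f"unknown evaluator id {evaluator_id!r}") from None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.values, index=list(self.participant_ids),
            columns=list(self.evaluator_ids),
        )
        df.index.name = "participant_id"
        df["n_items"] = list(self.n_items_per_participant)
        return df

    @classmethod
    def from_frame(cls, df) -> "ScoreMatrix":
        df = df.copy()
        if "n_items" in df.columns:
            n_items = tuple(int(v) for v in df.pop("n_items"))
        else:
            n_items = tuple([0] * len(df))
        return cls(
            participant_ids=tuple(str(i) for i in df.index),
            evaluator_ids=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            n_items_per_participant=n_items,
        )


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive cohort summary: counts, response-count bins, category mix."""

    n_participants: int
    n_records: int
    response_count_bins: dict[str, int]
    category_proportions: dict[str, dict[str, float]]
    category_proportion_mean_sd: dict[str, tuple[float, float]]
    metadata_tabulations: dict[str, dict[str, int]]


def read_records(path: str | Path, dialect: Mapping[str, str] | None = None
                 ) -> list[InterpretationRecord]:
    """Read long-format assessment records from a CSV file.

    The canonical dialect is a comma-separated UTF-8 file with header
    ``participant_id,item_id,evaluator_id,category,score``; ``dialect`` may
    remap the logical column names to the file's actual header names.  Either
    of category/score may be blank, but not both; when both are present they
    must agree under the 3-point scale.
    """
    colmap = {c: c for c in CSV_HEADER}
    if dialect:
        colmap.update(dialect)
    records: list[InterpretationRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        for logical in ("participant_id", "item_id", "evaluator_id"):
            if colmap[logical] not in reader.fieldnames:
                raise FormatError(
                    f"{path}: missing required column {colmap[logical]!r}"
                )
        has_cat = colmap["category"] in reader.fieldnames
        has_score = colmap["score"] in reader.fieldnames
        if not has_cat and not has_score:
            raise FormatError(
                f"{path}: need at least one of columns "
                f"{colmap['category']!r} or {colmap['score']!r}"
            )
        core_cols = {colmap[c] for c in CSV_HEADER}
        for lineno, row in enumerate(reader, start=2):
            cat_raw = (row.get(colmap["category"]) or "").strip() if has_cat else ""
            score_raw = (row.get(colmap["score"]) or "").strip() if has_score else ""
            if not cat_raw and not score_raw:
                raise FormatError(
                    f"{path}:{lineno}: both category and score are blank"
                )
            if score_raw:
                try:
                    score_val = float(score_raw)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: score {score_raw!r} is not numeric"
                    ) from None
                if score_val not in (0.0, 50.0, 100.0):
                    raise FormatError(
                        f"{path}:{lineno}: score {score_raw!r} not in {{0, 50, 100}}"
                    )
            category = cat_raw if cat_raw else decode_accuracy(float(score_raw))
            metadata = {
                k: v for k, v in row.items()
                if k is not None and k not in core_cols and v not in (None, "")
            }
            try:
                rec = InterpretationRecord(
                    participant_id=row[colmap["participant_id"]].strip(),
                    item_id=row[colmap["item_id"]].strip(),
                    evaluator_id=row[colmap["evaluator_id"]].strip(),
                    category=category,
                    score=int(float(score_raw)) if score_raw else -1,
                    metadata=metadata,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if rec.key in seen:
                raise UniquenessError(
                    f"{path}:{lineno}: duplicate (participant, item, evaluator) "
                    f"key {rec.key}"
                )
            seen.add(rec.key)
            records.append(rec)
    return records


def write_records(records: Iterable[InterpretationRecord], path: str | Path,
                  metadata_columns: Sequence[str] | None = None) -> None:
    """Write records to the canonical CSV dialect (round-trips read_records)."""
    records = list(records)
    if metadata_columns is None:
        cols: list[str] = []
        for rec in records:
            for key in rec.metadata:
                if key not in cols:
                    cols.append(key)
        metadata_columns = cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER + list(metadata_columns))
        for rec in records:
            writer.writerow(
                [rec.participant_id, rec.item_id, rec.evaluator_id,
                 rec.category, rec.score]
                + [rec.metadata.get(c, "") for c in metadata_columns]
            )


def filter_min_submissions(
    records: Sequence[InterpretationRecord], min_items: int = 5
) -> tuple[list[InterpretationRecord], list[str]]:
    """Drop participants who submitted fewer than ``min_items`` distinct items.

    A participant's submission count is the number of *distinct items* they
    answered, not the number of rows (each item typically yields one row per
    evaluator).  The threshold is inclusive: exactly ``min_items`` items keeps
    the participant.  Returns the kept records and the excluded participant
    ids, in first-seen order.
    """
    if min_items < 1:
        raise ValueError("min_items must be >= 1")
    if not records:
        logger.warning("filter_min_submissions called on empty record list")
        return [], []
    items_by_participant: dict[str, set[str]] = {}
    order: list[str] = []
    for rec in records:
        if rec.participant_id not in items_by_participant:
            items_by_participant[rec.participant_id] = set()
            order.append(rec.participant_id)
        items_by_participant[rec.participant_id].add(rec.item_id)
    excluded = [p for p in order if len(items_by_participant[p]) < min_items]
    excluded_set = set(excluded)
    kept = [r for r in records if r.participant_id not in excluded_set]
    return kept, excluded


def build_score_matrix(records: Sequence[InterpretationRecord]) -> ScoreMatrix:
    """Aggregate records into the participant x evaluator mean-score matrix.

    Every (participant, item) pair must carry a record from every evaluator
    appearing in the dataset; an incomplete panel is an error because all
    downstream agreement statistics assume a complete matrix.
    """
    if not records:
        raise ValueError("cannot build a score matrix from zero records")
    participants: list[str] = []
    evaluators: list[str] = []
    for rec in records:
        if rec.participant_id not in participants:
            participants.append(rec.participant_id)
        if rec.evaluator_id not in evaluators:
            evaluators.append(rec.evaluator_id)
    scores: dict[tuple[str, str], dict[str, int]] = {}
    for rec in records:
        scores.setdefault((rec.participant_id, rec.item_id), {})[
            rec.evaluator_id] = rec.score
    for (pid, iid), by_eval in scores.items():
        missing = [e for e in evaluators if e not in by_eval]
        if missing:
            raise CompletenessError(
                f"(participant={pid!r}, item={iid!r}) lacks records from "
                f"evaluator(s) {missing}"
            )
    n, k = len(participants), len(evaluators)
    values = np.zeros((n, k))
    n_items = []
    for i, pid in enumerate(participants):
        items = sorted(iid for (p, iid) in scores if p == pid)
        n_items.append(len(items))
        for r, eid in enumerate(evaluators):
            values[i, r] = float(np.mean([scores[(pid, iid)][eid] for iid in items]))
    return ScoreMatrix(
        participant_ids=tuple(participants),
        evaluator_ids=tuple(evaluators),
        values=values,
        n_items_per_participant=tuple(n_items),
    )


def _bin_label(lo: int, hi: float) -> str:
    return f">{lo - 1}" if math.isinf(hi) else f"{lo}-{int(hi)}"


def summarize_cohort(records: Sequence[InterpretationRecord]) -> CohortSummary:
    """Tabulate cohort descriptives: response-count bins and category mix.

    Category proportions are computed per evaluator, then summarized across
    evaluators as mean +/- SD — the convention used when reporting "scored
    100% for X +/- Y % of interpretations".
    """
    items_by_participant: dict[str, set[str]] = {}
    by_eval: dict[str, dict[str, int]] = {}
    meta_tab: dict[str, dict[str, int]] = {}
    seen_participant_meta: set[str] = set()
    for rec in records:
        items_by_participant.setdefault(rec.participant_id, set()).add(rec.item_id)
        counts = by_eval.setdefault(
            rec.evaluator_id, {c: 0 for c in ACCURACY_SCALE})
        counts[rec.category] += 1
        if rec.participant_id not in seen_participant_meta:
            seen_participant_meta.add(rec.participant_id)
            for key, val in rec.metadata.items():
                meta_tab.setdefault(key, {}).setdefault(val, 0)
                meta_tab[key][val] += 1
    bins = {_bin_label(lo, hi): 0 for lo, hi in RESPONSE_BINS}
    for items in items_by_participant.values():
        cnt = len(items)
        for lo, hi in RESPONSE_BINS:
            if lo <= cnt <= hi:
                bins[_bin_label(lo, hi)] += 1
                break
    proportions: dict[str, dict[str, float]] = {}
    for eid, counts in by_eval.items():
        total = sum(counts.values())
        proportions[eid] = {c: counts[c] / total for c in ACCURACY_SCALE}
    mean_sd: dict[str, tuple[float, float]] = {}
    for cat in ACCURACY_SCALE:
        vals = np.array([proportions[eid][cat] for eid in proportions])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        mean_sd[cat] = (float(np.mean(vals)), sd)
    return CohortSummary(
        n_participants=len(items_by_participant),
        n_records=len(records),
        response_count_bins=bins,
        category_proportions=proportions,
        category_proportion_mean_sd=mean_sd,
        metadata_tabulations=meta_tab,
    )


@dataclass(frozen=True)
class Describe:
    """Both summaries of a continuous variable plus the normality verdict.

    ``preferred`` follows the usual reporting rule: mean +/- SD when the
    Shapiro-Wilk test does not reject normality at alpha = 0.05, otherwise
    median (IQR).
    """

    n: int
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    shapiro_p: float | None
    normal: bool | None

    @property
    def preferred(self) -> str:
        if self.normal is None or self.normal:
            return f"{self.mean:.1f} ± {self.sd:.1f}"
        return f"{self.median:.1f} (IQR {self.iqr[0]:.1f}–{self.iqr[1]:.1f})"


def describe(values: Sequence[float], alpha: float = 0.05) -> Describe:
    """Summarize a continuous variable with a Shapiro-Wilk-driven format choice."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("describe requires at least one value")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    if arr.size >= 3 and np.ptp(arr) > 0:
        shapiro_p = float(stats.shapiro(arr).pvalue)
        normal = shapiro_p >= alpha
    elif arr.size >= 3:
        shapiro_p, normal = 1.0, True  # constant vector: trivially symmetric
    else:
        shapiro_p, normal = None, None
    return Describe(n=arr.size, mean=mean, sd=sd, median=med, iqr=(q1, q3),
                    shapiro_p=shapiro_p, normal=normal)
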