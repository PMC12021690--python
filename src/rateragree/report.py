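"""Pipeline orchestration, JSON/CSV serialization, and run provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .records import (
    CohortSummary, ScoreMatrix, build_score_matrix, describe,
    filter_min_submissions, read_records, summarize_cohort,
)
from . import agreement, bland_altman, ranking

logger = logging.getLogger(__name__)


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def to_jsonable(obj: Any, sig: int = 6) -> Any:
    """Recursively convert package result objects to JSON-friendly structures.

    Floats are rounded to ``sig`` significant digits so reruns diff cleanly.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name), sig)
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v, sig) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v, sig) for v in obj]
    return obj


def write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(to_jsonable(obj), indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def file_digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_manifest(command: str, inputs: dict[str, Path], params: dict[str, Any],
                  seed: int | None) -> dict[str, Any]:
    return {
        "tool": "rateragree",
        "version": __version__,
        "command": command,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in inputs.items()},
        "params": params,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "python": sys.version.split()[0],
    }


def agreement_bundle(matrix: ScoreMatrix, reference: str | None,
                     design: str = "repeated_measures") -> dict[str, Any]:
    """ICC table, Pearson grid, and bias report for one score matrix."""
    estimates = agreement.icc_all(matrix)
    r, p = agreement.pairwise_pearson(matrix)
    ref = reference if reference is not None else matrix.evaluator_ids[0]
    bias = agreement.evaluator_bias_anova(matrix, design=design, reference=ref)
    ms = agreement.anova_mean_squares(matrix)
    return {
        "n_participants": matrix.n,
        "n_evaluators": matrix.k,
        "mean_squares": {"msb": ms.msb, "msw": ms.msw, "msj": ms.msj,
                         "mse": ms.mse},
        "icc": [dataclasses.asdict(e) for e in estimates],
        "pearson": {
            "evaluator_ids": list(matrix.evaluator_ids),
            "r": r, "p": p,
        },
        "bias": bias,
    }


def run_full_pipeline(records_path: str | Path, outdir: str | Path,
                      min_items: int = 5, reference: str | None = None,
                      seed: int = 17, n_boot: int = 1000,
                      item_labels: Mapping[str, str] | None = None,
                      make_plots: bool = True) -> dict[str, Path]:
    """Ingest -> filter -> matrix -> agreement + Bland-Altman + ranking + items.

    Writes summary.json, matrix.csv, agreement.json, ba.json, ranks.csv,
    items.csv, manifest.json and (optionally) the four figures into
    ``outdir``; returns the mapping of output names to paths.  Any stage
    error propagates annotated with the stage name.
    """
    records_path = Path(records_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        stage("ingest")
        records = read_records(records_path)
        all_summary = summarize_cohort(records)
        stage("filter")
        kept, excluded = filter_min_submissions(records, min_items=min_items)
        if not kept:
            raise ValueError(
                f"no eligible participants: every participant submitted fewer "
                f"than {min_items} items"
            )
        cohort = summarize_cohort(kept)
        stage("matrix")
        matrix = build_score_matrix(kept)
        participant_desc = describe(matrix.values.mean(axis=1))
        stage("agreement")
        agree = agreement_bundle(matrix, reference)
        stage("bland_altman")
        ba = bland_altman.analyze(matrix, n_boot=n_boot, seed=seed)
        stage("ranking")
        ranks = ranking.rank_participants(matrix)
        between, within, ratio = ranking.variance_decomposition(matrix)
        stage("items")
        items = ranking.per_item_accuracy(kept, labels=item_labels)
    except Exception as exc:
        raise type(exc)(f"[pipeline] {exc}") from exc

    summary = {
        "all_participants": all_summary,
        "eligible": cohort,
        "excluded_participants": excluded,
        "min_items": min_items,
        "participant_mean_accuracy": participant_desc,
        "variance_decomposition": {
            "between": between, "within": within, "ratio": ratio},
    }
    write_json(summary, outdir / "summary.json")
    outputs["summary"] = outdir / "summary.json"

    matrix.to_frame().to_csv(outdir / "matrix.csv", float_format="%.6g")
    outputs["matrix"] = outdir / "matrix.csv"

    write_json(agree, outdir / "agreement.json")
    outputs["agreement"] = outdir / "agreement.json"

    write_json(ba, outdir / "ba.json")
    outputs["ba"] = outdir / "ba.json"

    import pandas as pd

    rank_df = pd.DataFrame([dataclasses.asdict(r) for r in ranks])
    rank_df["per_evaluator_means"] = rank_df["per_evaluator_means"].map(
        lambda t: ";".join(f"{v:.6g}" for v in t))
    rank_df.to_csv(outdir / "ranks.csv", index=False, float_format="%.6g")
    outputs["ranks"] = outdir / "ranks.csv"

    items_df = pd.DataFrame([dataclasses.asdict(s) for s in items])
    items_df.to_csv(outdir / "items.csv", index=False, float_format="%.6g")
    outputs["items"] = outdir / "items.csv"

    if make_plots:
        from . import plots

        outputs["rank_plot"] = plots.rank_plot(ranks, outdir / "rank.png")
        outputs["ba_plot"] = plots.ba_plot(ba, outdir / "ba.png")
        outputs["agreement_plot"] = plots.agreement_panel(
            agree, outdir / "agreement.png")
        outputs["items_plot"] = plots.items_plot(items, outdir / "items.png")

    manifest = make_manifest(
        command="run_full_pipeline",
        inputs={"records": records_path},
        params={"min_items": min_items, "reference": reference,
                "n_boot": n_boot},
        seed=seed,
    )
    manifest["outputs"] = {k: str(v) for k, v in outputs.items()}
    write_json(manifest, outdir / "manifest.json")
    outputs["manifest"] = outdir / "manifest.json"
    return outputs
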