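"""Leave-one-out clinic attribution and per-clinic average scores.

Each setup in turn is treated as the held-out table: the mean similarity
score of that table to the remaining setups is computed per clinic, the
clinic with the lowest mean is the predicted affiliation, and the total
(all-others) mean identifies the setup most representative of the whole
collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .io_setups import SetupCollection, TableSetup
from .metric import MetricWeights, Normalization, SimilarityMatrix, similarity_matrix

__all__ = [
    "ClinicAverages",
    "ClassificationResult",
    "clinic_averages",
    "loocv_classify",
    "most_representative",
    "accuracy",
    "render_table1",
    "table1_rows",
    "round1",
]

TotalStrategy = Literal["count-weighted", "clinic-mean"]


def round1(value: float) -> float:
    """Round to one decimal (round-half-even), presentation only."""
    return float(f"{value:.1f}")


@dataclass(frozen=True)
class ClinicAverages:
    """Mean scores of one held-out setup against each clinic's remaining
    setups, plus the total mean over all other setups."""

    setup_id: str
    per_clinic: dict[str, float]
    total: float


@dataclass(frozen=True)
class ClassificationResult:
    setup_id: str
    true_clinic: str
    predicted_clinic: str
    correct: bool
    averages: ClinicAverages
    #: all clinics attaining the minimal mean; length > 1 marks a tie
    tied_clinics: tuple[str, ...] = field(default=())


def _averages_from_matrix(
    target: TableSetup,
    collection: SetupCollection,
    matrix: SimilarityMatrix,
    total_strategy: TotalStrategy,
) -> ClinicAverages:
    idx = {sid: k for k, sid in enumerate(matrix.setup_ids)}
    t = idx[target.setup_id]
    per_clinic_scores: dict[str, list[float]] = {c: [] for c in collection.clinics}
    all_scores: list[float] = []
    for other in collection:
        if other.setup_id == target.setup_id:
            continue
        s = float(matrix.values[t, idx[other.setup_id]])
        per_clinic_scores[other.clinic_id].append(s)
        all_scores.append(s)
    empty = [c for c, v in per_clinic_scores.items() if not v]
    if empty:
        raise ValueError(
            f"removing {target.setup_id!r} leaves clinic(s) {empty} with no setups"
        )
    per_clinic = {c: math.fsum(v) / len(v) for c, v in per_clinic_scores.items()}
    if total_strategy == "count-weighted":
        total = math.fsum(all_scores) / len(all_scores)
    elif total_strategy == "clinic-mean":
        total = math.fsum(per_clinic.values()) / len(per_clinic)
    else:
        raise ValueError(f"unknown total strategy {total_strategy!r}")
    return ClinicAverages(target.setup_id, per_clinic, total)


def clinic_averages(
    target: TableSetup,
    collection: SetupCollection,
    w: MetricWeights = MetricWeights(),
    normalization: Normalization = "union",
    total_strategy: TotalStrategy = "count-weighted",
) -> ClinicAverages:
    """Per-clinic mean similarity of ``target`` to the other setups.

    The target's own clinic mean uses its remaining clinic mates.  The
    total is count-weighted by default: the mean over the full non-self
    score vector, not the mean of the clinic means.
    """
    if target.setup_id not in collection.setup_ids():
        raise ValueError(f"setup {target.setup_id!r} is not in the collection")
    matrix = similarity_matrix(collection, w, normalization)
    return _averages_from_matrix(target, collection, matrix, total_strategy)


def _classify_one(
    target: TableSetup, averages: ClinicAverages
) -> ClassificationResult:
    lowest = min(averages.per_clinic.values())
    tied = tuple(sorted(c for c, v in averages.per_clinic.items() if v == lowest))
    predicted = tied[0]
    # a tie counts as correct only if the true clinic is the unique minimum
    correct = len(tied) == 1 and predicted == target.clinic_id
    return ClassificationResult(
        setup_id=target.setup_id,
        true_clinic=target.clinic_id,
        predicted_clinic=predicted,
        correct=correct,
        averages=averages,
        tied_clinics=tied,
    )


def loocv_classify(
    collection: SetupCollection,
    w: MetricWeights = MetricWeights(),
    normalization: Normalization = "union",
    total_strategy: TotalStrategy = "count-weighted",
) -> list[ClassificationResult]:
    """Leave-one-out clinic attribution for every setup.

    Requires at least two clinics and at least two setups per clinic
    (so every clinic keeps a reference when its own member is held out).
    """
    by_clinic = collection.by_clinic()
    if len(by_clinic) < 2:
        raise ValueError("leave-one-out classification requires >= 2 clinics")
    small = [c for c, group in by_clinic.items() if len(group) < 2]
    if small:
        raise ValueError(f"clinic(s) {small} have fewer than 2 setups")
    matrix = similarity_matrix(collection, w, normalization)
    results = []
    for target in collection:
        averages = _averages_from_matrix(target, collection, matrix, total_strategy)
        results.append(_classify_one(target, averages))
    return results


def accuracy(results: list[ClassificationResult]) -> float:
    return sum(r.correct for r in results) / len(results)


def most_representative(
    collection: SetupCollection,
    w: MetricWeights = MetricWeights(),
    normalization: Normalization = "union",
) -> tuple[str, float]:
    """Setup with the lowest total (all-others) mean score; ties broken
    lexicographically by setup id."""
    if len(collection) < 2:
        raise ValueError("requires >= 2 setups")
    matrix = similarity_matrix(collection, w, normalization)
    idx = {sid: k for k, sid in enumerate(matrix.setup_ids)}
    best: tuple[float, str] | None = None
    for s in collection:
        i = idx[s.setup_id]
        others = [float(matrix.values[i, j]) for j in range(len(collection)) if j != i]
        total = math.fsum(others) / len(others)
        key = (total, s.setup_id)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1], best[0]


def table1_rows(results: list[ClassificationResult]) -> list[dict]:
    """Row dicts (one per setup) for the classification report: per-clinic
    means, total mean, prediction and correctness, rounded to one decimal."""
    rows = []
    for r in results:
        row: dict = {"setup_id": r.setup_id, "true_clinic": r.true_clinic}
        for clinic, mean in r.averages.per_clinic.items():
            row[f"{clinic}_mean"] = round1(mean)
        row["total_mean"] = round1(r.averages.total)
        row["predicted_clinic"] = r.predicted_clinic
        row["correct"] = r.correct
        if len(r.tied_clinics) > 1:
            row["tie"] = ";".join(r.tied_clinics)
        rows.append(row)
    return rows


def render_table1(results: list[ClassificationResult]) -> str:
    """Human-readable classification report.

    The held-out setup's mean for its predicted clinic is starred; a
    trailing marker flags correct (+) vs incorrect (!) attribution.
    """
    if not results:
        raise ValueError("no results to render")
    clinics = list(results[0].averages.per_clinic)
    header = ["setup", *[f"{c} mean" for c in clinics], "total", "predicted", "ok"]
    body = []
    for r in results:
        cells = [r.setup_id]
        for c in clinics:
            v = f"{round1(r.averages.per_clinic[c]):.1f}"
            if c == r.predicted_clinic:
                v = f"*{v}"
            cells.append(v)
        cells.append(f"{round1(r.averages.total):.1f}")
        cells.append(r.predicted_clinic)
        cells.append("+" if r.correct else "!")
        body.append(cells)
    widths = [max(len(row[k]) for row in [header, *body]) for k in range(len(header))]
    lines = [
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths))
        for row in [header, *body]
    ]
    n_ok = sum(r.correct for r in results)
    pct = 100.0 * n_ok / len(results)
    lines.append(f"correct: {n_ok}/{len(results)} ({round1(pct):.1f}%)")
    return "\n".join(lines)
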