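"""Table similarity metric.

The score of a pair of table setups is the normalized sum of
per-instrument scores.  An instrument present on both tables
contributes its weighted translational plus rotational deviation::

    s_inst = w_trans * d_trans + w_rot * d_rot

where ``d_trans`` is the Euclidean pixel distance between the two
placements and ``d_rot`` the minimal angle (degrees, in [0, 180])
transforming one orientation into the other.  An instrument present on
exactly one table contributes the missing-instrument penalty ``w_miss``
once.  The table score divides the sum by the size of the matching
universe, so 0 means identical setups and larger values mean less
similar setups; the function is symmetric in its two arguments.

Duplicate instances of one instrument identity (m on table A, n on B)
are matched as min(m, n) pairs by a minimum-total-cost assignment; the
|m - n| surplus instances each count as missing.

The "normalized sum" denominator is an injectable strategy:

``union`` (default)
    one slot per matched pair plus one per unmatched instance, i.e.
    ``sum over identities of max(m, n)`` — a per-instrument average.
``max-size``
    ``max(|A|, |B|)``.
``matched-only``
    number of matched pairs (penalties still enter the numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_setups import InstrumentPlacement, SetupCollection, TableSetup

__all__ = [
    "MetricWeights",
    "InstrumentScore",
    "SimilarityMatrix",
    "Normalization",
    "UndefinedSimilarityError",
    "trans_distance",
    "rot_distance",
    "instrument_scores",
    "table_similarity",
    "similarity_matrix",
]

Normalization = Literal["union", "max-size", "matched-only"]

MAX_TRANS = math.hypot(1920.0, 1080.0)  # diagonal of the table surface


class UndefinedSimilarityError(ValueError):
    """The similarity of the given pair is undefined (denominator 0)."""


@dataclass(frozen=True)
class MetricWeights:
    """Weights (w_trans, w_rot, w_miss) configuring the metric.

    Defaults are the study configuration ``(1, 1, 1000)``.
    """

    w_trans: float = 1.0
    w_rot: float = 1.0
    w_miss: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("w_trans", "w_rot", "w_miss"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class InstrumentScore:
    """Per-instrument contribution to a pairwise table score.

    ``status`` is ``"matched"`` when the instrument instance was paired
    across the two tables (then ``d_trans``/``d_rot`` are set), or
    ``"missing"`` when it exists on only one table (then
    ``s_inst == w_miss`` and the distances are ``None``).
    """

    instrument_id: str
    status: Literal["matched", "missing"]
    s_inst: float
    d_trans: float | None = None
    d_rot: float | None = None


def trans_distance(a: InstrumentPlacement, b: InstrumentPlacement) -> float:
    """Euclidean distance in pixels between two placements."""
    return math.hypot(a.x - b.x, a.y - b.y)


def rot_distance(angle_a: float, angle_b: float) -> float:
    """Minimal angular difference in degrees, in [0, 180]."""
    d = abs(float(angle_a) - float(angle_b))
    d %= 360.0
    return min(d, 360.0 - d)


def _pair_cost(a: InstrumentPlacement, b: InstrumentPlacement, w: MetricWeights) -> tuple[float, float, float]:
    dt = trans_distance(a, b)
    dr = rot_distance(a.angle, b.angle)
    return w.w_trans * dt + w.w_rot * dr, dt, dr


def _canonical_pair(a: TableSetup, b: TableSetup) -> tuple[TableSetup, TableSetup]:
    """Order the pair deterministically so (a, b) and (b, a) run the exact
    same computation, making symmetry bitwise."""
    key_a = (a.setup_id, tuple((p.instrument_id, p.x, p.y, p.angle) for p in a.placements))
    key_b = (b.setup_id, tuple((p.instrument_id, p.x, p.y, p.angle) for p in b.placements))
    return (a, b) if key_a <= key_b else (b, a)


def _group_by_id(setup: TableSetup) -> dict[str, list[InstrumentPlacement]]:
    groups: dict[str, list[InstrumentPlacement]] = {}
    for p in setup.placements:
        groups.setdefault(p.instrument_id, []).append(p)
    return groups


def instrument_scores(
    a: TableSetup, b: TableSetup, w: MetricWeights = MetricWeights()
) -> list[InstrumentScore]:
    """Per-instrument score breakdown for the pair (a, b).

    Returns one :class:`InstrumentScore` per element of the matching
    universe: each matched pair once and each unmatched instance once,
    sorted by instrument id (matched pairs before surplus instances,
    then by assignment order).  Symmetric in (a, b).
    """
    a, b = _canonical_pair(a, b)
    groups_a = _group_by_id(a)
    groups_b = _group_by_id(b)
    scores: list[InstrumentScore] = []
    for iid in sorted(set(groups_a) | set(groups_b)):
        pa = groups_a.get(iid, [])
        pb = groups_b.get(iid, [])
        if pa and pb:
            if len(pa) == 1 and len(pb) == 1:
                cost, dt, dr = _pair_cost(pa[0], pb[0], w)
                scores.append(InstrumentScore(iid, "matched", cost, dt, dr))
            else:
                # duplicates: min-total-cost assignment of min(m, n) pairs
                cost_mat = np.empty((len(pa), len(pb)))
                for i, x in enumerate(pa):
                    for j, y in enumerate(pb):
                        cost_mat[i, j] = _pair_cost(x, y, w)[0]
                rows, cols = linear_sum_assignment(cost_mat)
                matched_a, matched_b = set(rows.tolist()), set(cols.tolist())
                for i, j in zip(rows.tolist(), cols.tolist()):
                    cost, dt, dr = _pair_cost(pa[i], pb[j], w)
                    scores.append(InstrumentScore(iid, "matched", cost, dt, dr))
                n_surplus = (len(pa) - len(matched_a)) + (len(pb) - len(matched_b))
                scores.extend(
                    InstrumentScore(iid, "missing", w.w_miss) for _ in range(n_surplus)
                )
        else:
            # present on exactly one table: each instance is one penalty
            scores.extend(
                InstrumentScore(iid, "missing", w.w_miss) for _ in range(len(pa) + len(pb))
            )
    return scores


def _denominator(scores: Sequence[InstrumentScore], normalization: Normalization) -> int:
    if normalization == "union":
        return len(scores)
    if normalization == "matched-only":
        return sum(1 for s in scores if s.status == "matched")
    raise ValueError(f"unknown normalization {normalization!r}")


def table_similarity(
    a: TableSetup,
    b: TableSetup,
    w: MetricWeights = MetricWeights(),
    normalization: Normalization = "union",
) -> float:
    """Similarity score of two table setups (0 = identical, higher =
    less similar).

    Symmetric: ``table_similarity(a, b) == table_similarity(b, a)``
    bitwise.  Raises :class:`UndefinedSimilarityError` when the chosen
    denominator is zero (e.g. both setups empty).
    """
    scores = instrument_scores(a, b, w)
    if normalization == "max-size":
        denom = max(len(a.placements), len(b.placements))
    else:
        denom = _denominator(scores, normalization)
    if denom == 0:
        raise UndefinedSimilarityError(
            f"similarity of {a.setup_id!r} and {b.setup_id!r} is undefined "
            f"(denominator 0 under {normalization!r} normalization)"
        )
    # canonical summation order for bitwise-reproducible totals
    total = math.fsum(sorted(s.s_inst for s in scores))
    return total / denom


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise score matrix over a setup collection."""

    setup_ids: list[str]
    values: np.ndarray

    def score(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.setup_ids.index(id_a), self.setup_ids.index(id_b)])


def similarity_matrix(
    collection: SetupCollection,
    w: MetricWeights = MetricWeights(),
    normalization: Normalization = "union",
) -> SimilarityMatrix:
    """All pairwise scores; symmetric with a zero diagonal."""
    if len(collection) < 2:
        raise ValueError("similarity matrix requires at least 2 setups")
    collection.validate(require_unique_ids=True)
    setups = collection.setups
    n = len(setups)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = table_similarity(setups[i], setups[j], w, normalization)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(collection.setup_ids(), values)
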