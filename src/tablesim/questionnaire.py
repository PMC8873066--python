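"""Aggregation of closed yes/no questionnaire responses per clinic.

Responses arrive as yes-counts per clinic (raw per-participant answers
are not needed).  Questions may be chained: a question can *depend on*
earlier questions, meaning it only applies to participants who answered
yes to every dependency.  Percentages are always taken over all
participants of a clinic (participants failing a dependency count in
the denominator as "no"), which makes percentages non-increasing along
a dependency chain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "QuestionSpec",
    "ResponseSet",
    "QuestionnaireError",
    "clinic_percent",
    "total_percent",
    "render_question_tables",
    "question_table_rows",
    "read_counts_csv",
    "read_question_specs_csv",
]


class QuestionnaireError(ValueError):
    pass


@dataclass(frozen=True)
class QuestionSpec:
    """One yes/no question; ``depends_on`` lists question ids that must
    all be answered yes for this question to apply."""

    question_id: str
    text: str
    depends_on: tuple[str, ...] = ()


def validate_specs(specs: list[QuestionSpec]) -> None:
    seen: set[str] = set()
    for q in specs:
        for dep in q.depends_on:
            if dep not in seen:
                raise QuestionnaireError(
                    f"question {q.question_id!r} depends on {dep!r}, which does "
                    "not precede it"
                )
        if q.question_id in seen:
            raise QuestionnaireError(f"duplicate question id {q.question_id!r}")
        seen.add(q.question_id)


@dataclass
class ResponseSet:
    """Yes-counts per clinic.

    ``n_participants`` maps clinic id to its participant count and
    ``yes_counts`` maps clinic id to ``{question_id: yes_count}``.
    """

    n_participants: dict[str, int]
    yes_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def clinics(self) -> list[str]:
        return list(self.n_participants)

    def yes(self, clinic: str, question_id: str) -> int:
        if clinic not in self.n_participants:
            raise QuestionnaireError(f"unknown clinic {clinic!r}")
        counts = self.yes_counts.get(clinic, {})
        if question_id not in counts:
            raise QuestionnaireError(
                f"no count for question {question_id!r} in clinic {clinic!r}"
            )
        return counts[question_id]

    def validate(self, specs: list[QuestionSpec] | None = None) -> None:
        for clinic, counts in self.yes_counts.items():
            n = self.n_participants.get(clinic)
            if n is None:
                raise QuestionnaireError(f"counts for unknown clinic {clinic!r}")
            for qid, c in counts.items():
                if not (0 <= c <= n):
                    raise QuestionnaireError(
                        f"clinic {clinic!r}, question {qid!r}: yes-count {c} "
                        f"outside [0, {n}]"
                    )
        if specs is not None:
            validate_specs(specs)
            for q in specs:
                for dep in q.depends_on:
                    for clinic in self.clinics:
                        if self.yes(clinic, q.question_id) > self.yes(clinic, dep):
                            raise QuestionnaireError(
                                f"clinic {clinic!r}: question {q.question_id!r} has "
                                f"more yes answers than its dependency {dep!r}"
                            )


def clinic_percent(responses: ResponseSet, clinic: str, question_id: str) -> float:
    """Percent of the clinic's participants answering yes (exact, no
    rounding — round at presentation)."""
    n = responses.n_participants.get(clinic)
    if n is None:
        raise QuestionnaireError(f"unknown clinic {clinic!r}")
    if n == 0:
        raise QuestionnaireError(f"clinic {clinic!r} has zero participants")
    return 100.0 * responses.yes(clinic, question_id) / n


def total_percent(responses: ResponseSet, question_id: str) -> float:
    """Participant-weighted total percentage over all clinics.

    With equal clinic sizes this equals the unweighted mean of the
    per-clinic percentages.
    """
    total_n = sum(responses.n_participants.values())
    if total_n == 0:
        raise QuestionnaireError("zero participants in total")
    total_yes = sum(responses.yes(c, question_id) for c in responses.clinics)
    return 100.0 * total_yes / total_n


def _round1(v: float) -> float:
    return float(f"{v:.1f}")


def question_table_rows(
    specs: list[QuestionSpec], responses: ResponseSet
) -> list[dict]:
    """One row per question: chain annotation, per-clinic percentages and
    the participant-weighted total, rounded to one decimal."""
    responses.validate(specs)
    rows = []
    for q in specs:
        row: dict = {
            "question_id": q.question_id,
            "text": q.text,
            "applies_if": ";".join(q.depends_on),
        }
        for clinic in responses.clinics:
            row[f"{clinic}_pct"] = _round1(clinic_percent(responses, clinic, q.question_id))
        row["total_pct"] = _round1(total_percent(responses, q.question_id))
        rows.append(row)
    return rows


def render_question_tables(specs: list[QuestionSpec], responses: ResponseSet) -> str:
    """Plain-text report with per-clinic and total agreement percentages."""
    rows = question_table_rows(specs, responses)
    if not rows:
        return ""
    clinics = responses.clinics
    header = ["question", *[f"{c} %" for c in clinics], "total %"]
    body = []
    for q, row in zip(specs, rows):
        label = q.question_id
        if q.depends_on:
            label = " & ".join([*(f"{d} applies" for d in q.depends_on), label])
        cells = [label]
        cells += [f"{row[f'{c}_pct']:.1f}" for c in clinics]
        cells.append(f"{row['total_pct']:.1f}")
        body.append(cells)
    widths = [max(len(r[k]) for r in [header, *body]) for k in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) if i == 0 else cell.rjust(w) for i, (cell, w) in enumerate(zip(row, widths)))
        for row in [header, *body]
    ]
    return "\n".join(lines)


def read_counts_csv(path: str | Path) -> ResponseSet:
    """Read yes-counts from CSV with header
    ``clinic_id,question_id,yes_count,n``."""
    path = Path(path)
    n_participants: dict[str, int] = {}
    yes_counts: dict[str, dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ("clinic_id", "question_id", "yes_count", "n")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise QuestionnaireError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            clinic = row["clinic_id"]
            try:
                yes = int(row["yes_count"])
                n = int(row["n"])
            except (TypeError, ValueError) as exc:
                raise QuestionnaireError(f"{path}, row {lineno}: non-integer count") from exc
            if clinic in n_participants and n_participants[clinic] != n:
                raise QuestionnaireError(
                    f"{path}, row {lineno}: clinic {clinic!r} has conflicting n"
                )
            n_participants[clinic] = n
            yes_counts.setdefault(clinic, {})[row["question_id"]] = yes
    responses = ResponseSet(n_participants, yes_counts)
    responses.validate()
    return responses


def read_question_specs_csv(path: str | Path) -> list[QuestionSpec]:
    """Read question specs from CSV with header
    ``question_id,text,depends_on`` (dependencies semicolon-separated)."""
    path = Path(path)
    specs: list[QuestionSpec] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ("question_id", "text", "depends_on")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise QuestionnaireError(f"{path}: missing column(s) {missing}")
        for row in reader:
            deps = tuple(d for d in (row["depends_on"] or "").split(";") if d)
            specs.append(QuestionSpec(row["question_id"], row["text"], deps))
    validate_specs(specs)
    return specs
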