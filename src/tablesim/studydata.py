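"""Bundled questionnaire data of the three-clinic scrub-nurse study.

Five participants per clinic (insel, acqua, ukl) answered closed yes/no
questions about instrument-table setup standards (Q1.1-Q5) and about
influences on their initial setup (Q6.1-Q6.5).  The per-clinic yes-counts
below are exact: with n = 5 per clinic, each published per-clinic
percentage is a multiple of 20 and the count is percentage / 20.
"""

from __future__ import annotations

from .questionnaire import QuestionSpec, ResponseSet

__all__ = ["STUDY_CLINICS", "study_question_specs", "study_responses"]

STUDY_CLINICS = ("insel", "acqua", "ukl")
_N_PER_CLINIC = 5

_QUESTIONS: list[tuple[str, str, tuple[str, ...]]] = [
    ("Q1.1", "Is there a GENERAL standard for how to set up an instrument table in your team?", ()),
    ("Q1.2", "Do you know who made this standard?", ("Q1.1",)),
    ("Q1.3", "Is this standard written down somewhere?", ("Q1.1", "Q1.2")),
    ("Q1.4", "Do you have access to this standard?", ("Q1.1", "Q1.2", "Q1.3")),
    ("Q2.1", "Is there a SPECIAL standard for how to set up an instrument table for a FESS intervention in your team?", ()),
    ("Q2.2", "Do you know who made this standard?", ("Q2.1",)),
    ("Q2.3", "Is this standard written down somewhere?", ("Q2.1", "Q2.2")),
    ("Q2.4", "Do you have access to this standard?", ("Q2.1", "Q2.2", "Q2.3")),
    ("Q3", "Do you know any literature which describes how a table should be set up for an operation?", ()),
    ("Q4", "Would you support a written down standard per operation type for the setup of the instrument table?", ()),
    ("Q5", "Could a written down standard per operation help trainees and new entrants in the OR to familiarize themselves quicker?", ()),
    ("Q6.1", "Influence: the surgeon (different setups for different surgeons).", ()),
    ("Q6.2", "Influence: by chance / daily mood.", ()),
    ("Q6.3", "Influence: my personal preference.", ()),
    ("Q6.4", "Influence: my training (I set up the table the way I was trained).", ()),
    ("Q6.5", "Influence: the in-house standard.", ()),
]

# yes-counts per question: (insel, acqua, ukl), n = 5 each
_YES_COUNTS: dict[str, tuple[int, int, int]] = {
    "Q1.1": (2, 3, 3),
    "Q1.2": (2, 1, 1),
    "Q1.3": (2, 1, 1),
    "Q1.4": (2, 0, 1),
    "Q2.1": (2, 1, 2),
    "Q2.2": (1, 1, 2),
    "Q2.3": (1, 0, 2),
    "Q2.4": (1, 0, 2),
    "Q3": (2, 1, 4),
    "Q4": (4, 2, 5),
    "Q5": (4, 2, 5),
    "Q6.1": (1, 1, 3),
    "Q6.2": (0, 0, 0),
    "Q6.3": (4, 5, 5),
    "Q6.4": (3, 3, 4),
    "Q6.5": (3, 1, 1),
}

#: question ids of the standards block (first report table)
STANDARDS_QUESTIONS = tuple(q for q, _, _ in _QUESTIONS if not q.startswith("Q6"))
#: question ids of the setup-influences block (second report table)
INFLUENCE_QUESTIONS = tuple(q for q, _, _ in _QUESTIONS if q.startswith("Q6"))


def study_question_specs() -> list[QuestionSpec]:
    return [QuestionSpec(qid, text, deps) for qid, text, deps in _QUESTIONS]


def study_responses() -> ResponseSet:
    yes_counts = {
        clinic: {qid: counts[k] for qid, counts in _YES_COUNTS.items()}
        for k, clinic in enumerate(STUDY_CLINICS)
    }
    responses = ResponseSet(
        n_participants={c: _N_PER_CLINIC for c in STUDY_CLINICS},
        yes_counts=yes_counts,
    )
    responses.validate(study_question_specs())
    return responses
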