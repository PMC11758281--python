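"""Per-stimulus attention scores from recall answers.

Each stimulus in a sequence receives a score in {-1, 0, 0.2, 0.4, 0.6, 0.8, 1}
grading how well the participant remembered the Target or ignored the
Distractor; -1 marks an inconclusive stimulus.  Fractional values are only
possible for Targets.

Target (rank r among the sequence's Targets, digit d):
  * -1 (inconclusive) if d also occurs among the sequence's Distractors and
    d appears in the answer — we cannot tell whether the participant
    remembered the Target or failed to ignore the Distractor.
  * 0 if d is reported at answer position r; 0.2 * k if reported displaced by
    k positions (k = 1..4; larger displacements saturate at 1); 1 if d is not
    reported.  When the same digit occurs several times among the Targets,
    answer occurrences are matched to Target occurrences greedily left to
    right (deterministic and order-preserving).

Distractor (digit d, counts cA in the answer, cT among Targets, cTD among
Targets plus Distractors):
  * -1 if the Distractor is an empty circle (there is nothing to report, so
    nothing can be concluded about attention to it);
  * 0 if cA <= cT (every report is attributable to a Target: properly
    ignored); 1 if cA >= cTD (reported more often than it could possibly have
    appeared as a Target: certainly listed); -1 otherwise.

Downstream classification keeps only the conclusive extremes: score 0
(attentive) vs score 1 (inattentive).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import EMPTY
from .synthetic_data import TrialRecord

__all__ = [
    "SCORE_VALUES",
    "score_target",
    "score_distractor",
    "score_trial",
    "score_trials",
    "conclusive_binary_labels",
    "apply_scores",
]

SCORE_VALUES = (-1.0, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class ScoringError(ValueError):
    """Raised when a stimulus does not belong to the trial as claimed."""


def _answer_digits(trial: TrialRecord) -> list[int]:
    return [int(ch) for ch in trial.answer]


def score_target(digit: int, target_position: int, trial: TrialRecord) -> float:
    """Score the Target with rank ``target_position`` (1-based among Targets).

    See the module docstring for the full convention.
    """
    targets = trial.targets
    if not 1 <= target_position <= len(targets):
        raise ScoringError(
            f"target_position {target_position} out of range 1..{len(targets)}"
        )
    if targets[target_position - 1] != digit:
        raise ScoringError(
            f"digit {digit} is not the Target at rank {target_position} "
            f"(targets are {targets})"
        )
    answer = _answer_digits(trial)
    distractors = [d for d in trial.distractors if d != EMPTY]
    if digit in distractors and digit in answer:
        return -1.0
    # Greedy left-to-right matching of answer occurrences to Target
    # occurrences of the same digit.
    occurrence = sum(1 for d in targets[: target_position - 1] if d == digit)
    answer_positions = [i + 1 for i, d in enumerate(answer) if d == digit]
    if occurrence >= len(answer_positions):
        return 1.0  # this occurrence was not reported
    matched_pos = answer_positions[occurrence]
    displacement = abs(matched_pos - target_position)
    if displacement == 0:
        return 0.0
    return min(0.2 * displacement, 1.0)


def score_distractor(digit: int, trial: TrialRecord) -> float:
    """Score a Distractor digit (or :data:`EMPTY` for an empty circle)."""
    distractors = trial.distractors
    if digit not in distractors:
        raise ScoringError(f"digit {digit} is not a Distractor (got {distractors})")
    if digit == EMPTY:
        return -1.0
    answer = _answer_digits(trial)
    c_answer = answer.count(digit)
    c_targets = trial.targets.count(digit)
    c_both = c_targets + distractors.count(digit)
    if c_answer <= c_targets:
        return 0.0
    if c_answer >= c_both:
        return 1.0
    return -1.0


def score_trial(trial: TrialRecord) -> list[tuple[int, str, float]]:
    """Score every stimulus of a trial, in presentation order.

    Returns ``(position, kind, score)`` triples with 1-based sequence
    positions.
    """
    out: list[tuple[int, str, float]] = []
    target_rank = 0
    for pos0, (digit, kind) in enumerate(trial.stimuli):
        if kind == "Target":
            target_rank += 1
            value = score_target(digit, target_rank, trial)
        else:
            value = score_distractor(digit, trial)
        out.append((pos0 + 1, kind, value))
    return out


def score_trials(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Score a collection of trials into a tidy table.

    Columns: participant_id, condition, sequence_index, position, kind, score.
    """
    rows = []
    for trial in trials:
        for position, kind, value in score_trial(trial):
            rows.append(
                {
                    "participant_id": trial.participant_id,
                    "condition": trial.condition,
                    "sequence_index": trial.sequence_index,
                    "position": position,
                    "kind": kind,
                    "score": value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "sequence_index",
            "position",
            "kind",
            "score",
        ],
    )


def conclusive_binary_labels(scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Keep only conclusive extremes: score 0 (attentive) and 1 (inattentive).

    Returns the kept indices and their binary labels (0 for score 0, 1 for
    score 1); every other value (-1 and the fractional scores) is dropped.
    """
    scores = np.asarray(scores, dtype=float)
    keep = np.flatnonzero((scores == 0.0) | (scores == 1.0))
    labels = scores[keep].astype(int)
    return keep, labels


def apply_scores(epoch_meta: pd.DataFrame, trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Join per-stimulus scores onto an epoch metadata table.

    The join key is (participant_id, condition, sequence_index, position);
    returns a copy of ``epoch_meta`` with a ``score`` column filled in.
    """
    scores = score_trials(trials)
    keys = ["participant_id", "condition", "sequence_index", "position"]
    merged = epoch_meta.drop(columns=["score"], errors="ignore").merge(
        scores[keys + ["score"]], on=keys, how="left", validate="many_to_one"
    )
    if merged["score"].isna().any():
        missing = merged.loc[merged["score"].isna(), keys].iloc[0].to_dict()
        raise ScoringError(f"no trial record covers epoch {missing}")
    return merged
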