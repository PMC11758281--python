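"""Shared fixtures: small synthetic experiments and canonical worked examples."""

from __future__ import annotations

import pytest

from eegrep import GeneratorConfig, TrialRecord, generate_experiment
from eegrep.data_model import EMPTY


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down experiment: 3 participants, 4 sequences, 16 channels."""
    return GeneratorConfig(
        n_participants=3, n_sequences=4, n_channels=16, seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture()
def worked_trial() -> TrialRecord:
    """The canonical worked sequence: Targets 8,6,9,7,4 at positions
    1,4,5,8,10; Distractors 6,6,empty,9,5; answer '86694'."""
    stimuli = (
        (8, "Target"), (6, "Distractor"), (6, "Distractor"), (6, "Target"),
        (9, "Target"), (EMPTY, "Distractor"), (9, "Distractor"), (7, "Target"),
        (5, "Distractor"), (4, "Target"),
    )
    return TrialRecord(
        participant_id="EP01", condition="C1", sequence_index=0,
        stimuli=stimuli, attend_flags=(True,) * 10, answer="86694",
    )


def make_trial(stimuli, answer: str) -> TrialRecord:
    """Build a trial from (digit, kind) pairs and an answer string."""
    return TrialRecord(
        participant_id="EP01", condition="C1", sequence_index=0,
        stimuli=tuple(stimuli), attend_flags=(True,) * len(stimuli), answer=answer,
    )
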