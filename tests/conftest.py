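import numpy as np
import pytest

from npbtest import ParticipantRecord, StudyDataset


def make_record(pid="p0", awareness=(1, 0, 1, 0), conditions="AABB",
                responses=(1.0, 2.0, 0.5, 1.5)):
    return ParticipantRecord(
        participant_id=pid,
        awareness_correct=np.array(awareness),
        effect_condition=np.array(list(conditions)),
        effect_response=np.array(responses, dtype=float),
    )


def make_dataset(scores, n_trials=20, n_eff=10, effects=None, rng=None):
    """Dataset whose participants have prescribed awareness scores.

    Awareness vectors are deterministic 1s-then-0s realizing each score
    exactly; effect responses are standard-normal unless ``effects``
    gives per-participant mean shifts on condition A.
    """
    rng = rng or np.random.default_rng(0)
    records = []
    for i, s in enumerate(scores):
        k = int(round(s * n_trials))
        aware = np.array([1] * k + [0] * (n_trials - k))
        half = n_eff // 2
        shift = 0.0 if effects is None else effects[i]
        resp = np.concatenate([
            rng.normal(shift, 1.0, half), rng.normal(0.0, 1.0, n_eff - half)
        ])
        records.append(ParticipantRecord(
            participant_id=f"p{i}",
            awareness_correct=aware,
            effect_condition=np.array(["A"] * half + ["B"] * (n_eff - half)),
            effect_response=resp,
        ))
    return StudyDataset(participants=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
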