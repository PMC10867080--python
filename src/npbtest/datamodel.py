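"""Trial-level data model for awareness/effect studies, with CSV I/O.

A study consists of participants who each completed (a) a block of
two-alternative forced-choice (2AFC) awareness trials, scored 0/1, and
(b) a block of effect trials, each labeled with one of two experimental
conditions and carrying a numeric response (RT, accuracy, rating, ...).
The per-participant *awareness score* is the proportion of correct
awareness trials; the *effect score* is the difference between the two
condition means, ``mean(A) - mean(B)``.

Data travels as long-format CSV: one row per trial, columns
``participant_id, trial_type, condition, value``. Long format is the
canonical representation because downstream resampling needs the
trial-by-trial condition labels and supports unequal trial counts
across participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "StudyDataset",
    "Dialect",
    "read_dataset",
    "write_dataset",
    "DataFormatError",
    "ValidationError",
    "AnalysisError",
]


class DataFormatError(ValueError):
    """The file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """The data violate an invariant of the data model."""


class AnalysisError(RuntimeError):
    """A statistical procedure cannot be carried out on these data."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping and label conventions for reading foreign CSVs.

    ``condition_a`` designates the condition whose mean enters the effect
    score with positive sign: effect = mean(A) - mean(B).
    """

    participant_id: str = "participant_id"
    trial_type: str = "trial_type"
    condition: str = "condition"
    value: str = "value"
    awareness_label: str = "awareness"
    effect_label: str = "effect"
    condition_a: str = "A"
    condition_b: str = "B"

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        """Load a dialect from a JSON object or ``key=value`` lines."""
        text = Path(path).read_text()
        try:
            mapping = json.loads(text)
        except json.JSONDecodeError:
            mapping = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise DataFormatError(f"cannot parse dialect line: {line!r}")
                key, _, val = line.partition("=")
                mapping[key.strip()] = val.strip()
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataFormatError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class ParticipantRecord:
    """One subject's awareness trials and condition-labeled effect trials."""

    participant_id: str
    awareness_correct: np.ndarray
    effect_condition: np.ndarray
    effect_response: np.ndarray

    def __post_init__(self) -> None:
        self.awareness_correct = np.asarray(self.awareness_correct, dtype=np.int64)
        self.effect_condition = np.asarray(self.effect_condition, dtype="U1")
        self.effect_response = np.asarray(self.effect_response, dtype=np.float64)
        pid = self.participant_id
        if self.awareness_correct.size == 0:
            raise ValidationError(f"participant {pid!r}: no awareness trials")
        if not np.isin(self.awareness_correct, (0, 1)).all():
            raise ValidationError(
                f"participant {pid!r}: awareness values must be 0 or 1"
            )
        if self.effect_condition.shape != self.effect_response.shape:
            raise ValidationError(
                f"participant {pid!r}: condition and response lengths differ"
            )
        if self.effect_response.size < 2:
            raise ValidationError(f"participant {pid!r}: fewer than 2 effect trials")
        labels = set(self.effect_condition.tolist())
        if labels != {"A", "B"}:
            raise ValidationError(
                f"participant {pid!r}: effect conditions must be exactly "
                f"{{'A', 'B'}}, got {sorted(labels)}"
            )
        if not np.isfinite(self.effect_response).all():
            raise ValidationError(
                f"participant {pid!r}: non-finite effect responses are not allowed"
            )

    @property
    def n_awareness_trials(self) -> int:
        return int(self.awareness_correct.size)

    @property
    def awareness_score(self) -> float:
        """Proportion of correct 2AFC awareness trials."""
        return float(self.awareness_correct.sum()) / self.awareness_correct.size

    @property
    def effect_score(self) -> float:
        """mean(response | A) - mean(response | B)."""
        is_a = self.effect_condition == "A"
        return float(self.effect_response[is_a].mean() - self.effect_response[~is_a].mean())

    def with_conditions(self, conditions: np.ndarray) -> "ParticipantRecord":
        """Copy of this record with a replacement condition-label vector."""
        return replace(self, effect_condition=np.asarray(conditions, dtype="U1"))


@dataclass
class StudyDataset:
    """A collection of participant records plus task-level metadata."""

    participants: list[ParticipantRecord]
    chance_level: float = 0.5

    def __post_init__(self) -> None:
        if len(self.participants) < 2:
            raise ValidationError("a study dataset needs at least 2 participants")
        if not 0.0 < self.chance_level < 1.0:
            raise ValidationError("chance_level must lie in (0, 1)")
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate participant_id values")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def avg_awareness_trials(self) -> float:
        """Arithmetic mean of per-participant awareness trial counts."""
        return float(np.mean([p.n_awareness_trials for p in self.participants]))

    @property
    def awareness_scores(self) -> np.ndarray:
        return np.array([p.awareness_score for p in self.participants])

    @property
    def effect_scores(self) -> np.ndarray:
        return np.array([p.effect_score for p in self.participants])


def read_dataset(path: str | Path, dialect: Dialect | None = None) -> StudyDataset:
    """Read a long-format trial-level CSV into a :class:`StudyDataset`.

    Row order within each participant is preserved. Raises
    :class:`DataFormatError` for missing columns and
    :class:`ValidationError` for invariant violations (non-binary
    awareness values, participants lacking either trial type, ...).
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(
        path,
        dtype={dialect.participant_id: str, dialect.condition: str},
        float_precision="round_trip",
    )
    for col in (dialect.participant_id, dialect.trial_type, dialect.condition, dialect.value):
        if col not in df.columns:
            raise DataFormatError(f"missing required column {col!r} in {path}")

    records: list[ParticipantRecord] = []
    for pid, grp in df.groupby(dialect.participant_id, sort=False):
        aw = grp[grp[dialect.trial_type] == dialect.awareness_label]
        eff = grp[grp[dialect.trial_type] == dialect.effect_label]
        if len(aw) == 0:
            raise ValidationError(f"participant {pid!r}: zero awareness trials")
        if len(eff) == 0:
            raise ValidationError(f"participant {pid!r}: zero effect trials")
        aw_vals = aw[dialect.value].to_numpy(dtype=np.float64)
        if not np.isin(aw_vals, (0.0, 1.0)).all():
            raise ValidationError(
                f"participant {pid!r}: awareness values must be binary 0/1"
            )
        cond_raw = eff[dialect.condition].to_numpy()
        cond = np.where(cond_raw == dialect.condition_a, "A",
                        np.where(cond_raw == dialect.condition_b, "B", "?"))
        if (cond == "?").any():
            bad = sorted(set(cond_raw[cond == "?"]))
            raise ValidationError(
                f"participant {pid!r}: unknown condition labels {bad}"
            )
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                awareness_correct=aw_vals.astype(np.int64),
                effect_condition=cond,
                effect_response=eff[dialect.value].to_numpy(dtype=np.float64),
            )
        )
    return StudyDataset(participants=records)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset as canonical long-format CSV.

    Responses are written with Python's shortest round-tripping float
    representation, so ``read_dataset`` inverts this bit-exactly.
    """
    if not isinstance(dataset, StudyDataset):
        raise ValidationError("write_dataset expects a StudyDataset")
    rows: list[tuple[str, str, str, str]] = []
    for p in dataset.participants:
        for v in p.awareness_correct:
            rows.append((p.participant_id, "awareness", "", str(int(v))))
        for c, v in zip(p.effect_condition, p.effect_response):
            rows.append((p.participant_id, "effect", str(c), repr(float(v))))
    df = pd.DataFrame(rows, columns=["participant_id", "trial_type", "condition", "value"])
    df.to_csv(path, index=False)
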