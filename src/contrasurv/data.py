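"""Patient-level data containers shared across the package.

Everything is keyed by patient id; positional alignment between sources is
never assumed. The survival outcome container is vectorised: one object
holds the follow-up time and event indicator for a whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcomes for a set of patients.

    Parameters
    ----------
    time : array of positive follow-up times (consistent but arbitrary units).
    event : binary array; 1 = death observed, 0 = censored at ``time``.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != self.event.shape:
            raise ValidationError("time and event must be aligned")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = np.where(~(self.time > 0))[0]
            raise ValidationError(f"follow-up times must be positive and finite "
                                  f"(offending indices: {bad[:5].tolist()})")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_rate(self) -> float:
        return float(self.event.mean())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])

    def to_frame(self, patient_ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        if patient_ids is not None:
            df.insert(0, "patient_id", list(patient_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalOutcome":
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass
class EmbeddingMatrix:
    """Patients x dim real matrix produced by an encoder, id-aligned."""

    patient_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.patient_ids):
            raise ValidationError("embedding matrix must be patients x dim")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("embedding matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def reindex(self, patient_ids: Sequence[str]) -> "EmbeddingMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing:
            raise ValidationError(f"missing patients: {missing[:5]}")
        idx = [pos[p] for p in patient_ids]
        return EmbeddingMatrix(list(patient_ids), self.values[idx])


@dataclass
class Cohort:
    """Aligned patient-level multimodal container.

    ``mutation_matrix`` is a patients x genes binary DataFrame,
    ``clinical_table`` a mixed-type DataFrame, ``tile_embeddings`` a mapping
    patient id -> (tiles x dim) float array. All share the ordering of
    ``patient_ids``.
    """

    patient_ids: list[str]
    mutation_matrix: pd.DataFrame
    clinical_table: pd.DataFrame
    tile_embeddings: dict[str, np.ndarray]
    outcomes: SurvivalOutcome
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise ValidationError("duplicate patient ids")
        for name, obj in (("mutation_matrix", self.mutation_matrix),
                          ("clinical_table", self.clinical_table)):
            if list(map(str, obj.index)) != self.patient_ids:
                raise ValidationError(f"{name} index must equal patient_ids order")
        if len(self.outcomes) != n:
            raise ValidationError("outcomes misaligned with patient_ids")
        missing = [p for p in self.patient_ids if p not in self.tile_embeddings]
        if missing:
            raise ValidationError(f"tile embeddings missing for: {missing[:5]}")
        vals = self.mutation_matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix must be binary")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx: np.ndarray) -> "Cohort":
        ids = [self.patient_ids[i] for i in np.atleast_1d(idx)]
        return Cohort(
            patient_ids=ids,
            mutation_matrix=self.mutation_matrix.loc[ids],
            clinical_table=self.clinical_table.loc[ids],
            tile_embeddings={p: self.tile_embeddings[p] for p in ids},
            outcomes=self.outcomes.subset(np.atleast_1d(idx)),
            extras={k: (np.asarray(v)[np.atleast_1d(idx)]
                        if isinstance(v, np.ndarray) and
                        np.asarray(v).shape[:1] == (len(self),) else v)
                    for k, v in self.extras.items()},
        )

    def tile_dim(self) -> int:
        return next(iter(self.tile_embeddings.values())).shape[1]
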