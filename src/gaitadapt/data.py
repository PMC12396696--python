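"""Core containers for stride-indexed knee-angle trajectories.

The central object is :class:`TrialMatrix`: a dense ``T x N`` matrix of knee
flexion angles (degrees), one column per participant, one row per stride
step, with a group label attached to every column.  Both estimation tracks
(the sequential state-space filter and the functional-data spline fit)
consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class TrialMatrix:
    """Knee angles ``y_ijt`` for all participants over stride steps.

    Parameters
    ----------
    angles
        ``(T, N)`` array of knee flexion angles in degrees.  Rows are stride
        steps, columns are participants.  No missing cells are allowed.
    group_labels
        Length-``N`` array of group names (e.g. Control / Punishment /
        Reward), one per column.
    participant_ids
        Length-``N`` array of participant identifiers.
    time_index
        Length-``T`` strictly increasing, unit-spaced step counts
        (``tau_t = t``).  Defaults to ``1..T``.
    """

    angles: np.ndarray
    group_labels: np.ndarray
    participant_ids: np.ndarray
    time_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValidationError("angles must be a 2-D (steps x participants) array")
        T, N = self.angles.shape
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        if self.time_index is None:
            self.time_index = np.arange(1, T + 1, dtype=float)
        self.time_index = np.asarray(self.time_index, dtype=float)
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        T, N = self.angles.shape
        if not np.all(np.isfinite(self.angles)):
            bad = np.argwhere(~np.isfinite(self.angles))[0]
            raise ValidationError(
                f"missing or non-numeric angle at step row {bad[0] + 1}, "
                f"participant column {bad[1] + 1}"
            )
        if self.group_labels.shape != (N,):
            raise ValidationError(
                f"expected {N} group labels, got {self.group_labels.shape}"
            )
        if self.participant_ids.shape != (N,):
            raise ValidationError(
                f"expected {N} participant ids, got {self.participant_ids.shape}"
            )
        if any(str(g).strip() == "" for g in self.group_labels):
            raise ValidationError("every column needs a non-empty group label")
        if self.time_index.shape != (T,):
            raise ValidationError("time_index length must equal number of steps")
        d = np.diff(self.time_index)
        if T > 1 and not np.allclose(d, 1.0):
            raise ValidationError(
                "time index must be strictly increasing with unit spacing"
            )

    # -- views -----------------------------------------------------------
    @property
    def T(self) -> int:
        return self.angles.shape[0]

    @property
    def n_participants(self) -> int:
        return self.angles.shape[1]

    @property
    def groups(self) -> list:
        """Group names in order of first appearance."""
        seen: list = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, group) -> np.ndarray:
        cols = np.flatnonzero(self.group_labels == group)
        if cols.size == 0:
            raise ValidationError(f"unknown group {group!r}")
        return cols

    def group_sizes(self) -> dict:
        return {g: int(np.sum(self.group_labels == g)) for g in self.groups}

    def group_data(self) -> list:
        """List of ``(T, n_j)`` arrays, one per group, in group order."""
        return [self.angles[:, self.group_columns(g)] for g in self.groups]

    def group_means(self) -> np.ndarray:
        """Observed mean angles ``ybar_jt`` as a ``(G, T)`` array."""
        return np.stack(
            [self.angles[:, self.group_columns(g)].mean(axis=1) for g in self.groups]
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide frame with a (participant, group) column MultiIndex."""
        cols = pd.MultiIndex.from_arrays(
            [self.participant_ids.astype(str), self.group_labels.astype(str)],
            names=["participant", "group"],
        )
        return pd.DataFrame(self.angles, index=pd.Index(self.time_index.astype(int), name="step"), columns=cols)

    def copy_with(self, angles: np.ndarray) -> "TrialMatrix":
        return TrialMatrix(
            angles=np.array(angles, dtype=float),
            group_labels=self.group_labels.copy(),
            participant_ids=self.participant_ids.copy(),
            time_index=self.time_index.copy(),
        )
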