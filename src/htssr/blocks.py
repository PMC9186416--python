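"""Column block addressing for group-stacked matrices.

Both stages of the pipeline operate on wide matrices whose columns are
stacked over (subject, task, inner) triples: voxels in the first stage
(S1 is frames x (n_voxels * n_tasks * n_subjects)), temporal-dictionary
atoms in the second (S2 is voxels x (k1 * n_tasks * n_subjects)).  The
column order is fixed once — subject-major, then task in the canonical
seven-task order, then the inner index — and every module that touches a
stacked matrix goes through :class:`BlockIndex` rather than re-deriving
offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# Canonical task order: emotion, motor, gambling, language, relational,
# social, working memory.
TASKS: tuple[str, ...] = (
    "emotion",
    "motor",
    "gambling",
    "language",
    "relational",
    "social",
    "wm",
)
TASK_CODES: dict[str, str] = dict(zip(TASKS, "EMGLRSW"))


@dataclass(frozen=True)
class BlockIndex:
    """Bijection between flat column indices and (subject, task, inner).

    Parameters
    ----------
    subjects
        Ordered subject identifiers (the major axis).
    tasks
        Ordered task labels (middle axis); defaults to the seven-task set.
    n_inner
        Size of the fastest-varying axis: number of sampled voxels for the
        stage-1 signal matrix, number of temporal atoms (k1) for stage 2.
    """

    subjects: tuple[str, ...]
    tasks: tuple[str, ...]
    n_inner: int

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject identifiers")
        if self.n_inner <= 0:
            raise ValueError("n_inner must be positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_columns(self) -> int:
        return self.n_subjects * self.n_tasks * self.n_inner

    def _subject_pos(self, subject: str | int) -> int:
        if isinstance(subject, (int, np.integer)):
            return int(subject)
        return self.subjects.index(subject)

    def _task_pos(self, task: str | int) -> int:
        if isinstance(task, (int, np.integer)):
            return int(task)
        return self.tasks.index(task)

    def col(self, subject: str | int, task: str | int, inner: int) -> int:
        """Flat column index of one (subject, task, inner) triple."""
        i = self._subject_pos(subject)
        t = self._task_pos(task)
        if not (0 <= inner < self.n_inner):
            raise IndexError(f"inner index {inner} out of range [0, {self.n_inner})")
        return (i * self.n_tasks + t) * self.n_inner + inner

    def decode(self, col: int) -> tuple[str, str, int]:
        """Inverse of :meth:`col`."""
        if not (0 <= col < self.n_columns):
            raise IndexError(f"column {col} out of range [0, {self.n_columns})")
        inner = col % self.n_inner
        rest = col // self.n_inner
        t = rest % self.n_tasks
        i = rest // self.n_tasks
        return self.subjects[i], self.tasks[t], inner

    def block(self, subject: str | int, task: str | int) -> slice:
        """Column slice covering all inner indices of one (subject, task)."""
        start = self.col(subject, task, 0)
        return slice(start, start + self.n_inner)

    def task_columns(self, task: str | int) -> np.ndarray:
        """All column indices belonging to one task, across subjects."""
        t = self._task_pos(task)
        cols = [
            np.arange(self.block(i, t).start, self.block(i, t).stop)
            for i in range(self.n_subjects)
        ]
        return np.concatenate(cols)

    def with_subjects(self, subjects: Sequence[str]) -> "BlockIndex":
        """Same task set and inner size, different subject roster."""
        return BlockIndex(tuple(subjects), self.tasks, self.n_inner)
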