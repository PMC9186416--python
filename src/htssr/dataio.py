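"""Reading BOLD volumes and event files, and preparing the group matrix.

The preparation steps mirror a standard group sparse-representation
workflow: mask-extract each run to a frames x voxels matrix, truncate all
tasks to a common length, randomly subsample a fraction of in-mask voxels
(one seeded subset shared by every subject, so that stage-2 rows
correspond across subjects), normalize every column to zero mean and unit
l2 norm, and column-stack subjects and tasks into one wide matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .blocks import TASKS, BlockIndex
from .synthetic import TaskParadigm, make_task_paradigm


@dataclass(frozen=True)
class BoldMatrix:
    """One run as a frames x voxels matrix over in-mask voxels."""

    data: np.ndarray = field(repr=False)
    subject_id: str
    task_id: str
    tr: float
    voxel_index: np.ndarray = field(repr=False)  # linear mask indices per column

    def __post_init__(self) -> None:
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD matrix contains non-finite values")
        if self.data.shape[1] != self.voxel_index.size:
            raise ValueError("voxel_index length must match column count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class VoxelSampling:
    """A seeded without-replacement subsample of in-mask voxels."""

    mask_shape: tuple[int, ...]
    mask_indices: np.ndarray = field(repr=False)
    sampled_indices: np.ndarray = field(repr=False)
    fraction: float
    seed: int

    @property
    def n_sampled(self) -> int:
        return self.sampled_indices.size

    def positions_in_mask(self) -> np.ndarray:
        """Column positions of the sampled voxels within a full BoldMatrix."""
        pos = np.searchsorted(self.mask_indices, self.sampled_indices)
        if not np.array_equal(self.mask_indices[pos], self.sampled_indices):
            raise ValueError("sampled indices are not a subset of the mask")
        return pos


@dataclass(frozen=True)
class GroupSignalMatrix:
    """Column-stacked multi-subject multi-task signal matrix.

    Columns are ordered subject-major, then task (canonical order), then
    sampled voxel; every column is zero-mean, unit-norm (constant columns
    are zeroed and flagged).
    """

    data: np.ndarray = field(repr=False)
    index: BlockIndex
    sampling: VoxelSampling | None
    zero_flags: np.ndarray = field(repr=False)

    @property
    def t(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.index.n_inner

    @property
    def p(self) -> int:
        return self.index.n_subjects


def load_bold(
    volume: str | Path | nib.spatialimages.SpatialImage,
    mask: str | Path | nib.spatialimages.SpatialImage | np.ndarray,
    subject_id: str = "",
    task_id: str = "",
    tr: float = 0.72,
) -> BoldMatrix:
    """Extract a frames x voxels matrix from a 4D volume under a mask.

    Columns follow ascending linear (C-order) mask index.  All-zero voxels
    are kept; normalization deals with them later.
    """
    img = nib.load(str(volume)) if isinstance(volume, (str, Path)) else volume
    if isinstance(mask, (str, Path)):
        mask_arr = np.asarray(nib.load(str(mask)).dataobj) > 0
    elif isinstance(mask, np.ndarray):
        mask_arr = mask.astype(bool)
    else:
        mask_arr = np.asarray(mask.dataobj) > 0
    if img.shape[:3] != mask_arr.shape:
        raise ValueError(
            f"volume grid {img.shape[:3]} does not match mask grid {mask_arr.shape}"
        )
    lin = np.flatnonzero(mask_arr.ravel(order="C"))
    if lin.size == 0:
        raise ValueError("mask is empty")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    t = vol.shape[3] if vol.ndim == 4 else 1
    data = vol.reshape(-1, t, order="C")[lin].T
    return BoldMatrix(
        data=data, subject_id=subject_id, task_id=task_id, tr=tr, voxel_index=lin
    )


def load_paradigm(
    ev_paths: Sequence[str | Path],
    tr: float,
    n_frames: int,
) -> tuple[list[TaskParadigm], np.ndarray]:
    """Parse FSL-style 3-column event files into paradigms.

    Returns one paradigm per file plus the combined (summed) regressor over
    all events, truncated to ``n_frames``.  Events lying entirely beyond
    the scan window contribute a zero regressor and trigger a warning;
    events straddling the end of the window are clipped to it.
    """
    window = n_frames * tr
    paradigms: list[TaskParadigm] = []
    for path in ev_paths:
        path = Path(path)
        blocks: list[tuple[float, float, float]] = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                onset, duration, amplitude = (float(x) for x in parts[:3])
                if len(parts) < 3:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 'onset duration amplitude', "
                    f"got {line!r}"
                ) from None
            if onset >= window:
                warnings.warn(
                    f"{path.name}:{lineno}: event at {onset} s lies beyond the "
                    f"{window:.2f} s scan window; contributes a zero regressor",
                    stacklevel=2,
                )
                continue
            blocks.append((onset, min(duration, window - onset), amplitude))
        paradigms.append(make_task_paradigm(n_frames, tr, blocks, task_id=path.stem))
    combined = (
        np.sum([p.regressor for p in paradigms], axis=0)
        if paradigms
        else np.zeros(n_frames)
    )
    return paradigms, combined


def truncate_tasks(
    bolds: Sequence[BoldMatrix | np.ndarray],
) -> list[BoldMatrix | np.ndarray]:
    """Cut every run to the minimum frame count, keeping the earliest frames."""
    if len(bolds) == 0:
        raise ValueError("no runs to truncate")
    lengths = [
        b.n_frames if isinstance(b, BoldMatrix) else b.shape[0] for b in bolds
    ]
    t_min = min(lengths)
    out: list[BoldMatrix | np.ndarray] = []
    for b in bolds:
        if isinstance(b, BoldMatrix):
            out.append(
                BoldMatrix(
                    data=b.data[:t_min],
                    subject_id=b.subject_id,
                    task_id=b.task_id,
                    tr=b.tr,
                    voxel_index=b.voxel_index,
                )
            )
        else:
            out.append(b[:t_min])
    return out


def normalize_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and l2-normalize each column; zero-variance columns become 0.

    Returns the normalized matrix and a boolean flag per column marking the
    constant (dead-voxel) columns that were zeroed.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] < 2:
        raise ValueError("need at least two frames to normalize")
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    flags = norms <= 1e-12 * max(1.0, float(np.abs(matrix).max()))
    safe = np.where(flags, 1.0, norms)
    out = centered / safe
    out[:, flags] = 0.0
    return out, flags


def sample_voxels(
    mask: np.ndarray | VoxelSampling,
    fraction: float,
    seed: int,
) -> VoxelSampling:
    """Uniform without-replacement sample of round(fraction * n_mask) voxels.

    The returned subset is sorted ascending and is meant to be shared by
    every subject in a run, so stage-2 rows line up across subjects.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(mask, VoxelSampling):
        mask_shape = mask.mask_shape
        mask_indices = mask.mask_indices
    else:
        mask = np.asarray(mask).astype(bool)
        mask_shape = mask.shape
        mask_indices = np.flatnonzero(mask.ravel(order="C"))
    n = int(round(fraction * mask_indices.size))
    rng = np.random.default_rng(seed)
    sampled = np.sort(rng.choice(mask_indices, size=n, replace=False))
    return VoxelSampling(
        mask_shape=tuple(mask_shape),
        mask_indices=mask_indices,
        sampled_indices=sampled,
        fraction=float(fraction),
        seed=int(seed),
    )


def assemble_group_matrix(
    bolds: Mapping[str, Mapping[str, BoldMatrix]],
    sampling: VoxelSampling,
    subjects: Sequence[str] | None = None,
    tasks: Sequence[str] = TASKS,
) -> GroupSignalMatrix:
    """Stack per-(subject, task) runs into the wide stage-1 matrix.

    ``bolds[subject][task]`` must all share the frame count (run
    :func:`truncate_tasks` first) and the voxel set of ``sampling``'s mask.
    Columns are ordered subject-major, task-major (canonical task order),
    voxel-minor, and each is normalized to zero mean, unit norm.
    """
    if subjects is None:
        subjects = tuple(bolds.keys())
    subjects = tuple(subjects)
    tasks = tuple(tasks)
    pos = sampling.positions_in_mask()
    t_ref: int | None = None
    columns: list[np.ndarray] = []
    for sub in subjects:
        for task in tasks:
            try:
                b = bolds[sub][task]
            except KeyError:
                raise KeyError(f"missing run for subject {sub!r}, task {task!r}")
            if b.n_voxels != sampling.mask_indices.size:
                raise ValueError(
                    f"subject {sub!r} task {task!r}: {b.n_voxels} voxels, "
                    f"expected {sampling.mask_indices.size} (shared mask required)"
                )
            if t_ref is None:
                t_ref = b.n_frames
            elif b.n_frames != t_ref:
                raise ValueError(
                    f"subject {sub!r} task {task!r}: {b.n_frames} frames, "
                    f"expected {t_ref}; truncate first"
                )
            columns.append(b.data[:, pos])
    data = np.concatenate(columns, axis=1)
    data, flags = normalize_columns(data)
    index = BlockIndex(subjects=subjects, tasks=tasks, n_inner=sampling.n_sampled)
    return GroupSignalMatrix(data=data, index=index, sampling=sampling, zero_flags=flags)


def group_matrix_from_dataset(
    dataset,
    subjects: Sequence[str],
    sampling: VoxelSampling,
    truncate_to: int | None = None,
) -> GroupSignalMatrix:
    """Convenience path from a :class:`~htssr.synthetic.SyntheticDataset`.

    Equivalent to writing the dataset to NIfTI and re-loading it: signals
    are already frames x voxels over the full mask, so this truncates,
    subsamples and assembles in memory.
    """
    t_min = (
        min(dataset.task_lengths.values()) if truncate_to is None else truncate_to
    )
    bolds: dict[str, dict[str, BoldMatrix]] = {}
    for sub in subjects:
        bolds[sub] = {}
        for task in TASKS:
            sig = dataset.signals[(sub, task)][:t_min]
            bolds[sub][task] = BoldMatrix(
                data=sig,
                subject_id=sub,
                task_id=task,
                tr=dataset.gt.tr,
                voxel_index=sampling.mask_indices,
            )
    return assemble_group_matrix(bolds, sampling, subjects=subjects)
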